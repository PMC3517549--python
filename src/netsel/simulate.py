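"""Simulation of codon alignments along a tree under GY94 models.

Root codons are drawn from the stationary frequencies; each branch then
evolves states with the transition matrix exp(Qt).  For site-class
models the omega class of a site is drawn once and shared across the
whole tree (site-specific selection regimes, as the mixture models
assume).  All randomness flows through an explicit seed.
"""

from __future__ import annotations

import numpy as np

from ._genetic_code import SENSE_CODONS
from .alignment import CodonAlignment
from .codon_model import CodonModelSpec, ReversibleMatrixExponential
from .likelihood import mixture_rate_matrices
from .tree import PhylogeneticTree


def _sample_rows(P_cum: np.ndarray, states: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Vectorized categorical draw: next state per site from cumulative rows."""
    rows = P_cum[states]
    return (rows < u[:, None]).sum(axis=1)


def simulate_codon_alignment(
    tree: PhylogeneticTree,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int,
    branch_omegas: dict[str, float] | None = None,
) -> CodonAlignment:
    """Simulate an in-frame codon alignment.

    Parameters
    ----------
    tree
        Topology with branch lengths in expected substitutions per codon.
    spec
        Site model (M0/M1a/M2a/M7/M8/M8a).  If ``branch_omegas`` maps
        edge ids to omega values, those override the site mixture on the
        named branches (two-ratio style simulation) and the spec must be
        M0.
    n_codons
        Number of codon sites (>= 1).
    seed
        Seed for the generator; identical seeds give identical alignments.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    pi = spec.codon_frequencies

    if branch_omegas is not None:
        if spec.model_id != "M0":
            raise ValueError("branch_omegas requires an M0 base spec")
        unknown = sorted(set(branch_omegas) - set(tree.edge_ids))
        if unknown:
            raise ValueError(f"branch_omegas names unknown edges: {unknown}")

    omegas, probs = spec.site_classes()
    mats = mixture_rate_matrices(pi, spec.kappa, omegas, probs)
    # cumulative transition rows per (class, branch) are built lazily
    expms = [ReversibleMatrixExponential(Q, pi) for Q in mats]

    site_class = (
        rng.choice(len(omegas), size=n_codons, p=probs)
        if len(omegas) > 1
        else np.zeros(n_codons, dtype=np.int64)
    )
    states = {tree.root: np.searchsorted(np.cumsum(pi), rng.random(n_codons))}

    edge_id_of = dict(zip(tree.edge_nodes(), tree.edge_ids))
    # preorder = reversed postorder
    for node in tree.postorder[::-1]:
        if tree.parent[node] < 0:
            continue
        parent_states = states[tree.parent[node]]
        t = float(tree.lengths[node])
        child = np.empty(n_codons, dtype=np.int64)
        override = (
            branch_omegas.get(edge_id_of[node]) if branch_omegas is not None else None
        )
        if override is not None:
            from .codon_model import _unnormalized_rate_matrix

            Q = _unnormalized_rate_matrix(pi, spec.kappa, override)
            mu = -(pi * np.diag(Q)).sum()
            P_cum = np.cumsum(
                ReversibleMatrixExponential(Q / mu, pi).probabilities(t), axis=1
            )
            child = _sample_rows(P_cum, parent_states, rng.random(n_codons))
        else:
            for k in range(len(omegas)):
                sites = np.where(site_class == k)[0]
                if sites.size == 0:
                    continue
                P_cum = np.cumsum(expms[k].probabilities(t), axis=1)
                child[sites] = _sample_rows(
                    P_cum, parent_states[sites], rng.random(sites.size)
                )
        states[node] = child

    taxa = list(tree.taxa)
    sequences = [
        "".join(SENSE_CODONS[s] for s in states[leaf]) for leaf in range(tree.n_leaves)
    ]
    return CodonAlignment(taxa=taxa, sequences=sequences)
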