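"""Phylogenetic likelihood of codon alignments by Felsenstein pruning.

Site patterns are compressed once and partial likelihoods are
propagated as (61, n_patterns) arrays, so each edge costs a single
matrix product.  Per-pattern log scaling keeps deep trees from
underflowing.  Site-class mixtures share one generator normalization:
the mixture-averaged substitution rate is one per codon per unit branch
length, so branch lengths are comparable across M0 and the site models.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from ._genetic_code import N_CODONS
from .alignment import MISSING, CodonAlignment
from .codon_model import (
    CodonModelSpec,
    ReversibleMatrixExponential,
    _unnormalized_rate_matrix,
)
from .tree import PhylogeneticTree


class LikelihoodError(ValueError):
    """Raised when a likelihood cannot be computed."""


def mixture_rate_matrices(
    pi: np.ndarray, kappa: float, omegas: np.ndarray, probs: np.ndarray
) -> list[np.ndarray]:
    """Per-class generators sharing the mixture-average normalization."""
    raw = [_unnormalized_rate_matrix(pi, kappa, w) for w in omegas]
    mus = np.array([-(pi * np.diag(Q)).sum() for Q in raw])
    mu = float(probs @ mus)
    if mu <= 0:
        raise LikelihoodError("degenerate mixture: zero expected substitution rate")
    return [Q / mu for Q in raw]


class PruningEngine:
    """Reusable pruning machinery bound to one alignment/tree pair.

    Taxa present in the tree but absent from the alignment contribute a
    partial-likelihood vector of ones (missing data).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhylogeneticTree,
        mask_stops: bool = False,
    ):
        tree.check_taxa(alignment.taxa)
        self.tree = tree
        mat = alignment.codon_matrix(mask_stops=mask_stops)
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_counts = counts.astype(float)
        self.site_to_pattern = inverse
        self.n_patterns = patterns.shape[1]
        self.n_sites = mat.shape[1]
        # states per tree leaf (MISSING for taxa absent from the alignment)
        row_of = {t: i for i, t in enumerate(alignment.taxa)}
        self.leaf_states = np.full((tree.n_leaves, self.n_patterns), MISSING, np.int64)
        for leaf, taxon in enumerate(tree.taxa):
            if taxon in row_of:
                self.leaf_states[leaf] = patterns[row_of[taxon]]
        self._children = [tree.children(n) for n in range(tree.n_nodes)]

    # -- single rate class ---------------------------------------------

    def _class_pattern_loglik(
        self,
        expm: ReversibleMatrixExponential,
        lengths: np.ndarray,
        pi: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern log likelihood under a single generator."""
        return self._pattern_loglik_edgewise(
            {n: expm for n in range(self.tree.n_nodes)}, lengths, pi
        )

    def _pattern_loglik_edgewise(
        self,
        expm_by_node: dict[int, ReversibleMatrixExponential],
        lengths: np.ndarray,
        pi: np.ndarray,
    ) -> np.ndarray:
        """Per-pattern log likelihood with a (possibly distinct) generator per edge."""
        tree = self.tree
        partial: dict[int, np.ndarray] = {}
        logscale = np.zeros(self.n_patterns)
        for node in tree.postorder:
            kids = self._children[node]
            if not kids:
                continue
            L = np.ones((N_CODONS, self.n_patterns))
            for child in kids:
                P = expm_by_node[child].probabilities(lengths[child])
                if child < tree.n_leaves:
                    states = self.leaf_states[child]
                    contrib = np.ones((N_CODONS, self.n_patterns))
                    observed = states != MISSING
                    contrib[:, observed] = P[:, states[observed]]
                else:
                    contrib = P @ partial.pop(child)
                L *= contrib
            m = L.max(axis=0)
            if np.any(m <= 0):
                bad = int(np.where(self.site_to_pattern == np.argmin(m))[0][0])
                raise LikelihoodError(
                    f"zero partial likelihood at codon site {bad + 1}"
                )
            L /= m
            logscale += np.log(m)
            partial[node] = L
        root_L = partial[tree.root]
        site_lik = pi @ root_L
        if np.any(site_lik <= 0):
            bad = int(np.where(self.site_to_pattern == np.argmin(site_lik))[0][0])
            raise LikelihoodError(f"zero likelihood at codon site {bad + 1}")
        return np.log(site_lik) + logscale

    # -- site-class mixtures -------------------------------------------

    def pattern_loglik(
        self, spec: CodonModelSpec, lengths: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-pattern log likelihood under a site model spec.

        ``lengths`` (per-node branch lengths, tree node order) defaults
        to the tree's own.
        """
        if lengths is None:
            lengths = self.tree.lengths
        pi = spec.codon_frequencies
        omegas, probs = spec.site_classes()
        mats = mixture_rate_matrices(pi, spec.kappa, omegas, probs)
        per_class = np.empty((len(omegas), self.n_patterns))
        for k, Q in enumerate(mats):
            expm = ReversibleMatrixExponential(Q, pi)
            per_class[k] = self._class_pattern_loglik(expm, lengths, pi)
        if len(omegas) == 1:
            return per_class[0]
        with np.errstate(divide="ignore"):
            logw = np.log(probs)
        return logsumexp(per_class + logw[:, None], axis=0)

    def log_likelihood(
        self, spec: CodonModelSpec, lengths: np.ndarray | None = None
    ) -> float:
        return float(self.pattern_counts @ self.pattern_loglik(spec, lengths))

    # -- branch models --------------------------------------------------

    def branch_log_likelihood(
        self,
        spec: CodonModelSpec,
        omega_by_node: dict[int, float],
        lengths: np.ndarray | None = None,
    ) -> float:
        """Log likelihood with a distinct omega per edge (branch model).

        Each edge's generator is normalized by its own stationary rate,
        so every branch length stays in substitutions per codon.
        """
        if lengths is None:
            lengths = self.tree.lengths
        pi = spec.codon_frequencies
        cache: dict[float, ReversibleMatrixExponential] = {}
        expm_by_node: dict[int, ReversibleMatrixExponential] = {}
        for node in self.tree.edge_nodes():
            w = omega_by_node[node]
            if w not in cache:
                Q = _unnormalized_rate_matrix(pi, spec.kappa, w)
                mu = -(pi * np.diag(Q)).sum()
                if mu <= 0:
                    raise LikelihoodError("degenerate branch rate matrix")
                cache[w] = ReversibleMatrixExponential(Q / mu, pi)
            expm_by_node[node] = cache[w]
        pat = self._pattern_loglik_edgewise(expm_by_node, lengths, pi)
        return float(self.pattern_counts @ pat)


def log_likelihood(
    alignment: CodonAlignment,
    tree: PhylogeneticTree,
    spec: CodonModelSpec,
    mask_stops: bool = False,
) -> float:
    """Pruning log likelihood of ``alignment`` on ``tree`` under ``spec``."""
    return PruningEngine(alignment, tree, mask_stops=mask_stops).log_likelihood(spec)
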