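"""Generators emulating the study's inputs, so every stage runs offline.

Three generators: per-gene feature tables with a prescribed Spearman
correlation structure (Gaussian copula), pathway-wide codon-alignment
datasets with a position-graded omega (the signature the analysis is
meant to detect), and tiny engineered hit tables exercising each branch
of the homology decision rules.  Everything is deterministic under a
fixed seed and truth tables are always returned beside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_model import CodonModelSpec, uniform_frequencies
from .orthology import HitRecord, OrthologyCall
from .simulate import simulate_codon_alignment
from .tree import PhylogeneticTree

# -- feature tables ------------------------------------------------------


@dataclass(frozen=True)
class ZeroInflatedGeometric:
    """Connectivity-style marginal: excess zeros plus a geometric tail."""

    p_zero: float = 0.15
    p_geom: float = 0.035  # mean tail degree ~ 1/p_geom

    def ppf(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        tail = u > self.p_zero
        rescaled = (u[tail] - self.p_zero) / (1.0 - self.p_zero)
        out[tail] = stats.geom.ppf(rescaled, self.p_geom)
        return out


def default_marginals() -> dict[str, object]:
    """Marginals shaped like the reference TLR gene table."""
    return {
        "position": stats.randint(1, 9),
        "protein_length": stats.uniform(220, 830),
        "connectivity": ZeroInflatedGeometric(),
        "enc": stats.uniform(41, 16),
        "omega": stats.loguniform(0.005, 0.3),
    }


_INTEGER_COLUMNS = {"position", "protein_length", "connectivity"}


def _spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Normal-copula correlation giving a target Spearman rho."""
    return 2.0 * np.sin(np.pi * rho / 6.0)


def generate_feature_table(
    n: int,
    target_spearman: pd.DataFrame,
    marginals: dict[str, object] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian-copula feature table with a target Spearman structure.

    ``target_spearman`` must be symmetric with unit diagonal and
    positive semidefinite after conversion to the normal-copula scale;
    its index/columns name the output columns.  Marginals default to
    :func:`default_marginals` for known columns and standard normal
    otherwise; columns in ``{position, protein_length, connectivity}``
    are rounded to integers.
    """
    cols = list(target_spearman.columns)
    R = target_spearman.to_numpy(dtype=float)
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0):
        raise ValueError("target matrix must be symmetric with unit diagonal")
    C = _spearman_to_pearson(R)
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10:
        clipped = np.linalg.eigh(C)
        V = clipped.eigenvectors
        w = np.clip(clipped.eigenvalues, 1e-10, None)
        nearest = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(nearest))
        nearest = nearest / np.outer(d, d)
        raise ValueError(
            "target correlation matrix is not positive semidefinite; "
            f"nearest PSD candidate:\n{np.round(nearest, 3)}"
        )
    defaults = default_marginals()
    marginals = {**defaults, **(marginals or {})}
    rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(np.zeros(len(cols)), C, size=n, method="svd")
    U = stats.norm.cdf(Z)
    table = {}
    for j, col in enumerate(cols):
        dist = marginals.get(col, stats.norm())
        values = np.asarray(dist.ppf(U[:, j]), dtype=float)
        if col in _INTEGER_COLUMNS:
            values = np.round(values)
        table[col] = values
    out = pd.DataFrame(table, index=[f"gene{i + 1}" for i in range(n)])
    out.index.name = "gene"
    return out


# -- pathway datasets ----------------------------------------------------

#: a small vertebrate-like tree; lengths in substitutions per codon
DEFAULT_SCENARIO_TREE = "((A:0.08,B:0.10):0.06,(C:0.12,D:0.15):0.05,E:0.25);"


@dataclass
class PathwayScenario:
    """Design of a synthetic signaling-pathway dataset.

    Genes are placed on pathway positions 1-8; each gene's true omega
    follows a linear gradient from ``omega_upstream`` (position 1) to
    ``omega_downstream`` (position 8) with multiplicative lognormal
    noise (keeping omega positive).  All genes share the tree and kappa.
    """

    n_genes_per_position: dict[int, int] = field(
        default_factory=lambda: {p: 5 for p in range(1, 9)}
    )
    omega_upstream: float = 0.25
    omega_downstream: float = 0.02
    tree_newick: str = DEFAULT_SCENARIO_TREE
    kappa: float = 2.0
    n_codons: int = 200
    omega_noise_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_genes_per_position) != set(range(1, 9)):
            raise ValueError("positions must cover 1..8")
        if self.omega_upstream <= 0 or self.omega_downstream <= 0:
            raise ValueError("omega gradient endpoints must be > 0")

    def omega_at(self, position: int) -> float:
        frac = (position - 1) / 7.0
        return self.omega_upstream + frac * (self.omega_downstream - self.omega_upstream)


def generate_pathway_dataset(
    scenario: PathwayScenario,
) -> tuple[dict[str, object], pd.DataFrame]:
    """Simulate one alignment per gene of the scenario.

    Returns ``(alignments, truth)`` where ``truth`` has one row per
    gene with its position and the omega its alignment was actually
    simulated under.
    """
    rng = np.random.default_rng(scenario.seed)
    tree = PhylogeneticTree.from_newick(scenario.tree_newick)
    alignments: dict[str, object] = {}
    rows = []
    for position in range(1, 9):
        for k in range(scenario.n_genes_per_position[position]):
            gene = f"pos{position}_gene{k + 1}"
            noise = (
                np.exp(rng.normal(0.0, scenario.omega_noise_sigma))
                if scenario.omega_noise_sigma > 0
                else 1.0
            )
            omega = scenario.omega_at(position) * noise
            spec = CodonModelSpec(
                "M0",
                kappa=scenario.kappa,
                omega_params={"omega": omega},
                codon_frequencies=uniform_frequencies(),
            )
            sim_seed = int(rng.integers(0, 2**31 - 1))
            alignments[gene] = simulate_codon_alignment(
                tree, spec, scenario.n_codons, seed=sim_seed
            )
            rows.append({"gene": gene, "position": position, "true_omega": omega})
    truth = pd.DataFrame(rows).set_index("gene")
    return alignments, truth


# -- hit tables ----------------------------------------------------------

HIT_CASES = ("rbh", "fallback", "non_homolog", "absent", "tie")


def generate_hit_tables(
    case: str, seed: int = 0
) -> tuple[list[HitRecord], list[HitRecord], list[OrthologyCall]]:
    """Engineered hit tables with known expected verdicts.

    Cases: ``rbh`` (clean reciprocal best hit), ``fallback``
    (non-reciprocal but above the identity/similarity rescue
    thresholds), ``non_homolog`` (non-reciprocal and below them),
    ``absent`` (nothing survives filtering) and ``tie`` (equal top
    scores resolved by the documented tie order).  The seed only
    perturbs score digits that cannot change any verdict.
    """
    if case not in HIT_CASES:
        raise ValueError(f"unknown case {case!r}; choose from {HIT_CASES}")
    rng = np.random.default_rng(seed)

    def jitter() -> float:
        return float(np.round(rng.uniform(0.0, 0.4), 2))

    if case == "rbh":
        ab = [HitRecord("geneA1", "geneB1", 420.0 + jitter(), 310, 62.0, 78.0, 0.92)]
        ba = [HitRecord("geneB1", "geneA1", 415.0 + jitter(), 305, 61.0, 77.0, 0.90)]
        expected = [OrthologyCall("geneA1", "target", "ortholog_rbh")]
    elif case == "fallback":
        ab = [HitRecord("geneA1", "geneB1", 200.0 + jitter(), 180, 35.0, 45.0, 0.80)]
        # B1's best hit goes to a different A gene, breaking reciprocity
        ba = [
            HitRecord("geneB1", "geneA2", 300.0 + jitter(), 200, 55.0, 70.0, 0.95),
            HitRecord("geneB1", "geneA1", 190.0 + jitter(), 170, 34.0, 44.0, 0.75),
        ]
        expected = [OrthologyCall("geneA1", "target", "homolog_fallback")]
    elif case == "non_homolog":
        ab = [HitRecord("geneA1", "geneB1", 160.0 + jitter(), 120, 20.0, 30.0, 0.50)]
        ba = [HitRecord("geneB1", "geneA2", 300.0 + jitter(), 200, 55.0, 70.0, 0.95)]
        expected = [OrthologyCall("geneA1", "target", "non_homolog")]
    elif case == "absent":
        ab = [HitRecord("geneA1", "geneB1", 90.0 + jitter(), 40, 25.0, 35.0, 0.20)]
        ba = []
        expected = [OrthologyCall("geneA1", "target", "absent")]
    else:  # tie
        ab = [
            HitRecord("geneA1", "geneB2", 250.0, 200, 50.0, 65.0, 0.85),
            HitRecord("geneA1", "geneB1", 250.0, 200, 50.0, 65.0, 0.85),
        ]
        # tie resolves to the lexicographically smaller subject, geneB1,
        # whose best hit reciprocates
        ba = [
            HitRecord("geneB1", "geneA1", 250.0, 200, 50.0, 65.0, 0.85),
            HitRecord("geneB2", "geneA9", 300.0, 220, 55.0, 70.0, 0.90),
        ]
        expected = [OrthologyCall("geneA1", "target", "ortholog_rbh")]
    return ab, ba, expected
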