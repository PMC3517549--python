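"""The GY94 codon substitution model and its site-class extensions.

The instantaneous rate from sense codon *i* to *j* is nonzero only when
the codons differ at a single nucleotide position::

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

with ``pi`` the stationary codon frequencies, ``kappa`` the
transition/transversion rate ratio and ``omega`` the
nonsynonymous/synonymous rate ratio (dN/dS).  The generator is scaled so
that one unit of time equals one expected substitution per codon.

Site-class models place a small mixture of omega values over codon
sites: M0 (one ratio), M1a (nearly neutral), M2a (positive selection),
M7 (beta), M8 (beta plus a selection class) and M8a (M8 with the extra
class pinned at omega = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import betainc

from ._genetic_code import (
    CODON_INDEX,
    IS_NONSYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_CHANGE,
)
from .alignment import MISSING, CodonAlignment

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8", "M8a")
MODEL_IDS = SITE_MODELS + ("branch",)

_FREQ_FLOOR = 1e-10  # keeps the chain irreducible when a codon is unobserved


class ModelError(ValueError):
    """Raised for invalid model specifications."""


def uniform_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f61_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Empirical codon frequencies pooled over all sequences (F61)."""
    mat = alignment.codon_matrix(mask_stops=True)
    counts = np.bincount(mat[mat != MISSING].ravel(), minlength=N_CODONS).astype(float)
    counts = np.maximum(counts, _FREQ_FLOOR)
    return counts / counts.sum()


def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4).

    pi_codon is proportional to the product of the observed nucleotide
    frequencies at the three codon positions, renormalized over the 61
    sense codons.
    """
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    pos_counts = np.zeros((3, 4), dtype=float)
    for seq in alignment.sequences:
        for i, base in enumerate(seq):
            j = nt_index.get(base)
            if j is not None:
                pos_counts[i % 3, j] += 1
    pos_freq = pos_counts / np.maximum(pos_counts.sum(axis=1, keepdims=True), 1.0)
    pi = np.empty(N_CODONS)
    for codon, idx in CODON_INDEX.items():
        pi[idx] = np.prod([pos_freq[k, nt_index[c]] for k, c in enumerate(codon)])
    pi = np.maximum(pi, _FREQ_FLOOR)
    return pi / pi.sum()


def _validate_frequencies(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,):
        raise ModelError(f"codon frequencies must have length {N_CODONS}")
    if np.any(pi < 0):
        raise ModelError("codon frequencies must be nonnegative")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ModelError(f"codon frequencies sum to {pi.sum():.8f}, not 1")
    return pi / pi.sum()


@dataclass
class CodonModelSpec:
    """Parameters of a GY94 model variant.

    ``omega_params`` is model-dependent:

    ======  ==========================================================
    M0      ``omega``
    M1a     ``p0`` (weight of the 0 <= omega0 <= 1 class), ``omega0``
    M2a     ``p0``, ``p1``, ``omega0``, ``omega2`` (>= 1)
    M7      ``p``, ``q`` (beta shape)
    M8      ``p0`` (beta weight), ``p``, ``q``, ``omega_s`` (>= 1)
    M8a     ``p0``, ``p``, ``q`` (extra class fixed at omega = 1)
    branch  ``omega_background``, ``omega_foreground``
    ======  ==========================================================
    """

    model_id: str
    kappa: float = 2.0
    omega_params: dict[str, float] = field(default_factory=dict)
    codon_frequencies: np.ndarray = field(default_factory=uniform_frequencies)
    n_classes: int = 10

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ModelError(f"unknown model {self.model_id!r}; choose from {MODEL_IDS}")
        if self.kappa < 0:
            raise ModelError("kappa must be >= 0")
        self.codon_frequencies = _validate_frequencies(self.codon_frequencies)
        self.omega_params = dict(self.omega_params)
        self._check_omega_params()

    def _check_omega_params(self) -> None:
        p = self.omega_params
        mid = self.model_id
        def need(*keys):
            missing = [k for k in keys if k not in p]
            if missing:
                raise ModelError(f"{mid} requires omega_params {missing}")
        if mid == "M0":
            need("omega")
            if p["omega"] < 0:
                raise ModelError("omega must be >= 0")
        elif mid == "M1a":
            need("p0", "omega0")
            if not (0 <= p["p0"] <= 1 and 0 <= p["omega0"] <= 1):
                raise ModelError("M1a requires 0<=p0<=1 and 0<=omega0<=1")
        elif mid == "M2a":
            need("p0", "p1", "omega0", "omega2")
            if not (0 <= p["p0"] and 0 <= p["p1"] and p["p0"] + p["p1"] <= 1):
                raise ModelError("M2a class proportions invalid")
            if not (0 <= p["omega0"] <= 1 and p["omega2"] >= 1):
                raise ModelError("M2a requires omega0 in [0,1] and omega2 >= 1")
        elif mid == "M7":
            need("p", "q")
            if p["p"] <= 0 or p["q"] <= 0:
                raise ModelError("beta shapes must be > 0")
        elif mid in ("M8", "M8a"):
            need("p0", "p", "q")
            if not 0 <= p["p0"] <= 1:
                raise ModelError("p0 must be in [0,1]")
            if p["p"] <= 0 or p["q"] <= 0:
                raise ModelError("beta shapes must be > 0")
            if mid == "M8":
                need("omega_s")
                if p["omega_s"] < 1:
                    raise ModelError("M8 requires omega_s >= 1")
        elif mid == "branch":
            need("omega_background", "omega_foreground")
            if p["omega_background"] < 0 or p["omega_foreground"] < 0:
                raise ModelError("branch omegas must be >= 0")

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(omega values, class probabilities) of the site mixture."""
        p = self.omega_params
        mid = self.model_id
        if mid == "M0":
            return np.array([p["omega"]]), np.array([1.0])
        if mid == "M1a":
            return (
                np.array([p["omega0"], 1.0]),
                np.array([p["p0"], 1.0 - p["p0"]]),
            )
        if mid == "M2a":
            p2 = 1.0 - p["p0"] - p["p1"]
            return (
                np.array([p["omega0"], 1.0, p["omega2"]]),
                np.array([p["p0"], p["p1"], p2]),
            )
        if mid == "M7":
            w = discretize_beta(p["p"], p["q"], self.n_classes)
            return w, np.full(self.n_classes, 1.0 / self.n_classes)
        if mid in ("M8", "M8a"):
            w = discretize_beta(p["p"], p["q"], self.n_classes)
            ws = p["omega_s"] if mid == "M8" else 1.0
            omegas = np.append(w, ws)
            probs = np.append(
                np.full(self.n_classes, p["p0"] / self.n_classes), 1.0 - p["p0"]
            )
            return omegas, probs
        raise ModelError(f"{mid} has no site-class mixture")

    def with_params(self, **updates) -> "CodonModelSpec":
        """Copy with omega_params / kappa replaced."""
        new_omega = dict(self.omega_params)
        kappa = updates.pop("kappa", self.kappa)
        new_omega.update(updates)
        return replace(self, kappa=kappa, omega_params=new_omega)


def discretize_beta(p: float, q: float, k: int) -> np.ndarray:
    """Mean omega in each of ``k`` equal-probability classes of Beta(p, q).

    The class mean over the quantile bin [a, b] is
    ``p/(p+q) * (I_b(p+1, q) - I_a(p+1, q)) / (1/k)`` with I the
    regularized incomplete beta function.
    """
    if p <= 0 or q <= 0:
        raise ModelError("beta shapes must be > 0")
    from scipy.stats import beta as beta_dist

    edges = beta_dist.ppf(np.linspace(0, 1, k + 1), p, q)
    upper = betainc(p + 1, q, edges)
    means = (p / (p + q)) * np.diff(upper) * k
    return np.clip(means, 0.0, 1.0)


def build_rate_matrix(
    spec: CodonModelSpec, omega_value: float | None = None
) -> np.ndarray:
    """Normalized GY94 generator for a single omega value.

    ``omega_value`` overrides the spec's omega (used when expanding a
    site-class mixture); for M0 it defaults to the fitted omega.  The
    returned matrix has rows summing to zero and is scaled so the
    expected substitution rate at stationarity is one per codon.
    """
    if omega_value is None:
        if spec.model_id != "M0":
            raise ModelError("omega_value is required for non-M0 specs")
        omega_value = spec.omega_params["omega"]
    if omega_value < 0 or spec.kappa < 0:
        raise ModelError("kappa and omega must be >= 0")
    pi = spec.codon_frequencies
    Q = _unnormalized_rate_matrix(pi, spec.kappa, omega_value)
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    return Q / mu


def _unnormalized_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[SINGLE_CHANGE] = np.broadcast_to(pi, (N_CODONS, N_CODONS))[SINGLE_CHANGE]
    Q[SINGLE_CHANGE & IS_TRANSITION] *= kappa
    Q[SINGLE_CHANGE & IS_NONSYNONYMOUS] *= omega
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to one, entries clipped at zero."""
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    P = linalg.expm(Q * t)
    P[P < 0] = 0.0
    return P


class ReversibleMatrixExponential:
    """Fast P(t) for a reversible generator via its symmetrized eigenform.

    With D = diag(pi), the matrix B = D^1/2 Q D^-1/2 is symmetric; its
    eigendecomposition gives P(t) = D^-1/2 U exp(L t) U' D^1/2 for any
    batch of branch lengths at the cost of one 61x61 ``eigh``.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        self.eigenvalues, U = np.linalg.eigh(B)
        self.left = U / d[:, None] * 1.0  # D^-1/2 U
        self.right = (U * d[:, None]).T  # U' D^1/2

    def probabilities(self, t: float) -> np.ndarray:
        if t < 0:
            raise ModelError(f"branch length must be >= 0, got {t}")
        P = (self.left * np.exp(self.eigenvalues * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        return P
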