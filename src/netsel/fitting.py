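"""Maximum-likelihood fitting of GY94 codon models.

Branch lengths and model parameters are optimized jointly with
L-BFGS-B after mapping every constrained parameter to an unconstrained
scale (log for positive rates and branch lengths, logit/softmax for
class proportions).  Site-model likelihood surfaces can be multimodal,
so extra random starts are available via ``n_starts``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import chi2

from ._genetic_code import IS_NONSYNONYMOUS, SINGLE_CHANGE
from .alignment import CodonAlignment
from .codon_model import CodonModelSpec, ModelError, build_rate_matrix
from .likelihood import LikelihoodError, PruningEngine
from .tree import PhylogeneticTree

_LOG_BL_BOUNDS = (np.log(1e-6), np.log(20.0))
_LOG_KAPPA_BOUNDS = (np.log(1e-2), np.log(1e2))
_LOG_OMEGA_BOUNDS = (np.log(1e-6), np.log(50.0))
_LOGIT_BOUNDS = (-12.0, 12.0)
_LOG_BETA_BOUNDS = (np.log(5e-3), np.log(99.0))
_INIT_BRANCH_LENGTH = 0.1

OMEGA_UNDEFINED = float("nan")  #: sentinel when ds = 0


@dataclass
class ModelFit:
    """Result of a maximum-likelihood codon-model fit."""

    spec: CodonModelSpec
    log_likelihood: float
    branch_lengths: dict[str, float]
    dn: float | None = None
    ds: float | None = None
    omega: float | None = None
    converged: bool = True
    n_evaluations: int = 0
    notes: list[str] = field(default_factory=list)
    branch_omegas: dict[str, float] | None = None

    @property
    def tree_length(self) -> float:
        return float(sum(self.branch_lengths.values()))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


def _model_parameterization(spec: CodonModelSpec):
    """(x0, bounds, decode) for the free model parameters of ``spec``.

    ``decode(x)`` returns keyword updates for ``spec.with_params``.
    """
    p = spec.omega_params
    mid = spec.model_id
    x0 = [np.log(max(spec.kappa, 1e-2))]
    bounds = [_LOG_KAPPA_BOUNDS]

    if mid == "M0":
        x0 += [np.log(max(p.get("omega", 0.4), 1e-6))]
        bounds += [_LOG_OMEGA_BOUNDS]

        def decode(x):
            return {"kappa": np.exp(x[0]), "omega": np.exp(x[1])}

    elif mid == "M1a":
        x0 += [_logit(p.get("p0", 0.7)), _logit(p.get("omega0", 0.2))]
        bounds += [_LOGIT_BOUNDS, _LOGIT_BOUNDS]

        def decode(x):
            return {
                "kappa": np.exp(x[0]),
                "p0": float(_sigmoid(x[1])),
                "omega0": float(_sigmoid(x[2])),
            }

    elif mid == "M2a":
        p0, p1 = p.get("p0", 0.6), p.get("p1", 0.3)
        p2 = max(1.0 - p0 - p1, 1e-4)
        x0 += [
            np.log(p0 / p2),
            np.log(p1 / p2),
            _logit(p.get("omega0", 0.2)),
            np.log(max(p.get("omega2", 2.0) - 1.0, 1e-6)),
        ]
        bounds += [_LOGIT_BOUNDS, _LOGIT_BOUNDS, _LOGIT_BOUNDS, _LOG_OMEGA_BOUNDS]

        def decode(x):
            ex = np.exp([x[1], x[2], 0.0])
            probs = ex / ex.sum()
            return {
                "kappa": np.exp(x[0]),
                "p0": float(probs[0]),
                "p1": float(probs[1]),
                "omega0": float(_sigmoid(x[3])),
                "omega2": 1.0 + float(np.exp(x[4])),
            }

    elif mid == "M7":
        x0 += [np.log(p.get("p", 1.0)), np.log(p.get("q", 2.0))]
        bounds += [_LOG_BETA_BOUNDS, _LOG_BETA_BOUNDS]

        def decode(x):
            return {"kappa": np.exp(x[0]), "p": np.exp(x[1]), "q": np.exp(x[2])}

    elif mid in ("M8", "M8a"):
        x0 += [
            _logit(p.get("p0", 0.9)),
            np.log(p.get("p", 1.0)),
            np.log(p.get("q", 2.0)),
        ]
        bounds += [_LOGIT_BOUNDS, _LOG_BETA_BOUNDS, _LOG_BETA_BOUNDS]
        if mid == "M8":
            x0 += [np.log(max(p.get("omega_s", 2.0) - 1.0, 1e-6))]
            bounds += [_LOG_OMEGA_BOUNDS]

        def decode(x):
            out = {
                "kappa": np.exp(x[0]),
                "p0": float(_sigmoid(x[1])),
                "p": np.exp(x[2]),
                "q": np.exp(x[3]),
            }
            if mid == "M8":
                out["omega_s"] = 1.0 + float(np.exp(x[4]))
            return out

    elif mid == "branch":
        x0 += [
            np.log(max(p.get("omega_background", 0.4), 1e-6)),
            np.log(max(p.get("omega_foreground", 1.0), 1e-6)),
        ]
        bounds += [_LOG_OMEGA_BOUNDS, _LOG_OMEGA_BOUNDS]

        def decode(x):
            return {
                "kappa": np.exp(x[0]),
                "omega_background": np.exp(x[1]),
                "omega_foreground": np.exp(x[2]),
            }

    else:  # pragma: no cover - guarded by CodonModelSpec
        raise ModelError(f"cannot fit model {mid}")

    return np.array(x0), bounds, decode


def fit_model(
    alignment: CodonAlignment,
    tree: PhylogeneticTree,
    spec: CodonModelSpec,
    n_starts: int = 1,
    seed: int = 0,
    mask_stops: bool = False,
    max_iterations: int = 500,
) -> ModelFit:
    """Maximize the pruning likelihood over branch lengths and free parameters.

    Returns a :class:`ModelFit`; on optimizer failure after all starts
    the best point found is returned with ``converged=False`` rather
    than raising.  For M0 the dn/ds decomposition is filled in.
    """
    if alignment.n_taxa < 2:
        raise ModelError("need at least 2 taxa to fit a model")
    engine = PruningEngine(alignment, tree, mask_stops=mask_stops)
    edge_nodes = tree.edge_nodes()
    n_edges = len(edge_nodes)
    x0_model, model_bounds, decode = _model_parameterization(spec)
    x0 = np.concatenate([np.full(n_edges, np.log(_INIT_BRANCH_LENGTH)), x0_model])
    bounds = [_LOG_BL_BOUNDS] * n_edges + model_bounds

    n_eval = 0
    lengths_full = np.zeros(tree.n_nodes)

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        lengths_full[edge_nodes] = np.exp(x[:n_edges])
        try:
            cand = spec.with_params(**decode(x[n_edges:]))
            return -engine.log_likelihood(cand, lengths_full)
        except (LikelihoodError, ModelError, FloatingPointError):
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for start in range(max(n_starts, 1)):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, 0.5, size=x0.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            objective,
            xs,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iterations, "ftol": 1e-11, "gtol": 1e-7},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    x = best.x
    fitted = spec.with_params(**decode(x[n_edges:]))
    lengths = np.exp(x[:n_edges])
    branch_lengths = dict(zip(tree.edge_ids, (float(v) for v in lengths)))
    fit = ModelFit(
        spec=fitted,
        log_likelihood=float(-best.fun),
        branch_lengths=branch_lengths,
        converged=any_success,
        n_evaluations=n_eval,
    )
    if np.all(lengths <= np.exp(_LOG_BL_BOUNDS[0]) * 1.01):
        fit.notes.append(
            "all branch lengths at lower bound; omega is not identifiable"
        )
    if fitted.model_id == "M0":
        fit.dn, fit.ds = compute_dn_ds(fit)
        fit.omega = (
            fit.dn / fit.ds if fit.ds and fit.ds > 0 else OMEGA_UNDEFINED
        )
    return fit


def compute_dn_ds(fit: ModelFit) -> tuple[float, float]:
    """Tree-total dn and ds from a converged M0 fit.

    With the normalized generator Q(omega), the nonsynonymous share of
    the substitution flow is rho_N = sum over nonsynonymous pairs of
    pi_i q_ij; site proportions p_N, p_S come from the same matrix with
    omega = 1.  Then dn = T rho_N / (3 p_N) and ds = T rho_S / (3 p_S)
    with T the tree length in substitutions per codon, which makes
    dn/ds equal the fitted omega by construction.
    """
    spec = fit.spec
    if spec.model_id != "M0":
        raise ModelError("dn/ds decomposition is defined for M0 fits")
    pi = spec.codon_frequencies
    nonsyn = SINGLE_CHANGE & IS_NONSYNONYMOUS

    Q = build_rate_matrix(spec)
    rho_n = float((pi[:, None] * Q)[nonsyn].sum())
    rho_s = 1.0 - rho_n

    Q1 = build_rate_matrix(spec.with_params(omega=1.0))
    p_n = float((pi[:, None] * Q1)[nonsyn].sum())
    p_s = 1.0 - p_n

    T = fit.tree_length
    dn = T * rho_n / (3.0 * p_n) if p_n > 0 else 0.0
    ds = T * rho_s / (3.0 * p_s) if p_s > 0 else 0.0
    return dn, ds


def likelihood_ratio_test(
    null_fit: ModelFit, alt_fit: ModelFit, df: int
) -> tuple[float, float]:
    """2(lnL_alt - lnL_null) against a chi-square with ``df`` degrees.

    The statistic is clipped at zero; an alternative likelihood more
    than optimizer tolerance below the null records a warning (it means
    the alternative optimization failed, since the models are nested).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if delta < -1e-4:
        warnings.warn(
            f"alternative lnL below null by {-delta / 2:.6g}; "
            "optimization of the alternative model likely failed",
            stacklevel=2,
        )
    stat = max(delta, 0.0)
    return stat, float(chi2.sf(stat, df))


def fit_branch_model(
    alignment: CodonAlignment,
    tree: PhylogeneticTree,
    foreground_branches: set[str],
    kappa: float = 2.0,
    n_starts: int = 1,
    seed: int = 0,
    mask_stops: bool = False,
) -> tuple[dict[str, float], ModelFit]:
    """Two-ratio branch model: one omega for ``foreground_branches``,
    one for the rest; kappa and frequencies shared.

    Returns the per-edge omega map and the fit.  An empty foreground
    collapses to M0; a foreground covering every branch also collapses
    to a single ratio (with a warning).
    """
    edge_ids = set(tree.edge_ids)
    unknown = sorted(foreground_branches - edge_ids)
    if unknown:
        raise ModelError(f"foreground branches not in tree: {unknown}")

    from .codon_model import f3x4_frequencies

    pi = f3x4_frequencies(alignment)
    if not foreground_branches or foreground_branches == edge_ids:
        if foreground_branches == edge_ids:
            warnings.warn("foreground covers all branches; collapsing to M0")
        m0 = CodonModelSpec("M0", kappa=kappa, omega_params={"omega": 0.4},
                            codon_frequencies=pi)
        fit = fit_model(alignment, tree, m0, n_starts=n_starts, seed=seed,
                        mask_stops=mask_stops)
        w = fit.spec.omega_params["omega"]
        return {e: w for e in tree.edge_ids}, fit

    engine = PruningEngine(alignment, tree, mask_stops=mask_stops)
    edge_nodes = tree.edge_nodes()
    n_edges = len(edge_nodes)
    ids = tree.edge_ids
    fg_mask = np.array([e in foreground_branches for e in ids])

    spec = CodonModelSpec(
        "branch",
        kappa=kappa,
        omega_params={"omega_background": 0.4, "omega_foreground": 1.0},
        codon_frequencies=pi,
    )
    x0_model, model_bounds, decode = _model_parameterization(spec)
    x0 = np.concatenate([np.full(n_edges, np.log(_INIT_BRANCH_LENGTH)), x0_model])
    bounds = [_LOG_BL_BOUNDS] * n_edges + model_bounds

    n_eval = 0
    lengths_full = np.zeros(tree.n_nodes)

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        lengths_full[edge_nodes] = np.exp(x[:n_edges])
        params = decode(x[n_edges:])
        cand = spec.with_params(**params)
        omega_by_node = {
            node: params["omega_foreground"] if fg else params["omega_background"]
            for node, fg in zip(edge_nodes, fg_mask)
        }
        try:
            return -engine.branch_log_likelihood(cand, omega_by_node, lengths_full)
        except (LikelihoodError, ModelError):
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for start in range(max(n_starts, 1)):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, 0.5, size=x0.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        res = optimize.minimize(
            objective, xs, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    params = decode(best.x[n_edges:])
    fitted = spec.with_params(**params)
    lengths = np.exp(best.x[:n_edges])
    omega_map = {
        e: params["omega_foreground"] if fg else params["omega_background"]
        for e, fg in zip(ids, fg_mask)
    }
    fit = ModelFit(
        spec=fitted,
        log_likelihood=float(-best.fun),
        branch_lengths=dict(zip(ids, (float(v) for v in lengths))),
        converged=any_success,
        n_evaluations=n_eval,
        branch_omegas=omega_map,
    )
    return omega_map, fit
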