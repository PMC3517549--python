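"""Multivariate statistics relating selection pressure to pathway structure.

Three layers, all over a per-gene feature table: tie-corrected Spearman
rank correlations, partial correlations (residual method), and path
analysis — standardized OLS of each endogenous variable on its parents
in a user-declared causal DAG, with direct/indirect effect
decomposition along directed paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class CorrelationResult:
    """A correlation estimate with its two-sided p-value."""

    rho: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-9:
            raise ValueError(f"|rho| > 1: {self.rho}")


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of pairwise correlations with p-values."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    method: str

    def __getitem__(self, pair: tuple[str, str]) -> CorrelationResult:
        a, b = pair
        return CorrelationResult(
            float(self.rho.loc[a, b]), float(self.p.loc[a, b]), self.n, self.method
        )


def spearman_matrix(
    table: pd.DataFrame, variables: list[str] | None = None
) -> CorrelationMatrix:
    """Tie-corrected (mid-rank) Spearman correlations between columns.

    p-values use the t approximation with n - 2 degrees of freedom.
    Pairs involving a constant column get NaN.
    """
    if variables is None:
        variables = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    data = table[variables].dropna()
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 complete rows")
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        x, y = data[variables[i]], data[variables[j]]
        if x.nunique() < 2 or y.nunique() < 2:
            rho[i, j] = rho[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
            continue
        r, pv = stats.spearmanr(x, y)
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
        n=n,
        method="spearman",
    )


def partial_correlation(
    table: pd.DataFrame,
    x: str,
    y: str,
    controls: list[str],
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation between ``x`` and ``y`` after regressing out ``controls``.

    Both variables are regressed (with intercept) on the control set —
    on mid-ranks when ``method="rank"`` — and the residuals are
    correlated.  The p-value uses a t statistic with
    n - len(controls) - 2 degrees of freedom.
    """
    if method not in ("pearson", "rank"):
        raise ValueError("method must be 'pearson' or 'rank'")
    overlap = set(controls) & {x, y}
    if overlap:
        raise ValueError(f"controls overlap x/y: {sorted(overlap)}")
    cols = [x, y, *controls]
    data = table[cols].dropna().astype(float)
    n = len(data)
    if n <= len(controls) + 2:
        raise ValueError(f"need n > {len(controls) + 2} rows, got {n}")
    if method == "rank":
        data = data.rank()
    design = np.column_stack(
        [np.ones(n)] + [data[c].to_numpy() for c in controls]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear control set {controls}: design rank {rank} < {design.shape[1]}"
        )
    beta_x, *_ = np.linalg.lstsq(design, data[x].to_numpy(), rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, data[y].to_numpy(), rcond=None)
    rx = data[x].to_numpy() - design @ beta_x
    ry = data[y].to_numpy() - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - len(controls) - 2
    if abs(r) >= 1.0:
        pv = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        pv = float(2.0 * stats.t.sf(abs(t), df))
    tag = f"partial-{method}|{','.join(controls)}" if controls else method
    return CorrelationResult(r, pv, n, tag)


@dataclass
class CausalPathModel:
    """A causal DAG over feature-table columns.

    ``exogenous`` variables have no modeled parents; every other
    variable appearing in ``edges`` is endogenous and is fitted by
    standardized OLS on its parents.  After :func:`fit_path_model`,
    ``coefficients`` maps each edge to its standardized beta and
    ``p_values`` to the two-sided p-value; ``exogenous_correlations``
    reports the undirected associations among exogenous variables.
    """

    exogenous: list[str]
    edges: list[tuple[str, str]]
    coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    exogenous_correlations: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child in self.exogenous:
            for src, dst in self.edges:
                if dst == child:
                    raise ValueError(f"exogenous variable {child!r} has parent {src!r}")
        self._check_acyclic()
        for v in self.endogenous:
            if not self.parents(v):
                raise ValueError(f"endogenous variable {v!r} has no parents")

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = dict.fromkeys(self.exogenous)
        for src, dst in self.edges:
            seen.setdefault(src)
            seen.setdefault(dst)
        return list(seen)

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.variables if v not in self.exogenous]

    def parents(self, variable: str) -> list[str]:
        return [s for s, d in self.edges if d == variable]

    def _check_acyclic(self) -> None:
        order = self.topological_order()
        if order is None:
            raise ValueError("edge set contains a directed cycle")

    def topological_order(self) -> list[str] | None:
        indeg = {v: 0 for v in self.variables}
        for _, d in self.edges:
            indeg[d] += 1
        queue = [v for v, k in indeg.items() if k == 0]
        order = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for s, d in self.edges:
                if s == v:
                    indeg[d] -= 1
                    if indeg[d] == 0:
                        queue.append(d)
        return order if len(order) == len(self.variables) else None


def fit_path_model(
    table: pd.DataFrame, model: CausalPathModel, method: str = "pearson"
) -> CausalPathModel:
    """Fit standardized path coefficients by per-equation OLS.

    Each endogenous variable is z-scored and regressed on its z-scored
    parents (mid-ranked first when ``method="rank"``); the slope on a
    parent is the standardized path coefficient of that edge.
    """
    if method not in ("pearson", "rank"):
        raise ValueError("method must be 'pearson' or 'rank'")
    data = table[model.variables].dropna().astype(float)
    if method == "rank":
        data = data.rank()
    z = (data - data.mean()) / data.std(ddof=1)

    fitted = CausalPathModel(exogenous=list(model.exogenous), edges=list(model.edges))
    for dep in model.endogenous:
        parents = model.parents(dep)
        X = sm.add_constant(z[parents])
        res = sm.OLS(z[dep], X).fit()
        for parent in parents:
            fitted.coefficients[(parent, dep)] = float(res.params[parent])
            fitted.p_values[(parent, dep)] = float(res.pvalues[parent])
    for a, b in itertools.combinations(model.exogenous, 2):
        fitted.exogenous_correlations[(a, b)] = float(z[a].corr(z[b]))
    return fitted


def decompose_effects(
    fitted: CausalPathModel, source: str, target: str
) -> tuple[float, float, float]:
    """(direct, indirect, total) standardized effect of ``source`` on ``target``.

    Direct is the coefficient on the source->target edge (0 if absent);
    indirect sums the products of coefficients along every directed
    path of length >= 2; total is their sum.
    """
    if not fitted.coefficients:
        raise ValueError("model is not fitted")
    direct = fitted.coefficients.get((source, target), 0.0)
    children: dict[str, list[str]] = {}
    for s, d in fitted.edges:
        children.setdefault(s, []).append(d)

    indirect = 0.0

    def walk(node: str, product: float, length: int) -> None:
        nonlocal indirect
        for nxt in children.get(node, []):
            contrib = product * fitted.coefficients[(node, nxt)]
            if nxt == target:
                if length + 1 >= 2:
                    indirect += contrib
            else:
                walk(nxt, contrib, length + 1)

    walk(source, 1.0, 0)
    return direct, indirect, direct + indirect
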