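"""Reproduction of the published pathway-level statistics from the
packaged reference table: the bivariate Spearman matrix, the reported
partial correlations, and the path-analysis coefficients, each shown
beside its published value.

The published values live only in the ``REFERENCE_*`` constants below;
every ``computed`` number is recomputed from the fixture at call time.
"""

from __future__ import annotations

import pandas as pd

from .io import load_fixture_table
from .network_stats import (
    CausalPathModel,
    fit_path_model,
    partial_correlation,
    spearman_matrix,
)

#: published Spearman correlations of the reference table
REFERENCE_SPEARMAN = {
    ("position", "omega"): -0.575,
    ("position", "dn"): -0.439,
    ("position", "ds"): 0.243,
    ("position", "enc"): -0.321,
    ("position", "connectivity"): 0.479,
    ("position", "protein_length"): -0.447,
    ("omega", "dn"): 0.849,
    ("omega", "connectivity"): -0.331,
    ("omega", "protein_length"): 0.493,
    ("dn", "ds"): 0.305,
    ("dn", "protein_length"): 0.480,
    ("ds", "enc"): -0.306,
    ("ds", "connectivity"): 0.285,
    ("enc", "protein_length"): 0.358,
    ("connectivity", "protein_length"): -0.308,
}

#: published partial correlations: (x, y, controls) -> r
REFERENCE_PARTIALS = {
    ("position", "omega", ("connectivity",)): -0.676,
    ("connectivity", "omega", ("position",)): -0.103,
    ("position", "connectivity", ("omega",)): 0.136,
    ("dn", "position", ("omega",)): 0.095,
    ("dn", "omega", ("position", "connectivity")): 0.738,
    ("protein_length", "position", ("omega",)): -0.215,
    ("protein_length", "dn", ("omega",)): 0.050,
    ("protein_length", "connectivity", ("omega",)): 0.001,
}

#: published standardized path coefficients: (parent, child) -> beta
REFERENCE_PATH_BETAS = {
    ("position", "dn"): -0.448,
    ("protein_length", "dn"): 0.347,
    ("enc", "dn"): -0.290,
    ("dn", "omega"): 0.649,
    ("position", "omega"): -0.269,
}


def default_path_model() -> CausalPathModel:
    """The shipped causal diagram over the feature-table variables.

    Pathway position, protein length and connectivity are exogenous;
    codon bias (ENC), dn and omega are endogenous, with omega receiving
    dn and position directly plus the codon-bias and protein-length
    controls.
    """
    return CausalPathModel(
        exogenous=["position", "protein_length", "connectivity"],
        edges=[
            ("position", "enc"),
            ("protein_length", "enc"),
            ("position", "dn"),
            ("protein_length", "dn"),
            ("enc", "dn"),
            ("dn", "omega"),
            ("position", "omega"),
            ("enc", "omega"),
            ("protein_length", "omega"),
        ],
    )


def reproduce_report(
    table: pd.DataFrame | None = None, method: str = "pearson"
) -> pd.DataFrame:
    """Recompute every published statistic from the gene table.

    Returns a tidy frame with one row per quantity: section, quantity,
    computed value, computed p-value and the published value.  The
    partials and path coefficients are computed under the requested
    convention (``pearson`` on raw values, or ``rank``).
    """
    if table is None:
        table = load_fixture_table()
    rows = []

    corr = spearman_matrix(
        table,
        ["position", "omega", "dn", "ds", "enc", "connectivity", "protein_length"],
    )
    for (a, b), published in REFERENCE_SPEARMAN.items():
        res = corr[a, b]
        rows.append(
            {
                "section": "spearman",
                "quantity": f"rho({a}, {b})",
                "computed": res.rho,
                "p_value": res.p_value,
                "published": published,
            }
        )

    for (x, y, controls), published in REFERENCE_PARTIALS.items():
        res = partial_correlation(table, x, y, list(controls), method=method)
        rows.append(
            {
                "section": "partial",
                "quantity": f"r({x}, {y} | {', '.join(controls)})",
                "computed": res.rho,
                "p_value": res.p_value,
                "published": published,
            }
        )

    fitted = fit_path_model(table, default_path_model(), method=method)
    for (parent, child), published in REFERENCE_PATH_BETAS.items():
        rows.append(
            {
                "section": "path",
                "quantity": f"beta({parent} -> {child})",
                "computed": fitted.coefficients[(parent, child)],
                "p_value": fitted.p_values[(parent, child)],
                "published": published,
            }
        )
    report = pd.DataFrame(rows)
    report["difference"] = report["computed"] - report["published"]
    return report
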