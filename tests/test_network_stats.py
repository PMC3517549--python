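import numpy as np
import pandas as pd
import pytest

from netsel.network_stats import (
    CausalPathModel,
    decompose_effects,
    fit_path_model,
    partial_correlation,
    spearman_matrix,
)
from netsel.reproduce import default_path_model

from _oracles import partial_corr_recursive, spearman_midrank


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        table = pd.DataFrame({"x": [1, 2, 3], "y": [10, 20, 30], "z": [30, 20, 10]})
        corr = spearman_matrix(table)
        assert corr["x", "y"].rho == pytest.approx(1.0)
        assert corr["x", "z"].rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_formula(self):
        x = [3.0, 1.0, 1.0, 2.0, 5.0, 5.0]
        y = [1.0, 2.0, 2.0, 2.0, 4.0, 3.0]
        corr = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert corr["x", "y"].rho == pytest.approx(spearman_midrank(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        base = spearman_matrix(pd.DataFrame({"x": x, "y": y}))["x", "y"].rho
        warped = spearman_matrix(
            pd.DataFrame({"x": np.exp(x), "y": y**3})
        )["x", "y"].rho
        assert warped == pytest.approx(base, abs=1e-12)

    def test_constant_column_gives_nan(self):
        table = pd.DataFrame({"x": [1, 2, 3, 4], "y": [7, 7, 7, 7]})
        corr = spearman_matrix(table)
        assert np.isnan(corr["x", "y"].rho)

    def test_fixture_position_omega(self, fixture_table):
        corr = spearman_matrix(fixture_table)
        assert corr["position", "omega"].rho == pytest.approx(-0.575, abs=0.05)
        assert corr["position", "omega"].p_value < 0.001


class TestPartialCorrelation:
    def test_empty_controls_equals_simple_correlation(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"])
        res = partial_correlation(table, "x", "y", [])
        assert res.rho == pytest.approx(float(table["x"].corr(table["y"])), abs=1e-12)

    def test_orthogonal_control_leaves_r_unchanged(self):
        # control exactly orthogonal to x and y by construction
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        y = np.array([2.0, -2.0, 3.0, -3.0, 1.0, -1.0])
        z = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])  # sums against x, y to 0
        assert abs(np.dot(x - x.mean(), z - z.mean())) < 1e-12
        assert abs(np.dot(y - y.mean(), z - z.mean())) < 1e-12
        table = pd.DataFrame({"x": x, "y": y, "z": z})
        simple = partial_correlation(table, "x", "y", [])
        partial = partial_correlation(table, "x", "y", ["z"])
        assert partial.rho == pytest.approx(simple.rho, abs=1e-12)

    def test_residual_method_matches_recursion_formula(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(5, 3)), columns=["x", "y", "z"])
        res = partial_correlation(table, "x", "y", ["z"])
        r = table.corr()
        expected = partial_corr_recursive(
            r.loc["x", "y"], r.loc["x", "z"], r.loc["y", "z"]
        )
        assert res.rho == pytest.approx(expected, abs=1e-10)

    def test_collinear_controls_named(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=["x", "y", "a"])
        table["b"] = 2 * table["a"]
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(table, "x", "y", ["a", "b"])

    def test_control_overlap_rejected(self):
        table = pd.DataFrame(np.eye(4), columns=list("wxyz"))
        with pytest.raises(ValueError, match="overlap"):
            partial_correlation(table, "x", "y", ["x"])

    def test_fixture_position_omega_given_connectivity(self, fixture_table):
        res = partial_correlation(
            fixture_table, "position", "omega", ["connectivity"]
        )
        assert res.rho == pytest.approx(-0.676, abs=0.07)
        assert res.p_value < 0.001


class TestPathModel:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            CausalPathModel(exogenous=[], edges=[("a", "b"), ("b", "a")])

    def test_exogenous_with_parent_rejected(self):
        with pytest.raises(ValueError, match="exogenous"):
            CausalPathModel(exogenous=["a"], edges=[("b", "a")])

    def test_single_parent_beta_equals_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        table = pd.DataFrame({"x": x, "y": y})
        model = CausalPathModel(exogenous=["x"], edges=[("x", "y")])
        fitted = fit_path_model(table, model)
        assert fitted.coefficients[("x", "y")] == pytest.approx(
            float(table["x"].corr(table["y"])), abs=1e-12
        )

    def test_recovers_generative_coefficients(self):
        """Data generated from a linear DAG: betas recovered within 0.03."""
        rng = np.random.default_rng(5)
        n = 5000
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        b1, b2 = 0.5, -0.3
        resid_sd = np.sqrt(1 - b1**2 - b2**2)  # z1, z2 independent
        y = b1 * z1 + b2 * z2 + resid_sd * rng.normal(size=n)
        w = 0.7 * y + np.sqrt(1 - 0.49) * rng.normal(size=n)
        table = pd.DataFrame({"z1": z1, "z2": z2, "y": y, "w": w})
        model = CausalPathModel(
            exogenous=["z1", "z2"],
            edges=[("z1", "y"), ("z2", "y"), ("y", "w")],
        )
        fitted = fit_path_model(table, model)
        assert fitted.coefficients[("z1", "y")] == pytest.approx(b1, abs=0.03)
        assert fitted.coefficients[("z2", "y")] == pytest.approx(b2, abs=0.03)
        assert fitted.coefficients[("y", "w")] == pytest.approx(0.7, abs=0.03)

    def test_fixture_dn_equation(self, fixture_table):
        fitted = fit_path_model(fixture_table, default_path_model())
        assert fitted.coefficients[("position", "dn")] == pytest.approx(-0.448, abs=0.07)
        assert fitted.coefficients[("protein_length", "dn")] == pytest.approx(0.347, abs=0.07)
        assert fitted.coefficients[("enc", "dn")] == pytest.approx(-0.290, abs=0.07)


class TestDecomposeEffects:
    def _chain(self, b1, b2):
        model = CausalPathModel(exogenous=["a"], edges=[("a", "b"), ("b", "c")])
        model.coefficients = {("a", "b"): b1, ("b", "c"): b2}
        return model

    def test_chain_indirect_is_product(self):
        direct, indirect, total = decompose_effects(self._chain(0.5, 0.4), "a", "c")
        assert direct == 0.0
        assert indirect == pytest.approx(0.2)
        assert total == pytest.approx(0.2)

    def test_zero_beta_edge_leaves_total_unchanged(self):
        model = CausalPathModel(
            exogenous=["a"], edges=[("a", "b"), ("b", "c"), ("a", "c")]
        )
        model.coefficients = {("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.0}
        direct, indirect, total = decompose_effects(model, "a", "c")
        assert direct == 0.0
        assert total == pytest.approx(0.2)

    def test_no_path_gives_zeros(self):
        model = CausalPathModel(exogenous=["a", "x"], edges=[("a", "b"), ("x", "b")])
        model.coefficients = {("a", "b"): 0.5, ("x", "b"): 0.1}
        assert decompose_effects(model, "a", "x") == (0.0, 0.0, 0.0)

    def test_fixture_length_effect_on_omega_via_dn(self, fixture_table):
        """Protein length reaches omega mostly through dn."""
        fitted = fit_path_model(fixture_table, default_path_model())
        direct, indirect, total = decompose_effects(fitted, "protein_length", "omega")
        via_dn = (
            fitted.coefficients[("protein_length", "dn")]
            * fitted.coefficients[("dn", "omega")]
        )
        via_enc = fitted.coefficients[("protein_length", "enc")] * (
            fitted.coefficients[("enc", "omega")]
            + fitted.coefficients[("enc", "dn")] * fitted.coefficients[("dn", "omega")]
        )
        assert indirect == pytest.approx(via_dn + via_enc, abs=1e-12)
        assert direct == fitted.coefficients[("protein_length", "omega")]
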