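import numpy as np
import pytest

from netsel._genetic_code import SENSE_CODONS
from netsel.alignment import CodonAlignment
from netsel.codon_model import CodonModelSpec, f3x4_frequencies, uniform_frequencies
from netsel.fitting import (
    ModelFit,
    compute_dn_ds,
    fit_branch_model,
    fit_model,
    likelihood_ratio_test,
)
from netsel.simulate import simulate_codon_alignment

from _oracles import brute_force_dn_ds


@pytest.fixture(scope="module")
def m0_fit(small_alignment, four_taxon_tree):
    pi = f3x4_frequencies(small_alignment)
    spec = CodonModelSpec("M0", omega_params={"omega": 0.4}, codon_frequencies=pi)
    return fit_model(small_alignment, four_taxon_tree, spec)


class TestFitM0:
    def test_converges_and_recovers_reasonable_omega(self, m0_fit):
        assert m0_fit.converged
        assert 0.05 < m0_fit.spec.omega_params["omega"] < 2.0
        assert np.isfinite(m0_fit.log_likelihood)

    def test_dn_ds_ratio_equals_fitted_omega(self, m0_fit):
        assert m0_fit.dn / m0_fit.ds == pytest.approx(
            m0_fit.spec.omega_params["omega"], abs=1e-6
        )

    def test_identical_sequences_flag_non_identifiable(self, four_taxon_tree):
        seq = "ATGAAACCCGGG" * 5
        aln = CodonAlignment(
            taxa=["A", "B", "C", "D"], sequences=[seq] * 4
        )
        spec = CodonModelSpec("M0", omega_params={"omega": 0.4})
        fit = fit_model(aln, four_taxon_tree, spec)
        assert all(v <= 1.1e-6 for v in fit.branch_lengths.values())
        assert any("identifiable" in note for note in fit.notes)


class TestDnDs:
    def test_neutral_omega_gives_equal_dn_ds(self):
        spec = CodonModelSpec("M0", kappa=2.0, omega_params={"omega": 1.0})
        fit = ModelFit(spec=spec, log_likelihood=0.0,
                       branch_lengths={"A": 0.6, "B": 0.4})
        dn, ds = compute_dn_ds(fit)
        assert dn == pytest.approx(ds, rel=1e-12)

    def test_matches_exhaustive_pair_enumeration(self):
        spec = CodonModelSpec("M0", kappa=2.0, omega_params={"omega": 0.5})
        fit = ModelFit(spec=spec, log_likelihood=0.0, branch_lengths={"A": 1.0})
        dn, ds = compute_dn_ds(fit)
        pi = spec.codon_frequencies
        exp_dn, exp_ds = brute_force_dn_ds(list(SENSE_CODONS), pi, 2.0, 0.5, 1.0)
        assert dn == pytest.approx(exp_dn, abs=1e-10)
        assert ds == pytest.approx(exp_ds, abs=1e-10)
        assert dn / ds == pytest.approx(0.5, abs=1e-12)


@pytest.fixture(scope="module")
def site_model_data(four_taxon_tree, m1a_spec):
    aln = simulate_codon_alignment(four_taxon_tree, m1a_spec, 100, seed=13)
    return aln, f3x4_frequencies(aln)


class TestNesting:

    def test_m8a_loglik_not_above_m8(self, site_model_data, four_taxon_tree):
        aln, pi = site_model_data
        null = fit_model(
            aln, four_taxon_tree,
            CodonModelSpec("M8a", omega_params={"p0": 0.9, "p": 1.0, "q": 2.0},
                           codon_frequencies=pi),
        )
        alt = fit_model(
            aln, four_taxon_tree,
            CodonModelSpec("M8", omega_params={"p0": 0.9, "p": 1.0, "q": 2.0,
                                               "omega_s": 2.0},
                           codon_frequencies=pi),
        )
        assert null.log_likelihood <= alt.log_likelihood + 1e-4

    def test_m1a_loglik_not_above_m2a(self, site_model_data, four_taxon_tree):
        aln, pi = site_model_data
        null = fit_model(
            aln, four_taxon_tree,
            CodonModelSpec("M1a", omega_params={"p0": 0.7, "omega0": 0.2},
                           codon_frequencies=pi),
        )
        alt = fit_model(
            aln, four_taxon_tree,
            CodonModelSpec("M2a", omega_params={"p0": 0.6, "p1": 0.3, "omega0": 0.2,
                                                "omega2": 2.0},
                           codon_frequencies=pi),
        )
        assert null.log_likelihood <= alt.log_likelihood + 1e-4


class TestLikelihoodRatioTest:
    def _fit(self, lnl):
        spec = CodonModelSpec("M0", omega_params={"omega": 0.5})
        return ModelFit(spec=spec, log_likelihood=lnl, branch_lengths={})

    def test_equal_likelihoods_give_zero_statistic(self):
        stat, p = likelihood_ratio_test(self._fit(-100.0), self._fit(-100.0), df=2)
        assert stat == 0.0
        assert p == 1.0

    def test_chi_square_critical_value(self):
        stat, p = likelihood_ratio_test(self._fit(-100.0), self._fit(-100.0 + 5.991 / 2), df=2)
        assert stat == pytest.approx(5.991)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_worse_alternative_clips_and_warns(self):
        with pytest.warns(UserWarning, match="optimization"):
            stat, p = likelihood_ratio_test(self._fit(-100.0), self._fit(-101.0), df=1)
        assert stat == 0.0
        assert p == 1.0


class TestBranchModel:
    def test_empty_foreground_equals_m0(self, small_alignment, four_taxon_tree):
        omega_map, fit = fit_branch_model(small_alignment, four_taxon_tree, set())
        pi = f3x4_frequencies(small_alignment)
        m0 = fit_model(
            small_alignment, four_taxon_tree,
            CodonModelSpec("M0", omega_params={"omega": 0.4}, codon_frequencies=pi),
        )
        assert fit.log_likelihood == pytest.approx(m0.log_likelihood, abs=1e-4)
        assert set(omega_map.values()) == {fit.spec.omega_params["omega"]}

    def test_all_foreground_warns_and_collapses(self, small_alignment, four_taxon_tree):
        with pytest.warns(UserWarning, match="all branches"):
            omega_map, fit = fit_branch_model(
                small_alignment, four_taxon_tree, set(four_taxon_tree.edge_ids)
            )
        assert len(set(omega_map.values())) == 1

    def test_two_ratio_loglik_not_below_one_ratio(self, small_alignment, four_taxon_tree):
        _, two = fit_branch_model(small_alignment, four_taxon_tree, {"C"})
        _, one = fit_branch_model(small_alignment, four_taxon_tree, set())
        assert two.log_likelihood >= one.log_likelihood - 1e-4

    def test_recovers_elevated_foreground_omega(self, four_taxon_tree):
        base = CodonModelSpec("M0", kappa=2.0, omega_params={"omega": 0.1})
        hits = 0
        for seed in range(3):
            aln = simulate_codon_alignment(
                four_taxon_tree, base, 800, seed=seed, branch_omegas={"C": 2.0}
            )
            omega_map, _ = fit_branch_model(aln, four_taxon_tree, {"C"})
            if omega_map["C"] > 1.0 and omega_map["A"] < 0.3:
                hits += 1
        assert hits >= 2

    def test_unknown_foreground_branch_rejected(self, small_alignment, four_taxon_tree):
        from netsel.codon_model import ModelError

        with pytest.raises(ModelError, match="nosuch"):
            fit_branch_model(small_alignment, four_taxon_tree, {"nosuch"})
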