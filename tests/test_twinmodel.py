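"""FIML engine, saturated/ACE fits, LRT, profile CIs, decomposition."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from twinlink.twinmodel import (
    PairData,
    decompose_rph,
    extract_correlations,
    falconer_estimates,
    fiml_neg2ll,
    fit_ace,
    fit_bivariate_ace,
    fit_saturated,
    lrt_compare,
    profile_ci,
)

from conftest import ace_moments, latent_pair_data


class TestFimlLikelihood:
    def test_single_observation_at_mean(self):
        y = np.array([[0.0]])
        assert fiml_neg2ll(y, np.zeros(1), np.ones((1, 1))) == pytest.approx(
            math.log(2 * math.pi), abs=1e-12
        )

    def test_complete_data_matches_reference_density(self):
        rng = np.random.default_rng(0)
        mu = rng.standard_normal(4)
        A = rng.standard_normal((4, 4))
        Sigma = A @ A.T + 4 * np.eye(4)
        Y = rng.multivariate_normal(mu, Sigma, size=1000)
        ref = -2.0 * stats.multivariate_normal(mu, Sigma).logpdf(Y).sum()
        assert fiml_neg2ll(Y, mu, Sigma) == pytest.approx(ref, abs=1e-8)

    def test_missing_entries_contribute_marginal_density(self):
        rng = np.random.default_rng(1)
        mu = np.array([0.5, -0.2, 1.0, 0.0])
        A = rng.standard_normal((4, 4))
        Sigma = A @ A.T + 3 * np.eye(4)
        row = np.array([0.3, -1.2, np.nan, np.nan])
        ref = -2.0 * stats.multivariate_normal(mu[:2], Sigma[:2, :2]).logpdf(row[:2])
        assert fiml_neg2ll(row[None, :], mu, Sigma) == pytest.approx(ref, abs=1e-8)

    def test_singular_subblock_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fiml_neg2ll(np.array([[1.0, 2.0]]), np.zeros(2), np.ones((2, 2)))


@pytest.fixture(scope="module")
def data():
    return latent_pair_data(seed=30, n_mz=800, n_dz=800, a2=(0.5, 0.4), rA=0.3, rE=0.1)


@pytest.fixture(scope="module")
def ae_fit_1000():
    d = latent_pair_data(seed=34, n_mz=1000, n_dz=1000, a2=(0.6, 0.5), rA=0.5, rE=0.2)
    return fit_bivariate_ace(d, "AE")


class TestSaturatedModels:
    def test_unconstrained_ml_equals_sample_moments(self, data):
        fit = fit_saturated(data, 0)
        mom = fit.group_moments()
        for g in ("MZ", "DZ"):
            Y = data.y[g]
            mu_hat, Sigma_hat = mom[g]
            assert np.allclose(mu_hat, Y.mean(axis=0), atol=1e-6)
            n = Y.shape[0]
            S = np.cov(Y, rowvar=False, ddof=0)  # n-divisor ML covariance
            assert np.allclose(Sigma_hat, S, atol=1e-5)

    def test_constrained_fit_never_beats_unconstrained(self, data):
        fits = [fit_saturated(data, lvl) for lvl in (0, 1, 2)]
        assert fits[0].neg2ll <= fits[1].neg2ll + 1e-6
        assert fits[1].neg2ll <= fits[2].neg2ll + 1e-6

    def test_twin_order_permutation_invariance(self, data):
        fit = fit_saturated(data, 1)
        permuted = data.permuted_twin_order(seed=5)
        refit = fit_saturated(permuted, 1)
        # the constrained family is exchangeable in twin order
        assert refit.neg2ll == pytest.approx(fit.neg2ll, abs=1e-6)

    def test_assumption_lrt_calibration(self):
        # truth satisfies the twin-order constraints, so the level-1 test
        # should be non-significant in about 95% of replicates
        n_pass = 0
        reps = 120
        for s in range(reps):
            d = latent_pair_data(seed=1000 + s, n_mz=400, n_dz=400, a2=(0.5, 0.5),
                                 rA=0.3, rE=0.1)
            res = lrt_compare(fit_saturated(d, 0), fit_saturated(d, 1))
            n_pass += res.p_value > 0.05
        assert 0.90 <= n_pass / reps <= 0.99

    def test_ctct_closed_form_on_population_moments(self):
        mu, Smz, Sdz = ace_moments(a2=(0.5, 0.5), c2=(0.0, 0.0), rA=0.4)
        data = PairData.from_moments(mu, Smz, mu, Sdz, n=4000)
        fit = fit_saturated(data, 2)
        corr = extract_correlations(fit)
        assert corr["ctct"]["MZ"]["estimate"] == pytest.approx(0.20, abs=1e-3)
        assert corr["ctct"]["DZ"]["estimate"] == pytest.approx(0.10, abs=1e-3)
        # symmetry of the two CTCT orderings is imposed by the constraint
        mom = fit.group_moments()
        B = mom["MZ"][1][2:, :2]
        assert B[0, 1] == pytest.approx(B[1, 0], abs=1e-12)

    def test_no_cross_trait_linkage_gives_zero_ctct(self):
        d = latent_pair_data(seed=31, n_mz=5000, n_dz=5000, a2=(0.5, 0.5),
                             rA=0.0, rE=0.0)
        corr = extract_correlations(fit_saturated(d, 2))
        assert abs(corr["ctct"]["MZ"]["estimate"]) < 0.03
        assert abs(corr["ctct"]["DZ"]["estimate"]) < 0.03

    def test_extraction_requires_constrained_fit(self, data):
        with pytest.raises(ValueError, match="level-2"):
            extract_correlations(fit_saturated(data, 0))


class TestACEFits:
    def test_oracle_equivalence_univariate(self):
        # ML on exact population moments reproduces the Falconer closed forms
        a2, c2 = 0.5, 0.2
        r_mz, r_dz = a2 + c2, 0.5 * a2 + c2
        Smz = np.array([[1.0, r_mz], [r_mz, 1.0]])
        Sdz = np.array([[1.0, r_dz], [r_dz, 1.0]])
        data = PairData.from_moments(np.zeros(2), Smz, np.zeros(2), Sdz, n=4000)
        fit = fit_ace(data, "ACE")
        std = fit.standardized()
        ref = falconer_estimates(r_mz, r_dz)
        assert std["a2_0"] == pytest.approx(ref[0], abs=1e-4)
        assert std["c2_0"] == pytest.approx(ref[1], abs=1e-4)
        assert std["e2_0"] == pytest.approx(ref[2], abs=1e-4)

    def test_oracle_equivalence_bivariate(self, moment_data):
        std = fit_bivariate_ace(moment_data, "ACE").standardized()
        assert std["a2_0"] == pytest.approx(0.5, abs=1e-4)
        assert std["c2_0"] == pytest.approx(0.2, abs=1e-4)
        assert std["rA"] == pytest.approx(0.3, abs=1e-4)
        assert std["rC"] == pytest.approx(0.1, abs=1e-3)
        assert std["rE"] == pytest.approx(0.1, abs=1e-4)

    def test_parameterizations_agree(self, simulated_ae_data):
        f1 = fit_bivariate_ace(simulated_ae_data, "ACE", param="cholesky")
        f2 = fit_bivariate_ace(simulated_ae_data, "ACE", param="correlated_factors")
        assert f1.neg2ll == pytest.approx(f2.neg2ll, abs=1e-6)

    def test_nesting_chain(self, simulated_ae_data):
        sat = fit_saturated(simulated_ae_data, 0)
        ace = fit_bivariate_ace(simulated_ae_data, "ACE")
        ae = fit_bivariate_ace(simulated_ae_data, "AE")
        e = fit_bivariate_ace(simulated_ae_data, "E")
        assert sat.neg2ll <= ace.neg2ll + 1e-6
        assert ace.neg2ll <= ae.neg2ll + 1e-6
        assert ae.neg2ll <= e.neg2ll + 1e-6

    def test_parameter_recovery(self, simulated_ae_data):
        std = fit_bivariate_ace(simulated_ae_data, "ACE").standardized()
        assert std["a2_0"] + std["c2_0"] == pytest.approx(0.6, abs=0.05)
        assert std["a2_1"] + std["c2_1"] == pytest.approx(0.5, abs=0.05)
        assert std["rA"] == pytest.approx(0.5, abs=0.07)

    def test_e_only_data_recovers_null(self):
        d = latent_pair_data(seed=32, a2=(0.0, 0.0), rA=0.0, rE=0.3)
        std = fit_bivariate_ace(d, "ACE").standardized()
        for key in ("a2_0", "a2_1", "c2_0", "c2_1"):
            assert std[key] < 0.05

    def test_component_sums_to_one(self, simulated_ae_data):
        for model in ("ACE", "AE", "CE", "E"):
            std = fit_bivariate_ace(simulated_ae_data, model).standardized()
            for i in (0, 1):
                total = std[f"a2_{i}"] + std[f"c2_{i}"] + std[f"e2_{i}"]
                assert total == pytest.approx(1.0, abs=1e-8)

    def test_unknown_model_rejected(self, simulated_ae_data):
        with pytest.raises(ValueError, match="unknown model"):
            fit_bivariate_ace(simulated_ae_data, "ADE")


class TestLRT:
    def test_identical_models(self):
        a = SimpleNamespace(neg2ll=100.0, n_free_params=8, model="AE")
        assert lrt_compare(a, a).p_value == 1.0
        assert lrt_compare(a, a).delta_neg2ll == 0.0

    def test_chi_square_reference(self):
        full = SimpleNamespace(neg2ll=100.0, n_free_params=9, model="ACE")
        nested = SimpleNamespace(neg2ll=103.84, n_free_params=8, model="AE")
        res = lrt_compare(full, nested)
        assert res.delta_df == 1
        assert res.p_value == pytest.approx(0.0500, abs=1e-3)

    def test_nested_beating_full_raises(self):
        full = SimpleNamespace(neg2ll=100.0, n_free_params=9, model="ACE")
        nested = SimpleNamespace(neg2ll=99.0, n_free_params=8, model="AE")
        with pytest.raises(RuntimeError, match="refit"):
            lrt_compare(full, nested)


class TestDecomposition:
    def test_pure_genetic_association_gives_unit_a_share(self):
        mu, Smz, Sdz = ace_moments(a2=(0.5, 0.5), c2=(0.0, 0.0), rA=0.4, rE=0.0)
        data = PairData.from_moments(mu, Smz, mu, Sdz, n=4000)
        dec = decompose_rph(fit_bivariate_ace(data, "AE"))
        assert dec.share_A == pytest.approx(1.0, abs=1e-4)
        assert dec.share_E == pytest.approx(0.0, abs=1e-4)

    def test_shares_sum_to_one_and_identity_holds(self, simulated_ae_data):
        fit = fit_bivariate_ace(simulated_ae_data, "ACE")
        dec = decompose_rph(fit)
        assert dec.share_A + dec.share_C + dec.share_E == pytest.approx(1.0, abs=1e-8)
        std = fit.standardized()
        contribution = (
            math.sqrt(std["a2_0"] * std["a2_1"]) * std["rA"]
            + math.sqrt(std["c2_0"] * std["c2_1"]) * std["rC"]
            + math.sqrt(std["e2_0"] * std["e2_1"]) * std["rE"]
        )
        assert contribution == pytest.approx(dec.rph_model, abs=1e-8)

    def test_zero_rph_rejected(self):
        d = latent_pair_data(seed=33, n_mz=500, n_dz=500, a2=(0.5, 0.5), rA=0.0, rE=0.0)
        fit = fit_bivariate_ace(d, "AE")
        if abs(fit.standardized()["rph"]) < 1e-6:
            with pytest.raises(ValueError, match="undefined"):
                decompose_rph(fit)
        else:
            dec = decompose_rph(fit)
            assert np.isfinite(dec.share_A)


class TestProfileCI:
    def test_interval_contains_estimate(self, ae_fit_1000):
        lo, hi = profile_ci(ae_fit_1000, "rA")
        assert lo <= ae_fit_1000.target("rA") <= hi

    def test_bound_sits_at_likelihood_threshold(self, ae_fit_1000):
        from scipy.optimize import minimize

        fit = ae_fit_1000
        lo, hi = profile_ci(fit, "a2_0")
        crit = stats.chi2.ppf(0.95, 1)
        for bound in (lo, hi):
            res = minimize(
                lambda th: fit._objective(th) or np.inf,
                fit.theta,
                method="SLSQP",
                constraints=[{"type": "eq",
                              "fun": lambda th: fit._derived(th)["a2_0"] - bound}],
                options={"maxiter": 300, "ftol": 1e-11},
            )
            assert res.fun - fit.neg2ll == pytest.approx(crit, abs=1e-2)

    def test_interval_width_shrinks_with_n(self):
        small = fit_bivariate_ace(
            latent_pair_data(seed=35, n_mz=300, n_dz=300, a2=(0.6, 0.5), rA=0.5, rE=0.2),
            "AE",
        )
        big = fit_bivariate_ace(
            latent_pair_data(seed=35, n_mz=3000, n_dz=3000, a2=(0.6, 0.5), rA=0.5, rE=0.2),
            "AE",
        )
        lo_s, hi_s = profile_ci(small, "rA")
        lo_b, hi_b = profile_ci(big, "rA")
        assert (hi_b - lo_b) < (hi_s - lo_s)


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz, r_dz, expected",
        [
            ((0.8), 0.4, (0.8, 0.0, 0.2)),
            (0.4, 0.4, (0.0, 0.4, 0.6)),
            (0.6, 0.2, (0.8, -0.2, 0.4)),  # negatives returned untruncated
        ],
    )
    def test_closed_forms(self, r_mz, r_dz, expected):
        assert falconer_estimates(r_mz, r_dz) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            falconer_estimates(1.5, 0.2)
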