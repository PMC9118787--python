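import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from oracles import bh_oracle, ols_normal_equations, sem_ml_oracle
from templag.crosslag import (
    bh_fdr,
    fit_crosslag,
    screen_features,
    sensitivity_wc,
    sex_heterogeneity,
)
from templag.synthetic_cohort import SyntheticTruth


def _null_corr4(r3=0.0):
    S = np.eye(4)
    S[0, 1] = S[1, 0] = r3
    return S


def _simulate_panel(rng, S, n=426):
    L = np.linalg.cholesky(S)
    X = rng.standard_normal((n, 4)) @ L.T
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    return X, np.corrcoef(X.T)


class TestFitCrosslag:
    def test_null_matrix_zero_paths(self):
        res = fit_crosslag(_null_corr4(0.3), 426)
        assert res.rho1 == res.rho2 == res.r1 == res.r2 == 0.0
        assert res.r3 == 0.3

    def test_orthogonal_predictors_reduce_to_correlations(self):
        S = np.eye(4)
        S[1, 2] = S[2, 1] = 0.25  # F1-B2
        S[0, 3] = S[3, 0] = 0.15  # B1-F2
        res = fit_crosslag(S, 426)
        assert res.rho1 == pytest.approx(0.25)
        assert res.rho2 == pytest.approx(0.15)

    def test_matches_ols_and_sem_oracle(self, rng):
        truth = SyntheticTruth(rho1=0.1, rho2=0.2, r1=0.4, r2=0.3, r3=0.25)
        X, S = _simulate_panel(rng, truth.implied_corr4())
        res = fit_crosslag(S, 426)
        # OLS route on the raw standardized data
        Xi = np.column_stack([np.ones(426), X[:, 0], X[:, 1]])
        beta_b, se_b, _ = ols_normal_equations(X[:, 2], Xi)
        beta_f, se_f, _ = ols_normal_equations(X[:, 3], Xi)
        assert res.r1 == pytest.approx(beta_b[1], abs=1e-8)
        assert res.rho1 == pytest.approx(beta_b[2], abs=1e-8)
        assert res.rho2 == pytest.approx(beta_f[1], abs=1e-8)
        assert res.r2 == pytest.approx(beta_f[2], abs=1e-8)
        assert res.se_rho1 == pytest.approx(se_b[2], abs=1e-8)
        assert res.se_rho2 == pytest.approx(se_f[1], abs=1e-8)
        # fit indices vs the generic numeric optimizer
        T, srmr, cfi = sem_ml_oracle(S, 426)
        assert res.chisq == pytest.approx(T, abs=1e-6)
        assert res.srmr == pytest.approx(srmr, abs=1e-6)
        assert res.cfi == pytest.approx(cfi, abs=1e-6)

    def test_collinear_r3_rejected(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 1.0
        with pytest.raises(ValueError):
            fit_crosslag(S, 426)

    def test_non_psd_rejected(self):
        S = np.eye(4)
        S[0, 1] = S[1, 0] = 0.9
        S[0, 2] = S[2, 0] = 0.9
        S[1, 2] = S[2, 1] = -0.9
        with pytest.raises(ValueError):
            fit_crosslag(S, 426)

    def test_saturated_fit_trivial_indices(self, rng):
        truth = SyntheticTruth(rho2=0.2)
        _, S = _simulate_panel(rng, truth.implied_corr4())
        res = fit_crosslag(S, 426, saturated=True)
        assert res.srmr == 0.0
        assert res.cfi == 1.0
        assert res.chisq == 0.0

    def test_cfi_one_when_chisq_below_df(self, rng):
        # data generated from the constrained model: often T <= df
        truth = SyntheticTruth()
        for seed in range(5):
            _, S = _simulate_panel(np.random.default_rng(seed), truth.implied_corr4())
            res = fit_crosslag(S, 426)
            if res.chisq <= res.df:
                assert res.cfi == 1.0
                break
        else:  # pragma: no cover
            pytest.fail("no draw with T <= df")

    def test_t_statistic_null_calibration(self):
        # under the generating model T ~ chi2(1); rejection near 5%
        rng = np.random.default_rng(7)
        truth = SyntheticTruth(rho1=0.05, rho2=0.15, r3=0.2)
        crit = stats.chi2.ppf(0.95, 1)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            _, S = _simulate_panel(rng, truth.implied_corr4())
            rejections += fit_crosslag(S, 426).chisq > crit
        assert 0.037 <= rejections / n_reps <= 0.064


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=50),
        st.integers(min_value=0, max_value=10**6),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle_and_permutation_equivariant(self, p, seed):
        p = np.asarray(p)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)
        perm = np.random.default_rng(seed).permutation(len(p))
        np.testing.assert_allclose(bh_fdr(p[perm]), bh_fdr(p)[perm], atol=1e-12)


class TestScreenFeatures:
    def test_screen_flags_planted_feature(self, small_cohort):
        cohort, record = small_cohort
        table = screen_features(cohort, alpha_fdr=0.25)
        assert len(table) == 30
        assert table.loc[record["crosslag_feature"], "sig_rho2"]

    def test_fdr_matches_oracle(self, small_cohort):
        cohort, _ = small_cohort
        table = screen_features(cohort)
        np.testing.assert_allclose(
            table["fdr_rho2"].to_numpy(), bh_oracle(table["p_rho2"].to_numpy()), atol=1e-12
        )
        np.testing.assert_allclose(
            table["fdr_rho1"].to_numpy(), bh_oracle(table["p_rho1"].to_numpy()), atol=1e-12
        )

    def test_empty_feature_set_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            screen_features(cohort, feature_set=[])


class TestSexHeterogeneity:
    def _frame(self, beta, se):
        return pd.DataFrame(
            {"rho2": beta, "se_rho2": se}, index=[f"f{i}" for i in range(len(beta))]
        )

    def test_identical_estimates_q_zero(self):
        f = self._frame([0.2, -0.1], [0.05, 0.05])
        out = sex_heterogeneity(f, f.copy())
        np.testing.assert_allclose(out["q"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p_heterogeneity"], 1.0)

    def test_hand_computed_q(self):
        # w = 1/0.01 = 100 per stratum, pooled beta = 0:
        # Q = 100*(0.5)^2 + 100*(-0.5)^2 = 50
        out = sex_heterogeneity(self._frame([0.5], [0.1]), self._frame([-0.5], [0.1]))
        assert out["q"].iloc[0] == pytest.approx(50.0, abs=1e-10)

    def test_symmetric_in_strata(self):
        a = self._frame([0.3, 0.1], [0.1, 0.2])
        b = self._frame([0.1, 0.4], [0.15, 0.1])
        np.testing.assert_allclose(
            sex_heterogeneity(a, b)["q"], sex_heterogeneity(b, a)["q"], atol=1e-12
        )

    def test_missing_stratum_feature_skipped(self):
        a = self._frame([0.3, 0.1], [0.1, 0.2])
        b = self._frame([0.1], [0.15])
        with pytest.warns(UserWarning, match="skipped"):
            out = sex_heterogeneity(a, b)
        assert len(out) == 1


class TestSensitivityWc:
    def test_wc_tracks_bmi(self, small_cohort):
        cohort, _ = small_cohort
        out = sensitivity_wc(cohort)
        # generator builds WC as a noisy affine map of BMI
        assert out["coef_corr_rho2"] > 0.6

    def test_affine_wc_gives_near_identical_coefficients(self, small_cohort):
        cohort, _ = small_cohort
        clone = type(cohort)(
            meta=cohort.meta.copy(),
            features_baseline=cohort.features_baseline,
            features_followup=cohort.features_followup,
        )
        clone.meta["wc_baseline"] = 2.0 * clone.meta["bmi_baseline"] + 30.0
        clone.meta["wc_followup"] = 2.0 * clone.meta["bmi_followup"] + 30.0
        out = sensitivity_wc(clone)
        assert out["coef_corr_rho2"] == pytest.approx(1.0, abs=1e-8)

    def test_independent_wc_attenuates(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(0)
        clone = type(cohort)(
            meta=cohort.meta.copy(),
            features_baseline=cohort.features_baseline,
            features_followup=cohort.features_followup,
        )
        clone.meta["wc_baseline"] = rng.normal(85, 9, cohort.n)
        clone.meta["wc_followup"] = rng.normal(85, 9, cohort.n)
        out_noise = sensitivity_wc(clone)
        out_real = sensitivity_wc(cohort)
        assert abs(out_noise["coef_corr_rho2"]) < abs(out_real["coef_corr_rho2"])

    def test_matches_double_run(self, small_cohort):
        cohort, _ = small_cohort
        out = sensitivity_wc(cohort)
        manual_wc = screen_features(cohort, exposure="wc")
        np.testing.assert_allclose(
            out["wc"]["rho2"].to_numpy(), manual_wc["rho2"].to_numpy(), atol=1e-12
        )
        expected = np.corrcoef(
            out["bmi"]["rho2"].to_numpy(), manual_wc["rho2"].to_numpy()
        )[0, 1]
        assert out["coef_corr_rho2"] == pytest.approx(expected, abs=1e-12)
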