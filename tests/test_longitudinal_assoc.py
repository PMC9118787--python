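import numpy as np
import pandas as pd
import pytest

from oracles import gls_fixed_effects, ols_normal_equations
from templag.io_profiles import PairedCohort
from templag.longitudinal_assoc import (
    compute_vif,
    fit_exposure_model,
    fit_mixed_assoc,
    fit_pattern_model,
    median_split,
    mixed_screen,
    pattern_screen,
)
from templag.synthetic_cohort import SyntheticTruth, generate_paired_cohort


def _pattern_cohort(rng, n=400, effect=-0.5):
    """Cohort whose follow-up feature is shifted in the stable-adiposity group."""
    bmi1 = rng.normal(23.5, 3.0, n)
    bmi2 = bmi1 + rng.normal(0, 1.0, n)
    meta = pd.DataFrame(
        {
            "bmi_baseline": np.clip(bmi1, 15, 40),
            "bmi_followup": np.clip(bmi2, 15, 40),
            "age": rng.normal(63, 5, n),
            "sex": rng.binomial(1, 0.3, n).astype(float),
            "smoking": rng.binomial(1, 0.1, n).astype(float),
            "alcohol": rng.binomial(1, 0.1, n).astype(float),
            "education": rng.integers(1, 4, n).astype(float),
            "income": rng.integers(1, 5, n).astype(float),
            "physical_activity": rng.normal(40, 12, n),
            "energy_intake": rng.normal(1800, 400, n),
            "bristol": rng.integers(1, 8, n).astype(float),
            "interval": rng.normal(3.15, 0.3, n),
        },
        index=[f"P{i:04d}" for i in range(n)],
    )
    stable_adi = (meta["bmi_baseline"] >= 24) & (meta["bmi_followup"] >= 24)
    f1 = rng.standard_normal(n)
    f2 = 0.3 * f1 + effect * stable_adi.to_numpy() + rng.standard_normal(n)
    feats_b = pd.DataFrame({"s__x": f1}, index=meta.index)
    feats_f = pd.DataFrame({"s__x": f2}, index=meta.index)
    return PairedCohort(meta=meta, features_baseline=feats_b, features_followup=feats_f), effect, f2


class TestPatternModel:
    def test_recovers_planted_contrast(self, rng):
        cohort, effect, f2 = _pattern_cohort(rng)
        results = fit_pattern_model(cohort, "s__x")
        res = {r.term: r for r in results}["stable_adiposity"]
        # effect in SD units of the outcome
        expected = effect / f2.std(ddof=1)
        assert res.ci95_low < expected < res.ci95_high
        assert res.beta == pytest.approx(expected, abs=0.2)

    def test_permuted_labels_null(self, rng):
        cohort, _, _ = _pattern_cohort(rng, effect=0.0)
        results = fit_pattern_model(cohort, "s__x")
        for r in results:
            assert abs(r.beta) < 0.35

    def test_matches_normal_equations(self, rng):
        cohort, _, _ = _pattern_cohort(rng)
        results = fit_pattern_model(cohort, "s__x")
        # rebuild the identical design directly
        from templag.adjust import zscore
        from templag.io_profiles import weight_change_pattern

        meta = cohort.meta
        pat = weight_change_pattern(
            meta["bmi_baseline"].to_numpy(), meta["bmi_followup"].to_numpy()
        )
        keep = pat != "excluded_underweight"
        cols = []
        present = [r.term for r in results]
        for c in present:
            cols.append((pat[keep] == c).astype(float))
        for cov in (
            "age", "sex", "smoking", "alcohol", "education", "income",
            "physical_activity", "energy_intake", "bristol", "interval",
        ):
            cols.append(meta.loc[keep, cov].to_numpy(dtype=float))
        cols.append(zscore(cohort.features_baseline["s__x"][keep].to_numpy()))
        Xi = np.column_stack([np.ones(keep.sum())] + cols)
        y = zscore(cohort.features_followup["s__x"][keep].to_numpy())
        beta, se, _ = ols_normal_equations(y, Xi)
        for k, r in enumerate(results):
            assert r.beta == pytest.approx(beta[1 + k], abs=1e-10)
            assert r.se == pytest.approx(se[1 + k], abs=1e-10)

    def test_ci_definition_invariant(self, rng):
        from scipy import stats

        cohort, _, _ = _pattern_cohort(rng)
        for r in fit_pattern_model(cohort, "s__x"):
            df = r.n - 15  # intercept + 3 contrasts + 10 covariates + baseline feature
            tcrit = stats.t.ppf(0.975, df)
            assert r.ci95_low == pytest.approx(r.beta - tcrit * r.se, abs=1e-8)

    def test_screen_assigns_fdr_per_contrast(self, small_cohort):
        cohort, _ = small_cohort
        table = pattern_screen(cohort, cohort.feature_ids[:5])
        for term, sub in table.groupby(level="term"):
            assert (sub["fdr"] >= sub["p"] - 1e-12).all()

    def test_pattern_sign_agrees_with_crosslag(self):
        # positive rho2 -> stable-adiposity contrast positive (mostly)
        agree = 0
        reps = 20
        for seed in range(reps):
            truth = SyntheticTruth(
                n_participants=300, n_species=5, rho2=0.3, seed=seed + 500
            )
            cohort, record = generate_paired_cohort(truth)
            res = {r.term: r for r in fit_pattern_model(cohort, record["crosslag_feature"])}
            agree += res["stable_adiposity"].beta > 0
        assert agree / reps >= 0.7


class TestMixedAssoc:
    def test_beta_recovery_random_intercept(self):
        betas = []
        b = -0.13
        for seed in range(25):
            truth = SyntheticTruth(
                seed=seed + 100, b=b, phenotype_model="random_intercept",
                icc_phenotype=0.5, n_species=10,
            )
            cohort, record = generate_paired_cohort(truth)
            betas.append(fit_mixed_assoc(cohort, record["mediator_feature"]).beta)
        # standardized truth: b / sd(Y) with Var(Y) ~ b^2 Var(M) + 1
        expected = b / np.sqrt(1 + b**2)
        assert np.mean(betas) == pytest.approx(expected, abs=0.02)

    def test_icc_recovery(self):
        iccs = []
        for seed in range(15):
            truth = SyntheticTruth(
                seed=seed + 300, b=-0.13, phenotype_model="random_intercept",
                icc_phenotype=0.5, n_species=10,
            )
            cohort, record = generate_paired_cohort(truth)
            iccs.append(fit_mixed_assoc(cohort, record["mediator_feature"]).icc)
        assert np.mean(iccs) == pytest.approx(0.5, abs=0.05)

    def test_zero_between_variance_matches_ols(self):
        truth = SyntheticTruth(
            seed=11, b=-0.2, phenotype_model="random_intercept",
            icc_phenotype=0.0, n_species=10,
        )
        cohort, record = generate_paired_cohort(truth)
        res = fit_mixed_assoc(cohort, record["mediator_feature"])
        # pooled OLS on the stacked design
        from templag.adjust import zscore
        from templag.longitudinal_assoc import _phenotype_values

        meta = cohort.meta
        y = zscore(
            np.concatenate(
                [
                    _phenotype_values(cohort, "homa_ir", "baseline"),
                    _phenotype_values(cohort, "homa_ir", "followup"),
                ]
            )
        )
        m = zscore(
            np.concatenate(
                [
                    cohort.features_baseline[record["mediator_feature"]],
                    cohort.features_followup[record["mediator_feature"]],
                ]
            )
        )
        covs = [
            np.concatenate([meta[c], meta[c]]).astype(float)
            for c in (
                "age", "sex", "smoking", "alcohol", "education", "income",
                "physical_activity", "energy_intake",
            )
        ]
        Xi = np.column_stack([np.ones(len(y)), m] + covs)
        beta, *_ = ols_normal_equations(y, Xi)
        assert res.beta == pytest.approx(beta[1], abs=1e-4)

    def test_fixed_effects_match_gls_oracle(self):
        truth = SyntheticTruth(
            seed=21, b=-0.2, phenotype_model="random_intercept",
            icc_phenotype=0.5, n_species=10,
        )
        cohort, record = generate_paired_cohort(truth)
        res = fit_mixed_assoc(cohort, record["mediator_feature"])
        # GLS at the REML-estimated variance components reproduces the
        # mixed-model fixed effect
        from templag.adjust import zscore
        from templag.longitudinal_assoc import _phenotype_values

        meta = cohort.meta
        y = zscore(
            np.concatenate(
                [
                    _phenotype_values(cohort, "homa_ir", "baseline"),
                    _phenotype_values(cohort, "homa_ir", "followup"),
                ]
            )
        )
        m = zscore(
            np.concatenate(
                [
                    cohort.features_baseline[record["mediator_feature"]],
                    cohort.features_followup[record["mediator_feature"]],
                ]
            )
        )
        covs = [
            np.concatenate([meta[c], meta[c]]).astype(float)
            for c in (
                "age", "sex", "smoking", "alcohol", "education", "income",
                "physical_activity", "energy_intake",
            )
        ]
        Xi = np.column_stack([np.ones(len(y)), m] + covs)
        groups = np.concatenate([np.arange(cohort.n), np.arange(cohort.n)])
        sigma2 = (1 - res.icc)
        tau2 = res.icc
        beta = gls_fixed_effects(y, Xi, groups, tau2, sigma2)
        assert res.beta == pytest.approx(beta[1], abs=1e-5)

    def test_n_obs_invariant(self, small_cohort):
        cohort, record = small_cohort
        res = fit_mixed_assoc(cohort, record["mediator_feature"])
        assert res.n_obs == 2 * res.n_participants

    def test_mixed_screen_families(self, small_cohort):
        cohort, _ = small_cohort
        table = mixed_screen(cohort, cohort.feature_ids[:3], phenotypes=("homa_ir", "hba1c"))
        assert len(table) == 6
        assert (table["fdr"] >= table["p"] - 1e-12).all()

    def test_unknown_phenotype_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError):
            fit_mixed_assoc(cohort, cohort.feature_ids[0], phenotype="nope")


class TestExposureModel:
    def test_median_split_balance(self, rng):
        x = rng.standard_normal(401)
        split = median_split(x)
        assert abs(split.sum() - (401 - split.sum())) <= 1

    def test_median_split_degenerate(self):
        with pytest.raises(ValueError):
            median_split(np.ones(10))

    def test_null_diet_type_one_error(self):
        rejections = 0
        reps = 60
        for seed in range(reps):
            truth = SyntheticTruth(seed=seed + 900, n_participants=200, n_species=5)
            cohort, _ = generate_paired_cohort(truth)
            rng = np.random.default_rng(seed)
            cohort.meta["veg"] = rng.normal(300, 100, cohort.n)  # pure noise diet
            res = fit_exposure_model(cohort, "veg", "homa_ir")[0]
            rejections += res.p < 0.05
        assert rejections / reps < 0.15

    def test_adiposity_effect_sign_recovered(self):
        truth = SyntheticTruth(seed=5, alpha=0.5, b=0.5, cprime=0.8, n_species=5)
        cohort, _ = generate_paired_cohort(truth)
        from templag.io_profiles import is_adiposity

        groups = np.where(
            is_adiposity(cohort.meta["bmi_baseline"].to_numpy()), "adiposity", "ref"
        )
        res = fit_exposure_model(cohort, groups, "homa_ir")[0]
        assert res.beta > 0
        assert res.p < 0.05


class TestVif:
    def test_orthogonal_near_one(self, rng):
        n = 5000
        X = rng.standard_normal((n, 4))
        vif = compute_vif(X)
        np.testing.assert_allclose(vif.to_numpy(), 1.0, atol=0.01)

    def test_duplicate_column_inf(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0]])
        vif = compute_vif(X)
        assert np.isinf(vif.iloc[0]) and np.isinf(vif.iloc[2])

    def test_matches_definition_oracle(self, small_cohort):
        cohort, _ = small_cohort
        cols = ["age", "sex", "smoking", "alcohol", "education", "income",
                "physical_activity", "energy_intake", "bristol", "interval"]
        X = cohort.meta[cols].to_numpy(dtype=float)
        vif = compute_vif(cohort.meta[cols])
        for j, name in enumerate(cols):
            Xi = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
            beta, *_ = ols_normal_equations(X[:, j], Xi)
            resid = X[:, j] - Xi @ beta
            r2 = 1 - (resid**2).sum() / ((X[:, j] - X[:, j].mean()) ** 2).sum()
            assert vif[name] == pytest.approx(1 / (1 - r2), abs=1e-10)

    def test_shape_requirements(self, rng):
        with pytest.raises(ValueError):
            compute_vif(rng.standard_normal((10, 1)))
        with pytest.raises(ValueError):
            compute_vif(rng.standard_normal((3, 5)))
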