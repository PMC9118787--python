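"""Longitudinal association models.

Weight-change-pattern -> follow-up microbiome contrasts, repeated-
measures microbe-phenotype linear mixed models, median-split exposure
models, and VIF collinearity diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from templag.adjust import DEFAULT_CONFOUNDERS, zscore
from templag.crosslag import bh_fdr
from templag.io_profiles import weight_change_pattern

__all__ = [
    "LinearModelResult",
    "MixedModelResult",
    "PHENOTYPES",
    "fit_pattern_model",
    "pattern_screen",
    "fit_mixed_assoc",
    "mixed_screen",
    "fit_exposure_model",
    "median_split",
    "compute_vif",
]

#: Insulin-resistance phenotypes; skewed ones are log-transformed.
PHENOTYPES = ("homa_ir", "fasting_insulin", "fasting_glucose", "hba1c")
LOG_PHENOTYPES = ("homa_ir", "fasting_insulin", "fasting_glucose")

PATTERN_COVARIATES = DEFAULT_CONFOUNDERS + ("bristol", "interval")


@dataclass
class LinearModelResult:
    term: str
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p: float
    n: int
    fdr: float = np.nan

    def as_dict(self) -> dict:
        return {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "p": self.p,
            "n": self.n,
            "fdr": self.fdr,
        }


@dataclass
class MixedModelResult:
    feature_id: str
    phenotype: str
    beta: float
    se: float
    ci95_low: float
    ci95_high: float
    p: float
    n_obs: int
    n_participants: int
    icc: float
    converged: bool
    fdr: float = np.nan

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def _ols(y: np.ndarray, X: pd.DataFrame) -> sm.regression.linear_model.RegressionResults:
    design = sm.add_constant(X.astype(float), has_constant="add")
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def _extract_terms(fit, terms, n) -> list[LinearModelResult]:
    out = []
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    for term in terms:
        beta = float(fit.params[term])
        se = float(fit.bse[term])
        out.append(
            LinearModelResult(
                term=term,
                beta=beta,
                se=se,
                ci95_low=beta - tcrit * se,
                ci95_high=beta + tcrit * se,
                p=float(fit.pvalues[term]),
                n=n,
            )
        )
    return out


def _phenotype_values(cohort, phenotype: str, visit: str) -> np.ndarray:
    """Phenotype on the analysis scale (log for skewed ones)."""
    from templag.io_profiles import compute_homa_ir

    meta = cohort.meta
    suffix = "baseline" if visit == "baseline" else "followup"
    if phenotype == "homa_ir":
        col = f"homa_ir_{suffix}"
        if col in meta.columns:
            vals = meta[col].to_numpy(dtype=float)
        else:
            vals = compute_homa_ir(
                meta[f"fasting_insulin_{suffix}"].to_numpy(dtype=float),
                meta[f"fasting_glucose_{suffix}"].to_numpy(dtype=float),
            )
    else:
        vals = meta[f"{phenotype}_{suffix}"].to_numpy(dtype=float)
    if phenotype in LOG_PHENOTYPES:
        if (vals <= 0).any():
            raise ValueError(f"{phenotype} must be positive for log transform")
        vals = np.log(vals)
    return vals


def fit_pattern_model(
    cohort,
    feature_id: str,
    covariates: tuple[str, ...] = PATTERN_COVARIATES,
    feature_values: tuple | None = None,
) -> list[LinearModelResult]:
    """Weight-change-pattern contrasts on a follow-up microbial feature.

    OLS of the Z-scored follow-up feature on pattern dummies (stable
    normal as reference), the stated covariates, and the Z-scored
    baseline feature. Underweight-at-either-visit participants are
    excluded. Betas are in SD units of the log-transformed abundance.
    Empty pattern groups are skipped with a warning.
    """
    meta = cohort.meta
    patterns = pd.Series(
        weight_change_pattern(
            meta["bmi_baseline"].to_numpy(dtype=float),
            meta["bmi_followup"].to_numpy(dtype=float),
        ),
        index=meta.index,
    )
    keep = patterns != "excluded_underweight"
    if feature_values is not None:
        f1 = pd.Series(np.asarray(feature_values[0], dtype=float), index=meta.index)
        f2 = pd.Series(np.asarray(feature_values[1], dtype=float), index=meta.index)
    else:
        f1 = cohort.features_baseline[feature_id]
        f2 = cohort.features_followup[feature_id]
    contrasts = ["normal_to_adiposity", "adiposity_to_normal", "stable_adiposity"]
    present = [c for c in contrasts if (patterns[keep] == c).any()]
    for c in contrasts:
        if c not in present:
            warnings.warn(f"empty pattern group {c!r}; contrast skipped", stacklevel=2)
    X = pd.DataFrame(index=meta.index[keep])
    for c in present:
        X[c] = (patterns[keep] == c).astype(float)
    for cov in covariates:
        X[cov] = meta.loc[keep, cov].astype(float)
    X["baseline_feature"] = zscore(f1[keep].to_numpy())
    y = zscore(f2[keep].to_numpy())
    fit = _ols(y, X)
    return _extract_terms(fit, present, int(keep.sum()))


def pattern_screen(
    cohort, feature_set: list[str] | None = None, **kwargs
) -> pd.DataFrame:
    """Pattern contrasts across features, BH FDR per contrast family."""
    if feature_set is None:
        feature_set = cohort.feature_ids
    rows = []
    for fid in feature_set:
        for res in fit_pattern_model(cohort, fid, **kwargs):
            d = res.as_dict()
            d["feature_id"] = fid
            rows.append(d)
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for term, idx in table.groupby("term").groups.items():
        table.loc[idx, "fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    return table.set_index(["feature_id", "term"])


def fit_mixed_assoc(
    cohort,
    feature_id: str,
    phenotype: str = "homa_ir",
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS,
    include_visit: bool = False,
) -> MixedModelResult:
    """Random-intercept mixed model of a phenotype on a microbe.

    Both visits are stacked (two rows per participant); the feature is
    a time-varying covariate. Skewed phenotypes (HOMA-IR, insulin,
    glucose) are log-transformed; phenotype and microbe are Z-scored
    over the stacked observations, so the coefficient is the
    difference in phenotype SD units per 1-SD difference in the
    log-transformed abundance. REML with Wald (normal) inference.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    meta = cohort.meta
    y = np.concatenate(
        [
            _phenotype_values(cohort, phenotype, "baseline"),
            _phenotype_values(cohort, phenotype, "followup"),
        ]
    )
    m = np.concatenate(
        [
            cohort.features_baseline[feature_id].to_numpy(dtype=float),
            cohort.features_followup[feature_id].to_numpy(dtype=float),
        ]
    )
    groups = np.concatenate([meta.index.to_numpy(), meta.index.to_numpy()])
    X = pd.DataFrame({"feature": zscore(m)})
    for cov in confounders:
        X[cov] = np.concatenate([meta[cov], meta[cov]]).astype(float)
    if include_visit:
        X["visit"] = np.concatenate([np.zeros(len(meta)), np.ones(len(meta))])
    design = sm.add_constant(X, has_constant="add")
    model = sm.MixedLM(zscore(y), design, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    beta = float(fit.params["feature"])
    se = float(fit.bse["feature"])
    zcrit = stats.norm.ppf(0.975)
    tau2 = float(fit.cov_re.iloc[0, 0])
    sigma2 = float(fit.scale)
    return MixedModelResult(
        feature_id=feature_id,
        phenotype=phenotype,
        beta=beta,
        se=se,
        ci95_low=beta - zcrit * se,
        ci95_high=beta + zcrit * se,
        p=float(2 * stats.norm.sf(abs(beta / se))),
        n_obs=len(y),
        n_participants=len(meta),
        icc=tau2 / (tau2 + sigma2),
        converged=bool(fit.converged),
    )


def mixed_screen(
    cohort,
    feature_set: list[str] | None = None,
    phenotypes: tuple[str, ...] = PHENOTYPES,
    **kwargs,
) -> pd.DataFrame:
    """Mixed-model associations with BH FDR per phenotype across features.

    Non-converged fits are flagged and excluded from their FDR family.
    """
    if feature_set is None:
        feature_set = cohort.feature_ids
    rows = []
    for phen in phenotypes:
        for fid in feature_set:
            res = fit_mixed_assoc(cohort, fid, phen, **kwargs)
            rows.append(res.as_dict())
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for phen, idx in table.groupby("phenotype").groups.items():
        ok = table.loc[idx, "converged"].astype(bool)
        good = table.loc[idx][ok].index
        if len(good) < len(idx):
            warnings.warn(
                f"{(~ok).sum()} non-converged fits excluded from the "
                f"{phen} FDR family",
                stacklevel=2,
            )
        if len(good):
            table.loc[good, "fdr"] = bh_fdr(table.loc[good, "p"].to_numpy())
    return table.set_index(["phenotype", "feature_id"])


def median_split(values, lower_includes_median: bool = True) -> np.ndarray:
    """Binary higher/lower split at the median (1 = higher group).

    Values equal to the median join the lower group by default.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    high = v > med if lower_includes_median else v >= med
    if high.all() or (~high).all():
        raise ValueError("degenerate median split: exposure is constant")
    return high.astype(int)


def fit_exposure_model(
    cohort,
    exposure,
    outcome: str = "homa_ir",
    covariates: tuple[str, ...] = DEFAULT_CONFOUNDERS + ("interval",),
    adjust_baseline_outcome: bool = True,
) -> list[LinearModelResult]:
    """Prospective model of a follow-up phenotype on a binary/categorical exposure.

    `exposure` is either a metadata column name (continuous columns
    are median-split into higher/lower) or an aligned vector of group
    labels. The outcome is the Z-scored (log-transformed when skewed)
    follow-up phenotype; the baseline outcome enters as a covariate by
    default. One result per non-reference exposure level.
    """
    meta = cohort.meta
    if isinstance(exposure, str):
        vals = meta[exposure].to_numpy()
        if np.issubdtype(np.asarray(vals).dtype, np.number) and len(np.unique(vals)) > 4:
            vals = median_split(vals)
            name = f"{exposure}_high"
            levels = pd.Series(vals, index=meta.index).map({0: "ref", 1: name})
        else:
            levels = pd.Series(vals, index=meta.index).astype(str)
    else:
        levels = pd.Series(np.asarray(exposure), index=meta.index).astype(str)
    uniq = pd.unique(levels)
    if len(uniq) < 2:
        raise ValueError("degenerate exposure: single level")
    ref = "ref" if "ref" in uniq else uniq[0]
    terms = [lev for lev in uniq if lev != ref]
    X = pd.DataFrame(index=meta.index)
    for lev in terms:
        X[lev] = (levels == lev).astype(float)
    for cov in covariates:
        X[cov] = meta[cov].astype(float)
    if adjust_baseline_outcome:
        X["baseline_outcome"] = zscore(_phenotype_values(cohort, outcome, "baseline"))
    y = zscore(_phenotype_values(cohort, outcome, "followup"))
    fit = _ols(y, X)
    return _extract_terms(fit, terms, len(meta))


def compute_vif(covariate_matrix) -> pd.Series:
    """Variance inflation factor per covariate.

    VIF_j = 1 / (1 - R_j^2) from regressing covariate j on the others
    (with intercept). Perfect collinearity yields +inf, not an error.
    """
    if isinstance(covariate_matrix, pd.DataFrame):
        X = covariate_matrix.to_numpy(dtype=float)
        names = list(covariate_matrix.columns)
    else:
        X = np.asarray(covariate_matrix, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF requires at least two covariates")
    if n <= p:
        raise ValueError("VIF requires n > p")
    out = {}
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean()) ** 2).sum()
        if tss == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / tss
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)
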