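"""Random-effects meta-analysis and the four-clause replication rule.

Discovery (cross-lag rho2) and replication (single-timepoint
prospective regression) effect estimates are pooled per feature with
DerSimonian-Laird inverse-variance weights; a feature replicates when
p_meta < 0.05, p_heterogeneity > 0.05, I^2 < 50%, and the two cohorts
agree in direction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from templag.adjust import zscore
from templag.longitudinal_assoc import LinearModelResult

__all__ = [
    "MetaResult",
    "random_effects_meta",
    "replication_decision",
    "replication_regression",
    "HMP_COVARIATES",
]

HMP_COVARIATES = ("age", "sex", "race", "interval")


@dataclass
class MetaResult:
    feature_id: str
    beta_pooled: float
    se_pooled: float
    p_meta: float
    tau2: float
    q: float
    p_heterogeneity: float
    i2: float
    k: int

    def as_dict(self) -> dict:
        return asdict(self)


def random_effects_meta(betas, ses, feature_id: str = "") -> MetaResult:
    """DerSimonian-Laird random-effects pooling of k study estimates.

    Fixed-effect weights w = 1/se^2 give Cochran's Q; tau^2 is the
    DL moment estimator max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w));
    random-effects weights 1/(se^2 + tau^2) give the pooled estimate.
    I^2 = max(0, (Q - (k-1))/Q) * 100; heterogeneity p from
    chi-square with k-1 df.
    """
    beta = np.asarray(betas, dtype=float)
    se = np.asarray(ses, dtype=float)
    k = len(beta)
    if k < 2:
        raise ValueError("meta-analysis requires at least two studies")
    if len(se) != k:
        raise ValueError("betas and ses must have equal length")
    if (se <= 0).any() or not np.isfinite(se).all():
        raise ValueError("standard errors must be positive and finite")
    w = 1.0 / se**2
    beta_fe = float((w * beta).sum() / w.sum())
    if np.all(beta == beta[0]):
        beta_fe = float(beta[0])  # keep the degenerate case exact
    q = float((w * (beta - beta_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float((w_star * beta).sum() / w_star.sum())
    se_pooled = float(1.0 / np.sqrt(w_star.sum()))
    p_meta = float(2 * stats.norm.sf(abs(pooled / se_pooled)))
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0
    p_het = float(stats.chi2.sf(q, df=k - 1))
    return MetaResult(
        feature_id=feature_id,
        beta_pooled=pooled,
        se_pooled=se_pooled,
        p_meta=p_meta,
        tau2=float(tau2),
        q=q,
        p_heterogeneity=p_het,
        i2=i2,
        k=k,
    )


def replication_decision(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    beta_col: str = "beta",
    se_col: str = "se",
) -> pd.DataFrame:
    """Apply the four-clause replication rule per shared feature.

    Both inputs are indexed by feature id with effect (`beta_col`) and
    SE (`se_col`) columns. The returned table carries the meta-analysis
    fields plus each clause's pass flag and the conjunction
    ``replicated``.
    """
    shared = discovery.index.intersection(replication.index)
    rows = []
    for fid in shared:
        b = [discovery.loc[fid, beta_col], replication.loc[fid, beta_col]]
        s = [discovery.loc[fid, se_col], replication.loc[fid, se_col]]
        meta = random_effects_meta(b, s, feature_id=fid)
        d = meta.as_dict()
        d["direction_consistent"] = bool(np.sign(b[0]) == np.sign(b[1]) and b[0] != 0)
        d["pass_p_meta"] = meta.p_meta < 0.05
        d["pass_heterogeneity"] = meta.p_heterogeneity > 0.05
        d["pass_i2"] = meta.i2 < 50.0
        d["replicated"] = bool(
            d["pass_p_meta"]
            and d["pass_heterogeneity"]
            and d["pass_i2"]
            and d["direction_consistent"]
        )
        rows.append(d)
    return pd.DataFrame(rows).set_index("feature_id")


def replication_regression(
    cohort,
    feature_id: str,
    exposure: str = "bmi",
    covariates: tuple[str, ...] = HMP_COVARIATES,
) -> LinearModelResult:
    """Prospective association of baseline exposure with a follow-up microbe.

    For the HMP-style design where the exposure exists only at
    baseline: OLS of the Z-scored follow-up log abundance on the
    Z-scored baseline exposure, the stated covariates, and the
    Z-scored baseline abundance. The coefficient is standardized (SD
    outcome per SD exposure).
    """
    meta = cohort.meta
    exp_col = f"{exposure}_baseline" if f"{exposure}_baseline" in meta.columns else exposure
    X = pd.DataFrame(
        {"exposure": zscore(meta[exp_col].to_numpy(dtype=float))}, index=meta.index
    )
    for cov in covariates:
        X[cov] = meta[cov].astype(float)
    X["baseline_feature"] = zscore(
        cohort.features_baseline[feature_id].to_numpy(dtype=float)
    )
    y = zscore(cohort.features_followup[feature_id].to_numpy(dtype=float))
    fit = sm.OLS(y, sm.add_constant(X.astype(float), has_constant="add")).fit()
    beta = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    tcrit = stats.t.ppf(0.975, fit.df_resid)
    return LinearModelResult(
        term="exposure",
        beta=beta,
        se=se,
        ci95_low=beta - tcrit * se,
        ci95_high=beta + tcrit * se,
        p=float(fit.pvalues["exposure"]),
        n=len(meta),
    )
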