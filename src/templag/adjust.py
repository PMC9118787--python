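"""Confounder residualization, Z-scoring and interval-adjusted correlations.

This is the preprocessing stage feeding the cross-lagged panel model:
baseline and follow-up adiposity values are residualized on the
confounder set, microbial features on the same set plus Bristol stool
score, all four residual vectors are Z-scored, and the six pairwise
Pearson correlations are partialled on the follow-up time interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CONFOUNDERS",
    "AdjustedPanel",
    "residualize",
    "zscore",
    "partial_corr",
    "build_panel",
    "make_panel",
]

#: Confounders adjusted for the adiposity variable; features
#: additionally adjust Bristol stool score.
DEFAULT_CONFOUNDERS = (
    "age",
    "sex",
    "smoking",
    "alcohol",
    "education",
    "income",
    "physical_activity",
    "energy_intake",
)

PANEL_VARIABLES = ("exposure_baseline", "feature_baseline", "exposure_followup", "feature_followup")


@dataclass
class AdjustedPanel:
    """Z-scored confounder residuals for the 2x2 exposure/feature panel.

    ``corr`` is the 4x4 interval-adjusted correlation matrix over
    (exposure_baseline, feature_baseline, exposure_followup,
    feature_followup) — the input of the cross-lag fit.
    """

    data: pd.DataFrame  # columns PANEL_VARIABLES + interval
    corr: np.ndarray  # 4x4
    n: int

    def __post_init__(self) -> None:
        z = self.data[list(PANEL_VARIABLES)].to_numpy()
        if np.any(np.abs(z.mean(axis=0)) > 1e-8):
            raise ValueError("panel columns must have mean 0")
        if np.any(np.abs(z.std(axis=0, ddof=1) - 1) > 1e-8):
            raise ValueError("panel columns must have unit SD")
        eigs = np.linalg.eigvalsh((self.corr + self.corr.T) / 2.0)
        if eigs.min() < -1e-8:
            raise ValueError("interval-adjusted correlation matrix is not PSD")


def _design(covariates: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    return X, names


def residualize(y, covariate_matrix) -> np.ndarray:
    """OLS residuals of `y` on the covariates plus an intercept.

    Raises on rank deficiency, naming the collinear columns. The
    residuals are orthogonal to every covariate column.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(covariate_matrix)
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("residualize requires complete cases")
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y and covariates have different lengths")
    Xi = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Xi)
    if rank < Xi.shape[1]:
        # identify offenders: columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(Xi, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xi, y, rcond=None)
    return y - Xi @ beta


def zscore(x) -> np.ndarray:
    """(x - mean) / SD with the n-1 (sample) SD. Errors on constants."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot Z-score a constant vector")
    return (x - x.mean()) / sd


def partial_corr(x, y, z) -> float:
    """First-order partial correlation of x and y given z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    identical to the Pearson correlation of the OLS residuals of x on
    z and y on z.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(x) < 4:
        raise ValueError("partial correlation needs n >= 4")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("x or y collinear with conditioning variable")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def make_panel(
    exposure_baseline,
    exposure_followup,
    feature_baseline,
    feature_followup,
    exposure_covariates,
    feature_covariates,
    interval,
    interval_mode: str = "pairwise",
) -> AdjustedPanel:
    """Residualize, Z-score and interval-adjust the four panel variables.

    ``interval_mode="pairwise"`` partials each of the six pairwise
    correlations on the interval (first-order partial correlation);
    ``"covariate"`` instead appends the interval to both
    residualization covariate sets and uses plain correlations.
    """
    if interval_mode not in ("pairwise", "covariate"):
        raise ValueError(f"unknown interval_mode {interval_mode!r}")
    interval = np.asarray(interval, dtype=float)
    Xe, names_e = _design(exposure_covariates)
    Xf, names_f = _design(feature_covariates)
    if interval_mode == "covariate":
        Xe = np.column_stack([Xe, interval])
        Xf = np.column_stack([Xf, interval])
    cols = {}
    for name, y, X in (
        ("exposure_baseline", exposure_baseline, Xe),
        ("exposure_followup", exposure_followup, Xe),
        ("feature_baseline", feature_baseline, Xf),
        ("feature_followup", feature_followup, Xf),
    ):
        cols[name] = zscore(residualize(y, X))
    data = pd.DataFrame(cols)
    data["interval"] = interval
    z = data[list(PANEL_VARIABLES)].to_numpy()
    k = 4
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if interval_mode == "pairwise":
                r = partial_corr(z[:, i], z[:, j], interval)
            else:
                r = float(np.corrcoef(z[:, i], z[:, j])[0, 1])
            corr[i, j] = corr[j, i] = r
    return AdjustedPanel(data=data, corr=corr, n=len(data))


def build_panel(
    cohort,
    feature_id: str,
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS,
    extra_confounders_for_feature: tuple[str, ...] = ("bristol",),
    exposure: str = "bmi",
    interval_mode: str = "pairwise",
    feature_values: tuple | None = None,
) -> AdjustedPanel:
    """Assemble the cross-lag input panel for one feature of a cohort.

    The exposure (default BMI, ``exposure="wc"`` for the waist
    circumference sensitivity analysis) is residualized on the
    confounders; the feature's log abundance additionally on
    `extra_confounders_for_feature`. Pass ``feature_values`` as a
    (baseline, follow_up) pair of aligned vectors to analyse a derived
    endpoint (e.g. a diversity index) instead of a stored feature.
    """
    meta = cohort.meta
    missing = [c for c in confounders if c not in meta.columns]
    if missing:
        raise ValueError(f"cohort metadata lacks confounders: {missing}")
    if feature_values is not None:
        f1 = np.asarray(feature_values[0], dtype=float)
        f2 = np.asarray(feature_values[1], dtype=float)
    else:
        if cohort.features_baseline is None:
            raise ValueError("cohort has no attached features")
        f1 = cohort.features_baseline[feature_id].to_numpy(dtype=float)
        f2 = cohort.features_followup[feature_id].to_numpy(dtype=float)
    cov_e = meta[list(confounders)]
    cov_f = meta[list(confounders) + [c for c in extra_confounders_for_feature if c]]
    return make_panel(
        exposure_baseline=meta[f"{exposure}_baseline"].to_numpy(dtype=float),
        exposure_followup=meta[f"{exposure}_followup"].to_numpy(dtype=float),
        feature_baseline=f1,
        feature_followup=f2,
        exposure_covariates=cov_e,
        feature_covariates=cov_f,
        interval=meta["interval"].to_numpy(dtype=float),
        interval_mode=interval_mode,
    )
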