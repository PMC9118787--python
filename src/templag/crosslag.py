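"""Cross-lagged panel model estimation with fit indices and FDR screening.

The panel model over standardized (B1, F1, B2, F2) — exposure and
feature at baseline and follow-up — is

    B2 = r1 * B1 + rho1 * F1 + e_B
    F2 = rho2 * B1 + r2 * F1 + e_F

with r3 = corr(B1, F1) the synchronous baseline correlation. rho1 is
the standardized path from the baseline feature to follow-up exposure
and rho2 the reverse. The follow-up disturbance covariance is fixed at
zero (df = 1) so SRMR/CFI are informative; a saturated variant frees
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from templag.adjust import build_panel, DEFAULT_CONFOUNDERS

__all__ = [
    "CrossLagResult",
    "fit_crosslag",
    "bh_fdr",
    "screen_features",
    "sex_heterogeneity",
    "sensitivity_wc",
]


@dataclass
class CrossLagResult:
    """Standardized path estimates for one feature."""

    feature_id: str
    rho1: float
    rho2: float
    r1: float
    r2: float
    r3: float
    se_rho1: float
    se_rho2: float
    se_r1: float
    se_r2: float
    p_rho1: float
    p_rho2: float
    srmr: float
    cfi: float
    chisq: float
    df: int
    n: int
    fdr_rho1: float = np.nan
    fdr_rho2: float = np.nan

    def as_dict(self) -> dict:
        return asdict(self)


def _validate_corr4(corr4: np.ndarray) -> np.ndarray:
    S = np.asarray(corr4, dtype=float)
    if S.shape != (4, 4):
        raise ValueError("corr4 must be 4x4")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("corr4 must be symmetric")
    if not np.allclose(np.diag(S), 1.0, atol=1e-8):
        raise ValueError("corr4 must have unit diagonal")
    if np.linalg.eigvalsh(S).min() < -1e-10:
        raise ValueError("corr4 is not positive semidefinite")
    return (S + S.T) / 2.0


def _ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise ValueError("implied covariance is not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(sigma)) - 4.0)


def fit_crosslag(
    corr4, n: int, feature_id: str = "", saturated: bool = False
) -> CrossLagResult:
    """Fit the cross-lagged panel model from a 4x4 correlation matrix.

    Parameters
    ----------
    corr4 : array-like
        Correlation matrix over (B1, F1, B2, F2) in that order.
    n : int
        Analysis sample size (must exceed 10).
    saturated : bool
        Free the follow-up disturbance covariance (df = 0; chisq = 0,
        SRMR = 0, CFI = 1).

    Both follow-up equations share the predictors (B1, F1), so the
    maximum-likelihood path estimates coincide with the closed-form
    standardized OLS solutions; standard errors are normal-theory OLS
    SEs at sample size ``n`` with a t(n-3) reference.
    """
    S = _validate_corr4(corr4)
    if n <= 10:
        raise ValueError("n must exceed 10")
    r3 = S[0, 1]
    denom = 1.0 - r3**2
    if denom <= 1e-12:
        raise ValueError("baseline exposure and feature are collinear (|r3| = 1)")
    # B2 equation: predictors (B1, F1)
    r1 = (S[0, 2] - r3 * S[1, 2]) / denom
    rho1 = (S[1, 2] - r3 * S[0, 2]) / denom
    # F2 equation
    rho2 = (S[0, 3] - r3 * S[1, 3]) / denom
    r2 = (S[1, 3] - r3 * S[0, 3]) / denom

    r2_b = r1 * S[0, 2] + rho1 * S[1, 2]  # R^2 of the B2 equation
    r2_f = rho2 * S[0, 3] + r2 * S[1, 3]
    dof = n - 3
    se_b = np.sqrt(max(1.0 - r2_b, 0.0) / (denom * dof))
    se_f = np.sqrt(max(1.0 - r2_f, 0.0) / (denom * dof))

    def _pval(est, se):
        if se == 0:
            return 0.0 if est != 0 else 1.0
        return float(2 * stats.t.sf(abs(est / se), dof))

    if saturated:
        chisq, df, srmr, cfi = 0.0, 0, 0.0, 1.0
    else:
        # implied covariance with the disturbance covariance fixed at 0
        phi = S[:2, :2]
        B = np.array([[r1, rho1], [rho2, r2]])
        psi = np.diag([1.0 - r2_b, 1.0 - r2_f])
        sigma = np.empty((4, 4))
        sigma[:2, :2] = phi
        sigma[2:, :2] = B @ phi
        sigma[:2, 2:] = sigma[2:, :2].T
        sigma[2:, 2:] = B @ phi @ B.T + psi
        chisq = (n - 1) * _ml_discrepancy(S, sigma)
        df = 1
        # SRMR over the 10 unique standardized moments
        resid = S - sigma
        iu = np.triu_indices(4)
        srmr = float(np.sqrt((resid[iu] ** 2).sum() / 10.0))
        # independence baseline: all off-diagonals 0
        chisq_b = (n - 1) * _ml_discrepancy(S, np.diag(np.diag(S)))
        df_b = 6
        d = max(chisq - df, 0.0)
        d_b = max(chisq_b - df_b, d)
        cfi = 1.0 if d_b == 0 else float(1.0 - d / d_b)

    return CrossLagResult(
        feature_id=feature_id,
        rho1=float(rho1),
        rho2=float(rho2),
        r1=float(r1),
        r2=float(r2),
        r3=float(r3),
        se_rho1=float(se_b),
        se_rho2=float(se_f),
        se_r1=float(se_b),
        se_r2=float(se_f),
        p_rho1=_pval(rho1, se_b),
        p_rho2=_pval(rho2, se_f),
        srmr=float(srmr),
        cfi=float(cfi),
        chisq=float(chisq),
        df=df,
        n=int(n),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; ties share the
    q-value of their group.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def screen_features(
    cohort,
    feature_set: list[str] | None = None,
    alpha_fdr: float = 0.25,
    exposure: str = "bmi",
    confounders=DEFAULT_CONFOUNDERS,
    interval_mode: str = "pairwise",
    saturated: bool = False,
) -> pd.DataFrame:
    """Cross-lag fit per feature with BH FDR over the rho1 and rho2 families.

    Fit failures are recorded (``error`` column) and excluded from the
    FDR families with a warning. Returns one row per feature with the
    :class:`CrossLagResult` fields plus significance flags at
    `alpha_fdr`.
    """
    if feature_set is None:
        feature_set = cohort.feature_ids
    if len(feature_set) == 0:
        raise ValueError("empty feature set")
    rows, errors = [], []
    for fid in feature_set:
        try:
            panel = build_panel(
                cohort,
                fid,
                confounders=confounders,
                exposure=exposure,
                interval_mode=interval_mode,
            )
            res = fit_crosslag(panel.corr, panel.n, feature_id=fid, saturated=saturated)
            rows.append(res.as_dict())
        except (ValueError, np.linalg.LinAlgError) as exc:
            errors.append((fid, str(exc)))
    if errors:
        warnings.warn(
            f"{len(errors)} feature fits failed and were excluded from FDR: "
            f"{[fid for fid, _ in errors]}",
            stacklevel=2,
        )
    table = pd.DataFrame(rows).set_index("feature_id")
    if len(table):
        table["fdr_rho1"] = bh_fdr(table["p_rho1"].to_numpy())
        table["fdr_rho2"] = bh_fdr(table["p_rho2"].to_numpy())
        table["sig_rho1"] = table["fdr_rho1"] < alpha_fdr
        table["sig_rho2"] = table["fdr_rho2"] < alpha_fdr
    for fid, msg in errors:
        table.loc[fid, "error"] = msg
    return table


def sex_heterogeneity(
    result_female: pd.DataFrame,
    result_male: pd.DataFrame,
    path: str = "rho2",
) -> pd.DataFrame:
    """Cochran-Q heterogeneity of per-feature path estimates across sexes.

    Q = sum_g w_g (beta_g - beta_bar)^2 with w_g = 1/se_g^2 and the
    inverse-variance weighted mean beta_bar; p from chi-square with
    1 df; BH FDR across features. Features missing from a stratum are
    skipped with a warning.
    """
    shared = result_female.index.intersection(result_male.index)
    skipped = result_female.index.symmetric_difference(result_male.index)
    if len(skipped):
        warnings.warn(
            f"{len(skipped)} features missing from one stratum were skipped",
            stacklevel=2,
        )
    beta = np.column_stack(
        [result_female.loc[shared, path], result_male.loc[shared, path]]
    )
    se = np.column_stack(
        [result_female.loc[shared, f"se_{path}"], result_male.loc[shared, f"se_{path}"]]
    )
    w = 1.0 / se**2
    pooled = (w * beta).sum(axis=1) / w.sum(axis=1)
    q = (w * (beta - pooled[:, None]) ** 2).sum(axis=1)
    p = stats.chi2.sf(q, df=1)
    out = pd.DataFrame({"q": q, "p_heterogeneity": p}, index=shared)
    out["fdr_heterogeneity"] = bh_fdr(out["p_heterogeneity"].to_numpy())
    return out


def sensitivity_wc(
    cohort,
    feature_set: list[str] | None = None,
    alpha_fdr: float = 0.25,
    **kwargs,
) -> dict:
    """Re-screen with waist circumference as the adiposity variable.

    Returns both screens plus the Pearson correlation of the BMI- and
    WC-based coefficient vectors for each path family.
    """
    if "wc_baseline" not in cohort.meta.columns:
        raise ValueError("cohort has no waist-circumference columns")
    bmi = screen_features(cohort, feature_set, alpha_fdr, exposure="bmi", **kwargs)
    wc = screen_features(cohort, feature_set, alpha_fdr, exposure="wc", **kwargs)
    shared = bmi.index.intersection(wc.index)
    out = {"bmi": bmi, "wc": wc}
    for path in ("rho1", "rho2"):
        out[f"coef_corr_{path}"] = float(
            np.corrcoef(bmi.loc[shared, path], wc.loc[shared, path])[0, 1]
        )
    return out
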