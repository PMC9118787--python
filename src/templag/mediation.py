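"""Causal mediation of baseline adiposity -> follow-up microbe -> phenotype.

Linear mediator and outcome models without exposure-mediator
interaction, so the average causal mediation effect (ACME) is the
product of the exposure->mediator and mediator->outcome coefficients
and the average direct effect (ADE) is the exposure coefficient of
the outcome model. Uncertainty comes from quasi-Bayesian Monte Carlo:
joint normal draws of each model's coefficients, percentile intervals
over the implied effect draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from templag.adjust import DEFAULT_CONFOUNDERS, zscore
from templag.crosslag import bh_fdr
from templag.io_profiles import is_adiposity
from templag.longitudinal_assoc import _phenotype_values

__all__ = ["MediationResult", "fit_mediation", "mediation_screen"]

MEDIATION_COVARIATES = DEFAULT_CONFOUNDERS + ("bristol", "interval")


@dataclass
class MediationResult:
    exposure: str
    mediator_feature: str
    outcome: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    prop_mediated_median: float
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    prop_ci: tuple
    p_acme: float
    p_ade: float
    p_total: float
    prop_reliable: bool
    n: int
    n_sims: int
    seed: int
    fdr: float = np.nan

    def as_dict(self) -> dict:
        d = asdict(self)
        for key in ("acme_ci", "ade_ci", "total_ci", "prop_ci"):
            lo, hi = d.pop(key)
            d[f"{key}_low"] = lo
            d[f"{key}_high"] = hi
        return d


def _coef_draws(fit, rng, n_sims):
    """Joint normal draws from a fitted model's coefficient sampling law."""
    mean = np.asarray(fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)
    return rng.multivariate_normal(mean, cov, size=n_sims, method="cholesky")


def _tail_p(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return float(min(1.0, 2.0 * min(lo, hi)))


def fit_mediation(
    cohort,
    mediator_feature: str,
    outcome: str = "homa_ir",
    n_sims: int = 1000,
    seed: int | None = None,
    exposure: str = "adiposity",
    covariates: tuple[str, ...] = MEDIATION_COVARIATES,
    standardize: bool = True,
    bootstrap: bool = False,
) -> MediationResult:
    """Mediation of baseline adiposity through a follow-up microbe.

    Mediator model: M2 ~ X + M1 + C. Outcome model: Y2 ~ X + M2 + M1 +
    Y1 + C, where X is the binary baseline adiposity contrast, M the
    (log-abundance) mediator, Y the (log where skewed) phenotype and C
    the covariate set including Bristol score and follow-up interval.
    ACME = alpha * b, ADE = c', Total = ACME + ADE.

    The proportion mediated is reported as the signed point ratio
    ACME/Total plus the median of the draw-wise ratio; its CI is
    flagged unreliable when fewer than 95% of total-effect draws share
    a sign. ``bootstrap=True`` swaps the quasi-Bayesian draws for a
    nonparametric bootstrap of both models.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible mediation inference")
    meta = cohort.meta
    if exposure == "adiposity":
        x = is_adiposity(meta["bmi_baseline"].to_numpy(dtype=float)).astype(float)
        exposure_name = "adiposity"
    else:
        x = meta[exposure].to_numpy(dtype=float)
        exposure_name = exposure
    uniq = np.unique(x)
    if len(uniq) != 2:
        raise ValueError(f"exposure must be binary; saw {len(uniq)} levels")
    x = (x == uniq.max()).astype(float)

    m1 = cohort.features_baseline[mediator_feature].to_numpy(dtype=float)
    m2 = cohort.features_followup[mediator_feature].to_numpy(dtype=float)
    y1 = _phenotype_values(cohort, outcome, "baseline")
    y2 = _phenotype_values(cohort, outcome, "followup")
    if standardize:
        m1, m2 = zscore(m1), zscore(m2)
        y1, y2 = zscore(y1), zscore(y2)
    C = meta[list(covariates)].astype(float)

    Xm = pd.DataFrame({"exposure": x, "mediator_baseline": m1}, index=meta.index)
    Xm = pd.concat([Xm, C], axis=1)
    fit_m = sm.OLS(m2, sm.add_constant(Xm, has_constant="add")).fit()

    Xy = pd.DataFrame(
        {
            "exposure": x,
            "mediator": m2,
            "mediator_baseline": m1,
            "outcome_baseline": y1,
        },
        index=meta.index,
    )
    Xy = pd.concat([Xy, C], axis=1)
    fit_y = sm.OLS(y2, sm.add_constant(Xy, has_constant="add")).fit()

    alpha = float(fit_m.params["exposure"])
    b = float(fit_y.params["mediator"])
    cprime = float(fit_y.params["exposure"])
    acme = alpha * b
    ade = cprime
    total = acme + ade

    rng = np.random.default_rng(seed)
    if bootstrap:
        n = len(meta)
        alpha_d = np.empty(n_sims)
        b_d = np.empty(n_sims)
        c_d = np.empty(n_sims)
        Xm_c = sm.add_constant(Xm, has_constant="add").to_numpy()
        Xy_c = sm.add_constant(Xy, has_constant="add").to_numpy()
        i_alpha = 1  # exposure is the first column after the constant
        i_b = list(sm.add_constant(Xy, has_constant="add").columns).index("mediator")
        i_c = list(sm.add_constant(Xy, has_constant="add").columns).index("exposure")
        for s in range(n_sims):
            idx = rng.integers(0, n, size=n)
            bm, *_ = np.linalg.lstsq(Xm_c[idx], np.asarray(m2)[idx], rcond=None)
            by, *_ = np.linalg.lstsq(Xy_c[idx], np.asarray(y2)[idx], rcond=None)
            alpha_d[s] = bm[i_alpha]
            b_d[s] = by[i_b]
            c_d[s] = by[i_c]
    else:
        draws_m = _coef_draws(fit_m, rng, n_sims)
        draws_y = _coef_draws(fit_y, rng, n_sims)
        cols_m = list(sm.add_constant(Xm, has_constant="add").columns)
        cols_y = list(sm.add_constant(Xy, has_constant="add").columns)
        alpha_d = draws_m[:, cols_m.index("exposure")]
        b_d = draws_y[:, cols_y.index("mediator")]
        c_d = draws_y[:, cols_y.index("exposure")]

    acme_d = alpha_d * b_d
    total_d = acme_d + c_d
    ci = lambda d: tuple(np.percentile(d, [2.5, 97.5]))
    sign_frac = max(float(np.mean(total_d > 0)), float(np.mean(total_d < 0)))
    reliable = sign_frac >= 0.95 and total != 0
    if total == 0:
        warnings.warn("total effect is zero; proportion mediated undefined", stacklevel=2)
        prop = np.nan
        prop_median = np.nan
        prop_ci = (np.nan, np.nan)
    else:
        prop = acme / total
        ratio = np.divide(
            acme_d, total_d, out=np.full_like(acme_d, np.nan), where=total_d != 0
        )
        prop_median = float(np.nanmedian(ratio))
        prop_ci = ci(ratio[np.isfinite(ratio)]) if reliable else (np.nan, np.nan)

    return MediationResult(
        exposure=exposure_name,
        mediator_feature=mediator_feature,
        outcome=outcome,
        acme=acme,
        ade=ade,
        total=total,
        prop_mediated=prop,
        prop_mediated_median=prop_median,
        acme_ci=ci(acme_d),
        ade_ci=ci(c_d),
        total_ci=ci(total_d),
        prop_ci=prop_ci,
        p_acme=_tail_p(acme_d),
        p_ade=_tail_p(c_d),
        p_total=_tail_p(total_d),
        prop_reliable=bool(reliable),
        n=len(meta),
        n_sims=int(n_sims),
        seed=int(seed),
    )


def mediation_screen(
    cohort,
    mediator_list: list[str],
    outcome_list: tuple[str, ...] = ("homa_ir",),
    n_sims: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Mediation over mediator x outcome pairs with BH FDR on ACME p-values.

    Deterministic for a fixed seed: each pair gets an independent
    child seed spawned from the master seed.
    """
    if not mediator_list:
        raise ValueError("mediator_list must contain at least one feature")
    if seed is None:
        raise ValueError("a seed is required")
    seeds = np.random.SeedSequence(seed).generate_state(
        len(mediator_list) * len(outcome_list)
    )
    rows = []
    k = 0
    for outcome in outcome_list:
        for fid in mediator_list:
            res = fit_mediation(
                cohort,
                fid,
                outcome=outcome,
                n_sims=n_sims,
                seed=int(seeds[k]),
                **kwargs,
            )
            rows.append(res.as_dict())
            k += 1
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p_acme"].to_numpy())
    return table.set_index(["outcome", "mediator_feature"])
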