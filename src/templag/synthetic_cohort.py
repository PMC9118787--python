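"""Synthetic longitudinal cohort generator.

Produces paired-visit cohorts with known ground truth: standardized
cross-lag paths between an adiposity latent and a designated microbial
feature, additive confounding injected on the latent scale before
compositional rendering, a designated mediator wired to the
insulin-resistance phenotypes, detection-limit zero inflation, and
closure of each sample to relative abundances summing to 100.

Confounding is additive on the latent scale so that linear
residualization is exactly correct in the generating model; any bias
measured downstream is then attributable to the estimator, not the
generator. Zeros are produced by thresholding raw abundances at a
per-species detection limit — deliberately not with the
zero-replacement constant the analysis pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from templag.io_profiles import (
    AbundanceTable,
    PairedCohort,
    apply_exclusions,
    attach_features,
)

__all__ = [
    "SyntheticTruth",
    "generate_cohort",
    "generate_paired_cohort",
    "generate_replication_cohort",
    "make_fixture_roster",
]

CONFOUNDER_NAMES = (
    "age",
    "sex",
    "smoking",
    "alcohol",
    "education",
    "income",
    "physical_activity",
    "energy_intake",
)

#: Default additive effects of each z-scored confounder on the
#: adiposity latent (col 0) and on designated feature latents (col 1).
DEFAULT_CONFOUNDER_EFFECTS = np.array(
    [
        [0.15, 0.10],  # age
        [0.20, -0.10],  # sex
        [0.05, 0.10],  # smoking
        [0.05, 0.05],  # alcohol
        [-0.05, 0.05],  # education
        [0.05, -0.05],  # income
        [-0.10, 0.05],  # physical_activity
        [0.10, 0.10],  # energy_intake
    ]
)


@dataclass
class SyntheticTruth:
    """Generating parameters of a simulated paired cohort.

    Cross-lag paths (`rho1`, `rho2`, `r1`, `r2`, `r3`) act on the
    standardized latents of the designated cross-lag feature; the
    mediation triple (`alpha`, `b`, `cprime`) wires baseline adiposity
    through the designated mediator's follow-up latent into the
    log-HOMA-IR outcome. Scale defaults mirror a 426-participant,
    171-species, ~3.15-year design.
    """

    n_participants: int = 426
    n_species: int = 171
    rho1: float = 0.0
    rho2: float = 0.0
    r1: float = 0.45
    r2: float = 0.35
    r3: float = 0.10
    confounder_effects: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONFOUNDER_EFFECTS.copy()
    )
    bristol_effect: float = 0.10  # on feature latents only
    alpha: float = 0.0  # exposure -> mediator
    b: float = 0.0  # mediator -> outcome
    cprime: float = 0.0  # direct exposure -> outcome
    mediator_tracking: float = 0.30
    phenotype_model: str = "lagged"  # or "random_intercept"
    phenotype_lag: float = 0.30
    icc_phenotype: float = 0.50
    zero_inflation: float | np.ndarray = 0.90
    interval_mean: float = 3.15
    interval_sd: float = 0.30
    seed: int = 0
    # rendering scales
    feature_index: int = 0
    mediator_index: int = 1
    # designated features are kept rare so their own mass contributes
    # negligibly to the closure denominator; otherwise log-relative
    # abundance becomes a compressive transform of the latent and the
    # paths attenuate
    designated_mu: float = float(np.log(0.02))
    feature_scale: float = 1.2  # log-abundance SD per latent unit
    background_sigma: float = 0.6
    background_mu_spread: float = 1.0
    pheno_scale: float = 0.35  # log-HOMA units per latent unit
    bmi_mean: float = 23.4
    bmi_sd: float = 3.1

    def implied_corr4(self) -> np.ndarray:
        """Implied correlation matrix of (B1, F1, B2, F2)."""
        r1, r2, r3 = self.r1, self.r2, self.r3
        rho1, rho2 = self.rho1, self.rho2
        S = np.eye(4)
        S[0, 1] = S[1, 0] = r3
        S[0, 2] = S[2, 0] = r1 + rho1 * r3
        S[1, 2] = S[2, 1] = rho1 + r1 * r3
        S[0, 3] = S[3, 0] = rho2 + r2 * r3
        S[1, 3] = S[3, 1] = r2 + rho2 * r3
        S[2, 3] = S[3, 2] = (
            r1 * rho2 + ((r1 * r2) + (rho1 * rho2)) * r3 + rho1 * r2
        )
        return S

    def disturbance_variances(self) -> tuple[float, float]:
        v1 = 1.0 - (
            self.r1**2 + self.rho1**2 + 2 * self.r1 * self.rho1 * self.r3
        )
        v2 = 1.0 - (
            self.rho2**2 + self.r2**2 + 2 * self.rho2 * self.r2 * self.r3
        )
        return v1, v2

    def validate(self) -> None:
        if self.n_participants < 10 or self.n_species < 2:
            raise ValueError("cohort too small")
        if self.phenotype_model not in ("lagged", "random_intercept"):
            raise ValueError(f"unknown phenotype_model {self.phenotype_model!r}")
        if not 0 <= self.icc_phenotype < 1:
            raise ValueError("icc_phenotype must be in [0, 1)")
        zi = np.asarray(self.zero_inflation, dtype=float)
        if ((zi <= 0) | (zi > 1)).any():
            raise ValueError("zero_inflation detection probabilities must be in (0, 1]")
        v1, v2 = self.disturbance_variances()
        if v1 < 0 or v2 < 0:
            raise ValueError("cross-lag paths imply negative disturbance variance")
        if np.linalg.eigvalsh(self.implied_corr4()).min() < -1e-10:
            raise ValueError("implied cross-lag correlation matrix is not PSD")
        if self.feature_index == self.mediator_index:
            raise ValueError("feature_index and mediator_index must differ")
        for idx in (self.feature_index, self.mediator_index):
            if not 0 <= idx < self.n_species:
                raise ValueError("designated feature index out of range")

    def species_names(self) -> list[str]:
        return [f"s__species_{i:04d}" for i in range(self.n_species)]

    @property
    def crosslag_feature(self) -> str:
        return self.species_names()[self.feature_index]

    @property
    def mediator_feature(self) -> str:
        return self.species_names()[self.mediator_index]

    @property
    def acme(self) -> float:
        """True ACME on the latent outcome scale."""
        return self.alpha * self.b

    @property
    def ade(self) -> float:
        return self.cprime

    @property
    def prop_mediated(self) -> float:
        total = self.acme + self.ade
        return self.acme / total if total != 0 else np.nan


def _zscore_pop(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _draw_confounders(rng: np.random.Generator, n: int) -> pd.DataFrame:
    conf = pd.DataFrame(
        {
            "age": rng.normal(63.6, 5.4, n),
            "sex": rng.binomial(1, 0.319, n).astype(float),
            "smoking": rng.binomial(1, 0.08, n).astype(float),
            "alcohol": rng.binomial(1, 0.08, n).astype(float),
            "education": rng.choice([1, 2, 3], n, p=[0.23, 0.46, 0.31]).astype(float),
            "income": rng.choice([1, 2, 3, 4], n, p=[0.01, 0.21, 0.65, 0.13]).astype(
                float
            ),
            "physical_activity": rng.normal(40.8, 13.7, n),
            "energy_intake": rng.normal(1760.0, 460.0, n),
        }
    )
    return conf


def _detection_threshold(raw: np.ndarray, p_detect: np.ndarray) -> np.ndarray:
    """Zero values below the per-species detection-limit quantile.

    `raw` is species x samples; for species s with detection
    probability p the (1-p) quantile of its pooled values becomes the
    limit, so the empirical detection frequency tracks p.
    """
    out = raw.copy()
    for s in range(raw.shape[0]):
        p = p_detect[s]
        if p >= 1.0:
            continue
        limit = np.quantile(raw[s], 1.0 - p)
        out[s] = np.where(raw[s] >= limit, raw[s], 0.0)
    return out


def generate_cohort(truth: SyntheticTruth):
    """Simulate one paired cohort.

    Returns ``(baseline_table, followup_table, metadata, record)``:
    two percent-scale :class:`AbundanceTable` objects (samples =
    participant ids), long-format metadata (two rows per participant),
    and a truth record dict with the generating parameters and derived
    targets (true ACME on the observed log-phenotype scale, designated
    feature names, seed).
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed)
    n = truth.n_participants
    S = truth.n_species
    pids = [f"P{i:05d}" for i in range(n)]

    conf = _draw_confounders(rng, n)
    bristol = np.clip(np.round(rng.normal(4.0, 1.3, n)), 1, 7)
    conf_z = np.column_stack([_zscore_pop(conf[c].to_numpy()) for c in CONFOUNDER_NAMES])
    eff = np.asarray(truth.confounder_effects, dtype=float)
    conf_bmi = conf_z @ eff[:, 0]
    conf_feat = conf_z @ eff[:, 1] + truth.bristol_effect * _zscore_pop(bristol)

    # latent cross-lag system for the designated feature
    r3 = truth.r3
    z = rng.standard_normal((n, 2))
    B1 = z[:, 0]
    F1 = r3 * z[:, 0] + np.sqrt(1 - r3**2) * z[:, 1]
    v1, v2 = truth.disturbance_variances()
    B2 = truth.r1 * B1 + truth.rho1 * F1 + np.sqrt(v1) * rng.standard_normal(n)
    F2 = truth.rho2 * B1 + truth.r2 * F1 + np.sqrt(v2) * rng.standard_normal(n)

    bmi1 = truth.bmi_mean + truth.bmi_sd * (B1 + conf_bmi)
    bmi2 = truth.bmi_mean + 0.1 + truth.bmi_sd * (B2 + conf_bmi)
    wc1 = 2.1 * bmi1 + 36.0 + rng.normal(0, 3.0, n)
    wc2 = 2.1 * bmi2 + 36.0 + rng.normal(0, 3.0, n)

    # exposure contrast for the mediation arm
    x = (bmi1 >= 24.0).astype(float)
    xc = x - x.mean()

    # mediator latents
    kappa = truth.mediator_tracking
    M1 = rng.standard_normal(n)
    M2 = (
        truth.alpha * xc
        + kappa * M1
        + np.sqrt(max(1.0 - kappa**2, 0.05)) * rng.standard_normal(n)
    )

    # phenotypes on the latent scale
    if truth.phenotype_model == "lagged":
        psi = truth.phenotype_lag
        Y1 = truth.b * M1 + np.sqrt(0.75) * rng.standard_normal(n)
        Y2 = (
            truth.cprime * xc
            + truth.b * M2
            + psi * Y1
            + np.sqrt(0.75 * max(1.0 - psi**2, 0.05)) * rng.standard_normal(n)
        )
    else:
        u = np.sqrt(truth.icc_phenotype) * rng.standard_normal(n)
        sd_e = np.sqrt(1.0 - truth.icc_phenotype)
        Y1 = truth.b * M1 + u + sd_e * rng.standard_normal(n)
        Y2 = truth.cprime * xc + truth.b * M2 + u + sd_e * rng.standard_normal(n)

    log_homa1 = np.log(1.5) + truth.pheno_scale * Y1
    log_homa2 = np.log(1.5) + truth.pheno_scale * Y2
    glucose1 = np.exp(np.log(5.1) + 0.08 * rng.standard_normal(n))
    glucose2 = np.exp(np.log(5.1) + 0.08 * rng.standard_normal(n))
    insulin1 = np.exp(log_homa1) * 22.5 / glucose1
    insulin2 = np.exp(log_homa2) * 22.5 / glucose2
    hb_noise = rng.standard_normal((n, 2))
    hba1c1 = 5.65 + 0.45 * (0.4 * Y1 + np.sqrt(1 - 0.16) * hb_noise[:, 0])
    hba1c2 = 5.65 + 0.45 * (0.4 * Y2 + np.sqrt(1 - 0.16) * hb_noise[:, 1])

    # --- compositional rendering -----------------------------------------
    mus = np.log(0.3) + truth.background_mu_spread * rng.standard_normal(S)
    persist = rng.standard_normal((S, n))
    noise = rng.standard_normal((S, n, 2))
    log_raw = (
        mus[:, None, None]
        + truth.background_sigma
        * (np.sqrt(0.5) * persist[:, :, None] + np.sqrt(0.5) * noise)
    )
    fi, mi = truth.feature_index, truth.mediator_index
    sf = truth.feature_scale
    log_raw[fi, :, 0] = truth.designated_mu + sf * (F1 + conf_feat)
    log_raw[fi, :, 1] = truth.designated_mu + sf * (F2 + conf_feat)
    log_raw[mi, :, 0] = truth.designated_mu + sf * (M1 + conf_feat)
    log_raw[mi, :, 1] = truth.designated_mu + sf * (M2 + conf_feat)
    raw = np.exp(log_raw)

    p_detect = np.broadcast_to(
        np.asarray(truth.zero_inflation, dtype=float), (S,)
    ).copy()
    p_detect[[fi, mi]] = 1.0  # designated features always detected
    pooled = raw.reshape(S, -1)
    zeroed = _detection_threshold(pooled, p_detect).reshape(S, n, 2)

    totals = zeroed.sum(axis=0)
    rel = 100.0 * zeroed / totals  # closure to percent

    names = truth.species_names()
    baseline = AbundanceTable(
        pd.DataFrame(rel[:, :, 0], index=names, columns=pids), "percent", "s__"
    )
    follow_up = AbundanceTable(
        pd.DataFrame(rel[:, :, 1], index=names, columns=pids), "percent", "s__"
    )

    interval = truth.interval_mean + truth.interval_sd * rng.standard_normal(n)
    interval = np.maximum(interval, 0.1)
    height = np.where(
        conf["sex"].to_numpy() > 0,
        rng.normal(1.68, 0.055, n),
        rng.normal(1.57, 0.05, n),
    )

    def _visit_frame(visit, bmi, wc, ins, glu, hba):
        frame = pd.DataFrame(
            {
                "participant_id": pids,
                "visit": visit,
                "height": height,
                "weight": bmi * height**2,
                "bmi": bmi,
                "wc": wc,
                "bristol": bristol,
                "fasting_insulin": ins,
                "fasting_glucose": glu,
                "hba1c": hba,
                "diabetes_medication": 0,
            }
        )
        for c in CONFOUNDER_NAMES:
            frame[c] = conf[c].to_numpy()
        frame["followup_interval"] = interval if visit == "baseline" else np.nan
        return frame

    metadata = pd.concat(
        [
            _visit_frame("baseline", bmi1, wc1, insulin1, glucose1, hba1c1),
            _visit_frame("follow_up", bmi2, wc2, insulin2, glucose2, hba1c2),
        ],
        ignore_index=True,
    )

    record = {
        "seed": truth.seed,
        "n_participants": n,
        "n_species": S,
        "rho1": truth.rho1,
        "rho2": truth.rho2,
        "r1": truth.r1,
        "r2": truth.r2,
        "r3": truth.r3,
        "alpha": truth.alpha,
        "b": truth.b,
        "cprime": truth.cprime,
        "crosslag_feature": truth.crosslag_feature,
        "mediator_feature": truth.mediator_feature,
        "acme_latent": truth.acme,
        "ade_latent": truth.ade,
        "prop_mediated": truth.prop_mediated,
        "pheno_scale": truth.pheno_scale,
        # true effects on the observed log-phenotype scale
        "acme_observed": truth.pheno_scale * truth.acme,
        "ade_observed": truth.pheno_scale * truth.ade,
        "icc_phenotype": truth.icc_phenotype,
        "phenotype_model": truth.phenotype_model,
        "adiposity_rate": float(x.mean()),
    }
    return baseline, follow_up, metadata, record


def generate_paired_cohort(truth: SyntheticTruth):
    """Generate and assemble a ready-to-analyse :class:`PairedCohort`.

    Runs the exclusion filter (a no-op on clean synthetic metadata) and
    attaches log-transformed feature matrices. Returns
    ``(cohort, record)``.
    """
    baseline, follow_up, metadata, record = generate_cohort(truth)
    cohort = apply_exclusions(metadata)
    cohort = attach_features(cohort, baseline, follow_up)
    return cohort, record


def generate_replication_cohort(truth: SyntheticTruth, n: int = 43):
    """HMP-style replication cohort: exposure at baseline only.

    Ages uniform in [18, 40], a race covariate, ~1-year intervals, and
    the same latent cross-lag machinery as :func:`generate_cohort` but
    a reduced metadata schema (age, sex, race, interval, baseline
    BMI). Returns ``(cohort, record)`` with features attached.
    """
    truth.validate()
    rng = np.random.default_rng(truth.seed + 104729)
    S = truth.n_species
    pids = [f"H{i:04d}" for i in range(n)]

    r3 = truth.r3
    z = rng.standard_normal((n, 2))
    B1 = z[:, 0]
    F1 = r3 * z[:, 0] + np.sqrt(1 - r3**2) * z[:, 1]
    v1, v2 = truth.disturbance_variances()
    F2 = truth.rho2 * B1 + truth.r2 * F1 + np.sqrt(v2) * rng.standard_normal(n)

    bmi1 = 24.0 + 3.0 * B1

    mus = np.log(0.3) + truth.background_mu_spread * rng.standard_normal(S)
    persist = rng.standard_normal((S, n))
    noise = rng.standard_normal((S, n, 2))
    log_raw = (
        mus[:, None, None]
        + truth.background_sigma
        * (np.sqrt(0.5) * persist[:, :, None] + np.sqrt(0.5) * noise)
    )
    fi = truth.feature_index
    log_raw[fi, :, 0] = truth.designated_mu + truth.feature_scale * F1
    log_raw[fi, :, 1] = truth.designated_mu + truth.feature_scale * F2
    raw = np.exp(log_raw)
    p_detect = np.broadcast_to(
        np.asarray(truth.zero_inflation, dtype=float), (S,)
    ).copy()
    p_detect[[fi, truth.mediator_index]] = 1.0
    zeroed = _detection_threshold(raw.reshape(S, -1), p_detect).reshape(S, n, 2)
    rel = 100.0 * zeroed / zeroed.sum(axis=0)

    names = truth.species_names()
    baseline = AbundanceTable(
        pd.DataFrame(rel[:, :, 0], index=names, columns=pids), "percent", "s__"
    )
    follow_up = AbundanceTable(
        pd.DataFrame(rel[:, :, 1], index=names, columns=pids), "percent", "s__"
    )

    meta = pd.DataFrame(
        {
            "age": rng.uniform(18.0, 40.0, n),
            "sex": rng.binomial(1, 0.5, n).astype(float),
            "race": rng.binomial(1, 0.7, n).astype(float),
            "bmi_baseline": bmi1,
            "interval": np.maximum(1.0 + 0.1 * rng.standard_normal(n), 0.1),
        },
        index=pd.Index(pids, name="participant_id"),
    )
    cohort = PairedCohort(meta=meta)
    cohort = attach_features(cohort, baseline, follow_up)
    record = {
        "seed": truth.seed,
        "n": n,
        "rho2": truth.rho2,
        "crosslag_feature": truth.crosslag_feature,
    }
    return cohort, record


def make_fixture_roster(
    n_pairs: int = 505,
    n_missing_bmi: int = 37,
    n_missing_interval: int = 2,
    n_medication: int = 40,
    overlap: bool = False,
) -> pd.DataFrame:
    """Deterministic paired-visit roster with exclusion flags populated.

    505 paired participants by default, with 37 missing a BMI value,
    2 missing the follow-up interval, and 40 on diabetes medication —
    disjoint sets unless ``overlap=True``, in which case the first
    medication participant also has a missing BMI.
    """
    if n_missing_bmi + n_missing_interval + n_medication > n_pairs:
        raise ValueError("more flags than participants")
    rows = []
    for i in range(n_pairs):
        pid = f"R{i:04d}"
        bmi_b, bmi_f = 22.0 + (i % 7), 22.5 + (i % 7)
        interval = 3.15
        med = 0
        base = dict(
            participant_id=pid,
            age=60.0 + (i % 15),
            sex=i % 2,
            smoking=0,
            alcohol=0,
            education=1 + i % 3,
            income=1 + i % 4,
            physical_activity=40.0,
            energy_intake=1800.0,
            bristol=4,
            fasting_insulin=6.6,
            fasting_glucose=5.1,
            hba1c=5.6,
        )
        rows.append(
            dict(
                base,
                visit="baseline",
                bmi=bmi_b,
                diabetes_medication=med,
                followup_interval=interval,
            )
        )
        rows.append(
            dict(
                base,
                visit="follow_up",
                bmi=bmi_f,
                diabetes_medication=med,
                followup_interval=np.nan,
            )
        )
    roster = pd.DataFrame(rows)

    def _rows(pid):
        return roster["participant_id"] == pid

    i = 0
    for _ in range(n_missing_bmi):
        roster.loc[_rows(f"R{i:04d}") & (roster["visit"] == "follow_up"), "bmi"] = np.nan
        i += 1
    for _ in range(n_missing_interval):
        roster.loc[_rows(f"R{i:04d}"), "followup_interval"] = np.nan
        i += 1
    if overlap:
        # first medication participant shares the first missing-BMI flag
        roster.loc[_rows("R0000"), "diabetes_medication"] = 1
        n_medication -= 1
    for _ in range(n_medication):
        roster.loc[
            _rows(f"R{i:04d}") & (roster["visit"] == "baseline"), "diabetes_medication"
        ] = 1
        i += 1
    return roster
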