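"""Config-driven orchestration of the full analysis sequence.

Stage order mirrors the analysis design: prevalence filter ->
log transform -> diversity -> cross-lag screen (with sex strata and
the WC sensitivity run) -> weight-change-pattern models ->
mixed-model phenotype associations -> dietary models -> mediation on
qualifying features -> meta-analytic replication when a second cohort
is supplied. Every random stage is seeded from the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from templag import __version__
from templag.adjust import DEFAULT_CONFOUNDERS
from templag.crosslag import screen_features, sex_heterogeneity, sensitivity_wc
from templag.diversity import alpha_diversity, bray_curtis, pcoa
from templag.io_profiles import (
    apply_exclusions,
    attach_features,
    filter_prevalence,
    read_abundance_table,
    read_metadata,
)
from templag.longitudinal_assoc import mixed_screen, pattern_screen
from templag.mediation import mediation_screen
from templag.meta_replication import replication_decision, replication_regression
from templag.synthetic_cohort import SyntheticTruth, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = (
    "filter",
    "diversity",
    "crosslag",
    "patterns",
    "phenotypes",
    "mediation",
    "meta",
)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see :func:`PipelineConfig.from_yaml`."""

    baseline_table: str | None = None
    followup_table: str | None = None
    metadata: str | None = None
    synthetic: dict | None = None
    replication: dict | None = None
    out_dir: str = "templag_out"
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    min_abund: float = 0.01
    min_prev: float = 0.10
    zero_replacement: float = 1e-5
    fdr_screen: float = 0.25
    fdr_final: float = 0.05
    stages: tuple[str, ...] = ALL_STAGES
    n_sims: int = 1000
    seed: int = 0
    mediators: tuple[str, ...] = ()

    def validate(self) -> None:
        for thr in (self.fdr_screen, self.fdr_final, self.min_prev):
            if not 0 < thr <= 1:
                raise ValueError(f"threshold {thr} outside (0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        has_files = self.baseline_table and self.followup_table and self.metadata
        if not has_files and self.synthetic is None:
            raise ValueError("config needs either input tables or a synthetic block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("confounders", "stages", "mediators"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        truth = SyntheticTruth(seed=config.seed, **config.synthetic)
        baseline, follow_up, metadata, record = generate_cohort(truth)
        return baseline, follow_up, metadata, record
    baseline = read_abundance_table(config.baseline_table).select_rank("s__")
    follow_up = read_abundance_table(config.followup_table).select_rank("s__")
    metadata = read_metadata(config.metadata)
    missing = [
        c for c in config.confounders if c not in metadata.columns
    ]
    if missing:
        raise ValueError(f"metadata lacks configured confounder columns: {missing}")
    return baseline, follow_up, metadata, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the result bundle.

    Writes one TSV per stage plus ``run_log.json`` (stage order, FDR
    family sizes, versions, seed) under ``config.out_dir``. A stage
    failure aborts with the stage name; earlier outputs are retained.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": __version__, "seed": config.seed, "stages": []}
    results: dict = {}

    def _save(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t", float_format="%.10g")
        results[name] = frame

    stage = "load"
    try:
        baseline, follow_up, metadata, truth_record = _load_inputs(config)
        if truth_record is not None:
            log["synthetic_truth"] = {
                k: v for k, v in truth_record.items() if np.isscalar(v) or v is None
            }

        stage = "setup"
        cohort = apply_exclusions(metadata)
        log["exclusions"] = cohort.exclusion_log

        stage = "filter"
        if "filter" in config.stages:
            n_before = baseline.n_features
            shared = baseline.data.index.intersection(follow_up.data.index)
            pooled = pd.concat(
                [baseline.data.loc[shared], follow_up.data.loc[shared]], axis=1
            )
            pooled.columns = [f"c{i}" for i in range(pooled.shape[1])]
            pooled_table = type(baseline)(pooled, baseline.mode, baseline.level)
            kept = filter_prevalence(
                pooled_table, config.min_abund, config.min_prev
            ).feature_ids
            baseline = type(baseline)(
                baseline.data.loc[kept], baseline.mode, baseline.level
            )
            follow_up = type(follow_up)(
                follow_up.data.loc[kept], follow_up.mode, follow_up.level
            )
            log["stages"].append(
                {"stage": "filter", "features_in": n_before, "features_out": len(kept)}
            )
        cohort = attach_features(
            cohort, baseline, follow_up, zero_replacement=config.zero_replacement
        )

        stage = "diversity"
        if "diversity" in config.stages:
            frames = []
            for visit, table in (("baseline", baseline), ("follow_up", follow_up)):
                sub = type(table)(
                    table.data[cohort.meta.index], table.mode, table.level
                )
                alpha = alpha_diversity(sub).table
                ords = pcoa(bray_curtis(sub), n_axes=2)
                div = alpha.join(ords.coordinates)
                div["visit"] = visit
                frames.append(div)
            diversity_table = pd.concat(frames)
            _save("diversity", diversity_table)
            log["stages"].append({"stage": "diversity", "rows": len(diversity_table)})

        stage = "crosslag"
        screen = None
        if "crosslag" in config.stages:
            screen = screen_features(
                cohort,
                alpha_fdr=config.fdr_screen,
                confounders=config.confounders,
            )
            _save("crosslag", screen)
            log["stages"].append(
                {
                    "stage": "crosslag",
                    "fdr_family_size": int(len(screen)),
                    "n_sig_rho2": int(screen["sig_rho2"].sum()),
                }
            )
            # sex strata + heterogeneity
            strata = {}
            for label, mask in (
                ("female", cohort.meta["sex"] == 0),
                ("male", cohort.meta["sex"] == 1),
            ):
                sub = type(cohort)(
                    meta=cohort.meta[mask],
                    features_baseline=cohort.features_baseline[mask],
                    features_followup=cohort.features_followup[mask],
                )
                conf_wo_sex = tuple(c for c in config.confounders if c != "sex")
                strata[label] = screen_features(
                    sub, alpha_fdr=config.fdr_screen, confounders=conf_wo_sex
                )
            het = sex_heterogeneity(strata["female"], strata["male"])
            _save("sex_heterogeneity", het)
            if "wc_baseline" in cohort.meta.columns:
                wc = sensitivity_wc(cohort, confounders=config.confounders)
                _save("crosslag_wc", wc["wc"])
                log["stages"].append(
                    {
                        "stage": "sensitivity_wc",
                        "coef_corr_rho2": wc["coef_corr_rho2"],
                    }
                )

        stage = "patterns"
        if "patterns" in config.stages:
            feats = (
                list(screen.index[screen["sig_rho2"]])
                if screen is not None and screen["sig_rho2"].any()
                else cohort.feature_ids[: min(10, len(cohort.feature_ids))]
            )
            patterns = pattern_screen(cohort, feats)
            _save("patterns", patterns)
            log["stages"].append(
                {"stage": "patterns", "fdr_family_size": len(feats)}
            )

        stage = "phenotypes"
        mixed = None
        if "phenotypes" in config.stages:
            feats = (
                list(screen.index[screen["sig_rho2"]])
                if screen is not None and screen["sig_rho2"].any()
                else cohort.feature_ids[: min(10, len(cohort.feature_ids))]
            )
            mixed = mixed_screen(cohort, feats, confounders=config.confounders)
            _save("phenotypes", mixed)
            log["stages"].append(
                {"stage": "phenotypes", "fdr_family_size": int(len(mixed))}
            )

        stage = "mediation"
        if "mediation" in config.stages:
            if config.mediators:
                mediators = list(config.mediators)
            else:
                # features passing both the rho2 screen and a phenotype
                # association, mirroring the analysis progression
                mediators = []
                if screen is not None and mixed is not None:
                    sig_screen = set(screen.index[screen["sig_rho2"]])
                    sig_mixed = set(
                        mixed.index.get_level_values("feature_id")[
                            mixed["fdr"] < config.fdr_final
                        ]
                    )
                    mediators = sorted(sig_screen & sig_mixed)
            if mediators:
                med = mediation_screen(
                    cohort,
                    mediators,
                    n_sims=config.n_sims,
                    seed=config.seed,
                )
                _save("mediation", med)
                log["stages"].append(
                    {"stage": "mediation", "fdr_family_size": int(len(med))}
                )
            else:
                log["stages"].append({"stage": "mediation", "skipped": "no mediators"})

        stage = "meta"
        if "meta" in config.stages and config.replication is not None and screen is not None:
            rep_cfg = dict(config.replication)
            truth = SyntheticTruth(seed=config.seed + 1, **rep_cfg.get("synthetic", {}))
            rep_cohort, _ = __import__(
                "templag.synthetic_cohort", fromlist=["generate_replication_cohort"]
            ).generate_replication_cohort(truth, n=rep_cfg.get("n", 43))
            rows = []
            for fid in screen.index:
                if fid not in rep_cohort.feature_ids:
                    continue
                res = replication_regression(rep_cohort, fid)
                rows.append({"feature_id": fid, "beta": res.beta, "se": res.se})
            rep = pd.DataFrame(rows).set_index("feature_id")
            disc = screen.rename(columns={"rho2": "beta", "se_rho2": "se"})[
                ["beta", "se"]
            ]
            meta_table = replication_decision(disc, rep)
            _save("meta", meta_table)
            log["stages"].append(
                {"stage": "meta", "n_replicated": int(meta_table["replicated"].sum())}
            )
    except Exception as exc:
        log["failed_stage"] = stage
        log["error"] = str(exc)
        with open(out_dir / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    results["log"] = log
    return results
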