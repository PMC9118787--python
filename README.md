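# templag

Temporal analysis of adiposity and gut metagenome features: a tested,
reusable pipeline for paired-visit (baseline / follow-up) cohort designs
with species-level metagenomic profiles.

## What it does

- **I/O and preprocessing** (`templag.io_profiles`): MetaPhlAn2-style
  merged abundance tables and HUMAnN2-style pathway tables, prevalence
  filtering (0.01% in ≥10% of samples by default), zero-replaced natural-log
  transformation, participant exclusion criteria, WGOC BMI categories,
  weight-change patterns, and HOMA-IR.
- **Diversity** (`templag.diversity`): observed species, Shannon, Simpson,
  Pielou; Bray–Curtis dissimilarity with principal-coordinates analysis.
- **Adjustment** (`templag.adjust`): confounder residualization, Z-scoring,
  and interval-adjusted (first-order partial) correlations feeding the
  panel model.
- **Cross-lagged panel model** (`templag.crosslag`): simultaneous
  standardized paths baseline-feature→follow-up-BMI (ρ1) and
  baseline-BMI→follow-up-feature (ρ2) with tracking paths, synchronous
  correlation, ML fit indices (χ², SRMR, CFI), Benjamini–Hochberg FDR
  screening, sex-stratified Cochran-Q heterogeneity, and a waist-circumference
  sensitivity analysis.
- **Longitudinal associations** (`templag.longitudinal_assoc`):
  weight-change-pattern contrasts on follow-up microbial features,
  random-intercept mixed models of insulin-resistance phenotypes on
  microbes, median-split exposure models, and VIF diagnostics.
- **Mediation** (`templag.mediation`): baseline adiposity → follow-up
  microbe → follow-up phenotype with quasi-Bayesian Monte Carlo inference
  (ACME, ADE, total effect, proportion mediated).
- **Meta-analytic replication** (`templag.meta_replication`):
  DerSimonian–Laird random-effects pooling, I²/Cochran-Q, and the
  four-clause replication rule (p_meta < 0.05, p_het > 0.05, I² < 50%,
  concordant direction).
- **Synthetic cohorts** (`templag.synthetic_cohort`): a generator with
  known cross-lag paths, latent-scale confounding, compositional closure,
  detection-limit zero inflation, and wired mediation effects, so every
  stage is testable without any data download.
- **Orchestration** (`templag.pipeline`, `templag.cli`): a config-driven
  pipeline running the stages in analysis order with a seeded, fully
  deterministic report bundle.

## CLI

```bash
# simulate a cohort (426 participants x 171 species x 2 visits by default)
templag simulate --preset gnhs --seed 7 --rho2 0.3 -o sim/

# prevalence filter and log transform
templag filter sim/abundance_baseline.tsv --min-abund 0.01 --min-prev 0.10 -o filtered.tsv
templag transform sim/abundance_baseline.tsv --zero 1e-5 -o logged.tsv

# diversity, cross-lag screen, associations, mediation
templag diversity sim/abundance_baseline.tsv --pcoa 2 -o div
templag crosslag --baseline sim/abundance_baseline.tsv \
    --followup sim/abundance_followup.tsv --metadata sim/metadata.csv \
    --fdr 0.25 -o crosslag.tsv
templag assoc phenotypes --baseline ... --followup ... --metadata ... -o mixed.tsv
templag mediate --baseline ... --followup ... --metadata ... \
    --mediator s__species_0001 --outcome homa_ir --sims 1000 --seed 1 -o med.tsv

# meta-analysis of discovery vs replication effect tables
templag meta --discovery disc.tsv --replication rep.tsv -o meta.tsv

# full pipeline from a YAML config
templag run --config config.yaml
```

A minimal synthetic-pipeline config:

```yaml
synthetic:
  rho2: 0.3
  alpha: 0.5
  b: 0.5
  cprime: 0.5
seed: 11
out_dir: out/
```

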