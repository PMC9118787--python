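"""Abundance-profile and cohort-metadata I/O plus preprocessing.

Handles MetaPhlAn2-style merged taxonomic tables and HUMAnN2-style
pathway tables (features x samples, relative abundances), participant
metadata in long (one row per participant-visit) format, the
prevalence filter, zero-replaced log transformation, cohort exclusion
criteria, BMI categorisation, weight-change patterns, and HOMA-IR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "ParseError",
    "ValidationError",
    "PairedCohort",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "filter_prevalence",
    "log_transform",
    "pair_records",
    "apply_exclusions",
    "attach_features",
    "classify_weight",
    "weight_change_pattern",
    "compute_homa_ir",
    "DEFAULT_EXCLUSION_CRITERIA",
    "METADATA_COLUMNS",
    "WEIGHT_CATEGORIES",
    "WEIGHT_PATTERNS",
]


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Input violates a structural invariant."""


#: BMI categories per Chinese WGOC cut-offs, half-open so the real
#: line is partitioned: [0,18.5) underweight, [18.5,24) normal,
#: [24,28) overweight, [28,inf) obesity.
WEIGHT_CATEGORIES = ("underweight", "normal", "overweight", "obesity")

WEIGHT_PATTERNS = (
    "stable_normal",
    "normal_to_adiposity",
    "adiposity_to_normal",
    "stable_adiposity",
    "excluded_underweight",
)

#: Long-format participant-visit metadata schema.
METADATA_COLUMNS = [
    "participant_id",
    "visit",
    "age",
    "sex",
    "height",
    "weight",
    "bmi",
    "wc",
    "smoking",
    "alcohol",
    "education",
    "income",
    "physical_activity",
    "energy_intake",
    "bristol",
    "fasting_insulin",
    "fasting_glucose",
    "hba1c",
    "diabetes_medication",
    "followup_interval",
]

DEFAULT_EXCLUSION_CRITERIA = (
    "missing_bmi",
    "missing_interval",
    "diabetes_medication",
)

_SUM_TOL = 1e-6


@dataclass
class AbundanceTable:
    """Features x samples relative-abundance matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are features (taxonomy strings, pipe-delimited clade
        names for taxonomic tables), columns are samples.
    mode : {"percent", "fraction"}
        Scale of the values: per-sample feature sums near 100 or 1.
    level : str, optional
        Taxonomic rank tag (e.g. ``"s__"`` for species) when the
        table has been restricted to one rank.
    """

    data: pd.DataFrame
    mode: str = "percent"
    level: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("percent", "fraction"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("abundance table contains missing values")
        if (values < 0).any():
            raise ValidationError("negative abundance values")
        self.data = self.data.astype(float)
        # the per-rank closure bound only applies once a single rank
        # is selected; multi-rank MetaPhlAn tables repeat mass per rank
        if self.level is not None:
            limit = self.scale + _SUM_TOL
            sums = values.sum(axis=0)
            if (sums > limit).any():
                bad = self.data.columns[sums > limit].tolist()
                raise ValidationError(
                    f"per-sample abundance sums exceed {self.scale}: {bad}"
                )

    @property
    def scale(self) -> float:
        return 100.0 if self.mode == "percent" else 1.0

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def to_fraction(self) -> "AbundanceTable":
        """Return a copy on the fraction scale (values in [0, 1])."""
        if self.mode == "fraction":
            return AbundanceTable(self.data.copy(), "fraction", self.level)
        return AbundanceTable(self.data / 100.0, "fraction", self.level)

    def to_percent(self) -> "AbundanceTable":
        if self.mode == "percent":
            return AbundanceTable(self.data.copy(), "percent", self.level)
        return AbundanceTable(self.data * 100.0, "percent", self.level)

    def select_rank(self, rank: str = "s__") -> "AbundanceTable":
        """Restrict to rows whose deepest clade is at `rank`.

        For ``rank="s__"`` this keeps rows containing an ``s__``
        segment but no strain-level ``t__`` segment, matching how
        species are extracted from a merged multi-rank table.
        """
        order = ["k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__"]
        if rank not in order:
            raise ValueError(f"unknown rank tag {rank!r}")
        deeper = order[order.index(rank) + 1 :]

        def _keep(name: str) -> bool:
            segments = str(name).split("|")
            has = any(seg.startswith(rank) for seg in segments)
            has_deeper = any(
                seg.startswith(d) for seg in segments for d in deeper
            )
            return has and not has_deeper

        mask = [_keep(f) for f in self.data.index]
        return AbundanceTable(self.data.loc[mask].copy(), self.mode, rank)

    def write(self, path, index_label: str = "clade_name") -> None:
        write_abundance_table(self, path, index_label=index_label)


def _detect_mode(data: pd.DataFrame) -> str:
    """Percent vs fraction, from per-sample sums of the deepest rank."""
    has_ranks = any("s__" in str(f) for f in data.index)
    if has_ranks:
        mask = [
            "s__" in str(f) and "t__" not in str(f) for f in data.index
        ]
        probe = data.loc[mask] if any(mask) else data
    else:
        probe = data
    median_sum = float(np.median(probe.sum(axis=0)))
    return "percent" if median_sum > 2.0 else "fraction"


def read_abundance_table(path, dialect: str = "auto") -> AbundanceTable:
    """Read a MetaPhlAn2/HUMAnN2-style merged TSV into an AbundanceTable.

    The first column holds feature ids (header commonly ``clade_name``,
    ``#SampleID``, or a pathway id column); remaining columns must be
    numeric. Percent vs fraction scale is auto-detected from column
    sums and recorded on the returned table.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature column plus >=1 sample")
    feature_col = raw.columns[0]
    raw = raw.set_index(feature_col)
    converted_cols = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(np.nonzero(converted.isna().to_numpy())[0][0]) + 2
            raise ParseError(f"{path}: missing value in column {col!r} at line {line}")
        converted_cols[col] = converted
    numeric = pd.DataFrame(converted_cols, index=raw.index)
    if (numeric.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative abundance values")
    if dialect == "auto":
        mode = _detect_mode(numeric)
    elif dialect in ("percent", "fraction"):
        mode = dialect
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return AbundanceTable(numeric, mode=mode)


def write_abundance_table(table: AbundanceTable, path, index_label="clade_name"):
    table.data.to_csv(path, sep="\t", index_label=index_label, float_format="%.12g")


def read_metadata(path) -> pd.DataFrame:
    """Read long-format participant metadata (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(path, sep=sep)
    missing = {"participant_id", "visit"} - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing required columns: {sorted(missing)}")
    return meta


def filter_prevalence(
    table: AbundanceTable, min_abund: float = 0.01, min_prev: float = 0.10
) -> AbundanceTable:
    """Keep features detected at >= `min_abund` percent in enough samples.

    `min_abund` is always given in percent units (default 0.01, i.e.
    0.01%) and converted to the table's scale internally; `min_prev`
    is the required fraction of samples, with the count threshold
    ``ceil(min_prev * n_samples)``. Feature ordering is preserved.
    """
    if not 0 < min_prev <= 1:
        raise ValueError("min_prev must be in (0, 1]")
    threshold = min_abund if table.mode == "percent" else min_abund / 100.0
    values = table.data.to_numpy(dtype=float)
    n_required = int(np.ceil(min_prev * table.n_samples))
    detected = (values >= threshold).sum(axis=1)
    mask = detected >= n_required
    if not mask.any():
        warnings.warn("prevalence filter removed every feature", stacklevel=2)
    return AbundanceTable(table.data.loc[mask].copy(), table.mode, table.level)


def log_transform(
    table: AbundanceTable, zero_replacement: float = 1e-5
) -> pd.DataFrame:
    """Natural-log abundances after replacing zeros with a small constant.

    Zero replacement is defined on the fraction scale (default 1e-5
    for species tables; 1e-9 is conventional for pathway tables), so a
    percent-mode table is converted to fractions first. Non-zero
    values are left untouched before the log.
    """
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be positive")
    frac = table.to_fraction().data.to_numpy(dtype=float)
    if (frac < 0).any():
        raise ValidationError("negative abundance values")
    filled = np.where(frac == 0.0, zero_replacement, frac)
    return pd.DataFrame(
        np.log(filled), index=table.data.index, columns=table.data.columns
    )


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class PairedCohort:
    """Per-participant baseline/follow-up records plus aligned features.

    `meta` is wide, one row per participant: static covariates taken
    from the baseline visit plus ``_baseline``/``_followup`` suffixed
    time-varying columns. Feature matrices (participants x features,
    log abundances) are attached by :func:`attach_features`.
    """

    meta: pd.DataFrame
    features_baseline: pd.DataFrame | None = None
    features_followup: pd.DataFrame | None = None
    exclusion_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            raise ValidationError("duplicate participants in cohort")
        for feats in (self.features_baseline, self.features_followup):
            if feats is not None and not feats.index.equals(self.meta.index):
                raise ValidationError("feature rows not aligned to cohort")
        if (
            self.features_baseline is not None
            and self.features_followup is not None
            and not self.features_baseline.columns.equals(
                self.features_followup.columns
            )
        ):
            raise ValidationError("baseline/follow-up feature indexes differ")

    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def feature_ids(self) -> list[str]:
        if self.features_baseline is None:
            return []
        return list(self.features_baseline.columns)


_TIME_VARYING = [
    "bmi",
    "wc",
    "weight",
    "height",
    "bristol",
    "fasting_insulin",
    "fasting_glucose",
    "hba1c",
    "diabetes_medication",
]
_STATIC = [
    "age",
    "sex",
    "smoking",
    "alcohol",
    "education",
    "income",
    "physical_activity",
    "energy_intake",
    "race",
]


def pair_records(records: pd.DataFrame) -> pd.DataFrame:
    """Pivot long participant-visit records to one wide row per pair.

    Participants lacking exactly the two visits {baseline, follow_up}
    are dropped with a warning. Static covariates and the follow-up
    interval are carried from the baseline row.
    """
    visits = set(records["visit"].unique())
    bad = visits - {"baseline", "follow_up"}
    if bad:
        raise ValidationError(f"unknown visit labels: {sorted(bad)}")
    counts = records.groupby("participant_id")["visit"].nunique()
    sizes = records.groupby("participant_id").size()
    complete = counts[(counts == 2) & (sizes == 2)].index
    n_unpaired = records["participant_id"].nunique() - len(complete)
    if n_unpaired:
        warnings.warn(f"dropping {n_unpaired} unpaired participants", stacklevel=2)
    sub = records[records["participant_id"].isin(complete)]
    base = sub[sub["visit"] == "baseline"].set_index("participant_id")
    follow = sub[sub["visit"] == "follow_up"].set_index("participant_id")
    follow = follow.loc[base.index]

    wide = pd.DataFrame(index=base.index)
    for col in _STATIC:
        if col in base.columns:
            wide[col] = base[col]
    for col in _TIME_VARYING:
        if col in base.columns:
            wide[f"{col}_baseline"] = base[col]
        if col in follow.columns:
            wide[f"{col}_followup"] = follow[col]
    if "followup_interval" in base.columns:
        wide["interval"] = base["followup_interval"]
    # convenience alias: baseline bristol is the default covariate
    if "bristol_baseline" in wide.columns:
        wide["bristol"] = wide["bristol_baseline"]
    return wide


def apply_exclusions(
    records: pd.DataFrame,
    criteria: tuple[str, ...] = DEFAULT_EXCLUSION_CRITERIA,
) -> PairedCohort:
    """Pair visits and drop participants failing any exclusion criterion.

    Criteria (any subset of :data:`DEFAULT_EXCLUSION_CRITERIA`):

    - ``missing_bmi``: BMI missing at baseline or follow-up
    - ``missing_interval``: follow-up time missing or non-positive
    - ``diabetes_medication``: medication flag set at either visit

    A participant failing several criteria is removed once; the
    per-criterion flag counts and the union are recorded in
    ``exclusion_log``.
    """
    unknown = set(criteria) - set(DEFAULT_EXCLUSION_CRITERIA)
    if unknown:
        raise ValueError(f"unknown exclusion criteria: {sorted(unknown)}")
    wide = pair_records(records)
    flagged: dict[str, pd.Index] = {}
    if "missing_bmi" in criteria:
        flagged["missing_bmi"] = wide.index[
            wide.get("bmi_baseline", pd.Series(np.nan, index=wide.index)).isna()
            | wide.get("bmi_followup", pd.Series(np.nan, index=wide.index)).isna()
        ]
    if "missing_interval" in criteria:
        interval = wide.get("interval", pd.Series(np.nan, index=wide.index))
        flagged["missing_interval"] = wide.index[
            interval.isna() | (interval <= 0)
        ]
    if "diabetes_medication" in criteria:
        med_b = wide.get(
            "diabetes_medication_baseline", pd.Series(0, index=wide.index)
        ).fillna(0)
        med_f = wide.get(
            "diabetes_medication_followup", pd.Series(0, index=wide.index)
        ).fillna(0)
        flagged["diabetes_medication"] = wide.index[(med_b > 0) | (med_f > 0)]
    union: set = set()
    log: dict = {}
    for name, idx in flagged.items():
        log[f"flagged_{name}"] = len(idx)
        union |= set(idx)
        logger.info("exclusion %s flagged %d participants", name, len(idx))
    log["removed_total"] = len(union)
    log["n_pairs_in"] = len(wide)
    kept = wide.loc[~wide.index.isin(union)].copy()
    log["n_remaining"] = len(kept)
    return PairedCohort(meta=kept, exclusion_log=log)


def attach_features(
    cohort: PairedCohort,
    baseline: AbundanceTable,
    follow_up: AbundanceTable,
    zero_replacement: float = 1e-5,
    transform: bool = True,
) -> PairedCohort:
    """Align per-visit abundance tables to the cohort as feature matrices.

    Sample ids in each table must be participant ids. Tables are
    log-transformed (zero-replaced) by default; pass
    ``transform=False`` to attach raw relative abundances.
    """
    shared = baseline.data.columns.intersection(follow_up.data.columns)
    missing = cohort.meta.index.difference(shared)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} cohort participants lack samples in both tables"
        )
    common_feats = baseline.data.index.intersection(follow_up.data.index)
    b = AbundanceTable(
        baseline.data.loc[common_feats, cohort.meta.index],
        baseline.mode,
        baseline.level,
    )
    f = AbundanceTable(
        follow_up.data.loc[common_feats, cohort.meta.index],
        follow_up.mode,
        follow_up.level,
    )
    if transform:
        fb = log_transform(b, zero_replacement).T
        ff = log_transform(f, zero_replacement).T
    else:
        fb = b.data.T
        ff = f.data.T
    return PairedCohort(
        meta=cohort.meta,
        features_baseline=fb,
        features_followup=ff,
        exclusion_log=cohort.exclusion_log,
    )


# ---------------------------------------------------------------------------
# anthropometric derivations


def classify_weight(bmi):
    """BMI -> weight category per the WGOC Chinese cut-offs.

    Half-open intervals: <18.5 underweight, [18.5, 24) normal,
    [24, 28) overweight, >=28 obesity. Accepts scalars or arrays.
    """
    arr = np.asarray(bmi, dtype=float)
    if np.isnan(arr).any() or (arr <= 0).any():
        raise ValueError("bmi must be positive and non-missing")
    cats = np.select(
        [arr < 18.5, arr < 24.0, arr < 28.0],
        ["underweight", "normal", "overweight"],
        default="obesity",
    )
    if np.ndim(bmi) == 0:
        return str(cats[()])
    return cats


def is_adiposity(bmi):
    """Adiposity flag: overweight or obesity (BMI >= 24)."""
    cat = classify_weight(bmi)
    return np.isin(cat, ("overweight", "obesity")) if np.ndim(bmi) else cat in (
        "overweight",
        "obesity",
    )


def weight_change_pattern(bmi_baseline, bmi_followup):
    """Cross the two visits' adiposity flags into a weight-change pattern.

    Underweight at either visit maps to ``excluded_underweight``.
    """
    b = np.asarray(bmi_baseline, dtype=float)
    f = np.asarray(bmi_followup, dtype=float)
    cat_b = classify_weight(b)
    cat_f = classify_weight(f)
    under = (np.asarray(cat_b) == "underweight") | (np.asarray(cat_f) == "underweight")
    adi_b = np.isin(cat_b, ("overweight", "obesity"))
    adi_f = np.isin(cat_f, ("overweight", "obesity"))
    pattern = np.select(
        [under, ~adi_b & ~adi_f, ~adi_b & adi_f, adi_b & ~adi_f],
        [
            "excluded_underweight",
            "stable_normal",
            "normal_to_adiposity",
            "adiposity_to_normal",
        ],
        default="stable_adiposity",
    )
    if np.ndim(bmi_baseline) == 0 and np.ndim(bmi_followup) == 0:
        return str(pattern[()])
    return pattern


def compute_homa_ir(fasting_insulin, fasting_glucose):
    """HOMA-IR = insulin (uU/mL) x glucose (mmol/L) / 22.5."""
    ins = np.asarray(fasting_insulin, dtype=float)
    glu = np.asarray(fasting_glucose, dtype=float)
    if (ins <= 0).any() or (glu <= 0).any():
        raise ValueError("fasting insulin and glucose must be positive")
    out = ins * glu / 22.5
    if np.ndim(fasting_insulin) == 0 and np.ndim(fasting_glucose) == 0:
        return float(out)
    return out
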