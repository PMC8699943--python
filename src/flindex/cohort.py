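"""Subject-level cohort table: ingestion, validation, exclusions, comorbidities.

The cohort is carried as a :class:`pandas.DataFrame` with one row per
subject and the canonical columns listed in :data:`COLUMNS`. Quantitative
columns are floats with ``NaN`` for missing; flag columns use the pandas
nullable boolean dtype so that missingness propagates through logic
(Kleene three-valued semantics).

The exclusion cascade mirrors the screening design of health-checkup
NAFLD studies: subjects with hepatitis B or C serology, significant
alcohol intake (sex-specific thresholds), or missing analysis-critical
fields are removed sequentially, each subject attributed to the first
matching reason so the per-reason counts are disjoint and sum to the
excluded total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order for a cohort table.
COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "bmi",
    "wc",
    "sbp",
    "dbp",
    "fasting_glucose",
    "tg",
    "ast",
    "alt",
    "ggt",
    "creatinine",
    "alcohol",
    "hbv_positive",
    "hcv_positive",
    "on_antihypertensives",
    "on_glucose_lowering",
    "us_steatosis",
    "cap",
    "lsm_median",
    "lsm_iqr_over_median",
    "lsm_n_valid",
)

NUMERIC_COLUMNS = (
    "age", "bmi", "wc", "sbp", "dbp", "fasting_glucose", "tg", "ast",
    "alt", "ggt", "creatinine", "alcohol", "cap", "lsm_median",
    "lsm_iqr_over_median", "lsm_n_valid",
)

BOOLEAN_COLUMNS = (
    "hbv_positive", "hcv_positive", "on_antihypertensives",
    "on_glucose_lowering", "us_steatosis",
)

#: Columns that must exist in any input file.
MANDATORY_COLUMNS = ("sex", "bmi", "wc", "tg", "ggt")

#: Fields whose absence sends a subject to the "missing" exclusion bucket:
#: everything the fatty liver index needs, plus sex (stratification) and
#: the ultrasound reference label.
DEFAULT_REQUIRED_FIELDS = ("sex", "bmi", "wc", "tg", "ggt", "us_steatosis")

#: Plausibility window for controlled attenuation parameter readings, dB/m.
CAP_PLAUSIBLE = (100.0, 400.0)

_TRUE_TOKENS = {"true", "t", "1", "yes", "y", "1.0"}
_FALSE_TOKENS = {"false", "f", "0", "no", "n", "0.0"}


class SchemaError(ValueError):
    """An input table is missing a mandatory column."""


@dataclass
class ParseReport:
    """Tally of cells that could not be used as-is during ingestion."""

    n_rows: int = 0
    n_bad_cells: int = 0
    by_column: dict = field(default_factory=dict)

    def count(self, column: str, n: int) -> None:
        if n:
            self.n_bad_cells += int(n)
            self.by_column[column] = self.by_column.get(column, 0) + int(n)


@dataclass
class ExclusionLog:
    """Ordered per-reason exclusion counts with the conservation identity."""

    entries: list = field(default_factory=list)  # [(reason, count), ...]
    n_initial: int = 0
    n_final: int = 0

    def __post_init__(self) -> None:
        total = sum(c for _, c in self.entries)
        if self.n_final != self.n_initial - total:
            raise ValueError(
                f"exclusion arithmetic violated: {self.n_initial} - {total} "
                f"!= {self.n_final}"
            )
        if any(c < 0 for _, c in self.entries):
            raise ValueError("negative exclusion count")

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_final": self.n_final,
            "excluded": {reason: count for reason, count in self.entries},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _coerce_boolean(series: pd.Series) -> tuple[pd.Series, int]:
    """Map string/numeric truth tokens to the nullable boolean dtype."""
    s = series.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=series.index, dtype="boolean")
    out[s.isin(_TRUE_TOKENS)] = True
    out[s.isin(_FALSE_TOKENS)] = False
    bad = int((s.notna() & (s != "") & out.isna()).sum())
    return out, bad


def read_cohort(path, schema: dict | None = None, sep=None):
    """Read a delimited-text cohort table.

    Parameters
    ----------
    path : str or path-like
        Comma- or tab-separated file with one header row.
    schema : dict, optional
        Mapping from file column names to canonical field names in
        :data:`COLUMNS`; columns not mentioned keep their own name.
    sep : str, optional
        Field separator; sniffed from the header when omitted.

    Returns
    -------
    (cohort, report) : (pandas.DataFrame, ParseReport)
        Unparseable or out-of-range cells become missing and are
        counted in the report, never dropped silently.

    Raises
    ------
    SchemaError
        If a mandatory column (after renaming) is absent.
    """
    with open(path) as fh:
        if not fh.read(4096).strip():
            return pd.DataFrame(columns=list(COLUMNS)), ParseReport()
    try:
        raw = pd.read_csv(path, dtype=str, sep=sep, engine="python",
                          skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(COLUMNS)), ParseReport()
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing_cols = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")

    report = ParseReport(n_rows=len(raw))
    df = pd.DataFrame(index=raw.index)

    df["subject_id"] = (
        raw["subject_id"].astype("string")
        if "subject_id" in raw.columns
        else pd.Series([f"S{i + 1:05d}" for i in raw.index], dtype="string",
                       index=raw.index)
    )

    sex = raw["sex"].astype("string").str.strip().str.lower()
    sex_ok = sex.isin(["male", "female", "m", "f"])
    report.count("sex", int((sex.notna() & ~sex_ok).sum()))
    df["sex"] = sex.where(sex_ok).replace({"m": "male", "f": "female"})

    for col in NUMERIC_COLUMNS:
        if col not in raw.columns:
            df[col] = np.nan
            continue
        present = raw[col].astype("string").str.strip()
        present = present.mask(present.isin(["", "NA", "NaN", "nan", "None"]))
        values = pd.to_numeric(present, errors="coerce")
        report.count(col, int((present.notna() & values.isna()).sum()))
        negative = values < 0
        report.count(col, int(negative.sum()))
        values = values.mask(negative)
        if col == "cap":
            implausible = (values < CAP_PLAUSIBLE[0]) | (values > CAP_PLAUSIBLE[1])
            report.count(col, int(implausible.sum()))
            values = values.mask(implausible)
        df[col] = values.astype(float)

    for col in BOOLEAN_COLUMNS:
        if col not in raw.columns:
            df[col] = pd.Series(pd.NA, index=raw.index, dtype="boolean")
            continue
        df[col], bad = _coerce_boolean(raw[col])
        report.count(col, bad)

    return df[list(COLUMNS)], report


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort table in the same delimited-text schema it is read from."""
    df.to_csv(path, sep=sep, index=False)


def apply_exclusions(
    cohort: pd.DataFrame,
    male_alcohol_max: float = 20.0,
    female_alcohol_max: float = 10.0,
    required_fields: tuple = DEFAULT_REQUIRED_FIELDS,
):
    """Apply the exclusion cascade HBV -> HCV -> alcohol -> missing fields.

    Each subject is attributed to the first matching reason only, so the
    logged counts are disjoint. Alcohol intake strictly above the
    sex-specific limit (default >20 g/day male, >10 g/day female) excludes;
    intake exactly at the limit is retained.

    Returns
    -------
    (retained, log) : (pandas.DataFrame, ExclusionLog)
    """
    if male_alcohol_max <= 0 or female_alcohol_max <= 0:
        raise ValueError("alcohol thresholds must be positive")
    n_initial = len(cohort)
    remaining = cohort

    def _take(mask: pd.Series):
        nonlocal remaining
        n = int(mask.sum())
        remaining = remaining.loc[~mask]
        return n

    hbv = _take(remaining["hbv_positive"].fillna(False).astype(bool))
    hcv = _take(remaining["hcv_positive"].fillna(False).astype(bool))

    limit = remaining["sex"].map(
        {"male": male_alcohol_max, "female": female_alcohol_max}
    ).astype(float)
    alcohol = _take((remaining["alcohol"] > limit).fillna(False))

    fields = [f for f in required_fields if f in remaining.columns]
    missing = _take(remaining[fields].isna().any(axis=1))

    log = ExclusionLog(
        entries=[("hbv", hbv), ("hcv", hcv), ("alcohol", alcohol),
                 ("missing", missing)],
        n_initial=n_initial,
        n_final=len(remaining),
    )
    return remaining.copy(), log


def derive_comorbidities(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add nullable-boolean ``hypertension`` and ``diabetes`` columns.

    Hypertension: systolic >= 140 mmHg, diastolic >= 90 mmHg, or current
    antihypertensive medication. Diabetes: fasting glucose >= 126 mg/dL or
    glucose-lowering treatment. A flag is missing only when no component
    can decide it (Kleene OR: one True component settles the flag even if
    others are missing).
    """
    out = cohort.copy()
    sbp_high = pd.array(out["sbp"].to_numpy() >= 140, dtype="boolean")
    sbp_high[out["sbp"].isna().to_numpy()] = pd.NA
    dbp_high = pd.array(out["dbp"].to_numpy() >= 90, dtype="boolean")
    dbp_high[out["dbp"].isna().to_numpy()] = pd.NA
    glu_high = pd.array(out["fasting_glucose"].to_numpy() >= 126, dtype="boolean")
    glu_high[out["fasting_glucose"].isna().to_numpy()] = pd.NA

    out["hypertension"] = (
        pd.Series(sbp_high, index=out.index)
        | pd.Series(dbp_high, index=out.index)
        | out["on_antihypertensives"].astype("boolean")
    )
    out["diabetes"] = (
        pd.Series(glu_high, index=out.index)
        | out["on_glucose_lowering"].astype("boolean")
    )
    return out
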