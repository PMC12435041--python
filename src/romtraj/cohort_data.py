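"""Domain types, CSV I/O, validation and interval binning for longitudinal ROM cohorts.

A cohort is two tables:

* a **patient table** — one row per shoulder, with prosthesis type
  (aTSA/rTSA), demographics, diagnosis and comorbidity flags, and
  radiographic/complication fields;
* a **visit table** in long format — one row per (patient, time point,
  measure), where a measure is one of the four active range-of-motion
  measures (abduction, forward elevation, external rotation in degrees; the
  ordinal 0-6 internal-rotation score) or an opaque patient-reported outcome
  score carried along for reporting.

Time is measured in months since surgery; the preoperative assessment is
stored at time 0 with ``is_preop = 1``.

Validation is total: malformed input raises a typed error
(:class:`SchemaError`, :class:`ValidationError`, :class:`IntegrityError`)
rather than being silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Measures

ANGLE_MEASURES: tuple[str, ...] = ("abduction", "forward_elevation", "external_rotation")
ROM_MEASURES: tuple[str, ...] = ANGLE_MEASURES + ("ir_score",)
PRO_MEASURES: tuple[str, ...] = ("vas_pain", "function", "ases", "constant", "sas")
ALL_MEASURES: tuple[str, ...] = ROM_MEASURES + PRO_MEASURES

ANGLE_RANGE: tuple[float, float] = (0.0, 200.0)
IR_SCORE_RANGE: tuple[int, int] = (0, 6)

PROSTHESES: tuple[str, ...] = ("aTSA", "rTSA")
SEXES: tuple[str, ...] = ("F", "M", "unknown")


class CohortError(ValueError):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """A required column is missing or a file does not match the schema."""


class ValidationError(CohortError):
    """A value is out of range, inconsistent, or of the wrong kind."""


class IntegrityError(CohortError):
    """Referential integrity or uniqueness violated."""


# ---------------------------------------------------------------------------
# Windows and bins


@dataclass(frozen=True)
class AnalysisWindows:
    """Analysis windows on the months-since-surgery axis.

    ``recovery`` is the nominal 0-24-month recovery period over which
    per-visit rates of improvement are computed (membership is decided by
    the interval bins, whose last bin extends past 24 months so that
    late "2-year" visits are kept); ``peak`` is the closed 2-3-year window
    searched for each patient's peak value; ``longterm`` is the left-closed
    96+-month window over which rates of decline are computed.
    """

    recovery_start: float = 0.0
    recovery_end: float = 24.0
    peak_start: float = 24.0
    peak_end: float = 36.0
    longterm_start: float = 96.0

    def __post_init__(self) -> None:
        if not (self.recovery_start <= self.recovery_end <= self.peak_start
                <= self.peak_end <= self.longterm_start):
            raise ValidationError(
                "analysis windows must be ordered: recovery <= peak <= longterm")


@dataclass(frozen=True)
class IntervalBin:
    """A postoperative interval bin: ``lower <= t < upper`` months (t > 0)."""

    nominal_months: int
    lower: float
    upper: float

    def contains(self, time_months: float) -> bool:
        return self.lower <= time_months < self.upper and time_months > 0


#: Default bins: edges at midpoints between scheduled visits; the 24-month
#: bin runs to 30 months so late "2-year" visits are not dropped.
DEFAULT_BINS: tuple[IntervalBin, ...] = (
    IntervalBin(3, 0.0, 4.5),
    IntervalBin(6, 4.5, 9.0),
    IntervalBin(12, 9.0, 18.0),
    IntervalBin(24, 18.0, 30.0),
)

DEFAULT_WINDOWS = AnalysisWindows()


def bin_interval(time_months: float,
                 bins: Sequence[IntervalBin] = DEFAULT_BINS) -> Optional[IntervalBin]:
    """Map a postoperative time to its interval bin, or ``None`` if outside all bins.

    Parameters
    ----------
    time_months : positive months since surgery.
    bins : candidate bins; the defaults partition (0, 30) months.
    """
    if time_months <= 0:
        raise ValidationError(f"bin_interval requires time_months > 0, got {time_months}")
    for b in bins:
        if b.contains(time_months):
            return b
    return None


# ---------------------------------------------------------------------------
# Table schemas

PATIENT_COLUMNS: tuple[str, ...] = (
    "patient_id", "prosthesis", "age_years", "sex", "bmi",
    "previous_surgery", "injections",
    "dx_osteoarthritis", "dx_osteonecrosis", "dx_rotator_cuff_tear",
    "dx_cuff_tear_arthropathy", "dx_rheumatoid_arthritis",
    "cm_none", "cm_hypertension", "cm_heart_disease", "cm_diabetes",
    "cm_tobacco", "cm_renal_failure",
    "humeral_rll", "glenoid_rll", "glenoid_rll_grade",
    "scapular_notching", "notching_grade",
    "complication", "revision", "revision_time_months",
)

VISIT_COLUMNS: tuple[str, ...] = ("patient_id", "time_months", "is_preop", "measure", "value")

PATIENT_BOOL_COLUMNS: tuple[str, ...] = (
    "previous_surgery", "injections",
    "dx_osteoarthritis", "dx_osteonecrosis", "dx_rotator_cuff_tear",
    "dx_cuff_tear_arthropathy", "dx_rheumatoid_arthritis",
    "cm_none", "cm_hypertension", "cm_heart_disease", "cm_diabetes",
    "cm_tobacco", "cm_renal_failure",
    "humeral_rll", "glenoid_rll", "scapular_notching", "complication", "revision",
)

COMORBIDITY_FLAGS: tuple[str, ...] = (
    "cm_hypertension", "cm_heart_disease", "cm_diabetes", "cm_tobacco", "cm_renal_failure",
)


def round_half_up(x: float, step: float = 1.0) -> float:
    """Round to the nearest multiple of ``step``, halves away from zero-free (half-up)."""
    return math.floor(x / step + 0.5) * step


# ---------------------------------------------------------------------------
# Dataset container


@dataclass
class CohortDataset:
    """A validated pair of patient and visit tables.

    ``patients`` has exactly the columns of :data:`PATIENT_COLUMNS`;
    ``visits`` has exactly the columns of :data:`VISIT_COLUMNS`. Construct
    via :func:`read_cohort`, :func:`romtraj.synthetic_cohort.simulate_cohort`,
    or directly from frames followed by :meth:`validate`.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def prosthesis_of(self) -> pd.Series:
        """patient_id -> prosthesis mapping."""
        return self.patients.set_index("patient_id")["prosthesis"]

    def preop_values(self) -> pd.DataFrame:
        """Preoperative rows of the visit table."""
        return self.visits[self.visits["is_preop"] == 1]

    def validate(self) -> "CohortDataset":
        _validate_patients(self.patients)
        _validate_visits(self.visits)
        known = set(self.patients["patient_id"])
        unknown = set(self.visits["patient_id"]) - known
        if unknown:
            raise IntegrityError(
                f"visits reference unknown patient ids: {sorted(unknown)[:5]}")
        return self


# ---------------------------------------------------------------------------
# Validation internals


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing required column(s): {missing}")


def _check_bool(df: pd.DataFrame, col: str, table: str) -> None:
    vals = df[col].dropna()
    bad = ~vals.isin([0, 1, 0.0, 1.0])
    if bad.any():
        row = vals[bad].index[0]
        raise ValidationError(
            f"{table}.{col} must be 0/1; row {row} has {vals[bad].iloc[0]!r}")


def _validate_patients(patients: pd.DataFrame) -> None:
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    dup = patients["patient_id"].duplicated()
    if dup.any():
        raise IntegrityError(
            f"duplicate patient_id: {patients.loc[dup, 'patient_id'].iloc[0]!r}")
    bad_pros = ~patients["prosthesis"].isin(PROSTHESES)
    if bad_pros.any():
        raise ValidationError(
            f"prosthesis must be one of {PROSTHESES}; got "
            f"{patients.loc[bad_pros, 'prosthesis'].iloc[0]!r}")
    bad_sex = ~patients["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"sex must be one of {SEXES}; got {patients.loc[bad_sex, 'sex'].iloc[0]!r}")
    for col in PATIENT_BOOL_COLUMNS:
        _check_bool(patients, col, "patients")
    # cm_none = 1 implies all other comorbidity flags are 0
    none_on = patients["cm_none"] == 1
    if none_on.any():
        others = patients.loc[none_on, list(COMORBIDITY_FLAGS)]
        if (others == 1).any().any():
            raise ValidationError(
                "cm_none = 1 is inconsistent with another comorbidity flag set")
    # revision_time_months present <=> revision = 1
    has_time = patients["revision_time_months"].notna()
    is_rev = patients["revision"] == 1
    if (has_time != is_rev).any():
        row = patients.index[(has_time != is_rev)][0]
        raise ValidationError(
            f"row {row}: revision_time_months must be present iff revision = 1")
    for col, lo, hi in (("glenoid_rll_grade", 0, 5), ("notching_grade", 0, 4)):
        vals = patients[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise ValidationError(f"patients.{col} outside [{lo}, {hi}]")


def _validate_visits(visits: pd.DataFrame) -> None:
    _require_columns(visits, VISIT_COLUMNS, "visits")
    if len(visits) == 0:
        return
    bad_measure = ~visits["measure"].isin(ALL_MEASURES)
    if bad_measure.any():
        raise ValidationError(
            f"unknown measure {visits.loc[bad_measure, 'measure'].iloc[0]!r}; "
            f"must be one of {ALL_MEASURES}")
    if visits["time_months"].isna().any() or (visits["time_months"] < 0).any():
        raise ValidationError("time_months must be a non-negative number")
    if visits["value"].isna().any():
        row = visits.index[visits["value"].isna()][0]
        raise ValidationError(f"row {row}: visit value is missing")
    _check_bool(visits, "is_preop", "visits")
    # is_preop = 1 <=> time_months = 0
    preop = visits["is_preop"] == 1
    at_zero = visits["time_months"] == 0
    if (preop != at_zero).any():
        row = visits.index[(preop != at_zero)][0]
        raise ValidationError(
            f"row {row}: is_preop must be 1 exactly when time_months = 0")
    dup = visits.duplicated(subset=["patient_id", "time_months", "measure"])
    if dup.any():
        key = visits.loc[dup, ["patient_id", "time_months", "measure"]].iloc[0]
        raise IntegrityError(
            f"duplicate visit record for {tuple(key)} — "
            "(patient_id, time_months, measure) must be unique")
    # Range checks per measure family
    is_angle = visits["measure"].isin(ANGLE_MEASURES)
    angles = visits.loc[is_angle, "value"]
    out = (angles < ANGLE_RANGE[0]) | (angles > ANGLE_RANGE[1])
    if out.any():
        row = angles[out].index[0]
        raise ValidationError(
            f"row {row}: angle value {angles[out].iloc[0]} outside "
            f"[{ANGLE_RANGE[0]}, {ANGLE_RANGE[1]}] degrees")
    ir = visits.loc[visits["measure"] == "ir_score", "value"]
    ir_rounded = ir.map(round_half_up)
    out = (ir_rounded < IR_SCORE_RANGE[0]) | (ir_rounded > IR_SCORE_RANGE[1])
    if out.any():
        row = ir[out].index[0]
        raise ValidationError(
            f"row {row}: ir_score value {ir[out].iloc[0]} outside valid range "
            f"[{IR_SCORE_RANGE[0]}, {IR_SCORE_RANGE[1]}]")


# ---------------------------------------------------------------------------
# CSV I/O


def read_cohort(patients_path: str | Path, visits_path: str | Path) -> CohortDataset:
    """Read and validate a cohort from the two-table CSV layout.

    ``ir_score`` values are rounded half-up to the nearest integer before
    range checking, then stored rounded.

    Raises
    ------
    SchemaError, ValidationError, IntegrityError
        On missing columns, out-of-range values, duplicate keys, or visits
        referencing unknown patients.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    visits = pd.read_csv(visits_path, dtype={"patient_id": str})
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    _require_columns(visits, VISIT_COLUMNS, "visits")
    patients = patients[list(PATIENT_COLUMNS)]
    visits = visits[list(VISIT_COLUMNS)]
    if len(visits):
        visits["time_months"] = visits["time_months"].astype(float)
        visits["value"] = visits["value"].astype(float)
    ds = CohortDataset(patients=patients, visits=visits).validate()
    ir = ds.visits["measure"] == "ir_score"
    ds.visits.loc[ir, "value"] = ds.visits.loc[ir, "value"].map(round_half_up)
    return ds


def write_cohort(dataset: CohortDataset,
                 patients_path: str | Path,
                 visits_path: str | Path) -> None:
    """Write a validated cohort to CSV so that :func:`read_cohort` round-trips it.

    Floats are written with ``repr`` precision, so numeric values survive the
    round trip exactly; booleans are written as 0/1; missing values as empty
    cells.
    """
    dataset.validate()
    patients = dataset.patients[list(PATIENT_COLUMNS)].copy()
    for col in PATIENT_BOOL_COLUMNS:
        patients[col] = patients[col].astype(int)
    patients.to_csv(patients_path, index=False)
    visits = dataset.visits[list(VISIT_COLUMNS)].copy()
    if len(visits):
        visits["is_preop"] = visits["is_preop"].astype(int)
    visits.to_csv(visits_path, index=False)
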