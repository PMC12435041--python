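"""Cohort rate baselines and fast/average/slow voting classification.

The baseline is the arithmetic mean rate per cohort cell: for ROI a cell is
(prosthesis, measure, interval bin); for ROD it is (prosthesis, measure).
Each of a patient's rate records with a matching cell casts one vote; the
vote counts as an *exceedance* when the rate is strictly greater than the
cell mean.  With exceedance fraction f over n votes:

* f > 2/3  -> FAST
* f < 1/3  -> SLOW
* otherwise -> AVERAGE
* n below ``min_votes`` -> UNCLASSIFIED

Thresholds are compared exactly (as rationals), so a patient with 4 of 6
votes sits precisely at 2/3 and is AVERAGE.  For ROD the rates are stored
decline-positive, so exceeding the mean decline labels the patient FAST.
The baseline includes the patient's own records — votes are against the full
cohort average, with no leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd

from .cohort_data import CohortDataset, ValidationError

LABELS = ("FAST", "AVERAGE", "SLOW", "UNCLASSIFIED")

RESULT_COLUMNS = ("patient_id", "kind", "label", "n_votes", "n_exceed", "fraction")


@dataclass(frozen=True)
class ClassifierConfig:
    """Voting thresholds (exact rationals) and minimum vote count.

    ``vote_unit="visit"`` casts one vote per rate record (per measure, per
    visit); ``"measure_mean"`` first averages a patient's rates per measure
    and casts one vote per measure.
    """

    fast_threshold: Fraction = Fraction(2, 3)
    slow_threshold: Fraction = Fraction(1, 3)
    min_votes: int = 4
    vote_unit: str = "visit"

    def __post_init__(self) -> None:
        if not (0 <= self.slow_threshold < self.fast_threshold <= 1):
            raise ValidationError("need 0 <= slow_threshold < fast_threshold <= 1")
        if self.vote_unit not in ("visit", "measure_mean"):
            raise ValidationError("vote_unit must be 'visit' or 'measure_mean'")


DEFAULT_CLASSIFIER = ClassifierConfig()


@dataclass
class CohortRateBaseline:
    """Mean rate per cohort cell.

    ``table`` has the grouping keys plus ``mean_rate`` and ``n``; cells with
    no records are simply absent.
    """

    kind: str
    keys: tuple[str, ...]
    table: pd.DataFrame


@dataclass(frozen=True)
class ClassificationResult:
    patient_id: str
    kind: str
    label: str
    n_votes: int
    n_exceed: int

    @property
    def fraction(self) -> float:
        return self.n_exceed / self.n_votes if self.n_votes else float("nan")


def compute_baseline(rate_records: pd.DataFrame, kind: str) -> CohortRateBaseline:
    """Arithmetic mean rate per cohort cell for records of the stated kind.

    ROI cells are (prosthesis, measure, interval_bin); ROD cells are
    (prosthesis, measure).  Empty input yields an empty baseline.
    """
    if kind not in ("ROI", "ROD"):
        raise ValueError("kind must be 'ROI' or 'ROD'")
    recs = rate_records[rate_records["kind"] == kind]
    keys = (("prosthesis", "measure", "interval_bin") if kind == "ROI"
            else ("prosthesis", "measure"))
    if len(recs) == 0:
        table = pd.DataFrame(columns=list(keys) + ["mean_rate", "n"])
    else:
        table = (recs.groupby(list(keys), as_index=False)
                 .agg(mean_rate=("rate", "mean"), n=("rate", "size")))
    return CohortRateBaseline(kind=kind, keys=keys, table=table)


def _label_from_counts(n_votes: int, n_exceed: int,
                       config: ClassifierConfig) -> str:
    if n_votes < config.min_votes:
        return "UNCLASSIFIED"
    frac = Fraction(int(n_exceed), int(n_votes))
    if frac > config.fast_threshold:
        return "FAST"
    if frac < config.slow_threshold:
        return "SLOW"
    return "AVERAGE"


def _votes(patient_rates: pd.DataFrame, baseline: CohortRateBaseline,
           config: ClassifierConfig) -> pd.DataFrame:
    merged = patient_rates.merge(baseline.table, on=list(baseline.keys), how="left")
    merged = merged[merged["mean_rate"].notna()]  # no-cell votes are skipped
    if config.vote_unit == "measure_mean":
        merged = (merged.groupby(["patient_id", "prosthesis", "measure"],
                                 as_index=False)
                  .agg(rate=("rate", "mean"), mean_rate=("mean_rate", "mean")))
    merged["exceed"] = merged["rate"] > merged["mean_rate"]
    return merged


def classify_patient(patient_rates: pd.DataFrame, baseline: CohortRateBaseline,
                     config: ClassifierConfig = DEFAULT_CLASSIFIER) -> ClassificationResult:
    """Classify one patient from their rate records of one kind."""
    pids = patient_rates["patient_id"].unique()
    if len(pids) != 1:
        raise ValidationError("classify_patient expects records of exactly one patient")
    kinds = patient_rates["kind"].unique()
    if len(kinds) != 1 or kinds[0] != baseline.kind:
        raise ValidationError("rate records and baseline must share one kind")
    votes = _votes(patient_rates, baseline, config)
    n_votes = int(len(votes))
    n_exceed = int(votes["exceed"].sum())
    return ClassificationResult(
        patient_id=str(pids[0]), kind=baseline.kind,
        label=_label_from_counts(n_votes, n_exceed, config),
        n_votes=n_votes, n_exceed=n_exceed)


def classify_cohort(dataset: CohortDataset, rate_records: pd.DataFrame, kind: str,
                    config: ClassifierConfig = DEFAULT_CLASSIFIER) -> pd.DataFrame:
    """Classify every patient with at least one vote-eligible record.

    The baseline is computed from the supplied records themselves.  Returns
    one row per patient: ``patient_id, kind, label, n_votes, n_exceed,
    fraction``.
    """
    baseline = compute_baseline(rate_records, kind)
    recs = rate_records[rate_records["kind"] == kind]
    if len(recs) == 0:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    votes = _votes(recs, baseline, config)
    counts = (votes.groupby("patient_id", as_index=False)
              .agg(n_votes=("exceed", "size"), n_exceed=("exceed", "sum")))
    counts["label"] = [
        _label_from_counts(nv, ne, config)
        for nv, ne in zip(counts["n_votes"], counts["n_exceed"])
    ]
    counts["kind"] = kind
    counts["fraction"] = counts["n_exceed"] / counts["n_votes"]
    return counts[list(RESULT_COLUMNS)].reset_index(drop=True)


def label_counts(results: pd.DataFrame) -> dict[str, int]:
    """Label -> patient count summary of a classification result frame."""
    counts = results["label"].value_counts().to_dict()
    return {label: int(counts.get(label, 0)) for label in LABELS}
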