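"""Per-visit rate-of-improvement (ROI), windowed peak, and rate-of-decline (ROD) records.

ROI for a measure at a recovery-period visit is

    (value at visit - preoperative value) / months since surgery,

one record per (patient, measure, in-bin visit).  The peak is the highest
value of each measure among a patient's visits in the 2-3-year window
(earliest visit wins ties).  ROD at a long-term (96+ month) visit is

    (peak value - value at visit) / (visit time - peak time),

stored decline-positive: a patient still improving after the peak has a
negative ROD.  The denominator can be switched to months-since-surgery via
``time_base="surgery"``.

Rates are computed only at observed visits; there is no smoothing or
interpolation.  Visits that cannot contribute (no preoperative counterpart,
no peak, or non-positive denominator) are skipped and reported in the
result's ``skipped`` frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_data import (
    AnalysisWindows,
    CohortDataset,
    DEFAULT_BINS,
    DEFAULT_WINDOWS,
    IntervalBin,
    ROM_MEASURES,
    ValidationError,
    bin_interval,
)

RATE_COLUMNS = ("patient_id", "prosthesis", "measure", "visit_time_months",
                "interval_bin", "kind", "rate")
PEAK_COLUMNS = ("patient_id", "prosthesis", "measure", "peak_value", "peak_time_months")


@dataclass
class RateResult:
    """Rate records plus a log of skipped visits.

    records : one row per retained (patient, measure, visit) with columns
        ``patient_id, prosthesis, measure, visit_time_months, interval_bin,
        kind, rate``; ``interval_bin`` is the nominal bin months for ROI and
        empty for ROD.
    skipped : rows excluded from the computation, with a ``reason`` column.
    """

    records: pd.DataFrame
    skipped: pd.DataFrame


def _rom_postop(dataset: CohortDataset) -> pd.DataFrame:
    v = dataset.visits
    out = v[(v["measure"].isin(ROM_MEASURES)) & (v["is_preop"] == 0)].copy()
    if (out["time_months"] <= 0).any():
        bad = out[out["time_months"] <= 0].iloc[0]
        raise ValidationError(
            f"postoperative visit at time {bad['time_months']} for patient "
            f"{bad['patient_id']!r} — time 0 visits must be flagged preoperative")
    return out


def _attach_prosthesis(df: pd.DataFrame, dataset: CohortDataset) -> pd.DataFrame:
    return df.merge(dataset.patients[["patient_id", "prosthesis"]],
                    on="patient_id", how="left")


def compute_roi_records(dataset: CohortDataset,
                        windows: AnalysisWindows = DEFAULT_WINDOWS,
                        bins: Sequence[IntervalBin] = DEFAULT_BINS) -> RateResult:
    """Rate-of-improvement records for every recovery-period visit.

    A visit contributes when it maps into an interval bin and the patient has
    a preoperative value for the same measure; otherwise it is skipped with a
    reason.
    """
    post = _rom_postop(dataset)
    pre = dataset.preop_values()
    pre = pre[pre["measure"].isin(ROM_MEASURES)][["patient_id", "measure", "value"]]
    pre = pre.rename(columns={"value": "preop_value"})

    post = post.assign(
        interval_bin=[
            (b.nominal_months if b is not None else np.nan)
            for b in (bin_interval(t, bins) for t in post["time_months"])
        ])
    merged = post.merge(pre, on=["patient_id", "measure"], how="left")

    out_of_window = merged["interval_bin"].isna()
    no_preop = merged["preop_value"].isna() & ~out_of_window
    skipped = pd.concat([
        merged[out_of_window].assign(reason="outside recovery bins"),
        merged[no_preop].assign(reason="no preoperative value for measure"),
    ], ignore_index=True)

    keep = merged[~out_of_window & ~merged["preop_value"].isna()].copy()
    keep["rate"] = (keep["value"] - keep["preop_value"]) / keep["time_months"]
    keep["kind"] = "ROI"
    keep["interval_bin"] = keep["interval_bin"].astype(int)
    keep = keep.rename(columns={"time_months": "visit_time_months"})
    keep = _attach_prosthesis(keep, dataset)
    records = keep[list(RATE_COLUMNS)].reset_index(drop=True)
    return RateResult(records=records,
                      skipped=skipped[["patient_id", "time_months", "measure",
                                       "reason"]].reset_index(drop=True))


def find_peak(dataset: CohortDataset,
              windows: AnalysisWindows = DEFAULT_WINDOWS) -> pd.DataFrame:
    """Peak value of each measure per patient within the closed peak window.

    Returns one row per (patient, measure) with at least one in-window visit:
    ``patient_id, prosthesis, measure, peak_value, peak_time_months``.  Ties
    resolve to the earliest in-window visit, which keeps the decline-rate
    denominator conservative.  Patients with no in-window visit for a measure
    yield no row and are thereby excluded from ROD for that measure.
    """
    v = dataset.visits
    inwin = v[(v["measure"].isin(ROM_MEASURES)) & (v["is_preop"] == 0)
              & (v["time_months"] >= windows.peak_start)
              & (v["time_months"] <= windows.peak_end)]
    if len(inwin) == 0:
        return pd.DataFrame(columns=list(PEAK_COLUMNS))
    best = (inwin.sort_values(["value", "time_months"], ascending=[False, True])
            .groupby(["patient_id", "measure"], as_index=False).first())
    best = best.rename(columns={"value": "peak_value",
                                "time_months": "peak_time_months"})
    best = _attach_prosthesis(best, dataset)
    return best[list(PEAK_COLUMNS)].reset_index(drop=True)


def compute_rod_records(dataset: CohortDataset, peaks: pd.DataFrame,
                        windows: AnalysisWindows = DEFAULT_WINDOWS,
                        time_base: str = "peak") -> RateResult:
    """Rate-of-decline records for every long-term (96+ month) visit.

    ``time_base="peak"`` (default) divides the loss from peak by the months
    elapsed since the peak visit; ``"surgery"`` divides by months since
    surgery.  Visits at or before the peak time, and visits of (patient,
    measure) pairs without a peak, are skipped.
    """
    if time_base not in ("peak", "surgery"):
        raise ValueError("time_base must be 'peak' or 'surgery'")
    post = _rom_postop(dataset)
    lt = post[post["time_months"] >= windows.longterm_start]
    merged = lt.merge(peaks[["patient_id", "measure", "peak_value", "peak_time_months"]],
                      on=["patient_id", "measure"], how="left")
    no_peak = merged["peak_value"].isna()
    peak_time = merged["peak_time_months"].astype(float).fillna(-np.inf)
    too_early = (~no_peak) & (merged["time_months"] <= peak_time)
    skipped = pd.concat([
        merged[no_peak].assign(reason="no peak-window visit for measure"),
        merged[too_early].assign(reason="visit not after peak"),
    ], ignore_index=True)

    keep = merged[~no_peak & ~too_early].copy()
    denom = (keep["time_months"] - keep["peak_time_months"]
             if time_base == "peak" else keep["time_months"])
    keep["rate"] = (keep["peak_value"] - keep["value"]) / denom
    keep["kind"] = "ROD"
    keep["interval_bin"] = np.nan
    keep = keep.rename(columns={"time_months": "visit_time_months"})
    keep = _attach_prosthesis(keep, dataset)
    records = keep[list(RATE_COLUMNS)].reset_index(drop=True)
    return RateResult(records=records,
                      skipped=skipped[["patient_id", "time_months", "measure",
                                       "reason"]].reset_index(drop=True))
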