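"""Summary tables, the peak-to-long-term decline summary, and the full pipeline.

``summarize_groups`` reproduces the layout of cohort comparison tables:
rows are outcome measures, columns are trajectory-class groups, cells are
mean ± SD (with improvement over preop where applicable) and a between-group
p-value.  ``decline_from_peak`` performs the peak-minus-latest arithmetic at
reporting precision.  ``run_pipeline`` chains simulation/loading → rates →
baselines → classification → risk screens → tables, writing every artifact
as CSV plus a deterministic run log.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_data import (
    ALL_MEASURES,
    AnalysisWindows,
    CohortDataset,
    DEFAULT_BINS,
    DEFAULT_WINDOWS,
    ROM_MEASURES,
    read_cohort,
    round_half_up,
    write_cohort,
)
from .rate_classifier import ClassifierConfig, DEFAULT_CLASSIFIER, classify_cohort, label_counts
from .risk_screen import ClassSizeError, run_screen
from .synthetic_cohort import SimulationConfig, simulate_cohort
from .trajectory_metrics import compute_rod_records, compute_roi_records, find_peak

logger = logging.getLogger("romtraj")

#: Reporting precision of the decline summary: degrees for angles, half
#: points for the ordinal IR score.
DECLINE_ROUNDING: dict[str, float] = {
    "abduction": 1.0, "forward_elevation": 1.0, "external_rotation": 1.0,
    "ir_score": 0.5,
}


# ---------------------------------------------------------------------------
# Group summaries


def _value_at_timepoint(dataset: CohortDataset, timepoint_spec: str,
                        windows: AnalysisWindows,
                        latest_min_months: Optional[float]) -> pd.DataFrame:
    """One row per (patient, measure): the value this patient contributes."""
    v = dataset.visits
    if timepoint_spec == "preop":
        sel = v[v["is_preop"] == 1]
        return sel[["patient_id", "measure", "value"]].copy()
    if timepoint_spec == "peak":
        sel = v[(v["is_preop"] == 0)
                & (v["time_months"] >= windows.peak_start)
                & (v["time_months"] <= windows.peak_end)]
        out = (sel.sort_values(["value", "time_months"], ascending=[False, True])
               .groupby(["patient_id", "measure"], as_index=False).first())
        return out[["patient_id", "measure", "value"]]
    if timepoint_spec == "latest":
        sel = v[v["is_preop"] == 0]
        if latest_min_months is not None:
            sel = sel[sel["time_months"] >= latest_min_months]
        out = (sel.sort_values("time_months")
               .groupby(["patient_id", "measure"], as_index=False).last())
        return out[["patient_id", "measure", "value"]]
    raise ValueError("timepoint_spec must be 'preop', 'latest' or 'peak'")


@dataclass
class GroupSummaryTable:
    """Per-measure, per-group summary statistics with between-group p-values.

    ``frame`` has one row per (measure, group) with n, mean, sd and — for
    postoperative timepoints — mean/sd of the improvement over preop.
    ``p_values`` compares the two named extreme groups per measure
    (Welch t-test on values; improvements likewise when present).
    """

    timepoint_spec: str
    frame: pd.DataFrame
    p_values: pd.DataFrame


def summarize_groups(dataset: CohortDataset, labels: pd.DataFrame,
                     timepoint_spec: str,
                     windows: AnalysisWindows = DEFAULT_WINDOWS,
                     latest_min_months: Optional[float] = 96.0,
                     compare: tuple[str, str] = ("FAST", "SLOW"),
                     measures: Sequence[str] = ALL_MEASURES) -> GroupSummaryTable:
    """Summarise outcome measures by trajectory-class group at a timepoint.

    ``timepoint_spec``: ``preop`` (time-0 visit), ``latest`` (each patient's
    maximum-time visit per measure, guarded to ``latest_min_months`` and
    later), or ``peak`` (highest in-window value).  Improvements
    (value − preop) are computed per patient then averaged, and are reported
    for postoperative timepoints.
    """
    from .risk_screen import two_sample_t_test  # local import to avoid cycle

    values = _value_at_timepoint(dataset, timepoint_spec, windows, latest_min_months)
    values = values[values["measure"].isin(measures)]
    if timepoint_spec != "preop":
        pre = _value_at_timepoint(dataset, "preop", windows, None)
        pre = pre.rename(columns={"value": "preop_value"})
        values = values.merge(pre, on=["patient_id", "measure"], how="left")
        values["improvement"] = values["value"] - values["preop_value"]
    lab = labels[labels["label"].isin(("FAST", "AVERAGE", "SLOW"))]
    merged = values.merge(lab[["patient_id", "label"]], on="patient_id", how="inner")

    agg = {"n": ("value", "size"), "mean": ("value", "mean"), "sd": ("value", "std")}
    if "improvement" in merged.columns:
        agg.update(improve_mean=("improvement", "mean"),
                   improve_sd=("improvement", "std"))
    frame = merged.groupby(["measure", "label"], as_index=False).agg(**agg)

    p_rows = []
    g1, g2 = compare
    for measure, grp in merged.groupby("measure"):
        x = grp.loc[grp["label"] == g1, "value"].to_numpy()
        y = grp.loc[grp["label"] == g2, "value"].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            _, p = two_sample_t_test(x, y)
        else:
            p = np.nan
        row = {"measure": measure, "group1": g1, "group2": g2, "p_value": p}
        if "improvement" in grp.columns:
            xi = grp.loc[grp["label"] == g1, "improvement"].dropna().to_numpy()
            yi = grp.loc[grp["label"] == g2, "improvement"].dropna().to_numpy()
            row["p_improvement"] = (two_sample_t_test(xi, yi)[1]
                                    if len(xi) >= 2 and len(yi) >= 2 else np.nan)
        p_rows.append(row)
    return GroupSummaryTable(timepoint_spec=timepoint_spec, frame=frame,
                             p_values=pd.DataFrame(p_rows))


# ---------------------------------------------------------------------------
# Decline summary


def decline_from_peak(peak_means: Mapping[str, float],
                      latest_means: Mapping[str, float],
                      rounding: Mapping[str, float] = DECLINE_ROUNDING,
                      ) -> dict[str, float]:
    """Peak-minus-latest decline per measure at reporting precision.

    Angles round half-up to the nearest degree, the IR score to the nearest
    half point.  Both mappings must cover the same measures.
    """
    if set(peak_means) != set(latest_means):
        raise KeyError(
            f"measure mismatch: {sorted(set(peak_means) ^ set(latest_means))}")
    out = {}
    for measure, peak in peak_means.items():
        step = rounding.get(measure, 1.0)
        out[measure] = round_half_up(peak - latest_means[measure], step)
    return out


def decline_summary(dataset: CohortDataset,
                    windows: AnalysisWindows = DEFAULT_WINDOWS,
                    latest_min_months: Optional[float] = 96.0) -> pd.DataFrame:
    """Cohort-level decline summary: per prosthesis and measure, the mean
    peak value, mean latest long-term value, and their rounded difference."""
    rows = []
    pros = dataset.patients[["patient_id", "prosthesis"]]
    peak = _value_at_timepoint(dataset, "peak", windows, None).merge(pros, on="patient_id")
    latest = _value_at_timepoint(dataset, "latest", windows, latest_min_months).merge(
        pros, on="patient_id")
    for prosthesis in ("aTSA", "rTSA"):
        pk = peak[(peak["prosthesis"] == prosthesis)
                  & peak["measure"].isin(ROM_MEASURES)]
        lt = latest[(latest["prosthesis"] == prosthesis)
                    & latest["measure"].isin(ROM_MEASURES)]
        if len(pk) == 0 or len(lt) == 0:
            continue
        pk_means = pk.groupby("measure")["value"].mean().to_dict()
        lt_means = lt.groupby("measure")["value"].mean().to_dict()
        common = sorted(set(pk_means) & set(lt_means))
        declines = decline_from_peak({m: pk_means[m] for m in common},
                                     {m: lt_means[m] for m in common})
        for m in common:
            rows.append({"prosthesis": prosthesis, "measure": m,
                         "peak_mean": pk_means[m], "latest_mean": lt_means[m],
                         "decline": declines[m]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``patients_path``/``visits_path`` point at an existing cohort, or
    ``simulation`` describes one to generate.  ``out_dir`` receives all CSV
    artifacts and ``run.log``.
    """

    out_dir: str | Path = "romtraj_out"
    patients_path: Optional[str | Path] = None
    visits_path: Optional[str | Path] = None
    simulation: Optional[SimulationConfig] = None
    windows: AnalysisWindows = field(default_factory=AnalysisWindows)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    latest_min_months: Optional[float] = 96.0
    alpha: float = 0.05
    seed: Optional[int] = None


_CSV_FLOAT = "%.10g"  # fixed format => byte-identical reruns


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write artifacts; returns the output dir.

    Stages: load/simulate → ROI records → ROI classification → peaks → ROD
    records → ROD classification → risk screens (slow-ROI and fast-ROD, per
    prosthesis) → group summary tables → decline summary → run log.  A stage
    failure aborts with the stage name; identical config and seed produce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    def done(name, t0, note=""):
        logger.info("stage %s finished in %.2fs %s", name, time.perf_counter() - t0, note)
        if note:
            log_lines.append(f"{name}: {note}")

    t0 = stage("load")
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            from dataclasses import replace
            sim = replace(sim, seed=config.seed)
        dataset = simulate_cohort(sim)
        write_cohort(dataset, out / "patients.csv", out / "visits.csv")
        log_lines.append(f"simulated cohort with seed {sim.seed}")
    elif config.patients_path and config.visits_path:
        dataset = read_cohort(config.patients_path, config.visits_path)
    else:
        raise ValueError("pipeline config needs either input paths or a simulation")
    done("load", t0, f"{dataset.n_patients} patients, {dataset.n_visits} visits")

    t0 = stage("roi")
    roi = compute_roi_records(dataset, config.windows)
    _write(roi.records, out / "roi_rates.csv")
    done("roi", t0, f"{len(roi.records)} records, {len(roi.skipped)} skipped")

    t0 = stage("classify_roi")
    roi_labels = classify_cohort(dataset, roi.records, "ROI", config.classifier)
    done("classify_roi", t0, f"labels {label_counts(roi_labels)}")

    t0 = stage("rod")
    peaks = find_peak(dataset, config.windows)
    rod = compute_rod_records(dataset, peaks, config.windows)
    _write(peaks, out / "peaks.csv")
    _write(rod.records, out / "rod_rates.csv")
    if len(rod.records) == 0:
        logger.warning("no long-term visits after %s months: ROD outputs empty",
                       config.windows.longterm_start)
        log_lines.append("warning: ROD outputs empty")
    done("rod", t0, f"{len(rod.records)} records, {len(rod.skipped)} skipped")

    t0 = stage("classify_rod")
    rod_labels = classify_cohort(dataset, rod.records, "ROD", config.classifier)
    done("classify_rod", t0, f"labels {label_counts(rod_labels)}")

    nonempty = [df for df in (roi_labels, rod_labels) if len(df)]
    labels = (pd.concat(nonempty, ignore_index=True) if nonempty
              else roi_labels)
    labels = labels.merge(dataset.patients[["patient_id", "prosthesis"]],
                          on="patient_id", how="left")
    _write(labels[["patient_id", "prosthesis", "kind", "label",
                   "n_votes", "n_exceed", "fraction"]], out / "labels.csv")

    t0 = stage("screen")
    screen_frames = []
    for comparison, lab in (("roi-slow", roi_labels), ("rod-fast", rod_labels)):
        for prosthesis in ("aTSA", "rTSA"):
            try:
                report = run_screen(dataset, lab, comparison,
                                    alpha=config.alpha, prosthesis=prosthesis)
            except ClassSizeError as exc:
                log_lines.append(f"screen {comparison}/{prosthesis} skipped: {exc}")
                continue
            frame = report.to_frame()
            frame.insert(0, "prosthesis", prosthesis)
            frame.insert(0, "comparison", comparison)
            screen_frames.append(frame)
    if screen_frames:
        _write(pd.concat(screen_frames, ignore_index=True), out / "screen.csv")
    done("screen", t0, f"{len(screen_frames)} screen(s)")

    t0 = stage("tables")
    for spec_name, lab in (("preop", roi_labels), ("latest", rod_labels),
                           ("peak", roi_labels)):
        summary = summarize_groups(dataset, lab, spec_name, config.windows,
                                   latest_min_months=config.latest_min_months)
        _write(summary.frame, out / f"summary_{spec_name}.csv")
        _write(summary.p_values, out / f"summary_{spec_name}_pvalues.csv")
    _write(decline_summary(dataset, config.windows, config.latest_min_months),
           out / "decline_summary.csv")
    done("tables", t0, "summary tables written")

    import romtraj
    header = [
        f"romtraj {romtraj.__version__}",
        f"seed: {config.seed if config.seed is not None else 'n/a'}",
        f"patients: {dataset.n_patients}",
        f"visits: {dataset.n_visits}",
    ]
    (out / "run.log").write_text("\n".join(header + log_lines) + "\n")
    return out
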