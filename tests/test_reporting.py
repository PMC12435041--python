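"""Group summary tables, decline-from-peak arithmetic, pipeline and CLI."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from romtraj import (
    CohortDataset,
    PipelineConfig,
    SimulationConfig,
    classify_cohort,
    compute_roi_records,
    decline_from_peak,
    run_pipeline,
    simulate_cohort,
    summarize_groups,
    write_cohort,
)
from romtraj.cli import main as cli_main
from romtraj.reporting import decline_summary

from conftest import make_patient, make_patients, make_visits


# ---------------------------------------------------------------------------
# summarize_groups


def _labels(rows):
    return pd.DataFrame(rows, columns=["patient_id", "kind", "label",
                                       "n_votes", "n_exceed", "fraction"])


def test_group_mean_of_two_patients():
    ds = CohortDataset(
        patients=make_patients([make_patient(pid="P1"), make_patient(pid="P2")]),
        visits=make_visits([("P1", 0.0, 1, "abduction", 100.0),
                            ("P2", 0.0, 1, "abduction", 120.0)]))
    labels = _labels([("P1", "ROI", "FAST", 8, 8, 1.0),
                      ("P2", "ROI", "FAST", 8, 8, 1.0)])
    table = summarize_groups(ds, labels, "preop")
    row = table.frame[(table.frame["measure"] == "abduction")
                      & (table.frame["label"] == "FAST")].iloc[0]
    assert row["mean"] == pytest.approx(110.0)
    assert row["n"] == 2


def test_latest_takes_maximum_time_visit():
    ds = CohortDataset(
        patients=make_patients([make_patient(pid="P1")]),
        visits=make_visits([("P1", 0.0, 1, "abduction", 80.0),
                            ("P1", 96.0, 0, "abduction", 120.0),
                            ("P1", 120.0, 0, "abduction", 111.0)]))
    labels = _labels([("P1", "ROD", "SLOW", 8, 0, 0.0)])
    table = summarize_groups(ds, labels, "latest")
    row = table.frame.iloc[0]
    assert row["mean"] == 111.0
    assert row["improve_mean"] == pytest.approx(31.0)


def test_latest_minimum_time_guard():
    ds = CohortDataset(
        patients=make_patients([make_patient(pid="P1")]),
        visits=make_visits([("P1", 0.0, 1, "abduction", 80.0),
                            ("P1", 60.0, 0, "abduction", 130.0)]))
    labels = _labels([("P1", "ROD", "SLOW", 8, 0, 0.0)])
    guarded = summarize_groups(ds, labels, "latest", latest_min_months=96.0)
    assert len(guarded.frame) == 0
    open_ = summarize_groups(ds, labels, "latest", latest_min_months=None)
    assert open_.frame.iloc[0]["mean"] == 130.0


def test_group_summary_matches_bruteforce(small_cohort):
    roi = compute_roi_records(small_cohort)
    labels = classify_cohort(small_cohort, roi.records, "ROI")
    table = summarize_groups(small_cohort, labels, "preop")
    v = small_cohort.visits
    lab = labels.set_index("patient_id")["label"]
    for _, row in table.frame.iterrows():
        sel = v[(v["is_preop"] == 1) & (v["measure"] == row["measure"])]
        sel = sel[sel["patient_id"].map(lab).eq(row["label"])]
        assert row["mean"] == pytest.approx(sel["value"].mean(), abs=1e-12)
        assert row["n"] == len(sel)


# ---------------------------------------------------------------------------
# decline_from_peak


def test_decline_reference_cohort_anatomic():
    """Published aTSA peak vs latest means give declines 16/12/10/1."""
    from romtraj.reference import LATEST_ROM, PEAK_ROM, rom_means
    out = decline_from_peak(rom_means(PEAK_ROM, "aTSA"),
                            rom_means(LATEST_ROM, "aTSA"))
    assert out == {"abduction": 16.0, "forward_elevation": 12.0,
                   "external_rotation": 10.0, "ir_score": 1.0}


def test_decline_reference_cohort_reverse():
    """Published rTSA peak vs latest means give declines 8/10/3/0.5."""
    from romtraj.reference import LATEST_ROM, PEAK_ROM, rom_means
    out = decline_from_peak(rom_means(PEAK_ROM, "rTSA"),
                            rom_means(LATEST_ROM, "rTSA"))
    assert out == {"abduction": 8.0, "forward_elevation": 10.0,
                   "external_rotation": 3.0, "ir_score": 0.5}


def test_decline_zero_when_no_change():
    out = decline_from_peak({"abduction": 120.0}, {"abduction": 120.0})
    assert out["abduction"] == 0.0


def test_decline_antisymmetric_before_rounding():
    peak = {"abduction": 131.9}
    latest = {"abduction": 115.8}
    fwd = (peak["abduction"] - latest["abduction"])
    rev = (latest["abduction"] - peak["abduction"])
    assert fwd == -rev  # unrounded antisymmetry of the underlying difference


def test_decline_measure_mismatch_raises():
    with pytest.raises(KeyError):
        decline_from_peak({"abduction": 120.0}, {"ir_score": 4.0})


def test_decline_summary_from_cohort(small_cohort):
    table = decline_summary(small_cohort)
    assert set(table["prosthesis"]) == {"aTSA", "rTSA"}
    for _, row in table.iterrows():
        assert row["decline"] == pytest.approx(
            np.floor((row["peak_mean"] - row["latest_mean"])
                     / (0.5 if row["measure"] == "ir_score" else 1.0) + 0.5)
            * (0.5 if row["measure"] == "ir_score" else 1.0))


# ---------------------------------------------------------------------------
# Pipeline


EXPECTED_ARTIFACTS = [
    "roi_rates.csv", "rod_rates.csv", "peaks.csv", "labels.csv", "screen.csv",
    "summary_preop.csv", "summary_latest.csv", "summary_peak.csv",
    "decline_summary.csv", "run.log",
]


def test_pipeline_smoke_on_simulated_cohort(tmp_path):
    cfg = PipelineConfig(out_dir=tmp_path / "out",
                         simulation=SimulationConfig(n_atsa=25, n_rtsa=25),
                         seed=77)
    out = run_pipeline(cfg)
    for name in EXPECTED_ARTIFACTS:
        assert (out / name).exists(), name
    labels = pd.read_csv(out / "labels.csv")
    assert set(labels["kind"]) == {"ROI", "ROD"}
    assert set(labels["label"]) <= {"FAST", "AVERAGE", "SLOW", "UNCLASSIFIED"}


def test_pipeline_rerun_is_byte_identical(tmp_path):
    sim = SimulationConfig(n_atsa=20, n_rtsa=20)
    out1 = run_pipeline(PipelineConfig(out_dir=tmp_path / "a", simulation=sim, seed=5))
    out2 = run_pipeline(PipelineConfig(out_dir=tmp_path / "b", simulation=sim, seed=5))
    for name in EXPECTED_ARTIFACTS:
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name


def test_pipeline_degenerate_longterm_window_completes(tmp_path):
    from romtraj.cohort_data import AnalysisWindows
    cfg = PipelineConfig(
        out_dir=tmp_path / "out",
        simulation=SimulationConfig(n_atsa=10, n_rtsa=10), seed=3,
        windows=AnalysisWindows(longterm_start=500.0),
        latest_min_months=None)
    out = run_pipeline(cfg)
    assert len(pd.read_csv(out / "rod_rates.csv")) == 0
    assert "warning: ROD outputs empty" in (out / "run.log").read_text()


def test_pipeline_requires_input_or_simulation(tmp_path):
    with pytest.raises(ValueError):
        run_pipeline(PipelineConfig(out_dir=tmp_path))


# ---------------------------------------------------------------------------
# CLI


def test_cli_simulate_rates_classify(tmp_path):
    runner = CliRunner()
    out = tmp_path / "sim"
    r = runner.invoke(cli_main, ["simulate", "--seed", "4", "--n-atsa", "10",
                                 "--n-rtsa", "10", "--out", str(out)])
    assert r.exit_code == 0, r.output
    assert (out / "patients.csv").exists() and (out / "visits.csv").exists()

    rates_csv = tmp_path / "roi.csv"
    r = runner.invoke(cli_main, ["rates", "--patients", str(out / "patients.csv"),
                                 "--visits", str(out / "visits.csv"),
                                 "--kind", "roi", "--out", str(rates_csv)])
    assert r.exit_code == 0, r.output
    rates = pd.read_csv(rates_csv)
    assert list(rates.columns) == ["patient_id", "measure", "visit_time_months",
                                   "interval_bin", "kind", "rate"]

    labels_csv = tmp_path / "labels.csv"
    r = runner.invoke(cli_main, ["classify", "--rates", str(rates_csv),
                                 "--patients", str(out / "patients.csv"),
                                 "--kind", "roi", "--out", str(labels_csv)])
    assert r.exit_code == 0, r.output
    labels = pd.read_csv(labels_csv)
    assert {"patient_id", "label", "n_votes"} <= set(labels.columns)


def test_cli_run_full_pipeline(tmp_path):
    runner = CliRunner()
    out = tmp_path / "run"
    r = runner.invoke(cli_main, ["run", "--seed", "2", "--n-atsa", "15",
                                 "--n-rtsa", "15", "--out", str(out)])
    assert r.exit_code == 0, r.output
    for name in EXPECTED_ARTIFACTS:
        assert (out / name).exists(), name
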