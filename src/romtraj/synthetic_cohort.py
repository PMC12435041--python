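"""Synthetic longitudinal shoulder-arthroplasty cohorts.

Generates patient + visit tables with the statistical structure the
downstream trajectory analysis assumes, so every stage is testable without
access to clinical data:

* preoperative ROM drawn per prosthesis from published cohort means, as a
  two-stratum mixture (a latent "high preoperative ROM" class) — patients in
  the high stratum recover little or transiently lose motion early and are
  the natural slow-rate-of-improvement group;
* an early post-surgical **dip** for patients whose preoperative value
  exceeds a threshold (high-functioning shoulders lose motion over the first
  ~3 months before recovering);
* saturating exponential recovery to a peak reached 2-3 years after surgery,
  with the peak only weakly correlated with the preoperative value;
* late linear decline beyond ~3 years, with a per-patient random slope;
* covariate effects planted through :class:`EffectSpec` (slower recovery,
  added decline slope, or shifted latent-class odds);
* a step loss of motion after revision surgery;
* a realistic visit schedule with Gaussian jitter and per-(visit, measure)
  missingness.

The per-visit mean trajectory is

    mu(t) = P - m (P - R0) exp(-t / tau)
              - D (t / tau_d) exp(1 - t / tau_d)
              - s max(0, t - t_decline)

with R0 the preoperative value, P the peak, m a recovery multiplier
(1 by default), tau the recovery time constant, D the dip depth
(``dip_coefficient * max(0, R0 - dip_threshold)``), tau_d the dip time
constant, and s the late decline slope.  mu(0) = R0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import reference
from .cohort_data import (
    ANGLE_MEASURES,
    ANGLE_RANGE,
    CohortDataset,
    IR_SCORE_RANGE,
    PATIENT_COLUMNS,
    PRO_MEASURES,
    ROM_MEASURES,
    VISIT_COLUMNS,
    round_half_up,
)

# ---------------------------------------------------------------------------
# Parameters


@dataclass(frozen=True)
class CurveParams:
    """Shape parameters of the mean trajectory for one measure.

    tau_recovery : months, time constant of the saturating recovery.
    tau_dip : months, time-to-trough of the early dip.
    dip_threshold : preop value above which the dip is active.
    dip_coefficient : dip depth per unit of preop value above the threshold.
    decline_start : months after which the late linear decline applies.
    """

    tau_recovery: float = 4.0
    tau_dip: float = 3.0
    dip_threshold: float = 90.0
    dip_coefficient: float = 0.75
    decline_start: float = 36.0


#: Per-measure dip settings.  The external-rotation threshold sits just above
#: its cohort mean (external rotation spans ~0-60 degrees, so a 90-degree
#: threshold would never trigger); the IR-score dip is 0.05 points per preop
#: point above 3.
_DIP_THRESHOLD = {"abduction": 90.0, "forward_elevation": 90.0,
                  "external_rotation": 20.0, "ir_score": 3.0}
_DIP_COEFFICIENT = {"abduction": 0.75, "forward_elevation": 0.75,
                    "external_rotation": 0.25, "ir_score": 0.05}


@dataclass(frozen=True)
class TrajectoryParams:
    """Population-level trajectory parameters.

    ``preop`` and ``peak`` map prosthesis -> measure -> (mean, sd); defaults
    are published cohort summary values.  Decline slopes are drawn per
    patient per measure from a truncated normal (negative draws set to 0);
    IR-score slopes are scaled down to the ordinal 0-6 range.  The latent
    high-preop stratum (prevalence ``slow_fraction``) shifts all preop
    measures up by ``stratum_separation`` pooled SDs and multiplies the
    recovery term by ``slow_recovery_multiplier``.
    """

    preop: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: reference.PREOP_ROM)
    peak: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: reference.PEAK_ROM)
    tau_recovery: float = 4.0
    tau_dip: float = 3.0
    dip_threshold: Mapping[str, float] = field(default_factory=lambda: dict(_DIP_THRESHOLD))
    dip_coefficient: Mapping[str, float] = field(default_factory=lambda: dict(_DIP_COEFFICIENT))
    decline_start: float = 36.0
    decline_slope_mean: float = 0.08
    decline_slope_sd: float = 0.05
    ir_slope_scale: float = 0.1
    noise_sd_angle: float = 5.0
    noise_sd_ir: float = 0.5
    peak_preop_correlation: float = 0.2
    slow_fraction: float = 0.3
    stratum_separation: float = 1.6
    slow_recovery_multiplier: float = 0.7
    revision_drop_angle: float = 30.0
    revision_drop_ir: float = 1.5

    def curve_params(self, measure: str) -> CurveParams:
        return CurveParams(
            tau_recovery=self.tau_recovery,
            tau_dip=self.tau_dip,
            dip_threshold=self.dip_threshold[measure],
            dip_coefficient=self.dip_coefficient[measure],
            decline_start=self.decline_start,
        )

    def noise_sd(self, measure: str) -> float:
        return self.noise_sd_ir if measure == "ir_score" else self.noise_sd_angle


@dataclass(frozen=True)
class EffectSpec:
    """A covariate effect planted into the generator.

    target:
      * ``early_rate_multiplier`` — multiplies the recovery term for
        carriers (values < 1 slow the recovery);
      * ``decline_slope_add`` — degrees/month added to the late decline
        slope of carriers;
      * ``class_probability`` — odds multiplier on membership in the latent
        high-preop (slow-recovery) class for carriers.
    """

    name: str
    target: str
    magnitude: float
    scope: str = "both"  # aTSA | rTSA | both

    def __post_init__(self) -> None:
        if self.target not in ("early_rate_multiplier", "decline_slope_add",
                               "class_probability"):
            raise ValueError(f"unknown effect target {self.target!r}")
        if self.target != "decline_slope_add" and self.magnitude <= 0:
            raise ValueError("multiplicative effect magnitudes must be > 0")

    def applies(self, prosthesis: str) -> bool:
        return self.scope in ("both", prosthesis)


DEFAULT_SCHEDULE: tuple[float, ...] = (0, 3, 6, 12, 24, 36, 60, 84, 96, 108, 120)

#: Default covariate prevalences; values may be a float or a
#: {"aTSA": p, "rTSA": p} mapping.  Calibrated to control-group proportions
#: of published long-term aTSA/rTSA cohorts.
DEFAULT_PREVALENCES: dict[str, object] = {
    "sex_female": {"aTSA": 0.49, "rTSA": 0.65},
    "previous_surgery": {"aTSA": 0.13, "rTSA": 0.28},
    "injections": {"aTSA": 0.40, "rTSA": 0.33},
    "dx_osteoarthritis": {"aTSA": 0.93, "rTSA": 0.54},
    "dx_osteonecrosis": 0.025,
    "dx_rotator_cuff_tear": {"aTSA": 0.03, "rTSA": 0.40},
    "dx_cuff_tear_arthropathy": {"aTSA": 0.007, "rTSA": 0.38},
    "dx_rheumatoid_arthritis": {"aTSA": 0.03, "rTSA": 0.055},
    "cm_hypertension": 0.47,
    "cm_heart_disease": 0.12,
    "cm_diabetes": 0.11,
    "cm_tobacco": 0.06,
    "cm_renal_failure": 0.005,
    "humeral_rll": {"aTSA": 0.20, "rTSA": 0.31},
    "glenoid_rll": {"aTSA": 0.38, "rTSA": 0.0},
    "scapular_notching": {"aTSA": 0.0, "rTSA": 0.15},
    "complication": {"aTSA": 0.055, "rTSA": 0.01},
    "revision": {"aTSA": 0.045, "rTSA": 0.015},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    n_atsa / n_rtsa : patients per prosthesis.
    schedule : nominal visit months (first entry 0 = preoperative).
    jitter_sd : SD in months of the Gaussian jitter on postop visit times.
    missingness : probability each postop (visit, measure) is unobserved;
        the preoperative visit is never missing.
    prevalences : overrides of :data:`DEFAULT_PREVALENCES`.
    effects : planted covariate effects.
    """

    n_atsa: int = 100
    n_rtsa: int = 100
    schedule: Sequence[float] = DEFAULT_SCHEDULE
    jitter_sd: float = 0.8
    missingness: float = 0.15
    prevalences: Mapping[str, object] = field(default_factory=dict)
    effects: Sequence[EffectSpec] = ()
    seed: int = 0
    include_pro_scores: bool = True
    trajectory: TrajectoryParams = field(default_factory=TrajectoryParams)

    def __post_init__(self) -> None:
        if not (0.0 <= self.missingness <= 1.0):
            raise ValueError("missingness must be in [0, 1]")
        sched = list(self.schedule)
        if sched != sorted(sched) or len(set(sched)) != len(sched):
            raise ValueError("visit schedule must be strictly increasing")
        if self.n_atsa < 0 or self.n_rtsa < 0:
            raise ValueError("cohort sizes must be non-negative")

    def prevalence(self, name: str, prosthesis: str) -> float:
        value = self.prevalences.get(name, DEFAULT_PREVALENCES.get(name, 0.0))
        if isinstance(value, Mapping):
            value = value[prosthesis]
        return float(value)


# PRO score trajectories: (preop mean, preop sd, long-term mean, long-term sd,
# noise sd, lower clamp, upper clamp).  Carried as opaque columns; a simple
# saturating approach with no dip or decline.
_PRO_PARAMS: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "vas_pain": (6.2, 2.1, 1.7, 2.2, 0.8, 0.0, 10.0),
    "function": (3.9, 2.0, 7.8, 2.3, 0.8, 0.0, 10.0),
    "ases": (35.9, 15.8, 78.6, 21.8, 4.0, 0.0, 100.0),
    "constant": (36.3, 13.7, 63.7, 16.6, 4.0, 0.0, 100.0),
    "sas": (45.7, 11.2, 72.6, 14.8, 4.0, 0.0, 100.0),
}


# ---------------------------------------------------------------------------
# Trajectory mean


def trajectory_mean(t, preop_value: float, peak_value: float,
                    params: CurveParams, slope: float,
                    recovery_multiplier: float = 1.0):
    """Mean trajectory mu(t); vectorised over ``t`` (months since surgery).

    Returns the preop value exactly at t = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    dip_depth = params.dip_coefficient * max(0.0, preop_value - params.dip_threshold)
    recovery = recovery_multiplier * (peak_value - preop_value) * (
        1.0 - np.exp(-t / params.tau_recovery))
    dip = dip_depth * (t / params.tau_dip) * np.exp(1.0 - t / params.tau_dip)
    decline = slope * np.maximum(0.0, t - params.decline_start)
    out = preop_value + recovery - dip - decline
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Patient-level simulation


def _effect_product(effects: Sequence[EffectSpec], target: str,
                    covariates: Mapping[str, object], prosthesis: str) -> float:
    prod = 1.0
    for e in effects:
        if e.target == target and e.applies(prosthesis) and covariates.get(e.name) == 1:
            prod *= e.magnitude
    return prod


def _effect_sum(effects: Sequence[EffectSpec], target: str,
                covariates: Mapping[str, object], prosthesis: str) -> float:
    total = 0.0
    for e in effects:
        if e.target == target and e.applies(prosthesis) and covariates.get(e.name) == 1:
            total += e.magnitude
    return total


def _clamp_value(measure: str, values: np.ndarray) -> np.ndarray:
    if measure == "ir_score":
        rounded = np.floor(values / 1.0 + 0.5)  # half-up
        return np.clip(rounded, IR_SCORE_RANGE[0], IR_SCORE_RANGE[1])
    if measure in ANGLE_MEASURES:
        return np.clip(values, ANGLE_RANGE[0], ANGLE_RANGE[1])
    lo, hi = _PRO_PARAMS[measure][5], _PRO_PARAMS[measure][6]
    return np.clip(values, lo, hi)


def simulate_patient(covariates: Mapping[str, object], config: SimulationConfig,
                     rng: np.random.Generator) -> tuple[dict, pd.DataFrame]:
    """Simulate one patient's record and visit table.

    ``covariates`` must contain ``patient_id``, ``prosthesis`` and the 0/1
    covariate flags (typically drawn by :func:`simulate_cohort`).  The same
    (covariates, config) with a generator in the same state reproduces the
    same output.
    """
    traj = config.trajectory
    prosthesis = str(covariates["prosthesis"])
    effects = config.effects

    # Latent high-preop / slow-recovery class; class_probability effects
    # multiply its odds for carriers.
    p0 = traj.slow_fraction
    odds = p0 / (1.0 - p0) * _effect_product(effects, "class_probability",
                                             covariates, prosthesis)
    latent_slow = bool(rng.random() < odds / (1.0 + odds))

    sep = traj.stratum_separation
    # Stratum means keep the mixture mean at the published value and the
    # within-stratum SD keeps the mixture SD near the published SD.
    shift_high, shift_low = (1.0 - p0) * sep, -p0 * sep
    within = np.sqrt(max(1.0 - p0 * (1.0 - p0) * sep ** 2, 0.2))

    rate_mult = _effect_product(effects, "early_rate_multiplier", covariates, prosthesis)
    if latent_slow:
        rate_mult *= traj.slow_recovery_multiplier
    slope_add = _effect_sum(effects, "decline_slope_add", covariates, prosthesis)

    revision_time = covariates.get("revision_time_months")
    if covariates.get("revision") == 1 and revision_time is None:
        revision_time = float(rng.uniform(40.0, 100.0))

    # Visit times: preop exactly 0; postop jittered, kept positive.
    nominal = np.asarray(config.schedule, dtype=float)
    postop = nominal[nominal > 0]
    times = postop + rng.normal(0.0, config.jitter_sd, size=postop.size)
    times = np.maximum(times, 0.5)

    rows: list[tuple] = []
    pid = str(covariates["patient_id"])

    for measure in ROM_MEASURES:
        pre_mean, pre_sd = traj.preop[prosthesis][measure]
        peak_mean, peak_sd = traj.peak[prosthesis][measure]
        shift = shift_high if latent_slow else shift_low
        r0 = pre_mean + shift * pre_sd + within * pre_sd * rng.normal()
        r0 = float(_clamp_value(measure, np.asarray(r0)))
        rho = traj.peak_preop_correlation
        peak = (peak_mean + rho * (peak_sd / pre_sd) * (r0 - pre_mean)
                + np.sqrt(1.0 - rho ** 2) * peak_sd * rng.normal())
        peak = float(np.clip(peak, ANGLE_RANGE[0],
                             IR_SCORE_RANGE[1] if measure == "ir_score" else ANGLE_RANGE[1]))
        slope = max(0.0, rng.normal(traj.decline_slope_mean, traj.decline_slope_sd))
        add = slope_add
        if measure == "ir_score":
            slope *= traj.ir_slope_scale
            add *= traj.ir_slope_scale
        slope += add

        mu = trajectory_mean(times, r0, peak, traj.curve_params(measure), slope,
                             recovery_multiplier=rate_mult)
        if revision_time is not None:
            drop = traj.revision_drop_ir if measure == "ir_score" else traj.revision_drop_angle
            mu = mu - drop * (times > revision_time)
        noise_sd = traj.noise_sd(measure)
        values = mu + (rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else 0.0)
        values = _clamp_value(measure, np.asarray(values, dtype=float))
        pre_noise = r0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        pre_value = float(_clamp_value(measure, np.asarray(pre_noise)))

        rows.append((pid, 0.0, 1, measure, pre_value))
        keep = rng.random(times.size) >= config.missingness
        for t, v, k in zip(times, values, keep):
            if k:
                rows.append((pid, float(t), 0, measure, float(v)))

    if config.include_pro_scores:
        for measure, (pm, ps, lm, ls, nsd, lo, hi) in _PRO_PARAMS.items():
            pre = float(np.clip(rng.normal(pm, ps), lo, hi))
            target = float(np.clip(rng.normal(lm, ls), lo, hi))
            mu = target + (pre - target) * np.exp(-times / traj.tau_recovery)
            values = np.clip(mu + rng.normal(0.0, nsd, size=times.size), lo, hi)
            rows.append((pid, 0.0, 1, measure, pre))
            keep = rng.random(times.size) >= config.missingness
            for t, v, k in zip(times, values, keep):
                if k:
                    rows.append((pid, float(t), 0, measure, float(v)))

    visits = pd.DataFrame(rows, columns=list(VISIT_COLUMNS))
    patient_row = {col: covariates.get(col) for col in PATIENT_COLUMNS}
    patient_row["revision_time_months"] = (
        float(revision_time) if revision_time is not None else np.nan)
    return patient_row, visits


# ---------------------------------------------------------------------------
# Cohort-level simulation


def _draw_covariates(pid: str, prosthesis: str, config: SimulationConfig,
                     rng: np.random.Generator) -> dict:
    cov: dict[str, object] = {"patient_id": pid, "prosthesis": prosthesis}
    if prosthesis == "aTSA":
        age = rng.normal(65.0, 8.2)
    else:
        age = rng.normal(70.7, 6.8)
    cov["age_years"] = float(np.clip(age, 30.0, 90.0))
    u = rng.random()
    p_f = config.prevalence("sex_female", prosthesis)
    cov["sex"] = "unknown" if u > 0.995 else ("F" if u < p_f else "M")
    cov["bmi"] = float(np.clip(rng.normal(29.5, 6.4), 15.0, 60.0))
    for flag in ("previous_surgery", "injections",
                 "dx_osteoarthritis", "dx_osteonecrosis", "dx_rotator_cuff_tear",
                 "dx_cuff_tear_arthropathy", "dx_rheumatoid_arthritis",
                 "cm_hypertension", "cm_heart_disease", "cm_diabetes",
                 "cm_tobacco", "cm_renal_failure",
                 "humeral_rll", "glenoid_rll", "scapular_notching",
                 "complication", "revision"):
        cov[flag] = int(rng.random() < config.prevalence(flag, prosthesis))
    cov["cm_none"] = int(not any(cov[c] for c in (
        "cm_hypertension", "cm_heart_disease", "cm_diabetes",
        "cm_tobacco", "cm_renal_failure")))
    cov["glenoid_rll_grade"] = int(rng.integers(1, 6)) if cov["glenoid_rll"] else 0
    cov["notching_grade"] = int(rng.integers(1, 5)) if cov["scapular_notching"] else 0
    cov["revision_time_months"] = None
    return cov


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Simulate a full two-prosthesis cohort; deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    patient_rows: list[dict] = []
    visit_frames: list[pd.DataFrame] = []
    for prosthesis, n in (("aTSA", config.n_atsa), ("rTSA", config.n_rtsa)):
        tag = "A" if prosthesis == "aTSA" else "R"
        for i in range(n):
            pid = f"P{tag}{i:04d}"
            cov = _draw_covariates(pid, prosthesis, config, rng)
            row, visits = simulate_patient(cov, config, rng)
            patient_rows.append(row)
            visit_frames.append(visits)
    if patient_rows:
        patients = pd.DataFrame(patient_rows, columns=list(PATIENT_COLUMNS))
        visits = pd.concat(visit_frames, ignore_index=True)
    else:
        patients = pd.DataFrame(columns=list(PATIENT_COLUMNS))
        visits = pd.DataFrame(columns=list(VISIT_COLUMNS))
    return CohortDataset(patients=patients, visits=visits).validate()
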