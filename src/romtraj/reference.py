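"""Published cohort summary statistics used as calibration anchors and worked-example inputs.

These are full-cohort summary means (± SD where carried) for active range of
motion after anatomic (aTSA) and reverse (rTSA) total shoulder arthroplasty,
taken from long-term (8+ year minimum follow-up) multicenter outcome
reporting: preoperative values, peak values reached in the 2-3 year
postoperative interval, and values at the latest long-term clinic visit.

They serve two purposes:

1. Defaults for the synthetic cohort generator, so simulated trajectories
   start and saturate at clinically realistic levels.
2. Inputs for the peak-to-long-term decline worked example
   (:func:`romtraj.reporting.decline_from_peak`).

Angles are degrees of active motion; ``ir_score`` is the ordinal 0-6
internal-rotation score.
"""

from __future__ import annotations

#: (mean, sd) of preoperative ROM per prosthesis per measure.
PREOP_ROM: dict[str, dict[str, tuple[float, float]]] = {
    "aTSA": {
        "abduction": (84.8, 29.7),
        "forward_elevation": (99.2, 31.5),
        "external_rotation": (17.6, 20.1),
        "ir_score": (3.1, 1.6),
    },
    "rTSA": {
        "abduction": (72.6, 34.5),
        "forward_elevation": (88.0, 38.9),
        "external_rotation": (18.2, 21.6),
        "ir_score": (3.1, 1.9),
    },
}

#: (mean, sd) of peak ROM reached during the 2-3 year postoperative window.
PEAK_ROM: dict[str, dict[str, tuple[float, float]]] = {
    "aTSA": {
        "abduction": (131.9, 28.4),
        "forward_elevation": (150.5, 22.8),
        "external_rotation": (53.3, 17.6),
        "ir_score": (5.4, 1.2),
    },
    "rTSA": {
        "abduction": (121.1, 25.9),
        "forward_elevation": (142.4, 21.3),
        "external_rotation": (35.7, 17.4),
        "ir_score": (4.9, 1.6),
    },
}

#: (mean, sd) of ROM at the latest long-term follow-up visit (96+ months).
LATEST_ROM: dict[str, dict[str, tuple[float, float]]] = {
    "aTSA": {
        "abduction": (115.8, 33.6),
        "forward_elevation": (138.2, 33.3),
        "external_rotation": (43.8, 19.4),
        "ir_score": (4.5, 1.6),
    },
    "rTSA": {
        "abduction": (112.8, 29.2),
        "forward_elevation": (132.5, 28.3),
        "external_rotation": (33.0, 18.8),
        "ir_score": (4.3, 1.8),
    },
}


def rom_means(table: dict[str, dict[str, tuple[float, float]]],
              prosthesis: str) -> dict[str, float]:
    """Return the per-measure means (dropping SDs) for one prosthesis."""
    return {measure: mean_sd[0] for measure, mean_sd in table[prosthesis].items()}
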