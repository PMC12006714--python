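"""Reference cohort profile: the published per-quadrant statistics of a
205-patient intertrochanteric-fracture series, used as default parameters for
the synthetic cohort simulator.

Coordinates are (X, Y) in mm of the medial fracture line's lowest point in
the patient-specific coronal/transverse frame; per-quadrant values are the
sample mean +/- SD reported for that series.  The rank correlations are the
reported Spearman rho between each classification grade and the quadrant
instability rank.
"""

from __future__ import annotations

__all__ = [
    "QUADRANT_COUNTS",
    "QUADRANT_COORD_PARAMS",
    "GRADE_RHO",
    "GRADE_LEVELS",
    "N_TOTAL",
]

#: patients per quadrant in the reference series
QUADRANT_COUNTS: dict[str, int] = {"Q1": 20, "Q2": 21, "Q3": 122, "Q4": 42}

N_TOTAL: int = sum(QUADRANT_COUNTS.values())  # 205

#: per-quadrant {mean_X, sd_X, mean_Y, sd_Y} in mm
QUADRANT_COORD_PARAMS: dict[str, dict[str, float]] = {
    "Q1": {"mean_X": 6.44, "sd_X": 5.47, "mean_Y": 6.14, "sd_Y": 2.71},
    "Q2": {"mean_X": -7.23, "sd_X": 5.86, "mean_Y": 8.31, "sd_Y": 6.59},
    "Q3": {"mean_X": -9.59, "sd_X": 4.32, "mean_Y": -24.43, "sd_Y": 15.79},
    "Q4": {"mean_X": 8.18, "sd_X": 4.56, "mean_Y": -18.20, "sd_Y": 12.92},
}

#: reported Spearman rho of each classification vs. instability rank
GRADE_RHO: dict[str, float] = {"AO": 0.32, "Evans": 0.38, "Tang": 0.40}

#: ordinal cardinality of each classification (AO 31-A1..A3; Evans/Tang I..V)
GRADE_LEVELS: dict[str, int] = {"AO": 3, "Evans": 5, "Tang": 5}
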