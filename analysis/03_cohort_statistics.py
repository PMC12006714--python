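#!/usr/bin/env python
"""Cohort statistics on the recovered table.

Per-quadrant descriptive statistics (n, mean +/- SD of X and Y, with
Shapiro-Wilk normality screening) and Spearman rank correlations with
Fisher-z 95% confidence intervals between each classification (AO, Evans,
Tang) and the quadrant instability rank.  Reads
results/cohort_recovered.csv (written by 02_recover_geometry.py) and writes
results/stats_report.json.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from femquad.frame import MedialCoordinate, classify_quadrant
from femquad.mesh_io import read_cohort_csv
from femquad.stats import (FractureCase, shapiro_wilk, spearman_with_ci,
                           summarize_quadrants)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    df = read_cohort_csv(RESULTS / "cohort_recovered.csv")
    rows = []
    for rec in df.itertuples(index=False):
        coord = MedialCoordinate(X=float(rec.X_mm), Y=float(rec.Y_mm),
                                 quadrant=classify_quadrant(rec.X_mm, rec.Y_mm),
                                 D=np.full(3, np.nan))
        grades = {s: int(getattr(rec, s)) for s in ("AO", "Evans", "Tang")
                  if not np.isnan(getattr(rec, s))}
        rows.append(FractureCase(case_id=str(rec.case_id), coord=coord, grades=grades))

    report = {"n": len(rows), "quadrant_summaries": [], "normality": {},
              "correlations": {}}
    for s in summarize_quadrants(rows):
        report["quadrant_summaries"].append(dataclasses.asdict(s))
        print(f"{s.quadrant}: n={s.n:3d}  X = {s.mean_X:7.2f} +/- {s.sd_X:5.2f} mm   "
              f"Y = {s.mean_Y:7.2f} +/- {s.sd_Y:5.2f} mm")
        xs = [r.coord.X for r in rows if r.coord.quadrant == s.quadrant]
        ys = [r.coord.Y for r in rows if r.coord.quadrant == s.quadrant]
        if len(xs) >= 3:
            report["normality"][s.quadrant] = {
                "X": shapiro_wilk(xs), "Y": shapiro_wilk(ys)}

    ranks = [r.instability_rank for r in rows]
    for sys_ in ("AO", "Evans", "Tang"):
        g = [r.grades[sys_] for r in rows if sys_ in r.grades]
        res = spearman_with_ci(g, ranks, alpha=0.05)
        report["correlations"][sys_] = dataclasses.asdict(
            dataclasses.replace(res, classification=sys_))
        print(f"{sys_:5s} vs instability: rho = {res.rho:.2f} "
              f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), p = {res.p_value:.2e}")

    (RESULTS / "stats_report.json").write_text(json.dumps(report, indent=2))
    print(f"report written to {RESULTS / 'stats_report.json'}")


if __name__ == "__main__":
    main()
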