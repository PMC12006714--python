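"""End-to-end per-case processing and cohort analysis.

``process_case`` runs the geometric chain — sphere fits of the head and
lesser-trochanter patches, cylinder fit of the shaft band, frame
construction, lowest-point extraction, signed coordinates — and attaches the
classification grades.  ``run_cohort`` maps it over a cohort, skipping (and
reporting) cases whose geometry cannot be fitted, then computes quadrant
summaries and one Spearman correlation per available classification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import FemquadError, RunError, UndefinedCorrelationError
from .frame import build_frame, extract_lowest_point, signed_coordinates
from .mesh_io import GRADE_SYSTEMS, CohortTable, LabeledCase, read_case, write_cohort_csv
from .primitives import FitConfig, fit_cylinder, fit_sphere
from .stats import FractureCase, spearman_with_ci, stability_rank, summarize_quadrants

__all__ = ["RunConfig", "process_case", "run_cohort"]

log = logging.getLogger("femquad")


@dataclass(frozen=True)
class RunConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    alpha: float = 0.05
    boundary_convention: str = "zero-positive"
    mirror_left: bool = True
    output_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.boundary_convention != "zero-positive":
            raise ValueError("only the 'zero-positive' boundary convention is implemented")


def process_case(case: LabeledCase, config: RunConfig | None = None) -> FractureCase:
    """Fit primitives, build the frame, and map the fracture lowest point."""
    config = config or RunConfig()
    case.validate(require_complete=True)
    head = fit_sphere(case.region_points("head_patch"), config.fit)
    lt = fit_sphere(case.region_points("lt_patch"), config.fit)
    shaft = fit_cylinder(case.region_points("shaft_patch"), config.fit)
    log.debug(
        "case %s: head rms %.4f mm (coverage %.2f), lt rms %.4f mm (coverage %.2f), "
        "shaft rms %.4f mm",
        case.case_id, head.rms_residual, head.coverage_fraction,
        lt.rms_residual, lt.coverage_fraction, shaft.rms_residual,
    )
    frame = build_frame(head, lt, shaft, case.anterior_ref, side=case.side)
    D = extract_lowest_point(case.region_points("fracture_line"), frame)
    coord = signed_coordinates(frame, D)
    return FractureCase(
        case_id=case.case_id,
        coord=coord,
        grades={s: case.grades.get(s) for s in GRADE_SYSTEMS if case.grades.get(s) is not None},
        side=case.side,
        instability_rank=stability_rank(coord.quadrant),
    )


def _load_if_path(item) -> LabeledCase:
    if isinstance(item, LabeledCase):
        return item
    mesh_path = Path(item)
    stem = mesh_path.with_suffix("")
    return read_case(mesh_path, f"{stem}.labels.json", f"{stem}.meta.json")


def run_cohort(cases, config: RunConfig | None = None):
    """Process a cohort; returns (CohortTable, report dict).

    ``cases`` is a sequence of LabeledCase objects or mesh paths (labels and
    metadata expected beside each mesh as <stem>.labels.json / <stem>.meta.json).
    Failing cases are skipped with a logged reason, never silently dropped.
    """
    config = config or RunConfig()
    rows, failures = [], []
    for item in cases:
        case_id = getattr(item, "case_id", str(item))
        try:
            case = _load_if_path(item)
            rows.append(process_case(case, config))
        except FemquadError as exc:
            log.warning("case %s failed: %s", case_id, exc)
            failures.append({"case_id": case_id, "error": str(exc)})
    if not rows:
        raise RunError(f"no case processed successfully ({len(failures)} failures)")
    table = CohortTable(rows=rows, provenance={"n_failed": len(failures)})

    summaries = summarize_quadrants(rows)
    correlations = {}
    for sys_ in GRADE_SYSTEMS:
        pairs = [(r.grades[sys_], r.instability_rank) for r in rows
                 if r.grades.get(sys_) is not None]
        if len(pairs) < 4:
            continue
        g, s = zip(*pairs)
        try:
            res = spearman_with_ci(g, s, alpha=config.alpha)
            correlations[sys_] = dataclasses.replace(res, classification=sys_)
        except UndefinedCorrelationError as exc:
            correlations[sys_] = {"classification": sys_, "undefined": str(exc)}
            log.warning("correlation for %s undefined: %s", sys_, exc)

    report = {
        "n_processed": len(rows),
        "n_failed": len(failures),
        "failures": failures,
        "quadrant_summaries": [dataclasses.asdict(s) for s in summaries],
        "correlations": {
            k: (dataclasses.asdict(v) if not isinstance(v, dict) else v)
            for k, v in correlations.items()
        },
        "config": {
            "alpha": config.alpha,
            "boundary_convention": config.boundary_convention,
            "fit_tolerance_mm": config.fit.tolerance_mm,
        },
    }
    log.info("cohort run: %d processed, %d failed", len(rows), len(failures))

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(table, out / "cohort.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return table, report
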