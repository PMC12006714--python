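"""Case and cohort I/O.

A case on disk is three files: a triangulated surface (STL or PLY, binary or
ASCII, coordinates in mm), a JSON label file mapping the four region names
(head_patch, lt_patch, shaft_patch, fracture_line) to vertex-index lists, and
a JSON metadata file with keys ``side`` ("left"/"right"), ``anterior_ref``
(3 floats, mm, same frame as the mesh) and ``grades`` (optional integers
under "AO", "Evans", "Tang").  Cohort tables are RFC-4180 CSV, UTF-8, "."
decimal separator, with empty strings for absent grades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError, IncompleteLabelingError

__all__ = [
    "REGIONS",
    "GRADE_SYSTEMS",
    "COHORT_COLUMNS",
    "LabeledCase",
    "CohortTable",
    "read_case",
    "write_case",
    "write_cohort_csv",
    "read_cohort_csv",
]

REGIONS = ("head_patch", "lt_patch", "shaft_patch", "fracture_line")
GRADE_SYSTEMS = ("AO", "Evans", "Tang")
COHORT_COLUMNS = ["case_id", "side", "AO", "Evans", "Tang", "X_mm", "Y_mm", "quadrant"]


@dataclass
class LabeledCase:
    """A reconstructed proximal femur with labeled surface regions."""

    case_id: str
    mesh: trimesh.Trimesh
    labels: dict[str, np.ndarray]  # region -> vertex indices
    side: str = "right"
    anterior_ref: np.ndarray = None  # (3,) mm, a point anterior to the coronal plane
    grades: dict[str, int | None] = field(default_factory=dict)

    def region_points(self, region: str) -> np.ndarray:
        """Vertex coordinates of a labeled region, (n, 3) mm."""
        if region not in self.labels or len(self.labels[region]) == 0:
            raise IncompleteLabelingError(region, self.case_id)
        return self.mesh.vertices[self.labels[region]]

    def validate(self, require_complete: bool = True) -> None:
        nv = len(self.mesh.vertices)
        if not np.isfinite(self.mesh.vertices).all():
            raise FormatError(f"case '{self.case_id}': non-finite vertex coordinates")
        if self.side not in ("left", "right"):
            raise FormatError(f"case '{self.case_id}': side must be 'left' or 'right'")
        for region, idx in self.labels.items():
            if region not in REGIONS:
                raise FormatError(f"case '{self.case_id}': unknown region '{region}'")
            idx = np.asarray(idx)
            if len(idx) and (idx.min() < 0 or idx.max() >= nv):
                raise FormatError(
                    f"case '{self.case_id}': region '{region}' references vertex "
                    f"{int(idx.max())} but the mesh has only {nv} vertices"
                )
        if require_complete:
            for region in REGIONS:
                if region not in self.labels or len(self.labels[region]) == 0:
                    raise IncompleteLabelingError(region, self.case_id)


@dataclass
class CohortTable:
    """Per-case results of a cohort run (rows are FractureCase objects)."""

    rows: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.case_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise FormatError("cohort table has duplicate case_ids")

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({
                "case_id": r.case_id,
                "side": r.side,
                "AO": r.grades.get("AO"),
                "Evans": r.grades.get("Evans"),
                "Tang": r.grades.get("Tang"),
                "X_mm": r.coord.X,
                "Y_mm": r.coord.Y,
                "quadrant": r.coord.quadrant,
            })
        return pd.DataFrame(recs, columns=COHORT_COLUMNS)


def _load_mesh(mesh_path) -> trimesh.Trimesh:
    try:
        mesh = trimesh.load(str(mesh_path), process=False, force="mesh")
    except Exception as exc:
        raise FormatError(f"{mesh_path}: cannot read mesh ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"{mesh_path}: not a readable triangulated surface")
    return mesh


def _export_ply_double(mesh: trimesh.Trimesh, path, encoding: str = "ascii") -> None:
    """PLY export with 64-bit vertex coordinates.

    trimesh's writer stores vertices as float32, which costs ~4e-6 mm at
    femur-scale coordinates; case files are the pipeline's format of record,
    so coordinates are written as doubles (readable by trimesh and any
    standard PLY reader).
    """
    v = np.asarray(mesh.vertices, dtype="<f8")
    f = np.asarray(mesh.faces, dtype=np.int64)
    fmt = "ascii" if encoding == "ascii" else "binary_little_endian"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {len(v)}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {len(f)}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if fmt == "ascii":
            for p in v:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n".encode("ascii"))
            for tri in f:
                fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n".encode("ascii"))
        else:
            fh.write(v.tobytes())
            rec = np.zeros(len(f), dtype=[("n", "u1"), ("idx", "<i4", (3,))])
            rec["n"] = 3
            rec["idx"] = f
            fh.write(rec.tobytes())


def read_case(mesh_path, labels_path, meta_path, require_complete: bool = True) -> LabeledCase:
    """Read and validate one case from its mesh + labels + metadata files."""
    mesh = _load_mesh(mesh_path)
    try:
        labels_raw = json.loads(Path(labels_path).read_text())
        meta = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON in case files: {exc}") from exc
    if not isinstance(labels_raw, dict):
        raise FormatError(f"{labels_path}: label file must be a JSON object")
    labels = {k: np.asarray(v, dtype=np.int64) for k, v in labels_raw.items()}
    grades = {k: (int(v) if v is not None else None)
              for k, v in (meta.get("grades") or {}).items()}
    anterior_ref = meta.get("anterior_ref")
    if anterior_ref is None or len(anterior_ref) != 3:
        raise FormatError(f"{meta_path}: metadata must supply a 3-vector 'anterior_ref'")
    case = LabeledCase(
        case_id=str(meta.get("case_id", Path(mesh_path).stem)),
        mesh=mesh,
        labels=labels,
        side=meta.get("side", "right"),
        anterior_ref=np.asarray(anterior_ref, float),
        grades=grades,
    )
    case.validate(require_complete=require_complete)
    return case


def write_case(case: LabeledCase, mesh_path, labels_path, meta_path,
               encoding: str = "ascii") -> None:
    """Write a case; PLY is used for meshes carrying fracture-line vertices.

    Fracture polyline points are stored as vertices not referenced by any
    face; STL stores triangles only and would drop them, so `.ply` is the
    format of record for planted cases.
    """
    mesh_path = Path(mesh_path)
    if mesh_path.suffix.lower() == ".stl" and len(case.labels.get("fracture_line", ())) > 0:
        raise FormatError("STL cannot carry unreferenced fracture-line vertices; use .ply")
    if mesh_path.suffix.lower() == ".ply":
        _export_ply_double(case.mesh, mesh_path, encoding=encoding)
    else:
        case.mesh.export(str(mesh_path))
    Path(labels_path).write_text(json.dumps(
        {k: np.asarray(v).tolist() for k, v in case.labels.items()}, indent=0))
    meta = {
        "case_id": case.case_id,
        "side": case.side,
        "anterior_ref": np.asarray(case.anterior_ref, float).tolist(),
        "grades": {k: v for k, v in case.grades.items()},
    }
    Path(meta_path).write_text(json.dumps(meta, indent=0))


def write_cohort_csv(table: CohortTable, path) -> None:
    """One row per case; absent grades become empty fields, floats full precision."""
    df = table.to_dataframe()
    for g in GRADE_SYSTEMS:  # keep integer formatting despite NaN-able column
        df[g] = df[g].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v))
                          else int(v))
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "side": str, "quadrant": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cohort CSV missing columns {missing}")
    return df
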