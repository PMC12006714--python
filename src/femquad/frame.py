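"""Patient-specific femoral coordinate frame and medial-wall quadrant mapping.

The coronal plane P_c passes through the femoral-head center O and the two
shaft-axis points C_1 (distal) and C_2 (proximal); its unit normal is oriented
toward a per-case anterior reference point, so positive X means anterior on
both left and right femora.  The transverse plane P_a passes through the
lesser-trochanter center O_1 with the proximally-pointing shaft axis as its
normal; because C_1 and C_2 lie on P_c this makes P_a perpendicular to P_c by
construction.  The two planes divide the medial wall into quadrants

    Q1 anterior-superior   (X >= 0, Y >= 0)
    Q2 posterior-superior  (X <  0, Y >= 0)
    Q3 posterior-inferior  (X <  0, Y <  0)
    Q4 anterior-inferior   (X >= 0, Y <  0)

with zeros assigned to the positive side (a fixed, zero-measure convention).
Mechanical stability of the fracture decreases from Q1 to Q4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AmbiguousOrientationError, DegenerateGeometryError, DegenerateInputError
from .primitives import CylinderFit, SphereFit

__all__ = [
    "PlaneDef",
    "FemurFrame",
    "MedialCoordinate",
    "QUADRANTS",
    "build_frame",
    "signed_coordinates",
    "extract_lowest_point",
    "classify_quadrant",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")

_TIE_TOL = 1e-6  # mm, for lowest-point tie-breaking


@dataclass(frozen=True)
class PlaneDef:
    point: np.ndarray  # (3,) mm
    unit_normal: np.ndarray  # (3,), |n| = 1

    def signed_distance(self, p) -> float:
        return float((np.asarray(p, float) - self.point) @ self.unit_normal)


@dataclass(frozen=True)
class FemurFrame:
    O: np.ndarray  # head center, mm
    O1: np.ndarray  # lesser-trochanter center, mm
    C1: np.ndarray  # distal shaft-axis endpoint, mm
    C2: np.ndarray  # proximal shaft-axis endpoint (nearer the head), mm
    Pc: PlaneDef  # coronal plane, normal anterior
    Pa: PlaneDef  # transverse plane, normal = proximal shaft axis
    side: str  # "left" | "right"


@dataclass(frozen=True)
class MedialCoordinate:
    X: float  # mm, positive anterior
    Y: float  # mm, positive superior (proximal)
    quadrant: str  # Q1..Q4
    D: np.ndarray  # (3,) mm, the lowest point in world coordinates


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_frame(
    head: SphereFit,
    lt: SphereFit,
    shaft: CylinderFit,
    anterior_ref,
    side: str = "right",
) -> FemurFrame:
    """Assemble the coronal/transverse plane frame from fitted primitives.

    The shaft endpoints are re-ordered so C_2 is the endpoint nearer the head
    center O; the coronal normal is flipped, if needed, toward ``anterior_ref``.

    Raises
    ------
    DegenerateGeometryError
        O, C_1, C_2 (near-)collinear: triangle area <= 1 mm^2.
    AmbiguousOrientationError
        ``anterior_ref`` lies within 0.1 mm of the coronal plane.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    O = np.asarray(head.center, float)
    O1 = np.asarray(lt.center, float)
    a_ref = np.asarray(anterior_ref, float)
    c_a, c_b = np.asarray(shaft.c1, float), np.asarray(shaft.c2, float)
    if np.linalg.norm(c_b - O) <= np.linalg.norm(c_a - O):
        C1, C2 = c_a, c_b
    else:
        C1, C2 = c_b, c_a
    area = 0.5 * np.linalg.norm(np.cross(C2 - C1, O - C1))
    if area <= 1.0:
        raise DegenerateGeometryError(
            f"head center and shaft axis are (near-)collinear (triangle area {area:.3g} mm^2)"
        )
    n = _unit(np.cross(C2 - C1, O - C1))
    d_ref = float((a_ref - O) @ n)
    if abs(d_ref) < 0.1:
        raise AmbiguousOrientationError(
            "anterior reference point lies on the coronal plane; orientation is ambiguous"
        )
    if d_ref < 0:
        n = -n
    axis = _unit(C2 - C1)
    return FemurFrame(
        O=O, O1=O1, C1=C1, C2=C2,
        Pc=PlaneDef(point=O, unit_normal=n),
        Pa=PlaneDef(point=O1, unit_normal=axis),
        side=side,
    )


def classify_quadrant(X: float, Y: float) -> str:
    """Sign-pattern quadrant of the medial wall; zeros count as positive."""
    if not (math.isfinite(X) and math.isfinite(Y)):
        raise DegenerateInputError("quadrant classification needs finite X, Y")
    if Y >= 0:
        return "Q1" if X >= 0 else "Q2"
    return "Q4" if X >= 0 else "Q3"


def signed_coordinates(frame: FemurFrame, D) -> MedialCoordinate:
    """Signed (X, Y) of a point D and its quadrant.

    X is the signed distance to the coronal plane (positive anterior); Y the
    signed distance to the transverse plane (positive superior).  The coronal
    normal was oriented by the per-case anterior reference at frame build
    time, which already mirror-normalizes left femora — anterior is +X on
    both sides, so no additional sign flip is applied here.
    """
    D = np.asarray(D, float)
    X = frame.Pc.signed_distance(D)
    Y = frame.Pa.signed_distance(D)
    return MedialCoordinate(X=X, Y=Y, quadrant=classify_quadrant(X, Y), D=D)


def extract_lowest_point(fracture_line, frame: FemurFrame) -> np.ndarray:
    """Lowest (most distal along the shaft axis) point of the fracture line.

    Ties in Y within 1e-6 mm are broken by minimal X, then lexicographically
    on world coordinates, so the choice is deterministic.
    """
    pts = np.asarray(fracture_line, float)
    if pts.size == 0:
        raise DegenerateInputError("fracture line is empty")
    pts = pts.reshape(-1, 3)
    Y = (pts - frame.Pa.point) @ frame.Pa.unit_normal
    cand = np.flatnonzero(Y <= Y.min() + _TIE_TOL)
    if len(cand) > 1:
        X = (pts[cand] - frame.Pc.point) @ frame.Pc.unit_normal
        cand = cand[np.flatnonzero(X <= X.min() + _TIE_TOL)]
        if len(cand) > 1:
            order = np.lexsort((pts[cand, 2], pts[cand, 1], pts[cand, 0]))
            cand = cand[order[:1]]
    return pts[cand[0]]
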