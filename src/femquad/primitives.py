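"""Least-squares geometric primitives: spheres and cylinders from surface patches.

The femoral head and lesser trochanter are modelled as spheres; the proximal
shaft segment as a circular cylinder.  Sphere fitting uses the classical
two-stage scheme: an algebraic (linearized) solution followed by Gauss-Newton
refinement of the orthogonal-distance objective.  Cylinder fitting initializes
the axis from the principal direction of the point cloud and refines
(axis direction, axis point, radius) with a trust-region least-squares solve.

All lengths are millimetres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, CoverageWarning, DegenerateInputError

__all__ = [
    "FitConfig",
    "SphereFit",
    "CylinderFit",
    "fit_sphere",
    "fit_cylinder",
    "algebraic_sphere_fit",
    "solid_angle_coverage",
]


@dataclass(frozen=True)
class FitConfig:
    """Fitting controls.

    tolerance_mm
        Convergence threshold on the movement of the fitted center (sphere) or
        axis point (cylinder) between refinement iterations.
    coverage_warn_threshold
        Emit a :class:`CoverageWarning` when a sphere patch subtends less than
        this fraction of the full solid angle around the fitted center.
    """

    tolerance_mm: float = 0.01
    max_iterations: int = 100
    coverage_warn_threshold: float = 0.80

    def __post_init__(self):
        if self.tolerance_mm <= 0:
            raise ValueError("tolerance_mm must be > 0")
        if not (0 < self.coverage_warn_threshold <= 1):
            raise ValueError("coverage_warn_threshold must be in (0, 1]")


@dataclass(frozen=True)
class SphereFit:
    center: np.ndarray  # (3,) mm
    radius: float  # mm
    rms_residual: float  # mm
    n_points: int
    coverage_fraction: float  # of full 4*pi solid angle, in [0, 1]


@dataclass(frozen=True)
class CylinderFit:
    c1: np.ndarray  # (3,) mm, distal axis endpoint
    c2: np.ndarray  # (3,) mm, proximal axis endpoint
    radius: float  # mm
    rms_residual: float  # mm
    n_points: int
    axis: np.ndarray = field(default=None)  # unit direction c1 -> c2

    def __post_init__(self):
        if self.axis is None:
            d = np.asarray(self.c2, float) - np.asarray(self.c1, float)
            object.__setattr__(self, "axis", d / np.linalg.norm(d))


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise DegenerateInputError("points must be an (n, 3) array")
    if not np.isfinite(pts).all():
        raise DegenerateInputError("points contain non-finite coordinates")
    return pts


def algebraic_sphere_fit(points) -> tuple[np.ndarray, float]:
    """Linear least-squares sphere (Coope's formulation).

    Expanding |p - c|^2 = r^2 gives the linear system
    ``2 p . c + (r^2 - |c|^2) = |p|^2`` in the unknowns ``(c, r^2 - |c|^2)``.
    Exact on noiseless data; used to seed the geometric refinement.
    """
    pts = _as_points(points)
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("algebraic sphere fit produced non-positive radius")
    return center, math.sqrt(r2)


def _fibonacci_directions(n: int = 2048) -> np.ndarray:
    i = np.arange(n)
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * math.pi * i / phi
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(theta), s * np.sin(theta), z])


_REF_DIRS = _fibonacci_directions(2048)


def solid_angle_coverage(directions: np.ndarray) -> float:
    """Fraction of the full sphere of directions covered by a patch.

    A quasi-uniform reference grid is marked covered where some patch
    direction lies within an angular reach adapted to the patch's own
    sampling density (at least 5 degrees, so coarse meshes are not
    penalized for discreteness).
    """
    dirs = np.asarray(directions, float)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    sub = dirs if len(dirs) <= 600 else dirs[:: len(dirs) // 600]
    g = np.clip(sub @ sub.T, -1.0, 1.0)
    np.fill_diagonal(g, -1.0)
    nn_angle = float(np.median(np.arccos(np.max(g, axis=1)))) if len(sub) > 1 else 0.0
    # clamp: below, coarse meshes are over-penalized; above, sparse point
    # sets would claim coverage they do not have
    reach = float(np.clip(2.0 * nn_angle, math.radians(5.0), math.radians(20.0)))
    covered = (_REF_DIRS @ dirs.T).max(axis=1) >= math.cos(reach)
    return float(covered.mean())


def fit_sphere(points, config: FitConfig | None = None) -> SphereFit:
    """Orthogonal-distance sphere fit.

    Minimizes ``sum_i (|p_i - c| - r)^2`` by Gauss-Newton from the algebraic
    solution.  Convergence: center movement below ``config.tolerance_mm``.

    Raises
    ------
    DegenerateInputError
        Fewer than 4 points, or a coplanar cloud.
    ConvergenceError
        No convergence within ``config.max_iterations`` (last iterate attached).
    """
    config = config or FitConfig()
    pts = _as_points(points)
    if len(pts) < 4:
        raise DegenerateInputError(f"sphere fit needs >= 4 points, got {len(pts)}")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateInputError("sphere fit: points are (near-)coplanar")

    center, radius = algebraic_sphere_fit(pts)
    converged = False
    for _ in range(config.max_iterations):
        diff = pts - center
        dists = np.linalg.norm(diff, axis=1)
        if np.any(dists < 1e-12):
            raise DegenerateInputError("sphere fit: a point coincides with the center")
        dirs = diff / dists[:, None]
        res = dists - radius
        # J = d res / d(c, r) = [-dirs, -1]; Gauss-Newton normal equations
        J = np.column_stack([-dirs, -np.ones(len(pts))])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        center = center + step[:3]
        radius = radius + step[3]
        if np.linalg.norm(step[:3]) < config.tolerance_mm:
            converged = True
            break
    dists = np.linalg.norm(pts - center, axis=1)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    coverage = solid_angle_coverage((pts - center) / dists[:, None])
    fit = SphereFit(center=center, radius=float(radius), rms_residual=rms,
                    n_points=len(pts), coverage_fraction=coverage)
    if not converged:
        raise ConvergenceError(
            f"sphere fit did not converge in {config.max_iterations} iterations", last_fit=fit
        )
    if coverage < config.coverage_warn_threshold:
        warnings.warn(
            f"sphere patch covers {coverage:.2f} of the solid angle "
            f"(< {config.coverage_warn_threshold:.2f}); center may be poorly constrained",
            CoverageWarning,
            stacklevel=2,
        )
    return fit


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def _angles_from_axis(a: np.ndarray) -> tuple[float, float]:
    a = a / np.linalg.norm(a)
    return math.acos(np.clip(a[2], -1.0, 1.0)), math.atan2(a[1], a[0])


def fit_cylinder(points, config: FitConfig | None = None) -> CylinderFit:
    """Orthogonal-distance circular-cylinder fit.

    The axis is seeded from the dominant principal direction; the in-plane
    circle center and radius from an algebraic 2-D circle fit of the
    projected points.  Refinement runs over (axis point, axis angles, radius)
    on the residual ``dist(p_i, axis) - r``.

    c1/c2 are the projections of the extreme points onto the fitted axis;
    their proximal/distal ordering is finalized by the frame builder, which
    knows the head center.
    """
    config = config or FitConfig()
    pts = _as_points(points)
    if len(pts) < 6:
        raise DegenerateInputError(f"cylinder fit needs >= 6 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, sv, Vt = np.linalg.svd(centered, full_matrices=False)
    axis0 = Vt[0]
    span = centered @ axis0
    if span.max() - span.min() < 10.0:
        raise DegenerateInputError(
            "cylinder fit: points span < 10 mm along the dominant direction"
        )
    # in-plane circle init (Coope in the plane orthogonal to axis0)
    e1 = Vt[1]
    e2 = Vt[2]
    uv = np.column_stack([centered @ e1, centered @ e2])
    A = np.column_stack([2.0 * uv, np.ones(len(uv))])
    b = np.einsum("ij,ij->i", uv, uv)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cu, cv = sol[0], sol[1]
    r0 = math.sqrt(max(sol[2] + cu * cu + cv * cv, 1e-6))
    p0 = centroid + cu * e1 + cv * e2
    theta0, phi0 = _angles_from_axis(axis0)

    def residual(x):
        p = x[:3]
        a = _axis_from_angles(x[3], x[4])
        d = pts - p
        along = d @ a
        perp = d - along[:, None] * a
        return np.linalg.norm(perp, axis=1) - x[5]

    x0 = np.array([*p0, theta0, phi0, r0])
    out = least_squares(residual, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=200 * config.max_iterations)
    p = out.x[:3]
    a = _axis_from_angles(out.x[3], out.x[4])
    radius = float(abs(out.x[5]))
    if radius < 1e-6:
        raise DegenerateInputError("cylinder fit collapsed to zero radius")
    res = residual(out.x)
    rms = float(np.sqrt(np.mean(res**2)))
    sphere_rms = None
    if rms > 0.5:  # guard against near-spherical clouds masquerading as cylinders
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", CoverageWarning)
                sphere_rms = fit_sphere(pts, config).rms_residual
        except Exception:
            sphere_rms = None
    if sphere_rms is not None and sphere_rms < 0.25 * rms:
        raise DegenerateInputError("cylinder fit: point cloud is near-spherical")
    if radius > 50.0 * sv[0]:
        raise DegenerateInputError("cylinder fit: point cloud is near-planar")
    t = (pts - p) @ a
    # anchor the (gauge-free) axis point at the centroid of projections
    p = p + t.mean() * a
    t = t - t.mean()
    c_lo = p + t.min() * a
    c_hi = p + t.max() * a
    return CylinderFit(c1=c_lo, c2=c_hi, radius=radius, rms_residual=rms, n_points=len(pts))
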