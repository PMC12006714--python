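"""Synthetic proximal femora and cohorts with known ground truth.

A parametric femur is the union of four primitive components — head sphere,
neck frustum, lesser-trochanter (LT) bump, and shaft cylinder — meshed at a
target edge length, with exact analytic labels for the head patch, the LT
patch, and the 5 cm cylindrical shaft band distal to the LT's lower edge.
Because every component is an analytic primitive, the ground-truth frame
(O, O_1, C_1, C_2, P_c, P_a) is known exactly, and fracture-line lowest
points can be planted at chosen signed coordinates (X, Y).

Cohorts are simulated directly in frame space: per-quadrant bivariate normal
(X, Y) draws (optionally rejection-truncated to the quadrant's sign pattern),
one femur per case, and ordinal classification grades coupled to the
quadrant instability rank through a Gaussian copula whose latent correlation
is calibrated exactly so the population Spearman of the discretized pair
matches a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal

from .errors import SpecError
from .frame import (QUADRANTS, FemurFrame, MedialCoordinate, build_frame,
                    classify_quadrant)
from .mesh_io import GRADE_SYSTEMS, REGIONS, CohortTable, LabeledCase
from .primitives import CylinderFit, SphereFit
from .stats import FractureCase, stability_rank
from . import reference

__all__ = [
    "FemurSpec",
    "CohortSpec",
    "SimulatedCohort",
    "make_proximal_femur",
    "plant_fracture_point",
    "simulate_cohort",
    "random_femur_spec",
    "truth_frame",
    "reference_cohort_spec",
    "calibrate_latent_rho",
    "population_spearman_discretized",
]

SHAFT_BAND_MM = 50.0  # length of the cylinder-fit band distal to the LT lower edge


@dataclass(frozen=True)
class FemurSpec:
    """Parametric proximal femur; all lengths in mm, world coordinates.

    The shaft axis runs from ``shaft_axis_point`` (proximal end of the shaft
    segment) a distance ``shaft_length`` in the ``-shaft_axis`` direction;
    ``shaft_axis`` points proximally.  Defaults describe a right femur in a
    canonical pose: shaft along +z, head medial (+y) and superior, anterior
    along +x.
    """

    head_radius: float = 24.0
    head_center: tuple = (0.0, 40.0, 45.0)
    lt_radius: float = 10.0
    lt_center: tuple = (-4.0, 16.0, 0.0)
    shaft_radius: float = 14.0
    shaft_axis: tuple = (0.0, 0.0, 1.0)
    shaft_axis_point: tuple = (0.0, 0.0, 42.0)
    shaft_length: float = 130.0
    neck_radius: float = 13.0
    neck_length: float = 25.0
    surface_noise_sd: float = 0.0
    mesh_resolution: float = 2.0  # target edge length
    seed: int = 0

    def __post_init__(self):
        for name in ("head_radius", "lt_radius", "shaft_radius", "shaft_length",
                     "neck_radius", "neck_length", "mesh_resolution"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        if self.shaft_length < SHAFT_BAND_MM:
            raise SpecError(f"shaft_length must be >= {SHAFT_BAND_MM} mm to host the fit band")
        a = np.asarray(self.shaft_axis, float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-8:
            raise SpecError("shaft_axis must be a unit vector")
        if self.surface_noise_sd < 0:
            raise SpecError("surface_noise_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort simulation parameters; defaults mirror the reference series."""

    n_total: int = reference.N_TOTAL
    quadrant_counts: dict = field(
        default_factory=lambda: dict(reference.QUADRANT_COUNTS))
    coord_params: dict = field(
        default_factory=lambda: {q: dict(v) for q, v in
                                 reference.QUADRANT_COORD_PARAMS.items()})
    grade_rho: dict = field(default_factory=lambda: dict(reference.GRADE_RHO))
    grade_levels: dict = field(default_factory=lambda: dict(reference.GRADE_LEVELS))
    truncate_to_quadrant: bool = True
    seed: int = 0

    def __post_init__(self):
        counts = {q: int(self.quadrant_counts.get(q, 0)) for q in QUADRANTS}
        if sum(counts.values()) != self.n_total:
            raise SpecError(
                f"quadrant_counts sum to {sum(counts.values())}, expected n_total={self.n_total}"
            )
        for sys_, rho in self.grade_rho.items():
            if abs(rho) > 1:
                raise SpecError(f"grade_rho[{sys_}] out of [-1, 1]")
        for q, p in self.coord_params.items():
            if p["sd_X"] < 0 or p["sd_Y"] < 0:
                raise SpecError(f"coord_params[{q}] has negative sd")


@dataclass
class SimulatedCohort:
    """Ground truth plus (optionally) the meshed cases of one simulation."""

    truth: CohortTable  # rows carry the planted coordinates
    cases: list  # LabeledCase per row (empty in coordinates-only mode)
    frames: list  # ground-truth FemurFrame per row (empty in coordinates-only mode)


# ---------------------------------------------------------------------------
# femur construction


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _basis_perp(u):
    """Two unit vectors completing ``u`` to an orthonormal right-handed triad."""
    h = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(h, u))
    e2 = np.cross(u, e1)
    return e1, e2


def _icosphere(center, radius, resolution):
    subdiv = int(np.clip(math.ceil(math.log2(max(1.05 * radius / resolution, 1.0))), 1, 4))
    m = trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    v = m.vertices + np.asarray(center, float)
    return v, m.faces.copy()


def _tube(p_start, p_end, r_start, r_end, resolution):
    """Open triangulated tube (frustum) between two axis points."""
    axis = np.asarray(p_end, float) - np.asarray(p_start, float)
    length = np.linalg.norm(axis)
    u = axis / length
    e1, e2 = _basis_perp(u)
    n_theta = max(16, int(math.ceil(2.0 * math.pi * max(r_start, r_end) / resolution)))
    n_rows = max(2, int(math.ceil(length / resolution)) + 1)
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    ring_dir = np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2)
    verts = []
    for k in range(n_rows):
        t = k / (n_rows - 1)
        c = np.asarray(p_start, float) + t * axis
        r = (1 - t) * r_start + t * r_end
        verts.append(c + r * ring_dir)
    verts = np.concatenate(verts, axis=0)
    faces = []
    for k in range(n_rows - 1):
        a0 = k * n_theta
        b0 = (k + 1) * n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    return verts, np.asarray(faces, dtype=np.int64)


def _mask_component(verts, faces, keep):
    """Drop vertices where ``keep`` is False, keeping only fully-kept faces."""
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[keep] = np.arange(int(keep.sum()))
    fkeep = keep[faces].all(axis=1)
    return verts[keep], remap[faces[fkeep]]


def truth_frame(spec: FemurSpec, side: str = "right"):
    """Exact analytic frame for a spec; also returns the anterior reference.

    C_2/C_1 are the proximal/distal endpoints of the 5 cm shaft-fit band,
    the band top sitting at the LT sphere's lower edge (its most distal
    surface point, which for the exposed bump is within one mesh edge of the
    labeled patch's own lower edge).
    """
    u = _unit(spec.shaft_axis)
    A = np.asarray(spec.shaft_axis_point, float)
    O = np.asarray(spec.head_center, float)
    O1 = np.asarray(spec.lt_center, float)
    t_band_top = (O1 - A) @ u - spec.lt_radius
    c2 = A + t_band_top * u
    c1 = A + (t_band_top - SHAFT_BAND_MM) * u
    w = O - (A + ((O - A) @ u) * u)
    if np.linalg.norm(w) < 1e-9:
        raise SpecError("head center lies on the shaft axis")
    n_ant = _unit(np.cross(_unit(w), u))  # anterior for a right femur (medial x proximal)
    anterior_ref = O + 30.0 * n_ant
    head = SphereFit(center=O, radius=spec.head_radius, rms_residual=0.0,
                     n_points=0, coverage_fraction=1.0)
    lt = SphereFit(center=O1, radius=spec.lt_radius, rms_residual=0.0,
                   n_points=0, coverage_fraction=1.0)
    shaft = CylinderFit(c1=c1, c2=c2, radius=spec.shaft_radius, rms_residual=0.0, n_points=0)
    return build_frame(head, lt, shaft, anterior_ref, side=side), anterior_ref


def make_proximal_femur(spec: FemurSpec, case_id: str = "synthetic"):
    """Build a labeled synthetic femur; returns (LabeledCase, ground-truth frame).

    The mesh is the concatenated union of the four components (not
    watertight at the junctions, which no downstream step requires).
    Surface noise, when requested, is i.i.d. Gaussian along each component's
    analytic normal; labels are assigned from the noise-free geometry so the
    same seed always yields the same label sets.
    """
    u = _unit(spec.shaft_axis)
    A = np.asarray(spec.shaft_axis_point, float)
    O = np.asarray(spec.head_center, float)
    O1 = np.asarray(spec.lt_center, float)
    rng = np.random.default_rng(spec.seed)

    t_O = (O - A) @ u
    t_O1 = (O1 - A) @ u
    band_top = t_O1 - spec.lt_radius
    band_bot = band_top - SHAFT_BAND_MM
    shaft_top = 0.0  # at shaft_axis_point
    shaft_bot = -spec.shaft_length
    if band_bot < shaft_bot - 1e-9 or band_top > shaft_top + 1e-9:
        raise SpecError("shaft segment does not contain the 5 cm fit band below the LT edge")
    if t_O - spec.head_radius < band_top + 5.0:
        raise SpecError("head sphere reaches into the shaft fit band; spec is impossible")
    d_lt_axis = np.linalg.norm(O1 - (A + t_O1 * u))
    if d_lt_axis + spec.lt_radius <= spec.shaft_radius + 1.0:
        raise SpecError("lesser trochanter is fully buried inside the shaft")

    # --- components (clean geometry first, labels from it) -----------------
    hv, hf = _icosphere(O, spec.head_radius, spec.mesh_resolution)
    neck_base = A + (t_O - spec.head_radius - spec.neck_length) * u
    neck_dir = _unit(O - neck_base)
    # keep all points except the cap facing the neck (cap half-angle 35 deg)
    keep = ((hv - O) @ neck_dir) / spec.head_radius < math.cos(math.radians(35.0))
    hv, hf = _mask_component(hv, hf, keep)

    lv, lf = _icosphere(O1, spec.lt_radius, spec.mesh_resolution)

    sv, sf = _tube(A + shaft_bot * u, A + shaft_top * u,
                   spec.shaft_radius, spec.shaft_radius, spec.mesh_resolution)

    nv, nf = _tube(neck_base, O - 0.6 * spec.head_radius * neck_dir,
                   spec.neck_radius, 0.9 * spec.neck_radius, spec.mesh_resolution)

    comps = []
    for verts, faces, normal_fn in (
        (hv, hf, lambda v: (v - O) / np.linalg.norm(v - O, axis=1, keepdims=True)),
        (lv, lf, lambda v: (v - O1) / np.linalg.norm(v - O1, axis=1, keepdims=True)),
        (sv, sf, lambda v: _radial_normals(v, A, u)),
        (nv, nf, None),
    ):
        noisy = verts
        if spec.surface_noise_sd > 0 and normal_fn is not None:
            noisy = verts + spec.surface_noise_sd * rng.standard_normal(
                (len(verts), 1)) * normal_fn(verts)
        elif spec.surface_noise_sd > 0:
            rng.standard_normal((len(verts), 1))  # keep the stream aligned
        comps.append((verts, noisy, faces))

    offsets = np.cumsum([0] + [len(c[0]) for c in comps])
    all_clean = np.concatenate([c[0] for c in comps])
    all_noisy = np.concatenate([c[1] for c in comps])
    all_faces = np.concatenate([c[2] + offsets[i] for i, c in enumerate(comps)])

    # --- labels from the clean geometry ------------------------------------
    h_idx = np.arange(offsets[0], offsets[1])
    l_idx = np.arange(offsets[1], offsets[2])
    s_idx = np.arange(offsets[2], offsets[3])
    lt_clean = all_clean[l_idx]
    lt_radial = np.linalg.norm(lt_clean - (A + (((lt_clean - A) @ u)[:, None] * u)), axis=1)
    lt_exposed = l_idx[lt_radial > spec.shaft_radius + 0.25]
    if len(lt_exposed) < 20:
        raise SpecError("lesser trochanter exposes too few surface points")
    s_t = (all_clean[s_idx] - A) @ u
    band_idx = s_idx[(s_t >= band_bot - 1e-9) & (s_t <= band_top + 1e-9)]

    mesh = trimesh.Trimesh(vertices=all_noisy, faces=all_faces, process=False)
    frame, anterior_ref = truth_frame(spec)
    labels = {
        "head_patch": h_idx.astype(np.int64),
        "lt_patch": lt_exposed.astype(np.int64),
        "shaft_patch": band_idx.astype(np.int64),
        "fracture_line": np.empty(0, dtype=np.int64),
    }
    case = LabeledCase(case_id=case_id, mesh=mesh, labels=labels, side="right",
                       anterior_ref=anterior_ref, grades={})
    case.validate(require_complete=False)
    return case, frame


def _radial_normals(v, A, u):
    d = v - A
    perp = d - (d @ u)[:, None] * u
    return perp / np.linalg.norm(perp, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# fracture-line planting


def plant_fracture_point(case: LabeledCase, truth: FemurFrame,
                         X_target: float, Y_target: float,
                         n_tail: int = 3, tail_step: float = 2.5) -> LabeledCase:
    """Plant a fracture polyline whose lowest point has exact frame coordinates.

    The designated lowest point D sits where the constant-(X, Y) medial line
    (direction P_c-normal x P_a-normal, pointing toward the head side)
    pierces the shaft cylinder; when |X| exceeds the cylinder radius — which
    untruncated Gaussian tails of the reference parameters can produce — D is
    placed on the same line at the plane of the shaft axis instead of on the
    surface, keeping the ground-truth coordinates exact rather than rejecting
    or clipping the draw.  ``n_tail`` additional polyline points are added at
    strictly larger Y.
    """
    n_c, n_a = truth.Pc.unit_normal, truth.Pa.unit_normal
    m = np.cross(n_c, n_a)
    axis_pt, u = truth.C1, truth.Pa.unit_normal
    head_side = truth.O - (axis_pt + (((truth.O - axis_pt) @ u) * u))
    if head_side @ m < 0:
        m = -m
    # shaft radius is not stored on the frame; recover it from the labeled band
    band = case.region_points("shaft_patch")
    d = band - axis_pt
    R = float(np.median(np.linalg.norm(d - (d @ u)[:, None] * u, axis=1)))

    def point_at(X, Y):
        base = truth.O1 + (X - (truth.O1 - truth.O) @ n_c) * n_c + Y * n_a
        w0 = base - axis_pt
        w0 = w0 - (w0 @ u) * u
        b = w0 @ m
        c = w0 @ w0 - R * R
        disc = b * b - c
        t = (-b + math.sqrt(disc)) if disc > 0 else 0.0
        return base + t * m

    pts = [point_at(X_target, Y_target)]
    for k in range(1, n_tail + 1):
        pts.append(point_at(X_target + 0.4 * k * tail_step, Y_target + k * tail_step))
    pts = np.asarray(pts)

    new_vertices = np.vstack([case.mesh.vertices, pts])
    new_idx = np.arange(len(case.mesh.vertices), len(new_vertices), dtype=np.int64)
    mesh = trimesh.Trimesh(vertices=new_vertices, faces=case.mesh.faces.copy(), process=False)
    labels = {k: np.asarray(v).copy() for k, v in case.labels.items()}
    labels["fracture_line"] = np.concatenate([
        labels.get("fracture_line", np.empty(0, dtype=np.int64)), new_idx])
    return LabeledCase(case_id=case.case_id, mesh=mesh, labels=labels, side=case.side,
                       anterior_ref=case.anterior_ref, grades=dict(case.grades))


# ---------------------------------------------------------------------------
# Gaussian-copula grade simulation


def _grade_thresholds(levels: int) -> np.ndarray:
    return ndtri(np.arange(1, levels) / levels)


def _rank_thresholds(rank_probs: np.ndarray) -> np.ndarray:
    cum = np.cumsum(rank_probs)[:-1]
    return ndtri(np.clip(cum, 1e-12, 1 - 1e-12))


def _midrank_scores(probs: np.ndarray) -> np.ndarray:
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    return (cum[:-1] + cum[1:]) / 2.0


def population_spearman_discretized(latent_rho: float, probs_a, probs_b) -> float:
    """Population Spearman of two thresholded standard normals.

    The joint cell probabilities come from bivariate-normal rectangle
    probabilities at the marginal quantile thresholds; Spearman with ties is
    the Pearson correlation of the population mid-rank scores under that pmf.
    Exact (to CDF quadrature accuracy) and free of sampling error.
    """
    pa = np.asarray(probs_a, float)
    pb = np.asarray(probs_b, float)
    if abs(latent_rho) < 1e-12:
        return 0.0
    ta = np.concatenate([[-8.0], ndtri(np.clip(np.cumsum(pa)[:-1], 1e-12, 1 - 1e-12)), [8.0]])
    tb = np.concatenate([[-8.0], ndtri(np.clip(np.cumsum(pb)[:-1], 1e-12, 1 - 1e-12)), [8.0]])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, latent_rho], [latent_rho, 1.0]])
    grid = np.array([[x, y] for x in ta for y in tb])
    F = mvn.cdf(grid).reshape(len(ta), len(tb))
    cell = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    cell = np.clip(cell, 0.0, None)
    cell = cell / cell.sum()
    sa = _midrank_scores(cell.sum(axis=1))
    sb = _midrank_scores(cell.sum(axis=0))
    ma = (cell.sum(axis=1) * sa).sum()
    mb = (cell.sum(axis=0) * sb).sum()
    va = (cell.sum(axis=1) * (sa - ma) ** 2).sum()
    vb = (cell.sum(axis=0) * (sb - mb) ** 2).sum()
    cov = (cell * np.outer(sa - ma, sb - mb)).sum()
    return float(cov / math.sqrt(va * vb))


@lru_cache(maxsize=64)
def _calibrate_cached(target: float, probs_a: tuple, probs_b: tuple) -> float:
    if abs(target) < 1e-9:
        return 0.0

    def f(r):
        return population_spearman_discretized(r, probs_a, probs_b) - target

    return float(brentq(f, -0.9999, 0.9999, xtol=1e-10))


def calibrate_latent_rho(target_spearman: float, probs_grade, probs_rank) -> float:
    """Latent Gaussian correlation giving a target population Spearman after
    discretization of both margins.  Deterministic; monotone in the target."""
    return _calibrate_cached(
        round(float(target_spearman), 10),
        tuple(np.round(np.asarray(probs_grade, float), 12)),
        tuple(np.round(np.asarray(probs_rank, float), 12)),
    )


def _sample_grades(rng, ranks, rank_probs, grade_levels, grade_rho):
    """Grades for each case via the copula, conditioned on realized ranks."""
    ranks = np.asarray(ranks, int)
    n = len(ranks)
    cum = np.concatenate([[0.0], np.cumsum(rank_probs)])
    lo = cum[ranks - 1]
    hi = cum[ranks]
    u_i = lo + (hi - lo) * rng.random(n)
    z_i = ndtri(np.clip(u_i, 1e-12, 1 - 1e-12))
    constant_ranks = np.count_nonzero(rank_probs) < 2
    out = {}
    for sys_ in GRADE_SYSTEMS:
        if sys_ not in grade_rho:
            continue
        L = grade_levels[sys_]
        # a single-quadrant cohort has a constant instability rank; no finite
        # latent correlation can induce a target Spearman there, so grades
        # are drawn independently
        rho_lat = 0.0 if constant_ranks else calibrate_latent_rho(
            grade_rho[sys_], np.full(L, 1.0 / L), rank_probs)
        z_g = rho_lat * z_i + math.sqrt(max(0.0, 1.0 - rho_lat**2)) * rng.standard_normal(n)
        thr = _grade_thresholds(L)
        out[sys_] = 1 + np.searchsorted(thr, z_g)
    return out


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_coordinates(rng, cspec: CohortSpec):
    coords, quads = [], []
    for q in QUADRANTS:
        count = int(cspec.quadrant_counts.get(q, 0))
        if count == 0:
            continue
        p = cspec.coord_params[q]
        for _ in range(count):
            while True:
                x = rng.normal(p["mean_X"], p["sd_X"])
                y = rng.normal(p["mean_Y"], p["sd_Y"])
                if not cspec.truncate_to_quadrant or classify_quadrant(x, y) == q:
                    break
            coords.append((x, y))
            quads.append(q)
    return np.asarray(coords), quads


def simulate_cohort(cspec: CohortSpec, fspec: FemurSpec | None = None,
                    meshed: bool = True) -> SimulatedCohort:
    """Simulate a cohort with known ground truth.

    In meshed mode each case gets a synthetic femur (per-case seed spawned
    from the cohort seed; when the femur spec is noise-free the base mesh is
    built once and shared, since it is then deterministic) with the drawn
    (X, Y) planted as the fracture line's lowest point.  In coordinates-only
    mode no meshes are built and quadrants come directly from the draws —
    the mode used for correlation-recovery experiments where geometry adds
    nothing but runtime.
    """
    fspec = fspec or FemurSpec()
    ss = np.random.SeedSequence(cspec.seed)
    rng = np.random.default_rng(ss)
    coords, quads = _draw_coordinates(rng, cspec)
    n = len(coords)
    ranks = np.array([stability_rank(q) for q in quads])
    rank_probs = np.array([cspec.quadrant_counts.get(q, 0) for q in QUADRANTS], float)
    rank_probs = rank_probs / rank_probs.sum()
    grades = _sample_grades(rng, ranks, rank_probs, cspec.grade_levels, cspec.grade_rho)

    rows, cases, frames = [], [], []
    base_case = base_frame = None
    child_seeds = ss.spawn(n) if meshed and fspec.surface_noise_sd > 0 else [None] * n
    for i in range(n):
        case_id = f"case_{i:04d}"
        x, y = coords[i]
        case = frame = None
        if meshed:
            if fspec.surface_noise_sd > 0:
                seed_i = int(child_seeds[i].generate_state(1)[0] % (2**31))
                case, frame = make_proximal_femur(replace(fspec, seed=seed_i), case_id)
            else:
                if base_case is None:
                    base_case, base_frame = make_proximal_femur(fspec, case_id)
                case, frame = base_case, base_frame
            case = plant_fracture_point(case, frame, x, y)
            case = LabeledCase(case_id=case_id, mesh=case.mesh, labels=case.labels,
                               side=case.side, anterior_ref=case.anterior_ref,
                               grades={s: int(g[i]) for s, g in grades.items()})
            cases.append(case)
            frames.append(frame)
        D = case.mesh.vertices[case.labels["fracture_line"][0]] if case is not None \
            else np.array([x, 0.0, y])
        coord = MedialCoordinate(X=float(x), Y=float(y),
                                 quadrant=classify_quadrant(x, y), D=D)
        rows.append(FractureCase(case_id=case_id, coord=coord,
                                 grades={s: int(g[i]) for s, g in grades.items()}))
    table = CohortTable(rows=rows, provenance={"seed": cspec.seed,
                                               "truncate": cspec.truncate_to_quadrant,
                                               "meshed": meshed})
    return SimulatedCohort(truth=table, cases=cases, frames=frames)


def reference_cohort_spec(seed: int = 0, truncate: bool = True) -> CohortSpec:
    """The reference-series cohort: counts 20/21/122/42 and published moments."""
    return CohortSpec(truncate_to_quadrant=truncate, seed=seed)


def random_femur_spec(rng) -> FemurSpec:
    """A random plausible femur spec in a random rigid pose (for property tests)."""
    from scipy.spatial.transform import Rotation

    Rm = Rotation.random(random_state=rng).as_matrix()
    tv = rng.uniform(-100, 100, size=3)
    head_r = rng.uniform(20, 27)
    shaft_r = rng.uniform(12, 16)
    lt_r = rng.uniform(8, 12)
    offset = rng.uniform(32, 48)  # head offset from the shaft axis
    head_z = rng.uniform(40, 55)
    lt_c = np.array([rng.uniform(-8, 2), shaft_r + rng.uniform(0, lt_r - 2), 0.0])
    spec = FemurSpec(
        head_radius=head_r,
        head_center=tuple(Rm @ np.array([rng.uniform(-4, 4), offset, head_z]) + tv),
        lt_radius=lt_r,
        lt_center=tuple(Rm @ lt_c + tv),
        shaft_radius=shaft_r,
        shaft_axis=tuple(Rm @ np.array([0.0, 0.0, 1.0])),
        shaft_axis_point=tuple(Rm @ np.array([0.0, 0.0, rng.uniform(35, 48)]) + tv),
        shaft_length=rng.uniform(120, 150),
        seed=int(rng.integers(2**31)),
    )
    return spec
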