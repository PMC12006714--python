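"""Cohort statistics: quadrant summaries, normality screening, and Spearman
rank correlation between ordinal fracture classifications and quadrant-based
instability.

Instability is the quadrant rank (Q1 -> 1 ... Q4 -> 4): mechanical stability
of the fracture decreases from Q1 to Q4, so a classification whose higher
grades mean less stability correlates positively.  Spearman's rho is the
Pearson correlation of mid-ranks (average ranks for ties), with a Student-t
p-value approximation and a Fisher-z confidence interval; a seeded
permutation p-value is available for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, UndefinedCorrelationError
from .frame import QUADRANTS, MedialCoordinate

__all__ = [
    "FractureCase",
    "QuadrantSummary",
    "CorrelationResult",
    "stability_rank",
    "summarize_quadrants",
    "shapiro_wilk",
    "spearman_with_ci",
    "fisher_confidence_interval",
]

_RANK_OF = {q: i + 1 for i, q in enumerate(QUADRANTS)}


def stability_rank(quadrant: str) -> int:
    """Instability rank of a quadrant: Q1 -> 1 (most stable) ... Q4 -> 4."""
    try:
        return _RANK_OF[quadrant]
    except KeyError:
        raise ValueError(f"unknown quadrant {quadrant!r}") from None


@dataclass
class FractureCase:
    """One patient: classification grades plus the mapped lowest-point coordinate."""

    case_id: str
    coord: MedialCoordinate
    grades: dict[str, int | None] = field(default_factory=dict)
    side: str = "right"
    instability_rank: int = None

    def __post_init__(self):
        expected = stability_rank(self.coord.quadrant)
        if self.instability_rank is None:
            self.instability_rank = expected
        elif self.instability_rank != expected:
            raise ValueError(
                f"case '{self.case_id}': instability_rank {self.instability_rank} "
                f"inconsistent with quadrant {self.coord.quadrant}"
            )


@dataclass(frozen=True)
class QuadrantSummary:
    quadrant: str
    n: int
    mean_X: float  # mm; NaN when n = 0
    sd_X: float  # mm, n-1 denominator; NaN when n < 2
    mean_Y: float
    sd_Y: float

    @property
    def moments_defined(self) -> bool:
        return self.n >= 2


@dataclass(frozen=True)
class CorrelationResult:
    classification: str
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def summarize_quadrants(cases) -> list[QuadrantSummary]:
    """Per-quadrant n and mean +/- SD of (X, Y); empty quadrants get n = 0."""
    cases = list(cases)
    if not cases:
        raise DegenerateInputError("summarize_quadrants needs >= 1 case")
    out = []
    for q in QUADRANTS:
        xs = np.array([c.coord.X for c in cases if c.coord.quadrant == q])
        ys = np.array([c.coord.Y for c in cases if c.coord.quadrant == q])
        n = len(xs)
        out.append(QuadrantSummary(
            quadrant=q,
            n=n,
            mean_X=float(xs.mean()) if n else math.nan,
            sd_X=float(xs.std(ddof=1)) if n >= 2 else math.nan,
            mean_Y=float(ys.mean()) if n else math.nan,
            sd_Y=float(ys.std(ddof=1)) if n >= 2 else math.nan,
        ))
    return out


def shapiro_wilk(values) -> dict:
    """Shapiro-Wilk normality test, {"W": ..., "p": ...}.

    Valid for 3 <= n <= 5000.  A constant vector has no distributional shape
    to test; this implementation raises a degenerate-input error for it
    rather than echoing scipy's W = 1 (which would read as "normal").
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or not (3 <= len(v) <= 5000):
        raise DegenerateInputError("Shapiro-Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise DegenerateInputError("Shapiro-Wilk is undefined for a constant sample")
    W, p = sps.shapiro(v)
    return {"W": float(W), "p": float(p)}


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def fisher_confidence_interval(rho: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval: tanh(atanh(rho) +/- z_{1-a/2} / sqrt(n-3))."""
    if n < 4:
        raise DegenerateInputError("Fisher-z CI needs n >= 4")
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    r_safe = float(np.clip(rho, -1 + 1e-15, 1 - 1e-15))
    half = z_crit / math.sqrt(n - 3)
    return math.tanh(math.atanh(r_safe) - half), math.tanh(math.atanh(r_safe) + half)


def spearman_with_ci(
    grade,
    instability,
    alpha: float = 0.05,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> CorrelationResult:
    """Spearman rho with Fisher-z CI and a p-value.

    rho is the Pearson correlation of mid-ranks.  ``method="t"`` uses the
    t-approximation with n-2 df; ``method="permutation"`` a seeded
    permutation test (for small n, where the approximation is crude).
    CI: tanh(atanh(rho) +/- z_{1-alpha/2} / sqrt(n-3)).
    """
    g = np.asarray(grade, float)
    s = np.asarray(instability, float)
    if g.shape != s.shape or g.ndim != 1:
        raise DegenerateInputError("grade and instability must be equal-length 1-D vectors")
    n = len(g)
    if n < 4:
        raise DegenerateInputError(f"Spearman needs n >= 4, got {n}")
    if np.ptp(g) == 0 or np.ptp(s) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    rg, rs = _midranks(g), _midranks(s)
    rho = float(np.corrcoef(rg, rs)[0, 1])

    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        sd_g, sd_s = rg.std(), rs.std()
        obs = abs(rho)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(rs)
            r = np.mean((rg - rg.mean()) * (perm - perm.mean())) / (sd_g * sd_s)
            if abs(r) >= obs - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    ci_low, ci_high = fisher_confidence_interval(rho, n, alpha)
    return CorrelationResult(
        classification="", rho=rho, ci_low=ci_low, ci_high=ci_high, p_value=p, n=n
    )
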