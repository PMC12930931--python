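"""Quadratic spline bases over infant age and data-driven knot selection.

The longitudinal mean model for weight-for-length uses a degree-2 B-spline
over age in months on the interval [0, 18], with interior knots placed where
a single population-mean fit has minimal residual sum of squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "bspline_basis", "basis_matrix", "select_knots"]


@dataclass(frozen=True)
class SplineSpec:
    """A quadratic spline specification over age.

    Parameters
    ----------
    knots
        Interior knot locations in months, strictly increasing, strictly
        inside the boundary interval.
    boundary
        Age interval covered by the basis (months). Ages outside are clamped
        with a warning when the design is built.
    """

    knots: tuple[float, ...] = (3.5, 9.0)
    boundary: tuple[float, float] = (0.0, 18.0)
    degree: int = field(default=2)

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        ks = tuple(float(k) for k in self.knots)
        if len(set(ks)) != len(ks):
            raise ValueError(f"duplicate interior knots: {ks}")
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError(f"knots must be strictly increasing: {ks}")
        if ks and (ks[0] <= lo or ks[-1] >= hi):
            raise ValueError(f"knots {ks} must lie strictly inside {self.boundary}")
        object.__setattr__(self, "knots", ks)

    @property
    def n_basis(self) -> int:
        """Number of design columns: degree + 1 + number of interior knots."""
        return self.degree + 1 + len(self.knots)

    @property
    def full_knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        d = self.degree
        return np.concatenate([[lo] * (d + 1), self.knots, [hi] * (d + 1)])


def _clamp_ages(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    lo, hi = spec.boundary
    ages = np.asarray(ages, dtype=float)
    if np.any(~np.isfinite(ages)):
        raise ValueError("non-finite ages in spline design")
    if np.any(ages < lo) or np.any(ages > hi):
        warnings.warn(
            f"ages outside boundary {spec.boundary} clamped", stacklevel=3
        )
        ages = np.clip(ages, lo, hi)
    return ages


def bspline_basis(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Raw normalized B-spline design (rows sum to one: partition of unity)."""
    ages = _clamp_ages(ages, spec)
    mat = BSpline.design_matrix(
        ages, spec.full_knot_vector, spec.degree, extrapolate=False
    ).toarray()
    return mat


def basis_matrix(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Spline design with an explicit intercept column.

    The first B-spline column is replaced by a constant column; because the
    normalized basis sums to one at every age, the column space is unchanged
    and contains the constant function, while the intercept becomes
    interpretable (the random-intercept structure attaches to it).
    Full column rank for at least ``spec.n_basis`` distinct ages.
    """
    raw = bspline_basis(ages, spec)
    out = raw.copy()
    out[:, 0] = 1.0
    return out


def select_knots(
    ages: np.ndarray,
    y: np.ndarray,
    n_knots: int = 2,
    grid: np.ndarray | None = None,
    boundary: tuple[float, float] = (0.0, 18.0),
) -> SplineSpec:
    """Pick interior knots minimizing the SSE of a population-mean spline fit.

    For each candidate knot tuple, a single one-class mean curve is fit to all
    (age, outcome) points by ordinary least squares and the residual sum of
    squares recorded; the tuple with minimal RSS wins, ties going to the
    lexicographically smallest tuple. Knot choice deliberately precedes any
    latent-class structure so that it cannot depend on the class count.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.size != y.size:
        raise ValueError("ages and y must have equal length")
    if ages.size < 20:
        raise ValueError("need at least 20 observations for knot selection")
    if grid is None:
        grid = np.arange(1.0, 15.0 + 1e-9, 0.5)
    grid = np.asarray(sorted(set(float(g) for g in grid)))
    if grid.size < n_knots:
        raise ValueError("candidate grid smaller than requested knot count")

    best: tuple[float, ...] | None = None
    best_rss = np.inf
    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    for cand in itertools.combinations(grid, n_knots):
        spec = SplineSpec(knots=cand, boundary=boundary)
        X = basis_matrix(ages, spec)
        _, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1] or rss.size == 0:
            coef = np.linalg.lstsq(X, y, rcond=None)[0]
            rss_val = float(np.sum((y - X @ coef) ** 2))
        else:
            rss_val = float(rss[0])
        # strict improvement beyond numerical noise keeps the first
        # (lexicographically smallest) of tied candidates
        if rss_val < best_rss - 1e-10 * scale:
            best_rss = rss_val
            best = cand
    assert best is not None
    return SplineSpec(knots=best, boundary=boundary)
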