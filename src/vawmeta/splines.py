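"""Natural cubic spline bases for age and time effects.

A natural cubic spline is a piecewise cubic polynomial that is linear
beyond its boundary knots (second derivative zero at and outside the
boundary).  With ``m`` knots in total (boundary + interior) the space has
dimension ``m``; dropping the intercept leaves ``m - 1`` basis columns, so
one interior knot gives K = 2 columns and two interior knots give K = 3.

The basis is built from the truncated-power representation
(d_k(x) = [(x − ξ_k)_+^3 − (x − ξ_m)_+^3] / (ξ_m − ξ_k)):

    N_1(x) = x,   N_{k+1}(x) = d_k(x) − d_{m−1}(x),  k = 1..m−2

Columns are centered at a reference point (age 30, or the time knot), so
the basis vanishes there and the hierarchical intercepts stay identified,
and each column is rescaled to unit maximum absolute value over its
evaluation grid so spline coefficients are O(1) regardless of the cubic
terms' raw magnitude (a pure linear reparametrization of the span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vaw_data import AGE_MIDPOINTS

#: candidate interior-knot sets explored for the age spline
AGE_KNOT_CANDIDATES = (
    (20,), (25,), (30,), (35,),
    (20, 35), (20, 40), (25, 35), (25, 40),
)
AGE_BOUNDARY = (15.0, 65.0)
AGE_CENTER = 30.0
#: ages above this are recoded down, so the age pattern is flat for 65+
AGE_CEILING = 65.0
DEFAULT_TIME_KNOT = 2011.0


def _ncs_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Non-intercept natural-cubic-spline basis at ``x`` for all ``knots``."""
    x = np.asarray(x, dtype=float)
    m = len(knots)
    if m < 3:
        # only boundary knots: the natural space is the linear polynomials
        return x[:, None] - 0.0

    def d(k):
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[k])

    d_last = d(m - 2)
    cols = [x] + [d(k) - d_last for k in range(m - 2)]
    return np.column_stack(cols)


@dataclass
class SplineBasis:
    """Evaluated natural-cubic-spline basis with its construction metadata."""

    kind: str                     # "age" or "time"
    knots: tuple                  # interior knot positions
    boundary: tuple               # (lower, upper) boundary knots
    grid: np.ndarray              # evaluation grid (ages or calendar years)
    matrix: np.ndarray            # (len(grid), K), centered and rescaled
    center: float
    col_scale: np.ndarray         # per-column rescaling factors

    @property
    def K(self) -> int:
        return self.matrix.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Basis rows at arbitrary points, with the same recoding, centering
        and column scaling as the stored matrix."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if self.kind == "age":
            x = np.minimum(x, AGE_CEILING)
        allk = np.concatenate(([self.boundary[0]], self.knots, [self.boundary[1]]))
        ref = _ncs_columns(np.array([self.center]), allk)
        return (_ncs_columns(x, allk) - ref) / self.col_scale


def _finalize(kind, knots, boundary, grid, center, eval_grid) -> SplineBasis:
    allk = np.concatenate(([boundary[0]], knots, [boundary[1]]))
    mat = _ncs_columns(eval_grid, allk) - _ncs_columns(np.array([center]), allk)
    scale = np.abs(mat).max(axis=0)
    scale[scale == 0] = 1.0
    return SplineBasis(kind, tuple(knots), tuple(boundary), grid, mat / scale,
                       center, scale)


def build_age_spline_basis(knot_set, boundary=AGE_BOUNDARY, center=AGE_CENTER) -> SplineBasis:
    """Age basis on the 5-year band midpoints, flat above 65, centered at 30."""
    knots = tuple(sorted(float(k) for k in np.atleast_1d(knot_set)))
    for k in knots:
        if not (boundary[0] <= k <= boundary[1]):
            raise ValueError(f"age knot {k} outside [{boundary[0]}, {boundary[1]}]")
    grid = np.minimum(AGE_MIDPOINTS, AGE_CEILING)
    return _finalize("age", knots, tuple(boundary), AGE_MIDPOINTS, center, grid)


def build_time_spline_basis(years, knot: float = DEFAULT_TIME_KNOT) -> SplineBasis:
    """Time basis over a range of calendar years, one interior knot (default 2011)."""
    years = np.asarray(sorted(years), dtype=float)
    boundary = (years[0], years[-1])
    if not (boundary[0] < knot < boundary[1]):
        raise ValueError(f"time knot {knot} outside the year range {boundary}")
    return _finalize("time", (knot,), boundary, years, knot, years)
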