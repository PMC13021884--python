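"""Dimension-reduction effect analysis of a fitted quadratic surface.

Fixing all but one or two factors at coded 0 yields single-factor and
two-factor sub-models whose coefficients are read directly off the
parent model.  The 1-D sub-models give per-factor dose-response curves
and their optima; the 2-D sub-models give interaction surfaces whose
stationary points partition the factor plane into four zones with a
definite response trend in each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import QuadraticModel

__all__ = [
    "SubModel1D",
    "SubModel2D",
    "StationaryPoint",
    "single_factor_submodel",
    "evaluate_1d",
    "submodel_extremum",
    "two_factor_submodel",
    "stationary_point",
    "zone_classification",
    "surface_grid",
    "truncate",
]


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero to a fixed number of decimals (no rounding)."""
    scale = 10.0**decimals
    return math.trunc(value * scale) / scale


@dataclass(frozen=True)
class SubModel1D:
    """Parent surface restricted to one factor, the others at coded 0."""

    factor: str
    index: int
    intercept: float
    linear: float
    quadratic: float

    def evaluate(self, level: float | np.ndarray):
        x = np.asarray(level, dtype=float)
        y = self.intercept + self.linear * x + self.quadratic * x**2
        return float(y) if y.ndim == 0 else y


@dataclass(frozen=True)
class SubModel2D:
    """Parent surface restricted to a factor pair, the others at coded 0."""

    factors: tuple[str, str]
    indices: tuple[int, int]
    intercept: float
    linear: tuple[float, float]
    quadratic: tuple[float, float]
    interaction: float

    def evaluate(self, xi: float | np.ndarray, xj: float | np.ndarray):
        a, b = np.asarray(xi, dtype=float), np.asarray(xj, dtype=float)
        y = (
            self.intercept
            + self.linear[0] * a + self.linear[1] * b
            + self.quadratic[0] * a**2 + self.quadratic[1] * b**2
            + self.interaction * a * b
        )
        return float(y) if y.ndim == 0 else y

    def gradient(self, xi: float, xj: float) -> np.ndarray:
        return np.array([
            self.linear[0] + 2 * self.quadratic[0] * xi + self.interaction * xj,
            self.linear[1] + 2 * self.quadratic[1] * xj + self.interaction * xi,
        ])

    def hessian(self) -> np.ndarray:
        return np.array([
            [2 * self.quadratic[0], self.interaction],
            [self.interaction, 2 * self.quadratic[1]],
        ])


@dataclass(frozen=True)
class StationaryPoint:
    """Critical point of a 2-D sub-model with its Hessian classification."""

    coordinates: tuple[float, float]
    response: float
    nature: str  # "maximum" | "minimum" | "saddle"


def single_factor_submodel(model: QuadraticModel, factor: int | str) -> SubModel1D:
    """Extract the 1-D sub-model of one factor (coefficients unchanged)."""
    i = model.factors.index(factor) if isinstance(factor, str) else int(factor)
    if not 0 <= i < model.k:
        raise IndexError(f"factor index {i} out of range for k={model.k}")
    return SubModel1D(
        factor=model.factors[i], index=i,
        intercept=model.intercept,
        linear=float(model.linear[i]),
        quadratic=float(model.quadratic[i]),
    )


def evaluate_1d(sub: SubModel1D, level: float | np.ndarray):
    return sub.evaluate(level)


def submodel_extremum(
    sub: SubModel1D, domain: tuple[float, float] = (-2.0, 2.0)
) -> tuple[float, float, bool]:
    """Maximizer of a 1-D sub-model on a closed coded interval.

    Returns ``(level, value, on_boundary)``.  The interior vertex
    ``-b / (2a)`` wins only when the parabola opens downward and the
    vertex lies inside the domain; otherwise the better endpoint is
    returned with the boundary flag set.
    """
    lo, hi = domain
    if lo >= hi:
        raise ValueError("domain must be a nondegenerate interval")
    if sub.quadratic == 0 and sub.linear == 0:
        raise ValueError("constant sub-model has no extremum")
    if sub.quadratic < 0:
        vertex = -sub.linear / (2.0 * sub.quadratic)
        if lo <= vertex <= hi:
            return vertex, sub.evaluate(vertex), False
    y_lo, y_hi = sub.evaluate(lo), sub.evaluate(hi)
    return (lo, y_lo, True) if y_lo >= y_hi else (hi, y_hi, True)


def two_factor_submodel(model: QuadraticModel, i: int | str, j: int | str) -> SubModel2D:
    """Extract the 2-D sub-model of a factor pair (coefficients unchanged)."""
    ii = model.factors.index(i) if isinstance(i, str) else int(i)
    jj = model.factors.index(j) if isinstance(j, str) else int(j)
    if ii == jj:
        raise ValueError("two_factor_submodel needs two distinct factors")
    return SubModel2D(
        factors=(model.factors[ii], model.factors[jj]),
        indices=(ii, jj),
        intercept=model.intercept,
        linear=(float(model.linear[ii]), float(model.linear[jj])),
        quadratic=(float(model.quadratic[ii]), float(model.quadratic[jj])),
        interaction=float(model.interaction[ii, jj]),
    )


def stationary_point(sub: SubModel2D, det_tol: float = 1e-9) -> StationaryPoint:
    """Solve the two partial-derivative equations of a 2-D sub-model.

    The gradient is linear, so the critical point is the exact solution
    of a 2x2 system; the Hessian's determinant and trace classify it as
    maximum, minimum or saddle.  A (near-)singular Hessian signals a
    degenerate ridge surface and raises.
    """
    H = sub.hessian()
    det = float(np.linalg.det(H))
    if abs(det) < det_tol:
        raise np.linalg.LinAlgError(
            "singular Hessian: the sub-model surface is a degenerate ridge"
        )
    xy = np.linalg.solve(H, -np.array(sub.linear))
    if det < 0:
        nature = "saddle"
    elif H[0, 0] < 0:
        nature = "maximum"
    else:
        nature = "minimum"
    return StationaryPoint(
        coordinates=(float(xy[0]), float(xy[1])),
        response=sub.evaluate(xy[0], xy[1]),
        nature=nature,
    )


def zone_classification(
    sub: SubModel2D,
    stationary: StationaryPoint,
    probe: Sequence[float],
    tol: float = 1e-12,
) -> dict:
    """Quadrant of a probe point relative to the stationary coordinates,
    with the response trend of raising each factor (the other held fixed).

    Trends come from the sign of the sub-model's partial derivatives at
    the probe: "+" means raising the factor raises the response, "-"
    means it lowers it, "0" a vanishing partial.
    """
    px, py = float(probe[0]), float(probe[1])
    sx, sy = stationary.coordinates
    on_boundary = abs(px - sx) <= tol or abs(py - sy) <= tol
    g = sub.gradient(px, py)

    def trend(v: float) -> str:
        if abs(v) <= tol:
            return "0"
        return "+" if v > 0 else "-"

    return {
        "zone": (
            ("low" if px < sx else "high"),
            ("low" if py < sy else "high"),
        ),
        "on_boundary": on_boundary,
        "trend": {sub.factors[0]: trend(g[0]), sub.factors[1]: trend(g[1])},
    }


def surface_grid(
    sub: SubModel2D, levels_i: Sequence[float], levels_j: Sequence[float]
) -> pd.DataFrame:
    """Sub-model predictions over the Cartesian product of level lists.

    Rows are labeled by the first factor's levels, columns by the
    second's — ready for contour or response-surface plotting.
    """
    li = np.asarray(list(levels_i), dtype=float)
    lj = np.asarray(list(levels_j), dtype=float)
    if li.size == 0 or lj.size == 0:
        raise ValueError("level lists must be nonempty")
    a, b = np.meshgrid(li, lj, indexing="ij")
    z = sub.evaluate(a, b)
    return pd.DataFrame(z, index=pd.Index(li, name=sub.factors[0]),
                        columns=pd.Index(lj, name=sub.factors[1]))
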