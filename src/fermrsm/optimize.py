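"""Exhaustive lattice optimization of a fitted response surface.

The optimizer enumerates every combination of per-factor coded levels
(e.g. five levels for four factors = 625 candidate media), predicts
each with the quadratic model, and returns the best scheme decoded into
actual medium amounts.  Exhaustive search over a small lattice is the
whole method here — it is exact on its lattice by construction and a
wet lab can only pipette a handful of levels anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np

from .design import FactorSpec
from .model import QuadraticModel

__all__ = ["OptimizationResult", "grid_search", "decode_optimum", "predict_at"]


@dataclass
class OptimizationResult:
    """Outcome of a lattice search over candidate media."""

    coded_optimum: tuple[float, ...]
    predicted_response: float
    n_candidates: int
    objective: str
    top: list[tuple[tuple[float, ...], float]]  # ranked (coded vector, prediction)

    def decoded(self, factors: Sequence[FactorSpec]) -> dict[str, float]:
        return decode_optimum(self, factors)


def grid_search(
    model: QuadraticModel,
    level_sets: Sequence[Sequence[float]],
    objective: str = "maximize",
    top_m: int = 10,
) -> OptimizationResult:
    """Best lattice point of the model over per-factor coded level sets.

    Ties on the predicted response are broken toward the
    lexicographically smallest coded vector, so the result does not
    depend on the enumeration order of the level sets.
    """
    if objective not in ("maximize", "minimize"):
        raise ValueError(f"objective must be 'maximize' or 'minimize', got {objective!r}")
    if len(level_sets) != model.k:
        raise ValueError(f"{len(level_sets)} level sets for a k={model.k} model")
    sets = [sorted(float(v) for v in s) for s in level_sets]
    if any(len(s) == 0 for s in sets):
        raise ValueError("every factor needs a nonempty level set")

    candidates = np.array(list(product(*sets)))
    values = model.evaluate(candidates)
    sign = -1.0 if objective == "maximize" else 1.0
    # candidates from product of sorted sets are already in lexicographic
    # order; a stable sort on the objective therefore breaks ties toward
    # the lexicographically smallest vector
    order = np.argsort(sign * values, kind="stable")
    ranked = [(tuple(candidates[i]), float(values[i])) for i in order[:top_m]]
    best_x, best_y = ranked[0]
    return OptimizationResult(
        coded_optimum=best_x,
        predicted_response=best_y,
        n_candidates=len(candidates),
        objective=objective,
        top=ranked,
    )


def decode_optimum(
    result: OptimizationResult, factors: Sequence[FactorSpec]
) -> dict[str, float]:
    """Translate the coded optimum into actual amounts per factor."""
    if len(factors) != len(result.coded_optimum):
        raise ValueError("factor count does not match optimum dimension")
    return {f.name: f.decode(c) for f, c in zip(factors, result.coded_optimum)}


def predict_at(
    model: QuadraticModel, coded: Sequence[float], clip_negative: bool = False
) -> float:
    """Model prediction at a coded point, optionally floored at zero.

    An inhibition-zone diameter cannot be negative, so callers reporting
    physical responses set ``clip_negative=True``.
    """
    y = float(model.evaluate(np.asarray(coded, dtype=float)))
    return max(y, 0.0) if clip_negative else y
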