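"""Central composite designs and coded/actual factor-level conversion.

Factor levels are handled in two parallel scales.  The *actual* scale is
the physical amount (e.g. g/L of peptone in the medium); the *coded*
scale is the dimensionless multiple of the factor spacing ``delta``
about the center level, so coded -2..2 spans the five design levels of a
rotatable four-factor design.  Fractional coded levels are legal
everywhere: optimization routinely lands off the design lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "decode_level",
    "encode_level",
    "rotatable_axial_distance",
    "generate_ccd",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor: name, center level and per-unit spacing.

    ``center`` is the actual amount at coded level 0 and ``delta`` the
    actual-scale increment corresponding to one coded unit, so the
    decoded level at coded ``c`` is ``center + c * delta``.
    """

    name: str
    center: float
    delta: float
    unit: str = "g/L"

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"factor {self.name!r}: delta must be > 0, got {self.delta}")
        if self.center - 2 * self.delta < 0:
            warnings.warn(
                f"factor {self.name!r}: decoded level at coded -2 is negative "
                f"({self.center - 2 * self.delta:g} {self.unit}); "
                "check center/delta for a concentration factor",
                stacklevel=2,
            )

    def decode(self, coded: float | np.ndarray) -> float | np.ndarray:
        return self.center + np.asarray(coded, dtype=float) * self.delta if isinstance(
            coded, (list, tuple, np.ndarray)
        ) else self.center + coded * self.delta

    def encode(self, actual: float | np.ndarray) -> float | np.ndarray:
        if isinstance(actual, (list, tuple, np.ndarray)):
            return (np.asarray(actual, dtype=float) - self.center) / self.delta
        return (actual - self.center) / self.delta


def decode_level(coded: float, factor: FactorSpec) -> float:
    """Actual amount at a coded level: ``center + coded * delta``."""
    return factor.decode(coded)


def encode_level(actual: float, factor: FactorSpec) -> float:
    """Coded level of an actual amount: ``(actual - center) / delta``."""
    return factor.encode(actual)


@dataclass
class DesignTable:
    """Runs of an experimental design in coded factor space.

    Parameters
    ----------
    factors
        Factor names, one per column of ``coded``.
    coded
        ``(n_runs, k)`` array of coded levels.
    response
        Optional length-``n_runs`` response vector (e.g. inhibition-zone
        diameter in mm).
    run_ids
        Optional run identifiers; defaults to 1..n.
    """

    factors: list[str]
    coded: np.ndarray
    response: np.ndarray | None = None
    run_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coded = np.atleast_2d(np.asarray(self.coded, dtype=float))
        if self.coded.shape[1] != len(self.factors):
            raise ValueError(
                f"coded matrix has {self.coded.shape[1]} columns for "
                f"{len(self.factors)} factors"
            )
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if self.response.shape != (self.n_runs,):
                raise ValueError("response length does not match number of runs")
        if not self.run_ids:
            self.run_ids = list(range(1, self.n_runs + 1))

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def k(self) -> int:
        return len(self.factors)

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs sharing an identical coded vector (replicates)."""
        seen: dict[tuple, list[int]] = {}
        for i, row in enumerate(self.coded):
            seen.setdefault(tuple(np.round(row, 12)), []).append(i)
        return [np.array(ix) for ix in seen.values()]

    def with_response(self, response: Sequence[float]) -> "DesignTable":
        return DesignTable(
            factors=list(self.factors),
            coded=self.coded.copy(),
            response=np.asarray(response, dtype=float),
            run_ids=list(self.run_ids),
        )

    def to_frame(self, factor_specs: Sequence[FactorSpec] | None = None) -> pd.DataFrame:
        """Tabular view: run_id, coded columns, optional actual columns, response."""
        data: dict[str, object] = {"run_id": self.run_ids}
        for j, name in enumerate(self.factors):
            data[f"{name}_coded"] = self.coded[:, j]
        if factor_specs is not None:
            if [f.name for f in factor_specs] != self.factors:
                raise ValueError("factor specs do not match design factors")
            for j, spec in enumerate(factor_specs):
                data[f"{spec.name}_actual"] = spec.center + self.coded[:, j] * spec.delta
        if self.response is not None:
            data["response"] = self.response
        return pd.DataFrame(data)


def rotatable_axial_distance(k: int) -> float:
    """Axial distance making a full-factorial-core CCD rotatable: (2^k)^(1/4)."""
    return float((2.0**k) ** 0.25)


def generate_ccd(
    factors: Sequence[FactorSpec] | Sequence[str],
    n_center: int = 1,
    axial_distance: float | str = "rotatable",
    randomize_seed: int | None = None,
) -> DesignTable:
    """Generate a central composite design in coded units.

    The design is the union of a full 2^k factorial at +/-1 (standard
    Yates order), 2k axis-aligned axial runs at ``+/-axial_distance``
    (paired by factor index), and ``n_center`` replicated center runs —
    ``2^k + 2k + n_center`` runs in total.  ``axial_distance="rotatable"``
    resolves to ``(2^k)^(1/4)``, which is 2 for four factors, so every
    non-center run then sits at coded radius 2.

    Run order is deterministic unless ``randomize_seed`` is given.
    """
    names = [f.name if isinstance(f, FactorSpec) else str(f) for f in factors]
    k = len(names)
    if k < 2:
        raise ValueError(f"a central composite design needs k >= 2 factors, got {k}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    alpha = rotatable_axial_distance(k) if axial_distance == "rotatable" else float(axial_distance)
    if alpha <= 0:
        raise ValueError("axial distance must be positive")

    factorial = np.array(list(product([-1.0, 1.0], repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -alpha
        axial[2 * j + 1, j] = alpha
    center = np.zeros((n_center, k))
    coded = np.vstack([factorial, axial, center])
    if randomize_seed is not None:
        rng = np.random.default_rng(randomize_seed)
        coded = coded[rng.permutation(coded.shape[0])]
    return DesignTable(factors=names, coded=coded)
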