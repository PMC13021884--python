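"""Synthetic data generators for every stage of the pipeline.

These emulate the data-generating situations the analysis modules are
built for: a central-composite response table arising from a known
quadratic surface plus homoscedastic Gaussian measurement noise, and
assay-level records (dual-culture diameters, spore counts, disease
grades) with the corresponding sampling distributions.  Every stochastic
call takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import DiseaseSurvey, DualCultureRecord, SporeGerminationRecord
from .design import DesignTable, generate_ccd
from .model import QuadraticModel

__all__ = [
    "SimulationSpec",
    "simulate_response_surface",
    "simulate_dual_culture",
    "simulate_spore_counts",
    "simulate_disease_grades",
]


@dataclass
class SimulationSpec:
    """A known quadratic surface plus the design and noise that sample it."""

    true_model: QuadraticModel
    n_center: int = 7
    axial_distance: float | str = "rotatable"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def simulate_response_surface(spec: SimulationSpec) -> DesignTable:
    """CCD response table: true-model evaluation plus N(0, sd^2) noise."""
    rng = np.random.default_rng(spec.seed)
    design = generate_ccd(
        spec.true_model.factors, n_center=spec.n_center,
        axial_distance=spec.axial_distance,
    )
    y = spec.true_model.evaluate(design.coded)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    return design.with_response(y)


def simulate_dual_culture(
    control_mean_mm: float,
    effect_fraction: float,
    sd_mm: float,
    n: int,
    seed: int,
    plug_mm: float = 4.0,
) -> list[DualCultureRecord]:
    """Paired control/treatment colony diameters for a dual-culture assay.

    Control diameters are Normal(control_mean, sd); the treatment colony
    grows the fraction ``1 - effect_fraction`` of the control's growth
    beyond the plug, plus noise, floored at the plug diameter — so at
    zero noise the per-plate inhibition rate is exactly
    ``effect_fraction * 100``.
    """
    if not 0 <= effect_fraction <= 1:
        raise ValueError("effect fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dc = np.maximum(rng.normal(control_mean_mm, sd_mm, n), plug_mm + 1e-9)
    dt = plug_mm + (1 - effect_fraction) * (dc - plug_mm) + rng.normal(0, sd_mm, n)
    dt = np.clip(dt, plug_mm, None)
    return [DualCultureRecord(c, t, plug_mm) for c, t in zip(dc, dt)]


def simulate_spore_counts(
    p_control: float,
    p_treated: float,
    n_spores: int,
    n_fields: int,
    seed: int,
) -> tuple[list[SporeGerminationRecord], list[SporeGerminationRecord]]:
    """Binomial germination counts per microscope field, control and treated."""
    for p in (p_control, p_treated):
        if not 0 <= p <= 1:
            raise ValueError("germination probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    control = [
        SporeGerminationRecord(int(g), n_spores, label="control")
        for g in rng.binomial(n_spores, p_control, n_fields)
    ]
    treated = [
        SporeGerminationRecord(int(g), n_spores, label="treated")
        for g in rng.binomial(n_spores, p_treated, n_fields)
    ]
    return control, treated


def simulate_disease_grades(
    grade_probabilities: "np.ndarray | list[float]",
    n_plants: int,
    seed: int,
    max_grade: int = 6,
) -> DiseaseSurvey:
    """Multinomial plant counts over the 0..max_grade severity scale."""
    p = np.asarray(grade_probabilities, dtype=float)
    if p.shape != (max_grade + 1,):
        raise ValueError(f"need {max_grade + 1} grade probabilities")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("grade probabilities must be a simplex vector")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_plants, p)
    return DiseaseSurvey({g: int(c) for g, c in enumerate(counts)}, max_grade=max_grade)
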