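"""Bioassay scoring formulas and group-comparison statistics.

Covers the standard screening metrics for a biocontrol strain:

* dual-culture antagonism — inhibition rate from control vs treatment
  colony diameters, corrected for the inoculum plug;
* spore-germination rate and its relative inhibition vs control;
* plant-disease severity index on a 0..6 wilt grading scale and the
  control effect (relative disease-index reduction vs untreated);
* growth increments;
* one-way ANOVA and Duncan's multiple range test, which produce the
  letter codes used to annotate assay result tables.

All percentages are carried at full precision; rounding to the two
decimals conventional in result tables is left to the caller.
"""

from __future__ import annotations

import math
import warnings
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DualCultureRecord",
    "SporeGerminationRecord",
    "DiseaseSurvey",
    "GroupedMeasurements",
    "AnovaSummary",
    "inhibition_rate",
    "spore_germination_rate",
    "spore_inhibition_rate",
    "disease_index",
    "control_effect",
    "growth_increment",
    "one_way_anova",
    "duncan_groups",
]

MIN_RECOMMENDED_SPORES = 300


@dataclass(frozen=True)
class DualCultureRecord:
    """Colony diameters (mm) from one dual-culture confrontation plate.

    ``plug_diameter`` is the diameter of the inoculum disc; colony
    growth is measured beyond it, hence the ``Dc - plug`` denominator
    in the inhibition rate.
    """

    control_diameter: float
    treatment_diameter: float
    plug_diameter: float = 4.0

    def __post_init__(self) -> None:
        if self.plug_diameter <= 0:
            raise ValueError("plug diameter must be positive")
        if self.control_diameter < self.plug_diameter:
            raise ValueError(
                f"control diameter {self.control_diameter} mm below plug "
                f"({self.plug_diameter} mm)"
            )
        if self.treatment_diameter < self.plug_diameter:
            raise ValueError(
                f"treatment diameter {self.treatment_diameter} mm below plug "
                f"({self.plug_diameter} mm)"
            )


@dataclass(frozen=True)
class SporeGerminationRecord:
    germinated: int
    total: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("spore total must be positive")
        if not 0 <= self.germinated <= self.total:
            raise ValueError(
                f"germinated count {self.germinated} outside [0, {self.total}]"
            )
        if self.total < MIN_RECOMMENDED_SPORES:
            warnings.warn(
                f"only {self.total} spores counted; at least "
                f"{MIN_RECOMMENDED_SPORES} are recommended for a stable rate",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DiseaseSurvey:
    """Plant counts per disease grade, 0 (healthy) .. max_grade (dead)."""

    grade_counts: Mapping[int, int]
    max_grade: int = 6

    def __post_init__(self) -> None:
        counts = dict(self.grade_counts)
        if any(c < 0 for c in counts.values()):
            raise ValueError("grade counts must be nonnegative")
        bad = [g for g in counts if not 0 <= g <= self.max_grade]
        if bad:
            raise ValueError(
                f"grades {bad} outside the 0..{self.max_grade} grading scale"
            )
        if sum(counts.values()) == 0:
            raise ValueError("survey contains no plants")
        object.__setattr__(self, "grade_counts", counts)

    @property
    def n_plants(self) -> int:
        return sum(self.grade_counts.values())


@dataclass
class GroupedMeasurements:
    """Replicate measurements per treatment group (OD readings, weights...)."""

    groups: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        self.groups = {str(k): np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups to compare")
        for label, vals in self.groups.items():
            if len(vals) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 replicates")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)


# ---------------------------------------------------------------------------
# scoring formulas


def inhibition_rate(record: DualCultureRecord) -> float:
    """Mycelial growth inhibition (%): (Dc - Dt) / (Dc - plug) * 100.

    Negative values (treatment colony larger than control) are returned
    as-is with a warning rather than clipped.
    """
    denom = record.control_diameter - record.plug_diameter
    if denom <= 0:
        raise ValueError(
            "degenerate control: control colony did not grow beyond the plug"
        )
    rate = (record.control_diameter - record.treatment_diameter) / denom * 100.0
    if rate < 0:
        warnings.warn("treatment colony larger than control: negative inhibition rate",
                      stacklevel=2)
    return rate


def spore_germination_rate(record: SporeGerminationRecord) -> float:
    """Germinated / total * 100, in [0, 100]."""
    return record.germinated / record.total * 100.0


def spore_inhibition_rate(sgr_control: float, sgr_treated: float) -> float:
    """Relative germination reduction (%): (SGRck - SGRtr) / SGRck * 100."""
    if sgr_control <= 0:
        raise ValueError("control germination rate must be positive")
    return (sgr_control - sgr_treated) / sgr_control * 100.0


def disease_index(survey: DiseaseSurvey) -> float:
    """Severity index (%): sum(count_g * g) / (N * max_grade) * 100."""
    weighted = sum(count * grade for grade, count in survey.grade_counts.items())
    return weighted / (survey.n_plants * survey.max_grade) * 100.0


def control_effect(di_control: float, di_treated: float) -> float:
    """Relative disease-index reduction (%): (DIck - DItr) / DIck * 100."""
    if di_control <= 0:
        raise ValueError("control disease index must be positive")
    return (di_control - di_treated) / di_control * 100.0


def growth_increment(before: float, after: float) -> float:
    """Growth over the observation window: after - before (negative allowed)."""
    inc = after - before
    if inc < 0:
        warnings.warn("negative growth increment", stacklevel=2)
    return inc


# ---------------------------------------------------------------------------
# one-way ANOVA and Duncan's multiple range test


@dataclass
class AnovaSummary:
    ss_between: float
    df_between: int
    ss_within: float
    df_within: int
    f_statistic: float
    p_value: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def one_way_anova(measurements: GroupedMeasurements) -> AnovaSummary:
    """Fixed-effects one-way ANOVA decomposition of grouped replicates.

    When every observation is identical the F statistic is reported as
    0 with p = 1 (no variance to partition).
    """
    values = list(measurements.groups.values())
    grand = np.concatenate(values)
    grand_mean = grand.mean()
    ss_between = float(sum(len(v) * (v.mean() - grand_mean) ** 2 for v in values))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_between = len(values) - 1
    df_within = len(grand) - len(values)
    if df_within == 0:
        raise ValueError("no within-group degrees of freedom")
    ms_within = ss_within / df_within
    if ss_between + ss_within == 0:
        return AnovaSummary(0.0, df_between, 0.0, df_within, 0.0, 1.0)
    if ms_within == 0:
        return AnovaSummary(ss_between, df_between, 0.0, df_within, math.inf, 0.0)
    f = (ss_between / df_between) / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaSummary(ss_between, df_between, ss_within, df_within, f, p)


@lru_cache(maxsize=4096)
def _duncan_quantile(alpha: float, span: int, df_error: int) -> float:
    # studentized-range ppf is a slow numerical inversion; memoize it
    return float(stats.studentized_range.ppf((1 - alpha) ** (span - 1), span, df_error))


def duncan_critical_range(alpha: float, span: int, df_error: int,
                          ms_error: float, n_per_group: float) -> float:
    """Least significant range for a comparison spanning ``span`` ordered means.

    Duncan's protection level for span r is 1 - (1 - alpha)^(r - 1), so
    the critical value is the studentized-range quantile at cumulative
    probability (1 - alpha)^(r - 1) with ``span`` means and the ANOVA
    error df, scaled by the standard error sqrt(MS_error / n).
    """
    if ms_error == 0:
        return 0.0
    q = _duncan_quantile(alpha, span, df_error)
    return q * math.sqrt(ms_error / n_per_group)


def duncan_groups(measurements: GroupedMeasurements, alpha: float = 0.05) -> dict[str, str]:
    """Letter codes from Duncan's multiple range test.

    Means are sorted descending (ties kept in input order) and compared
    stepwise: the range of every stretch of r consecutive ordered means
    is tested against the span-r least significant range, largest spans
    first, and any stretch inside a nonsignificant stretch is declared
    nonsignificant without testing.  Maximal nonsignificant stretches
    then become the shared letters — groups sharing a letter are not
    significantly different at ``alpha``.  Unequal group sizes use the
    harmonic mean size.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    summary = one_way_anova(measurements)
    labels = measurements.labels
    means = np.array([measurements.groups[g].mean() for g in labels])
    order = np.argsort(-means, kind="stable")
    k = len(labels)
    sizes = [len(measurements.groups[g]) for g in labels]
    n_h = len(sizes) / sum(1.0 / n for n in sizes)
    ms_err, df_err = summary.ms_within, summary.df_within

    sorted_means = means[order]
    tol = 1e-12 * max(1.0, float(np.abs(sorted_means).max()))
    nonsig_intervals: list[tuple[int, int]] = []

    def covered(i: int, j: int) -> bool:
        return any(a <= i and j <= b for a, b in nonsig_intervals)

    for span in range(k, 1, -1):
        lsr = duncan_critical_range(alpha, span, df_err, ms_err, n_h)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if covered(i, j):
                continue
            if sorted_means[i] - sorted_means[j] <= lsr + tol:
                nonsig_intervals.append((i, j))

    # maximal nonsignificant stretches plus singletons for lone groups
    intervals = [iv for iv in nonsig_intervals
                 if not any(iv != other and other[0] <= iv[0] and iv[1] <= other[1]
                            for other in nonsig_intervals)]
    for i in range(k):
        if not any(a <= i <= b for a, b in intervals):
            intervals.append((i, i))
    intervals.sort()

    letters = "abcdefghijklmnopqrstuvwxyz"
    assignment: dict[int, str] = {i: "" for i in range(k)}
    for letter, (a, b) in zip(letters, intervals):
        for i in range(a, b + 1):
            assignment[i] += letter
    if len(intervals) > len(letters):
        raise ValueError("more letter groups than available letters")

    return {labels[order[i]]: assignment[i] for i in range(k)}
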