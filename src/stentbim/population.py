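"""Annual treated-cohort construction.

The national cohort of newly stented patients per model year is built either
from a multiplicative "funnel" (national population × prevalence/eligibility
fractions × endovascular-procedure eligibility × drug-eluting-stent use rate,
then compounded by an annual procedure growth rate) or from an explicitly
supplied per-year schedule.  All cohort arithmetic is kept unrounded; rounding
is strictly a display concern handled by :mod:`stentbim.reporting`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "FunnelStage",
    "FunnelSpec",
    "ExplicitCohorts",
    "PopulationSpec",
    "CohortSchedule",
    "apply_funnel",
    "build_cohort_schedule",
    "build_schedule_from_spec",
    "scale_schedule",
]


class FunnelStage(BaseModel):
    """One multiplicative stage of the population funnel (e.g. a prevalence)."""

    model_config = ConfigDict(extra="forbid")

    label: str
    fraction: float = Field(ge=0.0, le=1.0)


class FunnelSpec(BaseModel):
    """Funnel-based cohort definition.

    ``base_population`` is reduced by every ``stages`` fraction, then by the
    endovascular-procedure (EVP) eligibility rate and the drug-eluting-stent
    (DES) use rate, yielding the first-year treated cohort; subsequent years
    grow multiplicatively by ``growth_rate``.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["funnel"] = "funnel"
    base_population: float = Field(ge=0.0)
    stages: list[FunnelStage] = Field(default_factory=list)
    evp_eligibility: float = Field(default=0.80, ge=0.0, le=1.0)
    des_use_rate: float = Field(default=0.28, ge=0.0, le=1.0)
    growth_rate: float = Field(default=0.068, gt=-1.0)


class ExplicitCohorts(BaseModel):
    """Explicit per-year cohort sizes overriding the funnel.

    The base EVP-eligibility and DES-use rates are retained as metadata so
    scenario sweeps can rescale the schedule by ``new_rate / base_rate``.
    """

    model_config = ConfigDict(extra="forbid")

    kind: Literal["explicit"] = "explicit"
    cohorts: list[float]
    evp_eligibility: float = Field(default=0.80, ge=0.0, le=1.0)
    des_use_rate: float = Field(default=0.28, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _non_negative(self) -> "ExplicitCohorts":
        if any(c < 0 for c in self.cohorts):
            raise ValueError("cohort sizes must be non-negative")
        return self


PopulationSpec = Union[FunnelSpec, ExplicitCohorts]


@dataclass(frozen=True)
class CohortSchedule:
    """Unrounded number of newly treated patients per model year."""

    N: np.ndarray
    year_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        N = np.asarray(self.N, dtype=float)
        if N.ndim != 1:
            raise ValueError("cohort schedule must be one-dimensional")
        if np.any(N < 0):
            raise ValueError("cohort sizes must be non-negative")
        object.__setattr__(self, "N", N)
        labels = self.year_labels
        if labels is None:
            labels = np.arange(N.size)
        labels = np.asarray(labels, dtype=int)
        if labels.size != N.size:
            raise ValueError("year_labels length must match schedule length")
        object.__setattr__(self, "year_labels", labels)

    @property
    def n_years(self) -> int:
        return int(self.N.size)

    @property
    def total(self) -> float:
        """Unrounded total treated patients across the horizon."""
        return float(self.N.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortSchedule):
            return NotImplemented
        return np.array_equal(self.N, other.N) and np.array_equal(
            self.year_labels, other.year_labels
        )


def apply_funnel(spec: FunnelSpec) -> float:
    """First-year treated cohort from the multiplicative funnel, unrounded."""
    count = float(spec.base_population)
    for stage in spec.stages:
        count *= stage.fraction
    count *= spec.evp_eligibility * spec.des_use_rate
    return count


def build_cohort_schedule(
    year0: float,
    growth_rate: float,
    n_years: int,
    start_year: Optional[int] = None,
) -> CohortSchedule:
    """Compound ``year0`` by ``(1 + growth_rate)**t`` for ``n_years`` years."""
    if year0 < 0:
        raise ValueError("year0 must be non-negative")
    if growth_rate <= -1.0:
        raise ValueError("growth_rate must be greater than -1")
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    t = np.arange(n_years, dtype=float)
    N = year0 * (1.0 + growth_rate) ** t
    labels = None
    if start_year is not None:
        labels = start_year + np.arange(n_years)
    return CohortSchedule(N=N, year_labels=labels)


def build_schedule_from_spec(
    population: PopulationSpec, n_years: int, start_year: Optional[int] = None
) -> CohortSchedule:
    """Materialise a :class:`CohortSchedule` from either population spec."""
    labels = None if start_year is None else start_year + np.arange(n_years)
    if isinstance(population, ExplicitCohorts):
        if len(population.cohorts) != n_years:
            raise ValueError(
                f"explicit cohort schedule has {len(population.cohorts)} entries "
                f"but the model horizon is {n_years} years"
            )
        return CohortSchedule(N=np.asarray(population.cohorts, float), year_labels=labels)
    year0 = apply_funnel(population)
    return build_cohort_schedule(year0, population.growth_rate, n_years, start_year)


def scale_schedule(schedule: CohortSchedule, factor: float) -> CohortSchedule:
    """Multiply every yearly cohort by ``factor`` (scenario rescaling).

    Because every downstream quantity is homogeneous of degree 1 in the
    cohort schedule, rescaling by ``new_rate / base_rate`` is exactly
    equivalent to re-running the funnel with the changed rate.
    """
    if factor < 0:
        raise ValueError("scale factor must be non-negative")
    return CohortSchedule(N=schedule.N * factor, year_labels=schedule.year_labels)
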