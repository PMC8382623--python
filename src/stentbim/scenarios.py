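"""Full pipeline driver, one-way scenario sweeps and state disaggregation.

Every model output is homogeneous of degree 1 in the cohort schedule, so
population scenarios (endovascular-procedure eligibility, drug-eluting-stent
use rate) are expressed as a multiplicative rescaling of the base schedule by
``new_rate / base_rate`` — provably identical to re-running the funnel with
the changed rate.  The same linearity drives the state/territory
disaggregation: each state receives its share of every national quantity.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .costing import BudgetImpactResult, budget_impact, cost_arm
from .events import project_events
from .parameters import ModelConfig
from .population import build_schedule_from_spec, scale_schedule

__all__ = [
    "ScenarioSpec",
    "StatePartition",
    "run_model",
    "run_scenario",
    "sweep",
    "disaggregate",
]


def run_model(
    config: ModelConfig,
    mode: Optional[str] = None,
    cohort_factor: float = 1.0,
) -> BudgetImpactResult:
    """Population funnel → event projection → costing → budget impact."""
    mode = mode or config.second_cycle_mode
    schedule = build_schedule_from_spec(
        config.population, config.n_years, config.start_year
    )
    if cohort_factor != 1.0:
        schedule = scale_schedule(schedule, cohort_factor)
    tables = []
    for arm in (config.arm_a, config.arm_b):
        proj = project_events(schedule, arm, mode)
        tables.append(cost_arm(proj, arm, config.costs))
    result = budget_impact(tables[0], tables[1])
    return replace(result, year_labels=np.asarray(schedule.year_labels))


class ScenarioSpec(BaseModel):
    """Sparse override set for one sensitivity scenario.

    Unset fields keep the base-case value.  Population overrides
    (``evp_eligibility``, ``des_use_rate``) act through schedule rescaling;
    ``stent_price_multiplier`` applies to both arms' stent prices;
    ``cohort_factor`` is an explicit extra multiplier on the schedule.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    evp_eligibility: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    des_use_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    stent_price_multiplier: Optional[float] = Field(default=None, gt=0.0)
    bed_day_cost_multiplier: Optional[float] = Field(default=None, gt=0.0)
    cohort_factor: float = Field(default=1.0, ge=0.0)


def _check_bounds(config: ModelConfig, spec: ScenarioSpec) -> None:
    ranges = config.scenario_ranges
    if not ranges.enforce_bounds:
        return
    checks = [
        ("evp_eligibility", spec.evp_eligibility, ranges.evp_eligibility),
        ("des_use_rate", spec.des_use_rate, ranges.des_use_rate),
        ("stent_price_multiplier", spec.stent_price_multiplier, ranges.stent_price_multiplier),
        ("bed_day_cost_multiplier", spec.bed_day_cost_multiplier, ranges.bed_day_cost_multiplier),
    ]
    for name, value, (lo, hi) in checks:
        if value is not None and not lo <= value <= hi:
            raise ValueError(
                f"scenario {spec.name!r}: {name}={value} outside the configured "
                f"bound [{lo}, {hi}]"
            )


def run_scenario(config: ModelConfig, spec: ScenarioSpec) -> BudgetImpactResult:
    """Apply a scenario's overrides and rerun the full pipeline."""
    _check_bounds(config, spec)
    pop = config.population
    factor = spec.cohort_factor
    if spec.evp_eligibility is not None:
        if pop.evp_eligibility == 0:
            raise ValueError("base EVP eligibility is zero; cannot rescale")
        factor *= spec.evp_eligibility / pop.evp_eligibility
    if spec.des_use_rate is not None:
        if pop.des_use_rate == 0:
            raise ValueError("base DES use rate is zero; cannot rescale")
        factor *= spec.des_use_rate / pop.des_use_rate

    updates: dict = {}
    if spec.stent_price_multiplier is not None:
        updates["arm_a"] = config.arm_a.model_copy(
            update={"stent_price": config.arm_a.stent_price * spec.stent_price_multiplier}
        )
        updates["arm_b"] = config.arm_b.model_copy(
            update={"stent_price": config.arm_b.stent_price * spec.stent_price_multiplier}
        )
    if spec.bed_day_cost_multiplier is not None:
        updates["costs"] = config.costs.model_copy(
            update={"c_bed_day": config.costs.c_bed_day * spec.bed_day_cost_multiplier}
        )
    if updates:
        config = config.model_copy(update=updates)
    return run_model(config, cohort_factor=factor)


def sweep(config: ModelConfig, specs: Sequence[ScenarioSpec]) -> pd.DataFrame:
    """Run a list of scenarios and tabulate horizon totals plus deltas vs base.

    Returns one row per scenario with the total treated population, TLRs
    avoided, bed-days averted and both savings totals (unrounded), ready for
    a tornado-style report.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("scenario names must be unique")
    base = run_model(config).totals()
    rows = []
    for spec in specs:
        totals = run_scenario(config, spec).totals()
        row = {"scenario": spec.name, **totals}
        row["delta_healthcare_savings"] = totals["healthcare_savings"] - base["healthcare_savings"]
        row["delta_hospital_savings"] = totals["hospital_savings"] - base["hospital_savings"]
        rows.append(row)
    columns = [
        "scenario",
        "patients",
        "tlr_avoided",
        "days_averted",
        "healthcare_savings",
        "hospital_savings",
        "delta_healthcare_savings",
        "delta_hospital_savings",
    ]
    return pd.DataFrame(rows, columns=columns)


class StatePartition(BaseModel):
    """State/territory shares of the national treated cohort.

    Shares need not total 1: the published state cohorts leave about 1.6% of
    the national cohort unallocated.
    """

    model_config = ConfigDict(extra="forbid")

    shares: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "StatePartition":
        for state, share in self.shares.items():
            if not 0.0 <= share <= 1.0:
                raise ValueError(f"share for {state!r} must be in [0, 1]")
        if sum(self.shares.values()) > 1.0 + 1e-9:
            raise ValueError("shares must sum to at most 1")
        return self


def disaggregate(
    national: BudgetImpactResult,
    partition: StatePartition,
    states: Optional[Sequence[str]] = None,
) -> dict[str, BudgetImpactResult]:
    """Scale the national result down to each state by its cohort share."""
    if states is None:
        states = list(partition.shares)
    results: dict[str, BudgetImpactResult] = {}
    for state in states:
        if state not in partition.shares:
            raise KeyError(f"unknown state label {state!r}")
        results[state] = national.scaled(partition.shares[state])
    return results
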