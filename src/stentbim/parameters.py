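"""Typed model configuration: arm-level clinical inputs, unit costs, horizon.

One :class:`ModelConfig` is one complete budget impact model: two stent arms
(comparator and intervention) with their trial-derived event rates, a unit
cost schedule, a population definition, the projection convention and the
sensitivity-analysis bounds.  Configs serialise to a strict YAML schema; the
shipped ``imperial_au_2019`` fixture encodes the Australian 2019 base case
built on the 12- and 24-month outcomes of the IMPERIAL randomised trial
(Eluvia drug-eluting stent vs Zilver PTX drug-coated stent).
"""

from __future__ import annotations

from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .population import ExplicitCohorts, FunnelSpec

__all__ = [
    "ArmParameters",
    "CostSchedule",
    "ScenarioRanges",
    "ModelConfig",
    "default_imperial_config",
    "load_config",
    "save_config",
    "fixture_path",
]

_MIX_TOL = 1e-9

SecondCycleMode = Literal["cumulative_recount", "incremental"]

# Published base-case per-year hospital-system costs (AUD) for the first two
# model years, used to back-solve the per-patient bed-day intensities h12/h24
# (cost cells carry more significant digits than the rounded day counts).
_CALIBRATION_HOSPITAL_COSTS_AUD = {
    "Zilver PTX": (14_184_422.0, 46_724_823.0),
    "Eluvia": (6_134_905.0, 31_964_449.0),
}
_CALIBRATION_COHORTS = (5674.0, 6060.0)

# National treated-cohort row of the published base case, Year 0..Year 5.
_BASE_CASE_COHORTS = [5674.0, 6060.0, 6474.0, 6915.0, 7386.0, 7890.0]

# State/territory treated cohorts at the 28% DES-use upper bound; shares are
# these counts divided by the national 40,399 total (they sum to 39,761 —
# about 1.6% of the national cohort is unallocated in the source).
_STATE_COHORTS_28PCT = {
    "NSW & ACT": 13_377.0,
    "VIC": 10_220.0,
    "SA": 2_787.0,
    "WA": 4_164.0,
    "NT": 399.0,
    "QLD": 7_969.0,
    "TAS": 845.0,
}


class ArmParameters(BaseModel):
    """Clinical rates, procedure mix and resource intensities for one stent arm.

    Rates are cumulative fractions of the treated cohort: ``r12``/``r24`` are
    the 12- and 24-month clinically driven target-lesion-revascularisation
    (CD-TLR) rates, ``a12``/``a24`` the major-amputation rates.  ``m*_perc`` /
    ``m*_open`` split TLRs between percutaneous and open surgical procedures
    per cycle.  ``h12``/``h24`` are adverse-event hospital bed-days per treated
    patient charged in the first and second model cycle respectively.
    """

    model_config = ConfigDict(extra="forbid")

    arm_name: str
    r12: float = Field(ge=0.0, le=1.0)
    r24: float = Field(ge=0.0, le=1.0)
    m12_perc: float = Field(ge=0.0, le=1.0)
    m12_open: float = Field(ge=0.0, le=1.0)
    m24_perc: float = Field(ge=0.0, le=1.0)
    m24_open: float = Field(ge=0.0, le=1.0)
    a12: float = Field(ge=0.0, le=1.0)
    a24: float = Field(ge=0.0, le=1.0)
    h12: float = Field(ge=0.0)
    h24: float = Field(ge=0.0)
    stent_price: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _mixes_sum_to_one(self) -> "ArmParameters":
        if abs(self.m12_perc + self.m12_open - 1.0) > _MIX_TOL:
            raise ValueError("12-month procedure mix must sum to 1")
        if abs(self.m24_perc + self.m24_open - 1.0) > _MIX_TOL:
            raise ValueError("24-month procedure mix must sum to 1")
        return self


class CostSchedule(BaseModel):
    """Unit costs in AUD.

    ``c_primary`` is the activity-based payment for the index stenting episode
    excluding the stent itself.  It is not separately published for the base
    case (the source DRG weight is unavailable), so it defaults to the
    percutaneous-intervention DRG payment and is flagged non-calibrated; it
    cancels exactly in every between-arm difference.
    """

    model_config = ConfigDict(extra="forbid")

    c_percutaneous: float = Field(ge=0.0)
    c_open: float = Field(ge=0.0)
    c_amputation: float = Field(ge=0.0)
    c_bed_day: float = Field(ge=0.0)
    c_primary: float = Field(default=5495.0, ge=0.0)
    c_primary_calibrated: bool = False


class ScenarioRanges(BaseModel):
    """Bounds for the one-way sensitivity analysis (inclusive)."""

    model_config = ConfigDict(extra="forbid")

    evp_eligibility: tuple[float, float] = (0.70, 0.99)
    des_use_rate: tuple[float, float] = (0.10, 0.40)
    stent_price_multiplier: tuple[float, float] = (0.90, 1.10)
    bed_day_cost_multiplier: tuple[float, float] = (0.90, 1.10)
    enforce_bounds: bool = True


class ModelConfig(BaseModel):
    """One complete two-arm budget impact model."""

    model_config = ConfigDict(extra="forbid")

    arm_a: ArmParameters  # comparator (Zilver PTX)
    arm_b: ArmParameters  # intervention (Eluvia)
    costs: CostSchedule
    population: Annotated[
        Union[FunnelSpec, ExplicitCohorts], Field(discriminator="kind")
    ]
    n_years: int = Field(default=6, ge=1)
    start_year: int = 2019
    second_cycle_mode: SecondCycleMode = "cumulative_recount"
    rounding: Literal["half_up_display"] = "half_up_display"
    state_shares: Optional[dict[str, float]] = None
    scenario_ranges: ScenarioRanges = Field(default_factory=ScenarioRanges)

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        for arm in (self.arm_a, self.arm_b):
            if arm.r24 < arm.r12:
                raise ValueError(
                    f"{arm.arm_name}: cumulative 24-month TLR rate r24 ({arm.r24}) "
                    f"must not be below the 12-month rate r12 ({arm.r12})"
                )
            if arm.a24 < arm.a12:
                raise ValueError(
                    f"{arm.arm_name}: cumulative 24-month amputation rate a24 "
                    "must not be below the 12-month rate a12"
                )
        if self.state_shares is not None:
            for state, share in self.state_shares.items():
                if not 0.0 <= share <= 1.0:
                    raise ValueError(f"state share for {state!r} must be in [0, 1]")
            if sum(self.state_shares.values()) > 1.0 + 1e-9:
                raise ValueError("state shares must sum to at most 1")
        return self


def default_imperial_config() -> ModelConfig:
    """The Australian 2019 base case.

    12-month event rates are the exact trial fractions (13/287, 13/145,
    1/287, 0/145); 24-month cumulative rates are the published one-decimal
    percentages (12.7%, 20.1%, 1.5%, 0.7%) — the mixed convention that
    regenerates the published projection cell-by-cell.  Bed-day intensities
    are back-solved from the first two years of published hospital-system
    costs divided by the per-diem.  Stent prices are equal in both arms
    (published price difference: $0), so they cancel in all differences.
    """
    from .events import calibrate_day_intensities

    c_bed_day = 2003.0
    n0, n1 = _CALIBRATION_COHORTS
    intensities = {
        name: calibrate_day_intensities(n0, n1, d0 / c_bed_day, d1 / c_bed_day)
        for name, (d0, d1) in _CALIBRATION_HOSPITAL_COSTS_AUD.items()
    }

    zilver = ArmParameters(
        arm_name="Zilver PTX",
        r12=13 / 145,
        r24=0.201,
        m12_perc=0.96,
        m12_open=0.04,
        m24_perc=0.971,
        m24_open=0.029,
        a12=0 / 145,
        a24=0.007,
        h12=intensities["Zilver PTX"][0],
        h24=intensities["Zilver PTX"][1],
        stent_price=0.0,
    )
    eluvia = ArmParameters(
        arm_name="Eluvia",
        r12=13 / 287,
        r24=0.127,
        m12_perc=0.967,
        m12_open=0.033,
        m24_perc=0.957,
        m24_open=0.043,
        a12=1 / 287,
        a24=0.015,
        h12=intensities["Eluvia"][0],
        h24=intensities["Eluvia"][1],
        stent_price=0.0,
    )
    costs = CostSchedule(
        c_percutaneous=5495.0,
        c_open=16411.0,
        c_amputation=35354.0,
        c_bed_day=c_bed_day,
        c_primary=5495.0,
        c_primary_calibrated=False,
    )
    national_total = sum(_BASE_CASE_COHORTS)
    shares = {s: n / national_total for s, n in _STATE_COHORTS_28PCT.items()}
    return ModelConfig(
        arm_a=zilver,
        arm_b=eluvia,
        costs=costs,
        population=ExplicitCohorts(
            cohorts=list(_BASE_CASE_COHORTS), evp_eligibility=0.80, des_use_rate=0.28
        ),
        n_years=6,
        start_year=2019,
        second_cycle_mode="cumulative_recount",
        state_shares=shares,
    )


def load_config(path: str | Path) -> ModelConfig:
    """Read and validate a YAML model configuration.

    Unknown keys are rejected; every type invariant is enforced on load.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML such that ``load_config`` round-trips it."""
    payload = config.model_dump(mode="python")
    text = yaml.safe_dump(payload, sort_keys=False, default_flow_style=False)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def fixture_path() -> Path:
    """Path of the shipped ``imperial_au_2019`` base-case fixture."""
    return Path(__file__).parent / "data" / "imperial_au_2019.yaml"
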