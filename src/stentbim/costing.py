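"""Dual-perspective costing and between-arm budget impact.

Two payer perspectives are costed.  The *healthcare system* (activity-based
funding) perspective prices the index procedure and every projected adverse
event at its DRG payment; the *hospital* perspective prices adverse-event
bed-days at the national weighted average per-diem, capturing length-of-stay
savings that activity-based payments do not.  The budget impact is the
element-wise difference between an all-comparator and an all-intervention
scenario.  All arithmetic is unrounded; display rounding happens only in
:mod:`stentbim.reporting`.

The absolute healthcare-system cost levels depend on the non-calibrated index
procedure payment ``c_primary`` and are therefore approximate; ``c_primary``
and any equal stent price cancel exactly in the between-arm differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .events import ArmProjection, split_tlr_by_procedure

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import ArmParameters, CostSchedule

__all__ = ["ArmCostTable", "BudgetImpactResult", "tlr_unit_cost", "cost_arm", "budget_impact"]


def tlr_unit_cost(mix_perc: float, mix_open: float, costs: "CostSchedule") -> float:
    """Blended cost of one TLR under a percutaneous/open procedure mix (AUD)."""
    return mix_perc * costs.c_percutaneous + mix_open * costs.c_open


@dataclass(frozen=True)
class ArmCostTable:
    """Per-year unrounded AUD costs for one arm, both perspectives."""

    arm_name: str
    projection: ArmProjection
    primary_cost: np.ndarray
    tlr_cost: np.ndarray
    amputation_cost: np.ndarray
    hospital_cost: np.ndarray

    @property
    def healthcare_total(self) -> np.ndarray:
        """Activity-based funding perspective: index + TLR + amputation costs."""
        return self.primary_cost + self.tlr_cost + self.amputation_cost

    @property
    def hospital_total(self) -> np.ndarray:
        """Hospital perspective: adverse-event bed-days at the per-diem."""
        return self.hospital_cost

    def totals(self) -> dict[str, float]:
        return {
            "healthcare": float(self.healthcare_total.sum()),
            "hospital": float(self.hospital_total.sum()),
        }

    def _scaled(self, factor: float) -> "ArmCostTable":
        p = self.projection
        proj = ArmProjection(
            arm_name=p.arm_name,
            cohort=p.cohort * factor,
            tlr_first_cycle=p.tlr_first_cycle * factor,
            tlr_second_cycle=p.tlr_second_cycle * factor,
            amputations_first_cycle=p.amputations_first_cycle * factor,
            amputations_second_cycle=p.amputations_second_cycle * factor,
            hospital_days=p.hospital_days * factor,
        )
        return replace(
            self,
            projection=proj,
            primary_cost=self.primary_cost * factor,
            tlr_cost=self.tlr_cost * factor,
            amputation_cost=self.amputation_cost * factor,
            hospital_cost=self.hospital_cost * factor,
        )


def cost_arm(
    projection: ArmProjection, arm: "ArmParameters", costs: "CostSchedule"
) -> ArmCostTable:
    """Convert one arm's event projection into per-year AUD costs."""
    if projection.arm_name != arm.arm_name:
        raise ValueError(
            f"projection is for {projection.arm_name!r} but parameters are for "
            f"{arm.arm_name!r}"
        )
    perc, open_ = split_tlr_by_procedure(
        projection.tlr_first_cycle, projection.tlr_second_cycle, arm
    )
    return ArmCostTable(
        arm_name=arm.arm_name,
        projection=projection,
        primary_cost=projection.cohort * (costs.c_primary + arm.stent_price),
        tlr_cost=perc * costs.c_percutaneous + open_ * costs.c_open,
        amputation_cost=projection.amputations_total * costs.c_amputation,
        hospital_cost=projection.hospital_days * costs.c_bed_day,
    )


@dataclass(frozen=True)
class BudgetImpactResult:
    """Per-year and cumulative between-arm differences (comparator − intervention)."""

    year_labels: np.ndarray
    cohort: np.ndarray
    comparator: ArmCostTable  # arm whose costs are avoided (Zilver PTX)
    intervention: ArmCostTable  # adopted arm (Eluvia)

    @property
    def n_years(self) -> int:
        return int(self.cohort.size)

    @property
    def tlr_avoided(self) -> np.ndarray:
        return self.comparator.projection.tlr_total - self.intervention.projection.tlr_total

    @property
    def amputations_avoided(self) -> np.ndarray:
        return (
            self.comparator.projection.amputations_total
            - self.intervention.projection.amputations_total
        )

    @property
    def days_averted(self) -> np.ndarray:
        return (
            self.comparator.projection.hospital_days
            - self.intervention.projection.hospital_days
        )

    @property
    def healthcare_savings(self) -> np.ndarray:
        return self.comparator.healthcare_total - self.intervention.healthcare_total

    @property
    def hospital_savings(self) -> np.ndarray:
        return self.comparator.hospital_total - self.intervention.hospital_total

    def totals(self) -> dict[str, float]:
        """Horizon totals computed from unrounded per-year values."""
        return {
            "patients": float(self.cohort.sum()),
            "tlr_avoided": float(self.tlr_avoided.sum()),
            "days_averted": float(self.days_averted.sum()),
            "healthcare_savings": float(self.healthcare_savings.sum()),
            "hospital_savings": float(self.hospital_savings.sum()),
        }

    def scaled(self, factor: float) -> "BudgetImpactResult":
        """Rescale every quantity by ``factor`` (cohort-linearity in action)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return BudgetImpactResult(
            year_labels=self.year_labels,
            cohort=self.cohort * factor,
            comparator=self.comparator._scaled(factor),
            intervention=self.intervention._scaled(factor),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.year_labels,
                "cohort": self.cohort,
                "tlr_avoided": self.tlr_avoided,
                "days_averted": self.days_averted,
                "healthcare_savings": self.healthcare_savings,
                "hospital_savings": self.hospital_savings,
            }
        )


def budget_impact(table_z: ArmCostTable, table_e: ArmCostTable) -> BudgetImpactResult:
    """Between-arm budget impact from two per-year cost tables.

    The comparator's costs minus the intervention's; positive values are
    savings from adopting the intervention.
    """
    if table_z.projection.n_years != table_e.projection.n_years:
        raise ValueError("arm cost tables span different numbers of years")
    if not np.allclose(table_z.projection.cohort, table_e.projection.cohort):
        raise ValueError("arm cost tables were built on different cohort schedules")
    n = table_z.projection.n_years
    return BudgetImpactResult(
        year_labels=np.arange(n),
        cohort=table_z.projection.cohort.copy(),
        comparator=table_z,
        intervention=table_e,
    )
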