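"""Synthetic trial and resource-use data with the structure the model assumes.

Generators emulate a two-arm device trial — binomial cumulative event counts
at 12 and 24 months, multinomial procedure-mix draws — and noisy per-year
adverse-event bed-day totals, so calibration and the full pipeline can be
validated by parameter recovery without any external data.  Every generator
is a pure function of ``(seed, spec)``; each draws from its own named
pseudo-random stream so adding a generator never perturbs existing ones.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .parameters import ArmParameters, CostSchedule, ModelConfig
from .population import ExplicitCohorts, build_schedule_from_spec

__all__ = ["SyntheticTrialSpec", "simulate_trial", "simulate_observed_days", "random_config"]

_STREAMS = {"trial": 0, "days": 1, "config": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


class SyntheticTrialSpec(BaseModel):
    """Ground truth and sampling sizes for a simulated two-arm trial."""

    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    seed: int
    n_per_arm: int = Field(ge=1)
    arm_a: ArmParameters  # true comparator parameters
    arm_b: ArmParameters  # true intervention parameters
    day_noise_sd: float = Field(default=0.0, ge=0.0)


def _observed_mix(rng: np.random.Generator, events: int, true_perc: float) -> tuple[float, float]:
    """Split an event count by procedure type; empirical mix, true mix if no events."""
    if events == 0:
        return true_perc, 1.0 - true_perc
    perc = int(rng.binomial(events, true_perc))
    return perc / events, (events - perc) / events


def _simulate_arm(rng: np.random.Generator, truth: ArmParameters, n: int) -> ArmParameters:
    # Cumulative counts: 24-month events are the 12-month events plus extra
    # events among the still event-free, at the conditional excess rate, so
    # the 24-month count is >= the 12-month count and its marginal rate is r24.
    def cumulative_pair(r12: float, r24: float) -> tuple[int, int]:
        c12 = int(rng.binomial(n, r12))
        if r12 >= 1.0:
            return c12, n
        excess = (r24 - r12) / (1.0 - r12)
        c24 = c12 + int(rng.binomial(n - c12, excess))
        return c12, c24

    t12, t24 = cumulative_pair(truth.r12, truth.r24)
    a12, a24 = cumulative_pair(truth.a12, truth.a24)
    m12 = _observed_mix(rng, t12, truth.m12_perc)
    m24 = _observed_mix(rng, t24, truth.m24_perc)
    return ArmParameters(
        arm_name=truth.arm_name,
        r12=t12 / n,
        r24=t24 / n,
        m12_perc=m12[0],
        m12_open=m12[1],
        m24_perc=m24[0],
        m24_open=m24[1],
        a12=a12 / n,
        a24=a24 / n,
        h12=truth.h12,
        h24=truth.h24,
        stent_price=truth.stent_price,
    )


def simulate_trial(spec: SyntheticTrialSpec) -> tuple[ArmParameters, ArmParameters]:
    """Draw observed arm parameters for both arms of a synthetic trial."""
    rng = _rng(spec.seed, "trial")
    return (
        _simulate_arm(rng, spec.arm_a, spec.n_per_arm),
        _simulate_arm(rng, spec.arm_b, spec.n_per_arm),
    )


def simulate_observed_days(
    config: ModelConfig, spec: SyntheticTrialSpec
) -> dict[str, np.ndarray]:
    """Noisy per-year adverse-event bed-day totals for each arm.

    ``D_t = N_t*h12 + N_{t-1}*h24`` plus Gaussian noise with standard
    deviation ``spec.day_noise_sd``, truncated at zero.  Day totals are
    continuous derived quantities, not integer admissions, hence the
    Gaussian rather than a count model.
    """
    rng = _rng(spec.seed, "days")
    schedule = build_schedule_from_spec(config.population, config.n_years)
    N = schedule.N
    prev = np.concatenate([[0.0], N[:-1]])
    out: dict[str, np.ndarray] = {}
    for arm in (spec.arm_a, spec.arm_b):
        clean = N * arm.h12 + prev * arm.h24
        noisy = clean + rng.normal(0.0, spec.day_noise_sd, size=clean.size) if spec.day_noise_sd > 0 else clean
        out[arm.arm_name] = np.maximum(noisy, 0.0)
    return out


def _random_arm(rng: np.random.Generator, name: str) -> ArmParameters:
    r12 = float(rng.uniform(0.0, 0.3))
    r24 = float(rng.uniform(r12, min(1.0, r12 + 0.3)))
    a12 = float(rng.uniform(0.0, 0.05))
    a24 = float(rng.uniform(a12, a12 + 0.05))
    m12 = float(rng.uniform(0.5, 1.0))
    m24 = float(rng.uniform(0.5, 1.0))
    return ArmParameters(
        arm_name=name,
        r12=r12,
        r24=r24,
        m12_perc=m12,
        m12_open=1.0 - m12,
        m24_perc=m24,
        m24_open=1.0 - m24,
        a12=a12,
        a24=a24,
        h12=float(rng.uniform(0.0, 3.0)),
        h24=float(rng.uniform(0.0, 5.0)),
        stent_price=float(rng.uniform(0.0, 5000.0)),
    )


def random_config(seed: int, n_years: Optional[int] = None) -> ModelConfig:
    """A valid random model configuration for property-based pipeline tests."""
    rng = _rng(seed, "config")
    T = int(n_years) if n_years is not None else int(rng.integers(3, 9))
    cohorts = rng.uniform(100.0, 10000.0, size=T).tolist()
    return ModelConfig(
        arm_a=_random_arm(rng, "comparator"),
        arm_b=_random_arm(rng, "intervention"),
        costs=CostSchedule(
            c_percutaneous=float(rng.uniform(1000, 10000)),
            c_open=float(rng.uniform(5000, 30000)),
            c_amputation=float(rng.uniform(10000, 60000)),
            c_bed_day=float(rng.uniform(500, 4000)),
            c_primary=float(rng.uniform(1000, 10000)),
        ),
        population=ExplicitCohorts(
            cohorts=cohorts,
            evp_eligibility=float(rng.uniform(0.5, 1.0)),
            des_use_rate=float(rng.uniform(0.05, 0.5)),
        ),
        n_years=T,
        start_year=int(rng.integers(2000, 2030)),
    )
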