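"""Scenario analysis: post-traumatic stress disorder after snakebite.

PTSD is added to the model as a mental disability.  By default it occurs
in 8% (95% interval 2-18%) of victims who survive systemic envenoming and
in 2% of victims without envenoming.  Each case contributes a YLD term
(weight x duration) and a productivity cost: a fraction of daily income
lost over the duration of the disorder.  The weight, duration and
productivity-loss fraction are configurable; the bundled defaults are
reconstructions (a moderate mental-disorder weight of 0.133, a one-year
course, and 30% of income lost while symptomatic).

The scenario only adds burden: scenario DALYs and costs are always at
least the base-case values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision_tree import TreeOutcome
from .parameters import ParameterValue, ParamValues, build_sampler

__all__ = ["PtsdSpec", "PtsdValues", "DEFAULT_PTSD", "ptsd_cases",
           "ptsd_burden", "base_ptsd_values", "sample_ptsd_values"]


@dataclass(frozen=True)
class PtsdSpec:
    """Uncertain PTSD inputs for the scenario analysis."""

    p_after_envenoming: ParameterValue = ParameterValue(0.08, 0.02, 0.18, "beta")
    p_after_no_envenoming: ParameterValue = ParameterValue.fixed(0.02)
    weight: float = 0.133
    duration: float = 1.0  # years
    productivity_loss_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError("PTSD weight must lie in (0, 1)")
        if self.duration <= 0:
            raise ValueError("PTSD duration must be > 0")
        if not 0.0 <= self.productivity_loss_fraction <= 1.0:
            raise ValueError("productivity_loss_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class PtsdValues:
    """One concrete realization of the PTSD inputs."""

    p_after_envenoming: float
    p_after_no_envenoming: float
    weight: float
    duration: float
    productivity_loss_fraction: float


DEFAULT_PTSD = PtsdSpec()


def base_ptsd_values(spec: PtsdSpec = DEFAULT_PTSD) -> PtsdValues:
    return PtsdValues(
        spec.p_after_envenoming.point,
        spec.p_after_no_envenoming.point,
        spec.weight,
        spec.duration,
        spec.productivity_loss_fraction,
    )


def sample_ptsd_values(spec: PtsdSpec, rng: np.random.Generator) -> PtsdValues:
    return PtsdValues(
        build_sampler(spec.p_after_envenoming, "probability").sample(rng),
        build_sampler(spec.p_after_no_envenoming, "probability").sample(rng),
        spec.weight,
        spec.duration,
        spec.productivity_loss_fraction,
    )


def ptsd_cases(outcome: TreeOutcome, ptsd: PtsdValues) -> float:
    """Expected PTSD cases: survivors of envenoming (amputees counted
    once — they are already part of the survivors) plus non-envenomed
    victims, each at their respective probability."""
    return (ptsd.p_after_envenoming * outcome.survivors_envenomed
            + ptsd.p_after_no_envenoming * outcome.not_indicated)


def ptsd_burden(cases: float, ptsd: PtsdValues, pv: ParamValues) -> tuple[float, float]:
    """(YLD years, productivity cost in USD) for the given case count."""
    yld = cases * ptsd.weight * ptsd.duration
    costs = (cases * ptsd.duration * 365.0 * pv.daily_income
             * ptsd.productivity_loss_fraction)
    return yld, costs
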