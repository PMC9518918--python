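"""Societal-perspective costing of annual snakebite outcomes.

Three cost blocks, all expressed in 2019 USD:

* direct medical — hospitalization, antivenom courses plus their
  logistics, ADR management, and amputation procedures, costed bottom-up
  from unit costs in local currency and converted at a single 2019
  exchange rate;
* direct non-medical — transport to conventional care and additional food
  for the victim and one accompanying relative during the admission;
* indirect — productivity lost during the episode by the victim and the
  relative (human-capital approach: person-days times daily income, with
  daily income = GDP per capita / 365 by default), plus productivity lost
  to premature death, valued as GDP per capita over the remaining working
  years up to retirement (60 by default), discounted at 3%/year and
  adjusted for annual GDP-per-capita growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .decision_tree import TreeOutcome
from .parameters import ParamValues

__all__ = [
    "CostBreakdown",
    "direct_medical_costs",
    "direct_nonmedical_costs",
    "episode_productivity_loss",
    "premature_death_loss",
    "total_costs",
]


@dataclass(frozen=True)
class CostBreakdown:
    """Cost components in USD; ``total`` is the societal sum."""

    hospitalization: float = 0.0
    antivenom: float = 0.0
    adr_management: float = 0.0
    amputation: float = 0.0
    transport: float = 0.0
    food: float = 0.0
    productivity_episode: float = 0.0
    productivity_premature_death: float = 0.0
    productivity_ptsd: float = 0.0  # populated only in the PTSD scenario

    @property
    def direct_medical(self) -> float:
        return (self.hospitalization + self.antivenom + self.adr_management
                + self.amputation)

    @property
    def direct_nonmedical(self) -> float:
        return self.transport + self.food

    @property
    def indirect(self) -> float:
        return (self.productivity_episode + self.productivity_premature_death
                + self.productivity_ptsd)

    @property
    def total(self) -> float:
        return self.direct_medical + self.direct_nonmedical + self.indirect


def _check_unit_costs(pv: ParamValues) -> None:
    for name in ("cost_hospital_day", "cost_antivenom_course",
                 "cost_antivenom_logistics", "cost_adr_management",
                 "cost_amputation", "cost_transport", "cost_food_day"):
        if getattr(pv, name) < 0:
            raise ValueError(f"negative unit cost {name}")


def direct_medical_costs(outcome: TreeOutcome, pv: ParamValues) -> dict:
    """Bottom-up direct medical components, converted to USD.

    Hospitalization covers every victim admitted to conventional care,
    with the length of stay depending on antivenom indication;
    traditional-only victims incur no facility costs.
    """
    _check_unit_costs(pv)
    xr = pv.exchange_rate
    hospital_days = (outcome.indicated_conventional * pv.los_indicated
                     + outcome.not_indicated_conventional * pv.los_not_indicated)
    return {
        "hospitalization": hospital_days * pv.cost_hospital_day / xr,
        "antivenom": outcome.treated_antivenom
        * (pv.cost_antivenom_course + pv.cost_antivenom_logistics) / xr,
        "adr_management": outcome.adr_cases * pv.cost_adr_management / xr,
        "amputation": outcome.amputations * pv.cost_amputation / xr,
    }


def direct_nonmedical_costs(outcome: TreeOutcome, pv: ParamValues) -> dict:
    """Transport per conventional-care episode and food for the victim
    plus one accompanying relative over the stay."""
    _check_unit_costs(pv)
    xr = pv.exchange_rate
    episodes = outcome.indicated_conventional + outcome.not_indicated_conventional
    person_days = 2.0 * (outcome.indicated_conventional * pv.los_indicated
                         + outcome.not_indicated_conventional * pv.los_not_indicated)
    return {
        "transport": episodes * pv.cost_transport / xr,
        "food": person_days * pv.cost_food_day / xr,
    }


def episode_productivity_loss(outcome: TreeOutcome, pv: ParamValues) -> float:
    """Income lost during the episode by victims and their relatives.

    Applied to every victim regardless of care venue — illness time is
    lost whether it is spent in hospital or with a traditional healer —
    using the indication-specific episode length.
    """
    person_days = 2.0 * (outcome.indicated * pv.los_indicated
                         + outcome.not_indicated * pv.los_not_indicated)
    return person_days * pv.daily_income


def premature_death_loss(age_at_death: float, pv: ParamValues) -> float:
    """Discounted, growth-adjusted production lost by one premature death.

    Sums GDP per capita over the remaining whole working years from the
    age at death up to the retirement age R (fractional years truncated;
    zero at or beyond R).  The first lost year is undiscounted (t = 0):

        sum_{t=0}^{R-a-1} gdp * ((1+g)/(1+r))**t
    """
    if age_at_death < 0:
        raise ValueError("age_at_death must be >= 0")
    years = int(math.floor(pv.retirement_age - age_at_death + 1e-9))
    if years <= 0:
        return 0.0
    q = (1.0 + pv.gdp_growth) / (1.0 + pv.discount_rate)
    if abs(q - 1.0) < 1e-12:
        series = float(years)
    else:
        series = (1.0 - q**years) / (1.0 - q)
    return pv.gdp_per_capita * series


def total_costs(outcome: TreeOutcome, pv: ParamValues) -> CostBreakdown:
    """Assemble the full societal cost breakdown for one country."""
    dm = direct_medical_costs(outcome, pv)
    dnm = direct_nonmedical_costs(outcome, pv)
    episode = episode_productivity_loss(outcome, pv)
    # deaths are allocated to strata by share; each stratum contributes its
    # mean age at death
    premature = sum(
        outcome.deaths * share * premature_death_loss(age, pv)
        for _, share, age in pv.strata
    )
    return CostBreakdown(
        productivity_episode=episode,
        productivity_premature_death=premature,
        **dm,
        **dnm,
    )
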