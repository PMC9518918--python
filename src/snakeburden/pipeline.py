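"""End-to-end evaluation: parameters -> tree -> costs -> DALYs.

One deterministic pass of the full model for a single numeric parameter
realization.  The probabilistic and one-way sensitivity analyses both
reduce to repeated calls of :func:`run_values`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import costing, daly
from .costing import CostBreakdown
from .daly import DalyBreakdown, DisabilitySpec, LifeTable
from .decision_tree import TreeOutcome, run_tree
from .parameters import CountryParameters, ParamValues, base_values
from .ptsd_scenario import PtsdValues, ptsd_burden, ptsd_cases

__all__ = ["CountryResult", "run_values", "run_country", "flatten"]


@dataclass(frozen=True)
class CountryResult:
    """All model outputs for one country and one parameter realization."""

    pv: ParamValues
    outcome: TreeOutcome
    costs: CostBreakdown
    dalys: DalyBreakdown
    ptsd_cases: float = 0.0


def run_values(pv: ParamValues,
               ptsd: PtsdValues | None = None,
               specs: dict[str, DisabilitySpec] | None = None,
               table: LifeTable | None = None,
               daly_discount_rate: float = 0.0) -> CountryResult:
    """Evaluate the whole pipeline for one numeric parameter set."""
    outcome = run_tree(pv)
    costs = costing.total_costs(outcome, pv)
    cases = 0.0
    ptsd_yld = 0.0
    if ptsd is not None:
        cases = ptsd_cases(outcome, ptsd)
        ptsd_yld, ptsd_cost = ptsd_burden(cases, ptsd, pv)
        costs = replace(costs, productivity_ptsd=ptsd_cost)
    dalys = daly.total_dalys(outcome, pv, specs=specs, table=table,
                             ptsd_yld=ptsd_yld,
                             discount_rate=daly_discount_rate)
    return CountryResult(pv=pv, outcome=outcome, costs=costs, dalys=dalys,
                         ptsd_cases=cases)


def run_country(cp: CountryParameters, **kwargs) -> CountryResult:
    """Base-case evaluation of a country at its point estimates."""
    return run_values(base_values(cp), **kwargs)


#: additive output quantities (summable across countries and PSA draws)
FLAT_FIELDS = (
    "victims", "indicated", "not_indicated", "treated_antivenom",
    "untreated_indicated", "adr_cases", "deaths", "survivors_envenomed",
    "amputations", "ptsd_cases",
    "yll", "yld_episode", "yld_amputation", "yld_ptsd", "yld", "dalys",
    "hospitalization", "antivenom", "adr_management", "amputation_cost",
    "transport", "food", "productivity_episode",
    "productivity_premature_death", "productivity_ptsd",
    "direct_medical", "direct_nonmedical", "indirect", "total_cost",
    "population", "gdp",
)


def flatten(res: CountryResult) -> dict[str, float]:
    """Flat dict of additive outputs for one result (PSA row / region sum)."""
    o, c, d = res.outcome, res.costs, res.dalys
    return {
        "victims": o.victims_total,
        "indicated": o.indicated,
        "not_indicated": o.not_indicated,
        "treated_antivenom": o.treated_antivenom,
        "untreated_indicated": o.untreated_indicated,
        "adr_cases": o.adr_cases,
        "deaths": o.deaths,
        "survivors_envenomed": o.survivors_envenomed,
        "amputations": o.amputations,
        "ptsd_cases": res.ptsd_cases,
        "yll": d.yll,
        "yld_episode": d.yld_episode,
        "yld_amputation": d.yld_amputation,
        "yld_ptsd": d.yld_ptsd,
        "yld": d.yld,
        "dalys": d.dalys,
        "hospitalization": c.hospitalization,
        "antivenom": c.antivenom,
        "adr_management": c.adr_management,
        "amputation_cost": c.amputation,
        "transport": c.transport,
        "food": c.food,
        "productivity_episode": c.productivity_episode,
        "productivity_premature_death": c.productivity_premature_death,
        "productivity_ptsd": c.productivity_ptsd,
        "direct_medical": c.direct_medical,
        "direct_nonmedical": c.direct_nonmedical,
        "indirect": c.indirect,
        "total_cost": c.total,
        "population": res.pv.population,
        "gdp": res.pv.population * res.pv.gdp_per_capita,
    }
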