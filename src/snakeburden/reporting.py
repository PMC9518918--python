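"""Reporting surfaces: per-country and regional burden tables.

Collects the tree counts, DALY terms and cost components for one country
(or a region) and derives the comparison metrics: rates per 100,000
population, burden per envenomed victim, percentage of GDP, percentage of
indicated victims treated, and cost shares.  Regional rates are always
recomputed from summed numerators and denominators, never averaged.
Derived values are kept at full precision; rounding happens only in the
display tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .costing import CostBreakdown
from .pipeline import CountryResult

__all__ = [
    "CountryReport",
    "make_report",
    "make_region_report",
    "report_from_totals",
    "reports_to_dataframe",
    "display_burden_table",
    "display_cost_table",
]

COST_COMPONENTS = (
    "hospitalization", "antivenom", "adr_management", "amputation",
    "transport", "food", "productivity_episode",
    "productivity_premature_death", "productivity_ptsd",
)


@dataclass(frozen=True)
class CountryReport:
    """Raw totals for one country (or a region) plus derived metrics."""

    name: str
    population: float
    gdp: float  # total GDP in 2019 USD
    victims: float
    indicated: float
    not_indicated: float
    treated_antivenom: float
    untreated_indicated: float
    deaths: float
    amputations: float
    ptsd_cases: float
    yll: float
    yld: float
    dalys: float
    costs: CostBreakdown

    # ----- rates per 100,000 population --------------------------------
    @property
    def incidence_per_100k(self) -> float:
        return self.victims / self.population * 1e5

    @property
    def mortality_per_100k(self) -> float:
        return self.deaths / self.population * 1e5

    @property
    def dalys_per_100k(self) -> float:
        return self.dalys / self.population * 1e5

    # ----- per envenomed victim ---------------------------------------
    def _per_envenomed(self, x: float) -> float | None:
        return None if self.indicated == 0 else x / self.indicated

    @property
    def mortality_per_envenomed(self) -> float | None:
        return self._per_envenomed(self.deaths)

    @property
    def amputation_per_envenomed(self) -> float | None:
        return self._per_envenomed(self.amputations)

    @property
    def dalys_per_envenomed(self) -> float | None:
        return self._per_envenomed(self.dalys)

    @property
    def cost_per_envenomed(self) -> float | None:
        return self._per_envenomed(self.costs.total)

    # ----- treatment coverage and macro shares ------------------------
    @property
    def pct_indicated_treated(self) -> float | None:
        """Victims treated with antivenom as % of those indicated."""
        if self.indicated == 0:
            return None
        return self.treated_antivenom / self.indicated * 100.0

    @property
    def victims_not_treated(self) -> float:
        """Indicated victims who never received antivenom (absolute count,
        reported alongside the percentage to keep both readings explicit)."""
        return self.untreated_indicated

    @property
    def pct_gdp(self) -> float | None:
        return None if self.gdp == 0 else self.costs.total / self.gdp * 100.0

    @property
    def cost_shares(self) -> dict[str, float] | None:
        """Share of total costs per component, in percent (sums to 100)."""
        total = self.costs.total
        if total == 0:
            return None
        return {c: getattr(self.costs, c) / total * 100.0 for c in COST_COMPONENTS}


def make_report(result: CountryResult) -> CountryReport:
    """Build the report for one pipeline result."""
    o, pv = result.outcome, result.pv
    if pv.population <= 0:
        raise ValueError("population must be > 0")
    return CountryReport(
        name=pv.name,
        population=pv.population,
        gdp=pv.population * pv.gdp_per_capita,
        victims=o.victims_total,
        indicated=o.indicated,
        not_indicated=o.not_indicated,
        treated_antivenom=o.treated_antivenom,
        untreated_indicated=o.untreated_indicated,
        deaths=o.deaths,
        amputations=o.amputations,
        ptsd_cases=result.ptsd_cases,
        yll=result.dalys.yll,
        yld=result.dalys.yld,
        dalys=result.dalys.dalys,
        costs=result.costs,
    )


def report_from_totals(name: str, *, population: float, victims: float,
                       indicated: float, deaths: float, amputations: float,
                       treated_antivenom: float, yll: float, yld: float,
                       gdp: float = 0.0, ptsd_cases: float = 0.0,
                       costs: CostBreakdown | Mapping[str, float] | None = None,
                       ) -> CountryReport:
    """Build a report directly from known totals (e.g. published tables),
    bypassing the model; all derived metrics follow the same definitions
    as :func:`make_report`."""
    if costs is None:
        costs = CostBreakdown()
    elif isinstance(costs, Mapping):
        costs = CostBreakdown(**costs)
    return CountryReport(
        name=name,
        population=population,
        gdp=gdp,
        victims=victims,
        indicated=indicated,
        not_indicated=victims - indicated,
        treated_antivenom=treated_antivenom,
        untreated_indicated=indicated - treated_antivenom,
        deaths=deaths,
        amputations=amputations,
        ptsd_cases=ptsd_cases,
        yll=yll,
        yld=yld,
        dalys=yll + yld,
        costs=costs,
    )


def make_region_report(reports: Sequence[CountryReport],
                       name: str = "region") -> CountryReport:
    """Aggregate country reports: counts, person-years and costs are
    summed; every rate is recomputed from the summed numerator and
    denominator."""
    if not reports:
        raise ValueError("need at least one country report")

    def s(attr):
        return sum(getattr(r, attr) for r in reports)

    costs = CostBreakdown(**{
        c: sum(getattr(r.costs, c) for r in reports) for c in COST_COMPONENTS
    })
    return CountryReport(
        name=name,
        population=s("population"),
        gdp=s("gdp"),
        victims=s("victims"),
        indicated=s("indicated"),
        not_indicated=s("not_indicated"),
        treated_antivenom=s("treated_antivenom"),
        untreated_indicated=s("untreated_indicated"),
        deaths=s("deaths"),
        amputations=s("amputations"),
        ptsd_cases=s("ptsd_cases"),
        yll=s("yll"),
        yld=s("yld"),
        dalys=s("dalys"),
        costs=costs,
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_RAW_COLUMNS = (
    "population", "gdp", "victims", "indicated", "not_indicated",
    "treated_antivenom", "untreated_indicated", "deaths", "amputations",
    "ptsd_cases", "yll", "yld", "dalys",
)
_DERIVED_COLUMNS = (
    "incidence_per_100k", "mortality_per_100k", "dalys_per_100k",
    "mortality_per_envenomed", "amputation_per_envenomed",
    "dalys_per_envenomed", "cost_per_envenomed",
    "pct_indicated_treated", "pct_gdp",
)


def reports_to_dataframe(reports: Sequence[CountryReport]) -> pd.DataFrame:
    """Full-precision table: one row per country, all raw and derived
    quantities plus USD cost components (undefined ratios left blank)."""
    rows = []
    for r in reports:
        row: dict = {"name": r.name}
        row.update({c: getattr(r, c) for c in _RAW_COLUMNS})
        row.update({f"cost_{c}_usd": getattr(r.costs, c) for c in COST_COMPONENTS})
        row["cost_direct_medical_usd"] = r.costs.direct_medical
        row["cost_direct_nonmedical_usd"] = r.costs.direct_nonmedical
        row["cost_indirect_usd"] = r.costs.indirect
        row["cost_total_usd"] = r.costs.total
        row.update({c: getattr(r, c) for c in _DERIVED_COLUMNS})
        shares = r.cost_shares
        for c in COST_COMPONENTS:
            row[f"share_{c}_pct"] = None if shares is None else shares[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("name")


def display_burden_table(reports: Sequence[CountryReport]) -> pd.DataFrame:
    """Epidemiology/DALY table rounded for display: counts and person-years
    to integers, rates to two decimals."""
    rows = []
    for r in reports:
        rows.append({
            "name": r.name,
            "victims": round(r.victims),
            "indicated": round(r.indicated),
            "treated_antivenom": round(r.treated_antivenom),
            "untreated_indicated": round(r.untreated_indicated),
            "deaths": round(r.deaths),
            "amputations": round(r.amputations),
            "yll": round(r.yll),
            "yld": round(r.yld),
            "dalys": round(r.dalys),
            "incidence_per_100k": round(r.incidence_per_100k, 2),
            "mortality_per_100k": round(r.mortality_per_100k, 2),
            "dalys_per_100k": round(r.dalys_per_100k, 2),
            "pct_indicated_treated": (
                "" if r.pct_indicated_treated is None
                else round(r.pct_indicated_treated, 1)
            ),
        })
    return pd.DataFrame(rows).set_index("name")


def display_cost_table(reports: Sequence[CountryReport]) -> pd.DataFrame:
    """Cost table in thousand USD, one decimal, plus % of GDP (3 dp)."""
    rows = []
    for r in reports:
        c = r.costs
        rows.append({
            "name": r.name,
            "direct_medical_kusd": round(c.direct_medical / 1e3, 1),
            "direct_nonmedical_kusd": round(c.direct_nonmedical / 1e3, 1),
            "productivity_episode_kusd": round(c.productivity_episode / 1e3, 1),
            "productivity_premature_death_kusd": round(
                c.productivity_premature_death / 1e3, 1),
            "productivity_ptsd_kusd": round(c.productivity_ptsd / 1e3, 1),
            "total_kusd": round(c.total / 1e3, 1),
            "pct_gdp": "" if r.pct_gdp is None else round(r.pct_gdp, 3),
        })
    return pd.DataFrame(rows).set_index("name")
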