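"""Cohort decision tree for annual snakebite outcomes.

Victims enter the tree once per year of incidence.  They first seek either
conventional care (hospitals/health facilities) or traditional healers;
traditional-first victims may later switch to conventional care.  A victim
may have systemic envenoming requiring antivenom ("indicated").
Non-envenomed victims always survive.  Indicated victims who reach
conventional care receive antivenom with probability equal to the access
level (annual antivenom treatment courses available divided by indicated
victims, capped at 1); treated victims may suffer an adverse drug reaction
(ADR, cost-bearing only).  Death occurs with the treated probability on
treated branches and with that probability scaled by a relative risk on
every untreated branch.  Survivors of envenoming may be left with an
amputation.

The tree is evaluated as a cohort expectation: counts are fractional
expected persons, rounded only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import ParamValues

__all__ = [
    "TreeOutcome",
    "Leaf",
    "ConsistencyError",
    "expected_victims",
    "access_level",
    "death_prob_untreated",
    "run_tree",
    "enumerate_paths",
    "aggregate_paths",
    "paths_to_dataframe",
]


class ConsistencyError(RuntimeError):
    """A composed branch probability left [0, 1]."""


#: additive count fields of a TreeOutcome
COUNT_FIELDS = (
    "victims_total",
    "not_indicated",
    "not_indicated_conventional",
    "not_indicated_traditional",
    "indicated",
    "indicated_conventional",
    "indicated_traditional_only",
    "treated_antivenom",
    "untreated_indicated",
    "adr_cases",
    "deaths",
    "survivors_envenomed",
    "amputations",
)


@dataclass(frozen=True)
class TreeOutcome:
    """Expected counts at the terminal and intermediate nodes of the tree."""

    victims_total: float = 0.0
    not_indicated: float = 0.0
    not_indicated_conventional: float = 0.0
    not_indicated_traditional: float = 0.0
    indicated: float = 0.0
    indicated_conventional: float = 0.0
    indicated_traditional_only: float = 0.0
    treated_antivenom: float = 0.0
    untreated_indicated: float = 0.0
    adr_cases: float = 0.0
    deaths: float = 0.0
    survivors_envenomed: float = 0.0
    amputations: float = 0.0
    access: float = 1.0
    per_stratum: dict = field(default_factory=dict, compare=False)

    def scaled(self, f: float) -> "TreeOutcome":
        """Counts multiplied by ``f`` (access is a rate and is kept)."""
        return TreeOutcome(
            access=self.access,
            **{n: getattr(self, n) * f for n in COUNT_FIELDS},
        )


def expected_victims(incidence: float, population: float) -> float:
    """Expected annual victims from an incidence per 100,000 population."""
    if incidence < 0 or population <= 0:
        raise ValueError("require incidence >= 0 and population > 0")
    return incidence * population / 1e5


def access_level(antivenom_courses: float, indicated: float) -> float:
    """Fraction of indicated victims the antivenom supply could treat.

    Defined as courses available divided by indicated victims, capped at 1;
    full access (1.0) when nobody is indicated.
    """
    if antivenom_courses < 0 or indicated < 0:
        raise ValueError("require non-negative courses and indicated victims")
    if indicated == 0:
        return 1.0
    return min(1.0, antivenom_courses / indicated)


def death_prob_untreated(p_death_treated: float, rr: float) -> float:
    """Probability of death without antivenom: relative risk times the
    treated probability, capped at 1."""
    if not 0.0 <= p_death_treated <= 1.0:
        raise ValueError("p_death_treated must lie in [0, 1]")
    if rr <= 0:
        raise ValueError("relative risk must be > 0")
    return min(1.0, rr * p_death_treated)


def _check_prob(p: float, what: str) -> float:
    if not -1e-12 <= p <= 1.0 + 1e-12:
        raise ConsistencyError(f"composed probability {what}={p} outside [0, 1]")
    return min(max(p, 0.0), 1.0)


def run_tree(pv: ParamValues) -> TreeOutcome:
    """Evaluate the decision tree as a cohort expectation for one country."""
    victims = pv.victims
    p_conv = _check_prob(pv.p_conventional_first, "p_conventional_first")
    p_switch = _check_prob(pv.p_switch_to_conventional, "p_switch_to_conventional")
    p_ind = _check_prob(pv.p_indicated, "p_indicated")

    reach_conv = _check_prob(p_conv + (1.0 - p_conv) * p_switch, "reach_conventional")
    trad_only = _check_prob((1.0 - p_conv) * (1.0 - p_switch), "traditional_only")

    indicated = victims * p_ind
    not_indicated = victims - indicated
    indicated_conv = indicated * reach_conv
    indicated_trad = indicated * trad_only

    access = access_level(pv.antivenom_courses, indicated)
    treated = indicated_conv * access
    untreated = indicated - treated

    p_dt = _check_prob(pv.p_death_treated, "p_death_treated")
    p_du = death_prob_untreated(p_dt, pv.rr_death_untreated)

    deaths = treated * p_dt + untreated * p_du
    survivors = indicated - deaths
    p_amp = _check_prob(pv.p_amputation_survivor, "p_amputation_survivor")

    totals = TreeOutcome(
        victims_total=victims,
        not_indicated=not_indicated,
        not_indicated_conventional=not_indicated * reach_conv,
        not_indicated_traditional=not_indicated * trad_only,
        indicated=indicated,
        indicated_conventional=indicated_conv,
        indicated_traditional_only=indicated_trad,
        treated_antivenom=treated,
        untreated_indicated=untreated,
        adr_cases=treated * _check_prob(pv.p_adr, "p_adr"),
        deaths=deaths,
        survivors_envenomed=survivors,
        amputations=survivors * p_amp,
        access=access,
    )
    # strata share the same tree probabilities; they differ only in share
    # and in the age used downstream for YLL / productivity loss
    for label, share, _ in pv.strata:
        totals.per_stratum[label] = totals.scaled(share)
    return totals


# ---------------------------------------------------------------------------
# Explicit path enumeration (audit trail and independent aggregation route)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Leaf:
    """One root-to-leaf path with its probability and terminal state."""

    label: str
    probability: float
    seeking: str  # conventional | traditional_switch | traditional_only
    indicated: bool
    treated: bool
    adr: bool
    dead: bool
    amputated: bool


def enumerate_paths(pv: ParamValues) -> list[Leaf]:
    """Exhaustively enumerate every root-to-leaf path of the tree.

    Probabilities are per victim and sum to 1.  This walks the branching
    structure explicitly, leaf by leaf, so it can serve as an audit table
    and as an aggregation route independent of :func:`run_tree`.
    """
    p_conv = pv.p_conventional_first
    p_switch = pv.p_switch_to_conventional
    seeking = [
        ("conventional", p_conv, True),
        ("traditional_switch", (1.0 - p_conv) * p_switch, True),
        ("traditional_only", (1.0 - p_conv) * (1.0 - p_switch), False),
    ]
    p_ind = pv.p_indicated
    indicated_total = pv.victims * p_ind
    acc = access_level(pv.antivenom_courses, indicated_total)
    p_dt = pv.p_death_treated
    p_du = death_prob_untreated(p_dt, pv.rr_death_untreated)
    p_adr = pv.p_adr
    p_amp = pv.p_amputation_survivor

    leaves: list[Leaf] = []

    def emit(label, prob, seek, ind, treated, adr, dead, amputated):
        leaves.append(Leaf(label, prob, seek, ind, treated, adr, dead, amputated))

    def terminal(prefix, prob, seek, treated, adr, p_death):
        # death / survival, then amputation among survivors
        emit(f"{prefix}/dead", prob * p_death, seek, True, treated, adr, True, False)
        p_alive = prob * (1.0 - p_death)
        emit(f"{prefix}/alive/amputation", p_alive * p_amp, seek, True, treated,
             adr, False, True)
        emit(f"{prefix}/alive/intact", p_alive * (1.0 - p_amp), seek, True,
             treated, adr, False, False)

    # zero-probability branches are still emitted: the leaf table stays
    # exhaustive and its probabilities always sum to 1
    for seek, p_seek, reaches_conventional in seeking:
        # not indicated -> alive by assumption
        emit(f"{seek}/not_indicated/alive", p_seek * (1.0 - p_ind), seek,
             False, False, False, False, False)
        p_here = p_seek * p_ind
        if reaches_conventional:
            p_treated = p_here * acc
            terminal(f"{seek}/indicated/antivenom/adr", p_treated * p_adr,
                     seek, True, True, p_dt)
            terminal(f"{seek}/indicated/antivenom/no_adr", p_treated * (1.0 - p_adr),
                     seek, True, False, p_dt)
            terminal(f"{seek}/indicated/no_antivenom", p_here * (1.0 - acc),
                     seek, False, False, p_du)
        else:
            terminal(f"{seek}/indicated/untreated", p_here, seek, False, False, p_du)

    return leaves


def aggregate_paths(pv: ParamValues, leaves: list[Leaf] | None = None) -> TreeOutcome:
    """Sum enumerated leaves into a :class:`TreeOutcome` (independent of
    the closed-form bookkeeping in :func:`run_tree`)."""
    if leaves is None:
        leaves = enumerate_paths(pv)
    v = pv.victims
    counts = dict.fromkeys(COUNT_FIELDS, 0.0)
    counts["victims_total"] = sum(l.probability for l in leaves) * v
    for l in leaves:
        n = l.probability * v
        conv = l.seeking in ("conventional", "traditional_switch")
        if l.indicated:
            counts["indicated"] += n
            counts["indicated_conventional" if conv
                   else "indicated_traditional_only"] += n
            counts["treated_antivenom" if l.treated else "untreated_indicated"] += n
            if l.adr:
                counts["adr_cases"] += n
            if l.dead:
                counts["deaths"] += n
            else:
                counts["survivors_envenomed"] += n
                if l.amputated:
                    counts["amputations"] += n
        else:
            counts["not_indicated"] += n
            counts["not_indicated_conventional" if conv
                   else "not_indicated_traditional"] += n
    indicated = counts["indicated"]
    acc = access_level(pv.antivenom_courses, indicated)
    return TreeOutcome(access=acc, **counts)


def paths_to_dataframe(pv: ParamValues) -> pd.DataFrame:
    """Enumerated path table (for CSV audit dumps)."""
    leaves = enumerate_paths(pv)
    return pd.DataFrame(
        {
            "path": [l.label for l in leaves],
            "probability": [l.probability for l in leaves],
            "expected_persons": [l.probability * pv.victims for l in leaves],
            "seeking": [l.seeking for l in leaves],
            "indicated": [l.indicated for l in leaves],
            "treated": [l.treated for l in leaves],
            "adr": [l.adr for l in leaves],
            "dead": [l.dead for l in leaves],
            "amputated": [l.amputated for l in leaves],
        }
    )
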