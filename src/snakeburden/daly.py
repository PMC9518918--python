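"""Disease burden as disability-adjusted life years (DALYs).

DALY = YLL + YLD.  Years of life lost (YLL) are deaths multiplied by the
residual life expectancy at the age of death, read from a standard life
table with linear interpolation between knots.  Years lived with
disability (YLD) are cases times a disability weight times the duration
of the condition; lifelong conditions (amputation) use the residual life
expectancy at the age of onset as their duration.  Following WHO/GBD
practice since 2010, YLLs are undiscounted and not age-weighted by
default; a discounting switch exists for sensitivity analyses.

The bundled life table and disability weights are editable CSV data files.
The life table is a reconstruction of the standard reference table used in
WHO/GBD burden work; the default weights are severe-acute-episode and
treated lower-limb-amputation categories with a short episode duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .decision_tree import TreeOutcome
from .parameters import ParamValues

__all__ = [
    "LifeTable",
    "DisabilitySpec",
    "DalyBreakdown",
    "load_life_table",
    "load_disability_specs",
    "yll",
    "yld",
    "total_dalys",
]

LIFELONG = "lifelong"


@dataclass(frozen=True)
class LifeTable:
    """Residual life expectancy by age, linearly interpolated."""

    ages: tuple[float, ...]
    expectancies: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, dtype=float)
        e = np.asarray(self.expectancies, dtype=float)
        if a.size < 2 or a.size != e.size:
            raise ValueError("life table needs matching age/expectancy columns")
        if np.any(np.diff(a) <= 0):
            raise ValueError("life-table ages must be strictly increasing")
        if np.any(e <= 0):
            raise ValueError("residual expectancies must be positive")

    def residual(self, age: float) -> float:
        """Residual life expectancy at ``age`` (error outside the span)."""
        if not self.ages[0] <= age <= self.ages[-1]:
            raise ValueError(
                f"age {age} outside life-table span "
                f"[{self.ages[0]}, {self.ages[-1]}]"
            )
        return float(np.interp(age, self.ages, self.expectancies))


@dataclass(frozen=True)
class DisabilitySpec:
    """Disability weight and duration for one condition."""

    condition: str  # episode | amputation | ptsd
    weight: float
    duration: float | str  # years, or "lifelong"

    def __post_init__(self) -> None:
        if not 0.0 < self.weight < 1.0:
            raise ValueError("disability weight must lie in (0, 1)")
        if self.duration != LIFELONG and not float(self.duration) > 0:
            raise ValueError("duration must be > 0 or 'lifelong'")

    @property
    def lifelong(self) -> bool:
        return self.duration == LIFELONG


@dataclass(frozen=True)
class DalyBreakdown:
    yll: float = 0.0
    yld_episode: float = 0.0
    yld_amputation: float = 0.0
    yld_ptsd: float = 0.0

    @property
    def yld(self) -> float:
        return self.yld_episode + self.yld_amputation + self.yld_ptsd

    @property
    def dalys(self) -> float:
        return self.yll + self.yld


def _data_path(name: str):
    return resources.files("snakeburden.data").joinpath(name)


@lru_cache(maxsize=None)
def _default_life_table() -> LifeTable:
    return load_life_table(_data_path("life_table.csv"))


@lru_cache(maxsize=None)
def _default_specs_cached() -> tuple:
    return tuple(load_disability_specs(_data_path("disability_weights.csv")).items())


def load_life_table(path: str | Path | None = None) -> LifeTable:
    """Load a life table CSV with columns ``age`` and ``life_expectancy``."""
    if path is None:
        return _default_life_table()
    src = path
    df = pd.read_csv(src)
    if not {"age", "life_expectancy"} <= set(df.columns):
        raise ValueError("life table CSV needs 'age' and 'life_expectancy' columns")
    return LifeTable(tuple(df["age"].astype(float)),
                     tuple(df["life_expectancy"].astype(float)))


def load_disability_specs(path: str | Path | None = None) -> dict[str, DisabilitySpec]:
    """Load disability weights CSV: ``condition,weight,duration_years``
    (duration ``lifelong`` for permanent conditions)."""
    if path is None:
        return dict(_default_specs_cached())
    src = path
    df = pd.read_csv(src)
    specs = {}
    for row in df.itertuples(index=False):
        dur = row.duration_years
        dur = LIFELONG if str(dur).strip() == LIFELONG else float(dur)
        specs[row.condition] = DisabilitySpec(row.condition, float(row.weight), dur)
    return specs


def yll(deaths_by_age: list[tuple[float, float]], table: LifeTable) -> float:
    """Years of life lost: sum of deaths times residual expectancy at age."""
    return sum(count * table.residual(age) for age, count in deaths_by_age)


def yld(count: float, spec: DisabilitySpec, age: float | None = None,
        table: LifeTable | None = None) -> float:
    """Years lived with disability for ``count`` cases of one condition.

    Lifelong conditions take the residual life expectancy at ``age`` as
    their duration, hence need both ``age`` and ``table``.
    """
    if spec.lifelong:
        if age is None or table is None:
            raise ValueError("lifelong condition needs an age and a life table")
        duration = table.residual(age)
    else:
        duration = float(spec.duration)
    return count * spec.weight * duration


def total_dalys(outcome: TreeOutcome, pv: ParamValues,
                specs: dict[str, DisabilitySpec] | None = None,
                table: LifeTable | None = None,
                ptsd_yld: float = 0.0,
                discount_rate: float = 0.0) -> DalyBreakdown:
    """Assemble YLL and YLD terms for one country.

    The episode YLD applies to all envenomed victims (the acute episode
    precedes death, so deaths contribute it too).  Deaths and amputations
    are allocated to demographic strata by share, each stratum contributing
    its representative age.  ``discount_rate > 0`` applies continuous
    discounting to future life years (off by default, matching current
    WHO/GBD practice).
    """
    if specs is None:
        specs = load_disability_specs()
    if table is None:
        table = load_life_table()

    def life_years(age: float) -> float:
        le = table.residual(age)
        if discount_rate > 0.0:
            return (1.0 - math.exp(-discount_rate * le)) / discount_rate
        return le

    yll_total = sum(
        outcome.deaths * share * life_years(age) for _, share, age in pv.strata
    )
    yld_episode = yld(outcome.indicated, specs["episode"])
    amp_spec = specs["amputation"]
    if amp_spec.lifelong:
        yld_amp = sum(
            outcome.amputations * share * amp_spec.weight * life_years(age)
            for _, share, age in pv.strata
        )
    else:
        yld_amp = yld(outcome.amputations, amp_spec)
    return DalyBreakdown(
        yll=yll_total,
        yld_episode=yld_episode,
        yld_amputation=yld_amp,
        yld_ptsd=ptsd_yld,
    )
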