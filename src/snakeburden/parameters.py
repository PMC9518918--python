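"""Country-level input parameters for the snakebite burden model.

A country is described by a demographic profile of snakebite victims, the
decision-tree probabilities (treatment seeking, antivenom indication,
adverse drug reactions, death, amputation), unit costs in local currency,
and macro-economic quantities (exchange rate to 2019 USD, GDP per capita
and its growth rate, discount rate).  Every uncertain quantity is carried
as a :class:`ParameterValue` — a point estimate plus a plausible range —
from which samplable distributions are built for probabilistic sensitivity
analysis and bounds are taken for one-way sensitivity analysis.

Configuration files are YAML (JSON is accepted; it is a YAML subset), one
file per country, validated strictly: unknown keys are errors, not
silently ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "ParameterValue",
    "Stratum",
    "AgeSexProfile",
    "CountryParameters",
    "ParamValues",
    "ConfigError",
    "SchemaError",
    "ValidationError",
    "ConflictError",
    "load_country_config",
    "save_country_config",
    "build_sampler",
    "base_values",
    "sample_values",
    "perturbed_values",
    "UNCERTAIN_FIELDS",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

#: half-width of a central 95% interval in standard-deviation units
_Z95 = 2.0 * stats.norm.ppf(0.975)

FAMILIES = {"beta", "gamma", "lognormal", "dirichlet_share", "uniform", "fixed"}

#: default distribution family per parameter kind (used when a config gives
#: a range without naming a family)
_DEFAULT_FAMILY = {
    "probability": "beta",
    "positive": "gamma",
    "relative_risk": "lognormal",
    "share": "dirichlet_share",
    "rate": "uniform",
}


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """Missing or unknown configuration key."""


class ValidationError(ConfigError):
    """A value violates its domain constraint."""


class ConflictError(ConfigError):
    """Mutually inconsistent values supplied for the same quantity."""


# ---------------------------------------------------------------------------
# ParameterValue
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterValue:
    """A point estimate with a plausible range and a sampling family.

    Ranges are interpreted as central 95% intervals.  ``family="fixed"``
    denotes a known constant (``low == point == high``).
    """

    point: float
    low: float
    high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", float(self.point))
        object.__setattr__(self, "low", float(self.low))
        object.__setattr__(self, "high", float(self.high))
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if not (self.low <= self.point <= self.high):
            raise ValidationError(
                f"require low <= point <= high, got "
                f"[{self.low}, {self.point}, {self.high}]"
            )
        if self.family == "fixed" and not (self.low == self.point == self.high):
            raise ValidationError("family='fixed' requires low == point == high")
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ValidationError("beta family requires support within [0, 1]")

    @classmethod
    def fixed(cls, x: float) -> "ParameterValue":
        return cls(x, x, x, "fixed")

    @property
    def is_fixed(self) -> bool:
        return self.family == "fixed" or self.low == self.high


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Degenerate:
    """Sampler for a known constant."""

    value: float

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = np.full(q.shape, self.value)
        return out if out.shape else float(out)


@dataclass(frozen=True)
class DistSampler:
    """Sampler wrapping a frozen scipy distribution."""

    family: str
    dist: object
    fallback: bool = False  # True when moment matching failed and a uniform was used

    def sample(self, rng: np.random.Generator, size=None):
        x = self.dist.rvs(size=size, random_state=rng)
        return float(x) if size is None else x

    def ppf(self, q):
        out = self.dist.ppf(q)
        return float(out) if np.isscalar(q) else out


def _range_sd(p: ParameterValue) -> float:
    return (p.high - p.low) / _Z95


def build_sampler(p: ParameterValue, kind: str):
    """Build a sampler for ``p`` suited to its ``kind``.

    kind is one of ``probability``, ``positive``, ``relative_risk``,
    ``share``, ``rate``.  The sampler's point of central tendency matches
    the point estimate (arithmetic mean for beta/gamma/uniform, median —
    i.e. geometric mean — for lognormal) and its central 95% mass
    approximates ``[low, high]``.  When the range cannot be moment-matched
    by the requested family, a uniform on ``[low, high]`` is used instead
    and a warning is emitted; a run never fails for one parameter.
    """
    if kind in ("probability", "share") and p.high > 1.0:
        raise ValidationError(f"{kind} parameter with high={p.high} > 1")
    if kind in ("probability", "positive", "share") and p.low < 0.0:
        raise ValidationError(f"{kind} parameter with low={p.low} < 0")

    if p.is_fixed:
        return Degenerate(p.point)

    family = p.family
    sd = _range_sd(p)

    if family == "uniform":
        return DistSampler("uniform", stats.uniform(p.low, p.high - p.low))

    if family in ("beta", "dirichlet_share"):
        m = p.point
        if 0.0 < m < 1.0 and sd > 0.0:
            nu = m * (1.0 - m) / sd**2 - 1.0
            if nu > 0.0:
                return DistSampler("beta", stats.beta(m * nu, (1.0 - m) * nu))
        warnings.warn(
            f"beta moment matching failed for point={m} range=[{p.low},{p.high}]; "
            "falling back to uniform",
            stacklevel=2,
        )
        return DistSampler("uniform", stats.uniform(p.low, p.high - p.low), True)

    if family == "gamma":
        m = p.point
        if m > 0.0 and sd > 0.0:
            shape = (m / sd) ** 2
            return DistSampler("gamma", stats.gamma(shape, scale=sd**2 / m))
        warnings.warn(
            f"gamma moment matching failed for point={m}; falling back to uniform",
            stacklevel=2,
        )
        return DistSampler("uniform", stats.uniform(p.low, p.high - p.low), True)

    if family == "lognormal":
        if p.point > 0.0 and p.low > 0.0:
            sigma = (math.log(p.high) - math.log(p.low)) / _Z95
            return DistSampler("lognormal", stats.lognorm(s=sigma, scale=p.point))
        warnings.warn(
            "lognormal requires a strictly positive range; falling back to uniform",
            stacklevel=2,
        )
        return DistSampler("uniform", stats.uniform(p.low, p.high - p.low), True)

    raise ValidationError(f"cannot build sampler for family {family!r}")


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stratum:
    """One sex/age stratum of snakebite victims.

    ``share`` is the fraction of victims in the stratum;
    ``mean_age_at_death`` is the representative age used for residual life
    expectancy and remaining working years when a death (or lifelong
    disability) occurs in this stratum.
    """

    sex: str
    age_low: float
    age_high: float
    share: ParameterValue
    mean_age_at_death: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.age_low < self.age_high:
            raise ValidationError("require age_low < age_high")
        if not (0.0 <= self.share.low and self.share.high <= 1.0):
            raise ValidationError("stratum share must lie in [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_low:g}_{self.age_high:g}"


@dataclass(frozen=True)
class AgeSexProfile:
    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        if not self.strata:
            raise ValidationError("profile needs at least one stratum")
        total = sum(s.share.point for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"stratum shares sum to {total}, expected 1")
        for sex in ("female", "male"):
            spans = sorted(
                (s.age_low, s.age_high) for s in self.strata if s.sex == sex
            )
            for (a0, a1), (b0, _) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValidationError(f"overlapping {sex} age strata")

    def sample_shares(self, rng: np.random.Generator) -> tuple[float, ...]:
        """Joint Dirichlet draw of the stratum shares.

        The concentration is moment-matched to the tightest stated share
        range; with all shares fixed the point values are returned.
        """
        pts = np.array([s.share.point for s in self.strata])
        uncertain = [s for s in self.strata if not s.share.is_fixed]
        if not uncertain:
            return tuple(pts)
        ks = []
        for s in uncertain:
            sd = _range_sd(s.share)
            m = s.share.point
            if 0.0 < m < 1.0 and sd > 0.0:
                ks.append(max(m * (1.0 - m) / sd**2 - 1.0, 2.0))
        k = min(ks) if ks else 100.0
        alpha = np.clip(pts * k, 1e-3, None)
        return tuple(rng.dirichlet(alpha))


# ---------------------------------------------------------------------------
# CountryParameters
# ---------------------------------------------------------------------------

#: uncertain fields sampled in the PSA and swept in one-way SA, with kinds
UNCERTAIN_FIELDS: tuple[tuple[str, str], ...] = (
    ("incidence", "positive"),
    ("p_conventional_first", "probability"),
    ("p_switch_to_conventional", "probability"),
    ("p_indicated", "probability"),
    ("antivenom_courses", "positive"),
    ("p_adr", "probability"),
    ("p_death_treated", "probability"),
    ("rr_death_untreated", "relative_risk"),
    ("p_amputation_survivor", "probability"),
    ("los_indicated", "positive"),
    ("los_not_indicated", "positive"),
    ("cost_hospital_day", "positive"),
    ("cost_antivenom_course", "positive"),
    ("cost_antivenom_logistics", "positive"),
    ("cost_adr_management", "positive"),
    ("cost_amputation", "positive"),
    ("cost_transport", "positive"),
    ("cost_food_day", "positive"),
    ("gdp_growth", "rate"),
    ("discount_rate", "rate"),
)

_KIND = dict(UNCERTAIN_FIELDS)

_PROBABILITY_FIELDS = tuple(n for n, k in UNCERTAIN_FIELDS if k == "probability")

# defaults applied when a config omits the key
DEFAULT_RR_DEATH_UNTREATED = ParameterValue(2.33, 1.26, 4.06, "lognormal")
DEFAULT_DISCOUNT_RATE = ParameterValue(0.03, 0.01, 0.05, "uniform")
DEFAULT_RETIREMENT_AGE = 60.0
DEFAULT_DAILY_INCOME_DIVISOR = 365.0


@dataclass(frozen=True)
class CountryParameters:
    """Complete, validated input set for one country."""

    name: str
    population: float
    profile: AgeSexProfile
    incidence: ParameterValue  # victims per 100,000 population per year
    p_conventional_first: ParameterValue
    p_switch_to_conventional: ParameterValue
    p_indicated: ParameterValue
    antivenom_courses: ParameterValue  # treatment courses available per year
    p_adr: ParameterValue
    p_death_treated: ParameterValue
    rr_death_untreated: ParameterValue = DEFAULT_RR_DEATH_UNTREATED
    p_amputation_survivor: ParameterValue = ParameterValue.fixed(0.0)
    los_indicated: ParameterValue = ParameterValue.fixed(0.0)  # days
    los_not_indicated: ParameterValue = ParameterValue.fixed(0.0)  # days
    # unit costs, local currency
    cost_hospital_day: ParameterValue = ParameterValue.fixed(0.0)
    cost_antivenom_course: ParameterValue = ParameterValue.fixed(0.0)
    cost_antivenom_logistics: ParameterValue = ParameterValue.fixed(0.0)
    cost_adr_management: ParameterValue = ParameterValue.fixed(0.0)
    cost_amputation: ParameterValue = ParameterValue.fixed(0.0)
    cost_transport: ParameterValue = ParameterValue.fixed(0.0)  # per episode
    cost_food_day: ParameterValue = ParameterValue.fixed(0.0)  # per person-day
    # macro-economics
    exchange_rate: float = 1.0  # local currency units per 2019 USD
    gdp_per_capita: float = 0.0  # 2019 USD
    gdp_growth: ParameterValue = ParameterValue.fixed(0.0)  # fraction / year
    discount_rate: ParameterValue = DEFAULT_DISCOUNT_RATE
    retirement_age: float = DEFAULT_RETIREMENT_AGE
    daily_income_divisor: float = DEFAULT_DAILY_INCOME_DIVISOR

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValidationError("population must be > 0")
        if self.exchange_rate <= 0:
            raise ValidationError("exchange_rate must be > 0")
        if self.retirement_age <= 0:
            raise ValidationError("retirement_age must be > 0")
        if self.gdp_per_capita < 0:
            raise ValidationError("gdp_per_capita must be >= 0")
        if self.incidence.low < 0:
            raise ValidationError("incidence must be >= 0")
        if self.antivenom_courses.low < 0:
            raise ValidationError("antivenom_courses must be >= 0")
        for name in _PROBABILITY_FIELDS:
            p: ParameterValue = getattr(self, name)
            if p.low < 0.0 or p.high > 1.0:
                raise ValidationError(f"probability {name} outside [0, 1]")

    @property
    def victims(self) -> float:
        """Expected annual snakebite victims at the point estimate."""
        return self.incidence.point * self.population / 1e5


# ---------------------------------------------------------------------------
# Numeric views: one concrete value per parameter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamValues:
    """One concrete numeric realization of a country's parameters.

    Produced by :func:`base_values` (point estimates) or
    :func:`sample_values` (one PSA draw); everything downstream of the
    parameters module consumes this flat container.
    """

    name: str
    population: float
    incidence: float
    victims: float
    p_conventional_first: float
    p_switch_to_conventional: float
    p_indicated: float
    antivenom_courses: float
    p_adr: float
    p_death_treated: float
    rr_death_untreated: float
    p_amputation_survivor: float
    los_indicated: float
    los_not_indicated: float
    cost_hospital_day: float
    cost_antivenom_course: float
    cost_antivenom_logistics: float
    cost_adr_management: float
    cost_amputation: float
    cost_transport: float
    cost_food_day: float
    exchange_rate: float
    gdp_per_capita: float
    gdp_growth: float
    discount_rate: float
    retirement_age: float
    daily_income_divisor: float
    #: (label, share, mean_age_at_death) per stratum
    strata: tuple[tuple[str, float, float], ...]

    @property
    def daily_income(self) -> float:
        """Daily income in USD, GDP per capita spread over the year."""
        return self.gdp_per_capita / self.daily_income_divisor


def _assemble_values(cp: CountryParameters, drawn: Mapping[str, float],
                     shares: Sequence[float]) -> ParamValues:
    strata = tuple(
        (s.label, float(w), s.mean_age_at_death)
        for s, w in zip(cp.profile.strata, shares)
    )
    incidence = drawn["incidence"]
    return ParamValues(
        name=cp.name,
        population=cp.population,
        incidence=incidence,
        victims=incidence * cp.population / 1e5,
        exchange_rate=cp.exchange_rate,
        gdp_per_capita=cp.gdp_per_capita,
        retirement_age=cp.retirement_age,
        daily_income_divisor=cp.daily_income_divisor,
        strata=strata,
        **{n: drawn[n] for n, _ in UNCERTAIN_FIELDS if n != "incidence"},
    )


def base_values(cp: CountryParameters) -> ParamValues:
    """Point-estimate (base-case) numeric view."""
    drawn = {n: getattr(cp, n).point for n, _ in UNCERTAIN_FIELDS}
    shares = [s.share.point for s in cp.profile.strata]
    return _assemble_values(cp, drawn, shares)


@lru_cache(maxsize=512)
def _country_samplers(cp: CountryParameters) -> tuple:
    return tuple(
        (name, build_sampler(getattr(cp, name), kind))
        for name, kind in UNCERTAIN_FIELDS
    )


def sample_values(cp: CountryParameters, rng: np.random.Generator) -> ParamValues:
    """Draw one joint realization of all uncertain parameters."""
    drawn = {name: s.sample(rng) for name, s in _country_samplers(cp)}
    shares = cp.profile.sample_shares(rng)
    return _assemble_values(cp, drawn, shares)


def sample_values_batch(cp: CountryParameters, rng: np.random.Generator,
                        n: int) -> list[ParamValues]:
    """Draw ``n`` joint realizations, vectorized per parameter.

    Statistically identical to ``n`` calls of :func:`sample_values` (the
    stream of underlying variates differs in order); used by the PSA for
    speed.
    """
    cols = {name: np.atleast_1d(s.sample(rng, size=n))
            for name, s in _country_samplers(cp)}
    pts = np.array([s.share.point for s in cp.profile.strata])
    if all(s.share.is_fixed for s in cp.profile.strata):
        share_rows = np.tile(pts, (n, 1))
    else:
        share_rows = np.vstack([cp.profile.sample_shares(rng) for _ in range(n)])
    return [
        _assemble_values(cp, {k: float(v[i]) for k, v in cols.items()},
                         share_rows[i])
        for i in range(n)
    ]


def perturbed_values(cp: CountryParameters, **overrides: float) -> ParamValues:
    """Base-case view with named parameters overridden (for one-way SA)."""
    bad = set(overrides) - set(_KIND)
    if bad:
        raise KeyError(f"unknown parameter(s): {sorted(bad)}")
    drawn = {n: getattr(cp, n).point for n, _ in UNCERTAIN_FIELDS}
    drawn.update(overrides)
    shares = [s.share.point for s in cp.profile.strata]
    return _assemble_values(cp, drawn, shares)


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------


def _parse_pv(node, key: str, kind: str) -> ParameterValue:
    """Parse a scalar (fixed) or {point, low, high[, family]} mapping."""
    if isinstance(node, (int, float)):
        return ParameterValue.fixed(float(node))
    if not isinstance(node, Mapping):
        raise SchemaError(f"{key}: expected a number or a point/low/high mapping")
    d = dict(node)
    try:
        point = float(d.pop("point"))
    except KeyError:
        raise SchemaError(f"{key}: missing required key 'point'") from None
    low = float(d.pop("low", point))
    high = float(d.pop("high", point))
    family = d.pop("family", None)
    if d:
        raise SchemaError(f"{key}: unknown key(s) {sorted(d)}")
    if family is None:
        family = "fixed" if low == point == high else _DEFAULT_FAMILY[kind]
    try:
        return ParameterValue(point, low, high, family)
    except ConfigError as e:
        raise ValidationError(f"{key}: {e}") from None


def _pop_section(doc: dict, key: str) -> dict:
    try:
        sec = doc.pop(key)
    except KeyError:
        raise SchemaError(f"missing required section {key!r}") from None
    if not isinstance(sec, Mapping):
        raise SchemaError(f"section {key!r} must be a mapping")
    return dict(sec)


def _pop_scalar(sec: dict, key: str, where: str, default=None):
    if key in sec:
        return sec.pop(key)
    if default is not None:
        return default
    raise SchemaError(f"missing required key {where}.{key}" if where else
                      f"missing required key {key!r}")


def load_country_config(path: str | Path) -> CountryParameters:
    """Read and validate a country configuration file (YAML or JSON).

    Defaults are filled for the relative risk of death when untreated
    (2.33, 95% interval 1.26-4.06), the discount rate (3%) and the
    retirement age (60 years).  Exactly one of ``incidence`` and
    ``victims`` is required; if both are given they must agree to within
    0.5% relative difference.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: configuration must be a mapping")
    doc = dict(doc)

    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"schema_version must be {SCHEMA_VERSION}, got {version!r}"
        )
    name = str(doc.pop("name", path.stem))
    population = float(_pop_scalar(doc, "population", ""))

    incidence_node = doc.pop("incidence", None)
    victims_node = doc.pop("victims", None)
    if incidence_node is None and victims_node is None:
        raise SchemaError("missing required key 'incidence' (or 'victims')")
    if incidence_node is not None:
        incidence = _parse_pv(incidence_node, "incidence", "positive")
    else:
        v = _parse_pv(victims_node, "victims", "positive")
        scale = 1e5 / population
        incidence = ParameterValue(
            v.point * scale, v.low * scale, v.high * scale, v.family
        )
    if incidence_node is not None and victims_node is not None:
        v = _parse_pv(victims_node, "victims", "positive")
        implied = incidence.point * population / 1e5
        if implied > 0 and abs(v.point - implied) / implied > 0.005:
            raise ConflictError(
                f"victims={v.point} inconsistent with incidence-implied "
                f"{implied:.1f} (>0.5% relative difference)"
            )

    demog = _pop_section(doc, "demography")
    strata_nodes = demog.pop("strata", None)
    if demog:
        raise SchemaError(f"demography: unknown key(s) {sorted(demog)}")
    if not isinstance(strata_nodes, list) or not strata_nodes:
        raise SchemaError("demography.strata must be a non-empty list")
    strata = []
    for i, sn in enumerate(strata_nodes):
        sn = dict(sn)
        where = f"demography.strata[{i}]"
        try:
            stratum = Stratum(
                sex=sn.pop("sex"),
                age_low=float(sn.pop("age_low")),
                age_high=float(sn.pop("age_high")),
                share=_parse_pv(sn.pop("share"), f"{where}.share", "share"),
                mean_age_at_death=float(sn.pop("mean_age_at_death")),
            )
        except KeyError as e:
            raise SchemaError(f"{where}: missing required key {e}") from None
        if sn:
            raise SchemaError(f"{where}: unknown key(s) {sorted(sn)}")
        strata.append(stratum)
    profile = AgeSexProfile(tuple(strata))

    probs = _pop_section(doc, "probabilities")
    prob_map = {
        "conventional_first": "p_conventional_first",
        "switch_to_conventional": "p_switch_to_conventional",
        "indicated": "p_indicated",
        "adr": "p_adr",
        "death_treated": "p_death_treated",
        "amputation_survivor": "p_amputation_survivor",
    }
    parsed_probs = {}
    for cfg_key, attr in prob_map.items():
        node = _pop_scalar(probs, cfg_key, "probabilities")
        parsed_probs[attr] = _parse_pv(node, f"probabilities.{cfg_key}", "probability")
    if probs:
        raise SchemaError(f"probabilities: unknown key(s) {sorted(probs)}")

    rr_node = doc.pop("rr_death_untreated", None)
    rr = (DEFAULT_RR_DEATH_UNTREATED if rr_node is None
          else _parse_pv(rr_node, "rr_death_untreated", "relative_risk"))

    courses = _parse_pv(
        _pop_scalar(doc, "antivenom_courses", ""), "antivenom_courses", "positive"
    )

    los = _pop_section(doc, "length_of_stay")
    los_ind = _parse_pv(_pop_scalar(los, "indicated", "length_of_stay"),
                        "length_of_stay.indicated", "positive")
    los_not = _parse_pv(_pop_scalar(los, "not_indicated", "length_of_stay"),
                        "length_of_stay.not_indicated", "positive")
    if los:
        raise SchemaError(f"length_of_stay: unknown key(s) {sorted(los)}")

    costs = _pop_section(doc, "unit_costs")
    cost_map = {
        "hospital_day": "cost_hospital_day",
        "antivenom_course": "cost_antivenom_course",
        "antivenom_logistics": "cost_antivenom_logistics",
        "adr_management": "cost_adr_management",
        "amputation": "cost_amputation",
        "transport": "cost_transport",
        "food_day": "cost_food_day",
    }
    parsed_costs = {}
    for cfg_key, attr in cost_map.items():
        node = _pop_scalar(costs, cfg_key, "unit_costs")
        parsed_costs[attr] = _parse_pv(node, f"unit_costs.{cfg_key}", "positive")
    if costs:
        raise SchemaError(f"unit_costs: unknown key(s) {sorted(costs)}")

    econ = _pop_section(doc, "economics")
    exchange_rate = float(_pop_scalar(econ, "exchange_rate", "economics"))
    gdp_per_capita = float(_pop_scalar(econ, "gdp_per_capita", "economics"))
    gdp_growth = _parse_pv(_pop_scalar(econ, "gdp_growth", "economics"),
                           "economics.gdp_growth", "rate")
    disc_node = econ.pop("discount_rate", None)
    discount = (DEFAULT_DISCOUNT_RATE if disc_node is None
                else _parse_pv(disc_node, "economics.discount_rate", "rate"))
    retirement = float(econ.pop("retirement_age", DEFAULT_RETIREMENT_AGE))
    divisor = float(econ.pop("daily_income_divisor", DEFAULT_DAILY_INCOME_DIVISOR))
    if econ:
        raise SchemaError(f"economics: unknown key(s) {sorted(econ)}")

    if doc:
        raise SchemaError(f"unknown top-level key(s) {sorted(doc)}")

    return CountryParameters(
        name=name,
        population=population,
        profile=profile,
        incidence=incidence,
        antivenom_courses=courses,
        rr_death_untreated=rr,
        los_indicated=los_ind,
        los_not_indicated=los_not,
        exchange_rate=exchange_rate,
        gdp_per_capita=gdp_per_capita,
        gdp_growth=gdp_growth,
        discount_rate=discount,
        retirement_age=retirement,
        daily_income_divisor=divisor,
        **parsed_probs,
        **parsed_costs,
    )


def _pv_to_node(p: ParameterValue):
    if p.family == "fixed":
        return p.point
    return {"point": p.point, "low": p.low, "high": p.high, "family": p.family}


def to_config_dict(cp: CountryParameters) -> dict:
    """Serialize to the configuration-file schema (inverse of loading)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "name": cp.name,
        "population": cp.population,
        "incidence": _pv_to_node(cp.incidence),
        "demography": {
            "strata": [
                {
                    "sex": s.sex,
                    "age_low": s.age_low,
                    "age_high": s.age_high,
                    "share": _pv_to_node(s.share),
                    "mean_age_at_death": s.mean_age_at_death,
                }
                for s in cp.profile.strata
            ]
        },
        "probabilities": {
            "conventional_first": _pv_to_node(cp.p_conventional_first),
            "switch_to_conventional": _pv_to_node(cp.p_switch_to_conventional),
            "indicated": _pv_to_node(cp.p_indicated),
            "adr": _pv_to_node(cp.p_adr),
            "death_treated": _pv_to_node(cp.p_death_treated),
            "amputation_survivor": _pv_to_node(cp.p_amputation_survivor),
        },
        "rr_death_untreated": _pv_to_node(cp.rr_death_untreated),
        "antivenom_courses": _pv_to_node(cp.antivenom_courses),
        "length_of_stay": {
            "indicated": _pv_to_node(cp.los_indicated),
            "not_indicated": _pv_to_node(cp.los_not_indicated),
        },
        "unit_costs": {
            "hospital_day": _pv_to_node(cp.cost_hospital_day),
            "antivenom_course": _pv_to_node(cp.cost_antivenom_course),
            "antivenom_logistics": _pv_to_node(cp.cost_antivenom_logistics),
            "adr_management": _pv_to_node(cp.cost_adr_management),
            "amputation": _pv_to_node(cp.cost_amputation),
            "transport": _pv_to_node(cp.cost_transport),
            "food_day": _pv_to_node(cp.cost_food_day),
        },
        "economics": {
            "exchange_rate": cp.exchange_rate,
            "gdp_per_capita": cp.gdp_per_capita,
            "gdp_growth": _pv_to_node(cp.gdp_growth),
            "discount_rate": _pv_to_node(cp.discount_rate),
            "retirement_age": cp.retirement_age,
            "daily_income_divisor": cp.daily_income_divisor,
        },
    }


def save_country_config(cp: CountryParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config_dict(cp), fh, sort_keys=False)
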