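import numpy as np
import pytest

from snakeburden.parameters import (
    AgeSexProfile,
    CountryParameters,
    ParameterValue,
    Stratum,
    base_values,
)
from snakeburden.synthetic_data import generate_region

F = ParameterValue.fixed


def make_toy_country(**overrides) -> CountryParameters:
    """Fully fixed country with round numbers for hand-checkable arithmetic.

    Base case: 1,000 victims; 80% reach conventional care; 500 indicated;
    200 antivenom courses -> access 0.4 -> 160 treated, 340 untreated;
    p(death|treated)=0.1, RR=2 -> 16 + 68 = 84 deaths; 416 survivors;
    10% amputation -> 41.6 amputations; 25% ADR -> 40 ADR cases.
    """
    kw = dict(
        name="toyland",
        population=1_000_000.0,
        profile=AgeSexProfile(
            (Stratum("female", 15, 60, F(0.5), 30.0),
             Stratum("male", 15, 60, F(0.5), 40.0))
        ),
        incidence=F(100.0),  # 1,000 victims
        p_conventional_first=F(0.6),
        p_switch_to_conventional=F(0.5),  # reach conventional: 0.8
        p_indicated=F(0.5),
        antivenom_courses=F(200.0),
        p_adr=F(0.25),
        p_death_treated=F(0.1),
        rr_death_untreated=F(2.0),
        p_amputation_survivor=F(0.1),
        los_indicated=F(4.0),
        los_not_indicated=F(2.0),
        cost_hospital_day=F(50.0),
        cost_antivenom_course=F(100.0),
        cost_antivenom_logistics=F(20.0),
        cost_adr_management=F(80.0),
        cost_amputation=F(500.0),
        cost_transport=F(10.0),
        cost_food_day=F(5.0),
        exchange_rate=2.0,
        gdp_per_capita=3650.0,  # daily income 10 USD
        gdp_growth=F(0.0),
        discount_rate=F(0.03),
    )
    kw.update(overrides)
    return CountryParameters(**kw)


@pytest.fixture
def toy_country() -> CountryParameters:
    return make_toy_country()


@pytest.fixture
def toy_values(toy_country):
    return base_values(toy_country)


@pytest.fixture(scope="session")
def region7():
    """The bundled seeded 7-country synthetic region."""
    return generate_region(20_250_925, 7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
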