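"""Societal costing: bottom-up components, productivity losses and the
discounted premature-death series."""

import dataclasses

import numpy as np
import pytest

from snakeburden.costing import (
    direct_medical_costs,
    direct_nonmedical_costs,
    episode_productivity_loss,
    premature_death_loss,
    total_costs,
)
from snakeburden.decision_tree import TreeOutcome, run_tree
from snakeburden.parameters import ParameterValue, base_values, perturbed_values
from snakeburden.synthetic_data import generate_country
from tests.conftest import make_toy_country

F = ParameterValue.fixed


def geometric_series_loss(age, pv):
    """Closed-form oracle: explicit year-by-year discounted sum."""
    years = int(np.floor(pv.retirement_age - age + 1e-9))
    return sum(
        pv.gdp_per_capita * ((1 + pv.gdp_growth) / (1 + pv.discount_rate)) ** t
        for t in range(max(years, 0))
    )


class TestDirectCosts:
    def test_zero_conventional_care_zero_costs(self, toy_values):
        o = TreeOutcome()
        dm = direct_medical_costs(o, toy_values)
        dnm = direct_nonmedical_costs(o, toy_values)
        assert all(v == 0.0 for v in {**dm, **dnm}.values())

    def test_antivenom_course_plus_logistics(self, toy_values):
        o = TreeOutcome(treated_antivenom=10.0)
        pv = dataclasses.replace(toy_values, cost_antivenom_course=100.0,
                                 cost_antivenom_logistics=20.0,
                                 exchange_rate=1.0)
        assert direct_medical_costs(o, pv)["antivenom"] == pytest.approx(1_200.0)

    def test_food_covers_victim_and_one_relative(self, toy_values):
        o = TreeOutcome(indicated_conventional=1.0)
        pv = dataclasses.replace(toy_values, los_indicated=3.0,
                                 cost_food_day=5.0, exchange_rate=1.0)
        assert direct_nonmedical_costs(o, pv)["food"] == pytest.approx(30.0)

    def test_negative_unit_cost_rejected(self, toy_values):
        pv = dataclasses.replace(toy_values, cost_hospital_day=-1.0)
        with pytest.raises(ValueError):
            direct_medical_costs(TreeOutcome(), pv)

    def test_currency_round_trip(self, toy_country):
        """Converting unit costs to USD first gives the same USD totals."""
        pv_local = base_values(toy_country)
        xr = pv_local.exchange_rate
        pv_usd = dataclasses.replace(
            pv_local, exchange_rate=1.0,
            **{f: getattr(pv_local, f) / xr
               for f in ("cost_hospital_day", "cost_antivenom_course",
                         "cost_antivenom_logistics", "cost_adr_management",
                         "cost_amputation", "cost_transport", "cost_food_day")},
        )
        o = run_tree(pv_local)
        a = total_costs(o, pv_local)
        b = total_costs(o, pv_usd)
        for f in ("hospitalization", "antivenom", "adr_management",
                  "amputation", "transport", "food"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9)


class TestEpisodeProductivity:
    def test_daily_income_unit_construction(self, toy_values):
        # GDP per capita 365 -> daily income 1; victim + relative, LOS 4 -> 8
        pv = dataclasses.replace(toy_values, gdp_per_capita=365.0,
                                 los_indicated=4.0)
        o = TreeOutcome(indicated=1.0)
        assert episode_productivity_loss(o, pv) == pytest.approx(8.0)

    def test_zero_victims_zero_loss(self, toy_values):
        assert episode_productivity_loss(TreeOutcome(), toy_values) == 0.0


class TestPrematureDeathLoss:
    def test_zero_at_and_beyond_retirement(self, toy_values):
        assert premature_death_loss(60.0, toy_values) == 0.0
        assert premature_death_loss(75.0, toy_values) == 0.0

    def test_growth_cancels_discounting(self, toy_values):
        pv = dataclasses.replace(toy_values, gdp_per_capita=1_000.0,
                                 gdp_growth=0.03, discount_rate=0.03)
        assert premature_death_loss(30.0, pv) == pytest.approx(30_000.0)

    def test_geometric_series_value(self, toy_values):
        pv = dataclasses.replace(toy_values, gdp_per_capita=1_000.0,
                                 gdp_growth=0.0, discount_rate=0.03)
        # 1000 * sum_{t=0}^{9} 1.03^-t
        assert premature_death_loss(50.0, pv) == pytest.approx(8_786.11,
                                                               abs=0.005)

    def test_matches_series_oracle_on_grid(self, toy_values):
        for age in (0.0, 17.5, 30.0, 42.2, 59.0, 60.0, 80.0):
            for r in (0.0, 0.03, 0.07):
                for g in (0.0, 0.02, 0.05):
                    pv = dataclasses.replace(toy_values, gdp_per_capita=2_345.0,
                                             gdp_growth=g, discount_rate=r)
                    expected = geometric_series_loss(age, pv)
                    assert premature_death_loss(age, pv) == pytest.approx(
                        expected, rel=1e-12, abs=1e-9)

    def test_monotonicity(self, toy_values):
        base = dataclasses.replace(toy_values, gdp_per_capita=1_000.0,
                                   gdp_growth=0.02, discount_rate=0.03)
        # non-increasing in discount rate
        losses_r = [premature_death_loss(30.0,
                                         dataclasses.replace(base,
                                                             discount_rate=r))
                    for r in (0.0, 0.02, 0.05, 0.10)]
        assert all(a >= b for a, b in zip(losses_r, losses_r[1:]))
        # non-decreasing in growth
        losses_g = [premature_death_loss(30.0,
                                         dataclasses.replace(base, gdp_growth=g))
                    for g in (0.0, 0.01, 0.04)]
        assert all(a <= b for a, b in zip(losses_g, losses_g[1:]))
        # strictly decreasing in age below retirement (whole years)
        losses_a = [premature_death_loss(a, base) for a in range(0, 60, 5)]
        assert all(a > b for a, b in zip(losses_a, losses_a[1:]))


class TestTotalCosts:
    def test_all_zero_outcome_all_zero_costs(self, toy_values):
        c = total_costs(TreeOutcome(), toy_values)
        assert c.total == 0.0

    def test_component_identities(self):
        rng = np.random.default_rng(3)
        for i in range(200):
            cp = generate_country(int(rng.integers(2**31)), "mid")
            pv = base_values(cp)
            c = total_costs(run_tree(pv), pv)
            assert c.direct_medical == pytest.approx(
                c.hospitalization + c.antivenom + c.adr_management
                + c.amputation, rel=1e-12)
            assert c.direct_nonmedical == pytest.approx(
                c.transport + c.food, rel=1e-12)
            assert c.indirect == pytest.approx(
                c.productivity_episode + c.productivity_premature_death
                + c.productivity_ptsd, rel=1e-12)
            assert c.total == pytest.approx(
                c.direct_medical + c.direct_nonmedical + c.indirect, rel=1e-12)

    def test_spreadsheet_oracle_on_toy_country(self, toy_values):
        """Every component recomputed independently from the toy numbers."""
        o = run_tree(toy_values)
        c = total_costs(o, toy_values)
        xr = 2.0
        # conventional care: 400 indicated (LOS 4) + 400 non-indicated (LOS 2)
        assert c.hospitalization == pytest.approx(
            (400 * 4 + 400 * 2) * 50 / xr)
        assert c.antivenom == pytest.approx(160 * 120 / xr)
        assert c.adr_management == pytest.approx(40 * 80 / xr)
        assert c.amputation == pytest.approx(41.6 * 500 / xr)
        assert c.transport == pytest.approx(800 * 10 / xr)
        assert c.food == pytest.approx(2 * (400 * 4 + 400 * 2) * 5 / xr)
        # all victims lose episode time: 500 envenomed x 4 d + 500 x 2 d,
        # doubled for the relative, at 10 USD/day
        assert c.productivity_episode == pytest.approx(
            2 * (500 * 4 + 500 * 2) * 10)
        # deaths 84, half at age 30 (30y to retirement), half at 40 (20y),
        # g=0, r=3%
        per30 = sum(3650 * 1.03**-t for t in range(30))
        per40 = sum(3650 * 1.03**-t for t in range(20))
        assert c.productivity_premature_death == pytest.approx(
            42 * per30 + 42 * per40, rel=1e-12)
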