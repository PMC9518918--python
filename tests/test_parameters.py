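"""Configuration loading, validation, defaults and PSA samplers."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from snakeburden.parameters import (
    ConflictError,
    ParameterValue,
    SchemaError,
    ValidationError,
    base_values,
    build_sampler,
    load_country_config,
    sample_values,
    sample_values_batch,
    save_country_config,
    to_config_dict,
)
from tests.conftest import make_toy_country


def _write(tmp_path, doc, name="country.yaml"):
    path = tmp_path / name
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)
    return path


@pytest.fixture
def config_doc():
    return to_config_dict(make_toy_country())


class TestLoading:
    def test_victims_derived_from_incidence(self, tmp_path, config_doc):
        config_doc["population"] = 7_169_500.0
        config_doc["incidence"] = 200.0
        cp = load_country_config(_write(tmp_path, config_doc))
        assert cp.victims == pytest.approx(14_339.0)

    def test_incidence_derived_from_victims(self, tmp_path, config_doc):
        del config_doc["incidence"]
        config_doc["victims"] = 2_000.0
        cp = load_country_config(_write(tmp_path, config_doc))
        assert cp.incidence.point == pytest.approx(200.0)  # pop 1e6

    def test_rr_default_filled(self, tmp_path, config_doc):
        config_doc.pop("rr_death_untreated", None)
        cp = load_country_config(_write(tmp_path, config_doc))
        assert (cp.rr_death_untreated.point, cp.rr_death_untreated.low,
                cp.rr_death_untreated.high) == (2.33, 1.26, 4.06)

    def test_discount_default_point(self, tmp_path, config_doc):
        del config_doc["economics"]["discount_rate"]
        cp = load_country_config(_write(tmp_path, config_doc))
        assert cp.discount_rate.point == 0.03
        assert cp.retirement_age == 60.0

    def test_probability_out_of_bounds_rejected(self, tmp_path, config_doc):
        config_doc["probabilities"]["indicated"] = 1.2
        with pytest.raises(ValidationError):
            load_country_config(_write(tmp_path, config_doc))

    def test_missing_key_names_the_key(self, tmp_path, config_doc):
        del config_doc["probabilities"]["death_treated"]
        with pytest.raises(SchemaError, match="death_treated"):
            load_country_config(_write(tmp_path, config_doc))

    def test_unknown_key_rejected(self, tmp_path, config_doc):
        config_doc["probabilities"]["death_trated"] = 0.1  # typo
        with pytest.raises(SchemaError, match="death_trated"):
            load_country_config(_write(tmp_path, config_doc))

    def test_wrong_schema_version_rejected(self, tmp_path, config_doc):
        config_doc["schema_version"] = 99
        with pytest.raises(SchemaError, match="schema_version"):
            load_country_config(_write(tmp_path, config_doc))

    def test_conflicting_victims_and_incidence(self, tmp_path, config_doc):
        config_doc["victims"] = 1_200.0  # incidence 100/1e6 implies 1,000
        with pytest.raises(ConflictError):
            load_country_config(_write(tmp_path, config_doc))

    def test_consistent_victims_and_incidence_accepted(self, tmp_path,
                                                       config_doc):
        config_doc["victims"] = 1_001.0  # within 0.5% of 1,000
        cp = load_country_config(_write(tmp_path, config_doc))
        assert cp.victims == pytest.approx(1_000.0)

    def test_round_trip_exact(self, tmp_path, region7):
        for cp in region7:
            path = tmp_path / f"{cp.name}.yaml"
            save_country_config(cp, path)
            assert load_country_config(path) == cp


class TestParameterValue:
    def test_ordering_enforced(self):
        with pytest.raises(ValidationError):
            ParameterValue(0.5, 0.6, 0.7, "beta")

    def test_fixed_requires_degenerate_range(self):
        with pytest.raises(ValidationError):
            ParameterValue(0.5, 0.4, 0.6, "fixed")

    def test_beta_support_bounded(self):
        with pytest.raises(ValidationError):
            ParameterValue(0.9, 0.5, 1.3, "beta")

    @given(st.floats(0.01, 0.99), st.floats(0.001, 0.3))
    @settings(max_examples=50, deadline=None)
    def test_valid_symmetric_ranges_accepted(self, point, half_width):
        low = max(point - half_width, 0.0)
        high = min(point + half_width, 1.0)
        pv = ParameterValue(point, low, high, "beta")
        assert pv.low <= pv.point <= pv.high


class TestSamplers:
    def test_fixed_degenerate(self, rng):
        s = build_sampler(ParameterValue.fixed(0.5), "probability")
        assert s.sample(rng) == 0.5
        assert np.all(s.sample(rng, size=100) == 0.5)

    def test_beta_mean_and_percentiles(self, rng):
        pv = ParameterValue(0.2, 0.1, 0.3, "beta")
        s = build_sampler(pv, "probability")
        x = s.sample(rng, size=10_000)
        assert np.mean(x) == pytest.approx(0.2, abs=0.01)
        q = np.quantile(x, [0.025, 0.975])
        width = pv.high - pv.low
        assert q[0] == pytest.approx(0.1, abs=0.2 * width)
        assert q[1] == pytest.approx(0.3, abs=0.2 * width)

    def test_lognormal_geometric_mean(self, rng):
        s = build_sampler(ParameterValue(2.33, 1.26, 4.06, "lognormal"),
                          "relative_risk")
        x = s.sample(rng, size=10_000)
        assert math.exp(np.mean(np.log(x))) == pytest.approx(2.33, rel=0.03)
        # sigma from the 95% range on the log scale
        lo, hi = np.quantile(x, [0.025, 0.975])
        assert lo == pytest.approx(1.26, rel=0.1)
        assert hi == pytest.approx(4.06, rel=0.1)

    @pytest.mark.parametrize("pv,kind", [
        (ParameterValue(0.2, 0.1, 0.3, "beta"), "probability"),
        (ParameterValue(5.0, 3.0, 7.0, "gamma"), "positive"),
        (ParameterValue(0.03, 0.01, 0.05, "uniform"), "rate"),
    ])
    def test_mean_matches_point_within_3_se(self, pv, kind, rng):
        s = build_sampler(pv, kind)
        x = s.sample(rng, size=100_000)
        se = np.std(x) / np.sqrt(x.size)
        assert abs(np.mean(x) - pv.point) < 3 * se

    def test_probability_kind_rejects_high_above_one(self):
        with pytest.raises(ValidationError):
            build_sampler(ParameterValue(0.9, 0.5, 1.2, "uniform"), "probability")

    def test_positive_kind_rejects_negative_low(self):
        with pytest.raises(ValidationError):
            build_sampler(ParameterValue(1.0, -1.0, 2.0, "gamma"), "positive")

    def test_unmatchable_range_falls_back_to_uniform(self, rng):
        # range far wider than a beta with this mean can carry
        pv = ParameterValue(0.05, 0.0, 1.0, "beta")
        with pytest.warns(UserWarning, match="falling back"):
            s = build_sampler(pv, "probability")
        x = s.sample(rng, size=1000)
        assert np.all((0 <= x) & (x <= 1))


class TestNumericViews:
    def test_fixed_country_samples_equal_base(self, toy_country, rng):
        base = base_values(toy_country)
        assert sample_values(toy_country, rng) == base
        assert all(pv == base
                   for pv in sample_values_batch(toy_country, rng, 5))

    def test_batch_matches_single_draw_distribution(self, region7):
        cp = region7[0]
        a = np.array([sample_values(cp, np.random.default_rng(i)).victims
                      for i in range(500)])
        b = np.array([pv.victims for pv in
                      sample_values_batch(cp, np.random.default_rng(0), 500)])
        assert np.mean(a) == pytest.approx(np.mean(b), rel=0.1)
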