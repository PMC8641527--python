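"""Parameter bundle: defaults, validation, conversions, treatment effects, PSA specs."""

import math

import numpy as np
import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

from afscreen.parameters import (
    DistributionSpec,
    ParameterError,
    TreatmentEffect,
    ValidationError,
    beta_spec_from_mean,
    default_parameters,
    dump_defaults,
    load_parameters,
    parameters_to_dict,
    to_cycle_probability,
    treated_probabilities,
    with_overrides,
)

#: published base-case inputs, frozen; the defaults must reproduce these exactly
PUBLISHED_DEFAULTS = {
    "events": {"p_stroke": 0.0108, "p_stroke_acute_death": 0.0023,
               "p_post_stroke_death": 0.1751, "p_major_bleed": 0.0013,
               "p_bleed_acute_death": 0.0001},
    "utilities": {"u_af": 0.8430, "u_acute_stroke": 0.3280, "u_post_stroke": 0.5490,
                  "u_major_bleed": 0.8140, "d_bleed": 0.029},
    "costs": {"c_acute_stroke": 938.0, "c_post_stroke": 6.0, "c_stroke_death": 1126.0,
              "c_major_bleed": 195.0, "c_bleed_death": 778.0, "c_noac": 448.0,
              "c_warfarin": 17.0, "c_inr": 30.0},
    "persistence": {"persist_first_cycle": 0.70, "persist_later": 0.60},
    "cycle": {"cycle_length": 0.5, "discount_rate": 0.04, "start_age": 55.0,
              "max_age": 110.0},
}


def test_defaults_reproduce_published_tables():
    got = parameters_to_dict(default_parameters())
    for section, expected in PUBLISHED_DEFAULTS.items():
        for key, value in expected.items():
            assert got[section][key] == value, f"{section}.{key}"
    assert got["mix"]["frac_noac"] == 1.0
    assert got["wtp"] == 2000.0
    assert got["screening"]["population"] == 9_053_294
    assert got["screening"]["attendance"] == 0.50
    assert got["screening"]["prevalence"] == 0.01
    assert got["screening"]["unknown_af"] == 0.70


@pytest.mark.parametrize("p,frm,to,expected", [
    (0.0, 1.0, 0.5, 0.0),
    (1.0, 1.0, 0.5, 1.0),
    (0.0215, 1.0, 0.5, 1 - (1 - 0.0215) ** 0.5),  # ~0.01081, the 6-month stroke value
])
def test_cycle_probability_conversion(p, frm, to, expected):
    assert to_cycle_probability(p, frm, to) == pytest.approx(expected, abs=1e-12)


def test_cycle_probability_matches_table_value():
    # the printed 6-month stroke probability is the annual 2.15% recalculated
    assert to_cycle_probability(0.0215, 1, 0.5) == pytest.approx(0.0108, abs=2e-5)


def test_cycle_probability_rejects_bad_input():
    with pytest.raises(ValidationError):
        to_cycle_probability(1.5, 1, 0.5)
    with pytest.raises(ValidationError):
        to_cycle_probability(0.5, 0, 0.5)


@given(st.floats(0.0, 0.999))
def test_cycle_probability_round_trip(p):
    half = to_cycle_probability(p, 1.0, 0.5)
    assert to_cycle_probability(half, 0.5, 1.0) == pytest.approx(p, abs=1e-12)


@given(st.floats(0.1, 3.0), st.floats(0.1, 3.0))
def test_treated_stroke_probability_monotone_in_multiplier(m1, m2):
    events = default_parameters().events
    lo, hi = sorted([m1, m2])
    t_lo, _ = treated_probabilities(
        events, TreatmentEffect(rr_stroke=lo, rr_bleed=1, rr_mortality=1), 0.0)
    t_hi, _ = treated_probabilities(
        events, TreatmentEffect(rr_stroke=hi, rr_bleed=1, rr_mortality=1), 0.0)
    assert t_lo.p_stroke <= t_hi.p_stroke


class TestTreatedProbabilities:
    def test_identity_at_unit_multipliers(self, params):
        eff = TreatmentEffect(rr_stroke=1.0, rr_bleed=1.0, rr_mortality=1.0)
        treated, q = treated_probabilities(params.events, eff, 0.03)
        assert treated == params.events
        assert q == 0.03

    def test_coherent_mapping_scales_events(self, params):
        treated, q = treated_probabilities(params.events, params.effect, 0.05)
        assert treated.p_stroke == pytest.approx(0.0108 * 0.38)        # 0.004104
        assert treated.p_major_bleed == pytest.approx(0.0013 * 2.40)   # 0.00312
        assert q == pytest.approx(0.05 * 0.74)
        # post-stroke mortality is governed separately, untouched by treatment
        assert treated.p_post_stroke_death == params.events.p_post_stroke_death

    def test_literal_table_mapping(self):
        eff = TreatmentEffect.from_table(mapping_mode="literal_table")
        assert (eff.rr_stroke, eff.rr_bleed, eff.rr_mortality) == (0.38, 0.74, 2.40)

    def test_coherent_table_mapping_swaps_rows(self):
        eff = TreatmentEffect.from_table(mapping_mode="clinically_coherent")
        assert (eff.rr_stroke, eff.rr_bleed, eff.rr_mortality) == (0.38, 2.40, 0.74)

    def test_clamping_warns(self, params):
        eff = TreatmentEffect(rr_stroke=200.0, rr_bleed=1.0, rr_mortality=1.0)
        with pytest.warns(UserWarning, match="clamped"):
            treated, _ = treated_probabilities(params.events, eff, 0.0)
        assert treated.p_stroke == 1.0


class TestBetaSpec:
    def test_moment_match_shapes(self):
        # mean 0.5, sd 0.05 on the unit interval -> alpha = beta = 49.5
        spec = beta_spec_from_mean(0.5, 0.5 - 0.098, 0.5 + 0.098, scale=1.0)
        a, b = spec.beta_shapes()
        assert a == pytest.approx(49.5, rel=1e-9)
        assert b == pytest.approx(49.5, rel=1e-9)

    def test_degenerate_range_is_fixed(self):
        spec = beta_spec_from_mean(0.5, 0.5, 0.5)
        assert spec.family == "fixed"
        assert spec.sample(np.random.default_rng(0)) == 0.5

    def test_sampled_mean_matches_input(self):
        spec = beta_spec_from_mean(0.0108)   # +/-20% default range
        rng = np.random.default_rng(12345)
        draws = np.array([spec.sample(rng) for _ in range(100_000)])
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.0108) < 3 * se
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_cost_scale_supports_range(self):
        spec = beta_spec_from_mean(938.0)
        assert spec.scale == pytest.approx(2 * 938.0)
        rng = np.random.default_rng(0)
        draws = np.array([spec.sample(rng) for _ in range(2000)])
        assert ((draws > 0) & (draws < spec.scale)).all()

    def test_incompatible_variance_rejected(self):
        with pytest.raises(ValidationError, match="fixed"):
            DistributionSpec(family="beta_scaled", mean=0.5, lower=0.0, upper=3.0,
                             scale=1.0).beta_shapes()


class TestConfigIO:
    def test_dump_then_load_round_trips(self, tmp_path):
        path = tmp_path / "defaults.yaml"
        dump_defaults(str(path))
        loaded = load_parameters(str(path))
        assert parameters_to_dict(loaded) == parameters_to_dict(default_parameters())

    def test_override_applies(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("events:\n  p_stroke: 0.02\nwtp: 3000\n")
        p = load_parameters(str(path))
        assert p.events.p_stroke == 0.02
        assert p.wtp == 3000
        assert p.costs.c_noac == 448.0  # untouched sections keep defaults

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("events:\n  p_strke: 0.02\n")
        with pytest.raises(ParameterError, match="p_strke"):
            load_parameters(str(path))

    def test_invalid_probability_rejected(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("events:\n  p_stroke: 1.5\n")
        with pytest.raises(ValidationError, match="p_stroke"):
            load_parameters(str(path))

    def test_validation_lists_all_failures(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("events:\n  p_stroke: 1.5\nutilities:\n  u_af: -0.2\n")
        with pytest.raises(ValidationError) as err:
            load_parameters(str(path))
        assert "p_stroke" in str(err.value) and "u_af" in str(err.value)

    def test_effect_table_rows_in_config(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("effect:\n  mapping_mode: literal_table\n")
        p = load_parameters(str(path))
        assert p.effect.rr_mortality == 2.40

    def test_dotted_overrides(self, params):
        p = with_overrides(params, {"costs.c_noac": 100.0, "wtp": 5000.0})
        assert p.costs.c_noac == 100.0 and p.wtp == 5000.0
        with pytest.raises(ParameterError):
            with_overrides(params, {"costs.nope": 1.0})

    def test_dumped_config_is_valid_yaml(self, tmp_path):
        path = tmp_path / "d.yaml"
        dump_defaults(str(path))
        data = yaml.safe_load(path.read_text())
        assert data["events"]["p_stroke"] == 0.0108
        assert data["costs"]["c_noac"] == 448.0
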