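"""Parameter defaults, conversions, config loading and validation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortcea.params import (
    ParameterError,
    annual_to_cycle_probability,
    default_parameters,
    dump_parameters,
    load_parameters,
    rate_to_probability,
)


class TestDefaults:
    def test_base_values_exact(self, base_params):
        p = base_params
        assert p.strategies["control"].p_cv_death == 0.00975
        assert p.strategies["control"].p_hosp == 0.02003
        assert p.strategies["control"].p_readmit == 0.417
        assert p.strategies["empagliflozin"].p_cv_death == 0.00864
        assert p.strategies["empagliflozin"].p_hosp == 0.01466
        assert p.strategies["empagliflozin"].p_readmit == 0.417
        assert p.mortality.bands == {65: 0.002430, 70: 0.003042, 75: 0.004185}
        assert p.utilities.nyha == (0.825, 0.780, 0.650, 0.585)
        assert p.utilities.hospitalization_disutility == -0.1
        assert p.costs.standard_therapy_per_cycle == 131.96
        assert p.costs.empagliflozin_per_cycle == pytest.approx(59.625, abs=1e-12)
        assert p.costs.empagliflozin_per_cycle == pytest.approx(0.6625 * 90, abs=1e-12)
        assert p.costs.hospitalization_per_event == 1783.39
        assert p.cohort.start_age == 66.0
        assert p.cohort.horizon == 10.0
        assert p.cohort.cycle_length == 0.25
        assert p.cohort.annual_discount_rate == 0.05
        assert p.wtp_thresholds == (12652.5, 37957.5)

    def test_transition_matrix_exact(self, base_params):
        expected = np.array(
            [
                [0.977, 0.019, 0.004, 0.000],
                [0.008, 0.981, 0.010, 0.001],
                [0.000, 0.034, 0.960, 0.006],
                [0.000, 0.000, 0.055, 0.945],
            ]
        )
        assert np.array_equal(base_params.transition_matrix, expected)
        # including the class IV -> III entry
        assert base_params.transition_matrix[3, 2] == 0.055

    def test_config_round_trip(self, base_params):
        text = dump_parameters(base_params)
        reloaded = load_parameters(text)
        assert reloaded.to_dict() == base_params.to_dict()

    def test_mortality_lookup_is_total(self, base_params):
        m = base_params.mortality
        assert m.annual_probability(60) == 0.002430   # below first band
        assert m.annual_probability(66) == 0.002430
        assert m.annual_probability(72.5) == 0.003042
        assert m.annual_probability(79.9) == 0.004185
        assert m.annual_probability(95) == 0.004185   # carried forward


class TestRateToProbability:
    def test_no_events(self):
        assert rate_to_probability(1.0, 12.0, 3.0) == 0.0

    @pytest.mark.parametrize(
        "S, t, T, expected",
        [
            # 8.3% CV-death cumulative incidence over 27.2 months -> 3-month p
            (1 - 0.083, 27.2, 3.0, 0.0095112),
            # 18% readmission within 30 days -> 90-day probability
            (1 - 0.18, 30.0, 90.0, 0.4486320),
        ],
    )
    def test_constant_hazard_conversion(self, S, t, T, expected):
        assert rate_to_probability(S, t, T) == pytest.approx(expected, abs=5e-7)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            rate_to_probability(0.0, 1.0, 1.0)
        with pytest.raises(ParameterError):
            rate_to_probability(1.2, 1.0, 1.0)
        with pytest.raises(ParameterError):
            rate_to_probability(0.5, -1.0, 1.0)

    @given(
        S=st.floats(0.05, 0.999),
        t=st.floats(0.1, 50.0),
        T=st.floats(0.1, 50.0),
    )
    def test_identity_and_monotonicity(self, S, t, T):
        # same window recovers the complement exactly
        assert rate_to_probability(S, t, t) == pytest.approx(1 - S, rel=1e-12)
        # longer exposure, more risk (strictly, away from saturation)
        p1 = rate_to_probability(S, t, T)
        p2 = rate_to_probability(S, t, T + 0.1)
        assert p2 >= p1
        if p1 < 1 - 1e-9:
            assert p2 > p1
        # in [0, 1); floating saturation may round extreme cases up to 1.0
        assert 0.0 <= p1 <= 1.0


class TestAnnualToCycle:
    @pytest.mark.parametrize(
        "p_annual, expected",
        [
            (0.0, 0.0),
            (0.002430, 6.0805437e-4),
            (0.004185, 1.0478960e-3),
        ],
    )
    def test_examples(self, p_annual, expected):
        assert annual_to_cycle_probability(p_annual, 0.25) == pytest.approx(
            expected, abs=1e-10
        )

    @given(p=st.floats(0.0, 0.99))
    def test_four_quarters_recover_annual(self, p):
        q = annual_to_cycle_probability(p, 0.25)
        assert 1 - (1 - q) ** 4 == pytest.approx(p, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ParameterError):
            annual_to_cycle_probability(1.0, 0.25)
        with pytest.raises(ParameterError):
            annual_to_cycle_probability(-0.1, 0.25)


class TestLoadParameters:
    def test_empty_config_is_default(self):
        assert load_parameters("").to_dict() == default_parameters().to_dict()
        assert load_parameters(None).to_dict() == default_parameters().to_dict()

    def test_override_horizon_only(self):
        p = load_parameters("cohort:\n  horizon: 20\n")
        assert p.cohort.horizon == 20
        d = default_parameters()
        assert p.strategies == d.strategies
        assert np.array_equal(p.transition_matrix, d.transition_matrix)
        assert p.costs == d.costs

    def test_non_stochastic_row_rejected(self):
        bad = {
            "transition_matrix": [
                [0.9, 0.0, 0.0, 0.0],  # sums to 0.9
                [0.008, 0.981, 0.010, 0.001],
                [0.0, 0.034, 0.960, 0.006],
                [0.0, 0.0, 0.055, 0.945],
            ]
        }
        with pytest.raises(ParameterError, match="row 1"):
            load_parameters(bad)

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="unknown config key"):
            load_parameters({"not_a_field": 1})
        with pytest.raises(ParameterError, match="cohort.not_a_field"):
            load_parameters({"cohort": {"not_a_field": 1}})

    @pytest.mark.parametrize(
        "config, match",
        [
            ({"cohort": {"annual_discount_rate": 0.2}}, "annual_discount_rate"),
            ({"cohort": {"initial_distribution": [0.5, 0.5, 0.5, 0.5]}}, "sum to 1"),
            ({"strategies": {"control": {"p_cv_death": 1.5}}}, "p_cv_death"),
            ({"utilities": {"nyha": [0.5, 0.6, 0.7, 0.8]}}, "decreasing"),
            ({"costs": {"hospitalization_per_event": -5}}, "nonnegative"),
        ],
    )
    def test_out_of_range_names_field(self, config, match):
        with pytest.raises(ParameterError, match=match):
            load_parameters(config)

    def test_bundled_config_reproduces_defaults(self):
        from importlib.resources import files

        text = files("cohortcea").joinpath("data/default_parameters.yaml").read_text()
        assert load_parameters(text).to_dict() == default_parameters().to_dict()

    def test_utilities_strictly_decreasing_default(self, base_params):
        u = base_params.utilities.nyha
        assert all(a > b for a, b in zip(u, u[1:]))
        assert math.isclose(sum(base_params.cohort.initial_distribution), 1.0)
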