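"""Tornado analysis, distribution fitting, PSA, CEAC, scenarios."""

import numpy as np
import pytest

from cohortcea.params import ParamDistribution, ParameterError
from cohortcea.sensitivity import (
    apply_override,
    base_icer,
    ceac,
    fit_distribution,
    one_way_dsa,
    probability_cost_effective,
    PSASample,
    run_psa,
    run_scenario,
    sample_parameters,
    ScenarioSpec,
    standard_scenarios,
)


class TestApplyOverride:
    def test_returns_modified_copy(self, base_params):
        out = apply_override(base_params, "p_cv_death.control", 0.02)
        assert out.strategies["control"].p_cv_death == 0.02
        assert base_params.strategies["control"].p_cv_death == 0.00975

    def test_readmission_is_shared(self, base_params):
        out = apply_override(base_params, "p_readmit", 0.3)
        assert out.strategies["control"].p_readmit == 0.3
        assert out.strategies["empagliflozin"].p_readmit == 0.3

    def test_rejects_invalid_value(self, base_params):
        with pytest.raises(ParameterError):
            apply_override(base_params, "p_hosp.control", 1.5)
        with pytest.raises(ParameterError):
            apply_override(base_params, "discount_rate", 0.2)

    def test_rejects_unknown_name(self, base_params):
        with pytest.raises(ParameterError):
            apply_override(base_params, "no_such_parameter", 0.5)


class TestOneWayDsa:
    def test_collapsed_range_reproduces_base(self, base_params):
        base = base_icer(base_params).icer
        entries = one_way_dsa(
            base_params, ranges={"cost.empagliflozin": (59.625, 59.625)}
        )
        assert len(entries) == 1
        assert entries[0].width == pytest.approx(0.0, abs=1e-9)
        assert entries[0].icer_low == pytest.approx(base, rel=1e-12)

    def test_discount_sweep_gives_finite_icers(self, base_params):
        entries = one_way_dsa(base_params, ranges={"discount_rate": (0.0, 0.08)})
        e = entries[0]
        assert np.isfinite(e.icer_low) and np.isfinite(e.icer_high)
        assert e.icer_low != e.icer_high

    def test_sorted_by_descending_width(self, base_params):
        entries = one_way_dsa(base_params)
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_cv_death_probabilities_dominate(self, base_params):
        entries = one_way_dsa(base_params)
        top2 = {entries[0].parameter, entries[1].parameter}
        assert top2 == {"p_cv_death.control", "p_cv_death.empagliflozin"}

    def test_out_of_support_range_rejected(self, base_params):
        with pytest.raises(ParameterError):
            one_way_dsa(base_params, ranges={"p_hosp.control": (0.0, 1.2)})


class TestFitDistribution:
    def test_beta_round_trip_mean(self):
        sampler = fit_distribution(
            ParamDistribution("beta", 0.00975, 0.00877, 0.01072)
        )
        assert sampler.mean == pytest.approx(0.00975, abs=1e-6)

    def test_gamma_monte_carlo_mean(self):
        sampler = fit_distribution(
            ParamDistribution("gamma", 1783.39, 1029.73, 3336.39)
        )
        rng = np.random.default_rng(0)
        draws = [sampler.rvs(rng) for _ in range(100_000)]
        assert np.mean(draws) == pytest.approx(1783.39, rel=0.01)
        assert min(draws) > 0

    def test_degenerate_interval_point_mass(self):
        sampler = fit_distribution(ParamDistribution("beta", 0.5, 0.5, 0.5))
        rng = np.random.default_rng(0)
        assert sampler.rvs(rng) == 0.5

    def test_infeasible_beta_variance_named(self):
        with pytest.raises(ParameterError, match="wide_one"):
            fit_distribution(
                ParamDistribution("beta", 0.5, -4.0, 5.0), name="wide_one"
            )

    def test_beta_draws_stay_in_unit_interval(self):
        sampler = fit_distribution(ParamDistribution("beta", 0.585, 0.510, 0.660))
        rng = np.random.default_rng(1)
        draws = np.array([sampler.rvs(rng) for _ in range(5000)])
        assert np.all((draws > 0) & (draws < 1))
        assert draws.mean() == pytest.approx(0.585, abs=0.005)


class TestRunPsa:
    def test_reproducible_given_seed(self, base_params):
        a = run_psa(base_params, n_iter=3, seed=11)
        b = run_psa(base_params, n_iter=3, seed=11)
        assert [(s.delta_cost, s.delta_qaly) for s in a] == [
            (s.delta_cost, s.delta_qaly) for s in b
        ]
        c = run_psa(base_params, n_iter=3, seed=12)
        assert [(s.delta_cost, s.delta_qaly) for s in a] != [
            (s.delta_cost, s.delta_qaly) for s in c
        ]

    def test_iteration_prefix_stable(self, base_params):
        """Iteration i's draw does not depend on how many iterations run."""
        short = run_psa(base_params, n_iter=2, seed=5)
        # substreams are spawned from the root sequence, so the first two of a
        # longer run may differ only if spawning depended on n_iter; it must not
        longer = run_psa(base_params, n_iter=4, seed=5)
        assert (short[0].delta_cost, short[0].delta_qaly) == (
            longer[0].delta_cost,
            longer[0].delta_qaly,
        )

    def test_sampled_parameters_stay_valid(self, base_params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            drawn = sample_parameters(base_params, rng)
            tm = drawn.transition_matrix
            assert np.allclose(tm.sum(axis=1), 1.0, atol=1e-12)
            assert np.all((tm >= 0) & (tm <= 1))
            for ev in drawn.strategies.values():
                assert 0 <= ev.p_cv_death <= 1
                assert 0 <= ev.p_hosp <= 1
            assert drawn.utilities.hospitalization_disutility < 0

    def test_share_arms_mode_differs(self, base_params):
        indep = run_psa(base_params, n_iter=5, seed=2)
        shared = run_psa(base_params, n_iter=5, seed=2, share_arms=True)
        de_ind = np.array([s.delta_qaly for s in indep])
        de_sh = np.array([s.delta_qaly for s in shared])
        assert not np.allclose(de_ind, de_sh)

    def test_sample_means_converge_to_base(self, base_params):
        """PSA draws are centred on the base-case inputs."""
        rng = np.random.default_rng(7)
        cv = [
            sample_parameters(base_params, rng).strategies["control"].p_cv_death
            for _ in range(400)
        ]
        se = (0.01072 - 0.00877) / 3.92
        assert np.mean(cv) == pytest.approx(0.00975, abs=3 * se / np.sqrt(400))


class TestCeac:
    def test_all_costlier_at_zero_wtp(self):
        samples = [PSASample(i, 100.0, 0.1) for i in range(10)]
        curve = ceac(samples, [0.0])
        assert curve.probability[0] == 0.0

    def test_limit_probability_one(self):
        samples = [PSASample(i, 100.0, 0.1) for i in range(10)]
        curve = ceac(samples, [1e9])
        assert curve.probability[0] == 1.0

    def test_nondecreasing_when_all_gain_qalys(self, base_params):
        samples = run_psa(base_params, n_iter=50, seed=9)
        gainers = [s for s in samples if s.delta_qaly > 0]
        grid = np.linspace(0, 60_000, 13)
        curve = ceac(gainers, grid)
        assert np.all(np.diff(curve.probability) >= 0)

    def test_nmb_zero_at_base_icer(self, base_params):
        """At a WTP equal to the base-case ICER the deterministic NMB is 0."""
        result = base_icer(base_params)
        assert result.net_monetary_benefit(result.icer) == pytest.approx(0.0, abs=1e-9)

    def test_probability_uses_strict_positivity(self):
        samples = [PSASample(0, 100.0, 0.01)]
        assert probability_cost_effective(samples, 10_000.0) == 0.0  # NMB == 0


class TestScenarios:
    def test_empty_scenario_identity(self, base_params):
        base = base_icer(base_params)
        scen = run_scenario(base_params, ScenarioSpec("noop", {}))
        assert scen.icer == base.icer
        assert scen.delta_cost == base.delta_cost
        assert scen.delta_qaly == base.delta_qaly

    def test_unknown_override_rejected(self, base_params):
        with pytest.raises(ParameterError, match="unknown override"):
            run_scenario(base_params, ScenarioSpec("bad", {"p_cv": 0.1}))

    def test_purchase_price_lowers_icer(self, base_params):
        base = base_icer(base_params)
        cheap = run_scenario(
            base_params,
            ScenarioSpec("purchase", {"empagliflozin_unit_price": 0.275}),
        )
        assert cheap.icer < 0.5 * base.icer

    def test_unit_price_conversion(self, base_params):
        from cohortcea.sensitivity import apply_scenario

        out = apply_scenario(
            base_params, ScenarioSpec("p", {"empagliflozin_unit_price": 0.275})
        )
        assert out.costs.empagliflozin_per_cycle == pytest.approx(24.75)

    def test_battery_covers_published_set(self, base_params):
        battery = standard_scenarios()
        assert set(battery) == {
            "initial_nyha1", "initial_nyha2", "initial_nyha3", "initial_nyha4",
            "purchase_price",
            "hospital_town", "hospital_county", "hospital_municipal",
            "hospital_provincial", "hospital_ministerial",
            "horizon_10y", "horizon_15y", "horizon_20y",
        }
        ten = run_scenario(base_params, battery["horizon_10y"])
        base = base_icer(base_params)
        assert ten.icer == base.icer  # 10-y override is bit-identical to base

    def test_longer_horizon_more_favourable(self, base_params):
        battery = standard_scenarios()
        icers = [
            run_scenario(base_params, battery[f"horizon_{h}y"]).icer
            for h in (10, 15, 20)
        ]
        assert icers[0] > icers[1] > icers[2]
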