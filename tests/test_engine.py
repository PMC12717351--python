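"""Optimization schemes: closed forms vs oracles, invasion analysis, CSS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soceeo import engine, model
from soceeo.engine import PowerLawKernel


def _feasible_soc(p, rng, factor_lo=2.0, factor_hi=20.0):
    thr = model.feasibility_threshold(p)
    return thr * rng.uniform(factor_lo, factor_hi)


class TestNumericOracle:
    def test_concave_quadratic(self):
        res = engine.numeric_oracle_maximize(lambda u: -((u - 2.0) ** 2), (0.0, 10.0))
        assert res.argmax == pytest.approx(2.0, abs=1e-8)
        assert not res.at_boundary

    def test_monotone_decreasing_hits_lower_bound(self):
        res = engine.numeric_oracle_maximize(lambda u: -u, (0.0, 5.0))
        assert res.argmax == pytest.approx(0.0, abs=1e-8)
        assert res.at_boundary

    def test_recovers_growth_optimum(self, fix_params):
        res = engine.numeric_oracle_maximize(
            lambda m: model.net_specific_growth(1.0, m, fix_params),
            (0.0, fix_params.m_e_max),
        )
        assert res.argmax == pytest.approx(4.0, rel=1e-6)


class TestInstantaneousOptimum:
    def test_hand_value(self, fix_params):
        opt = engine.maximize_instantaneous(1.0, fix_params)
        assert opt.value == pytest.approx(4.0, rel=1e-12)
        assert opt.objective_value == pytest.approx(8.0, rel=1e-12)
        assert opt.feasible
        assert opt.gradient_residual < 1e-8
        assert opt.second_derivative < 0.0

    def test_below_threshold_clamps_to_zero(self, fix_params):
        thr = model.feasibility_threshold(fix_params)
        opt = engine.maximize_instantaneous(0.5 * thr, fix_params)
        assert opt.value == 0.0
        assert not opt.feasible

    def test_closed_form_zero_at_threshold(self, fix_params):
        thr = model.feasibility_threshold(fix_params)
        with pytest.raises(engine.InfeasibleTraitError):
            engine.instantaneous_closed_form(thr, fix_params)
        # just above the threshold the optimum is tiny and positive
        assert 0.0 < engine.instantaneous_closed_form(thr * (1 + 1e-9), fix_params) < 1e-6

    def test_matches_grid_oracle_on_random_sets(self, random_fixtures):
        rng = np.random.default_rng(42)
        for p in random_fixtures:
            x_s = _feasible_soc(p, rng)
            closed = engine.instantaneous_closed_form(x_s, p)
            oracle = engine.numeric_oracle_maximize(
                lambda m: model.net_specific_growth(x_s, m, p),
                (0.0, p.m_e_max), grid_size=400,
            )
            assert closed == pytest.approx(oracle.argmax, rel=1e-6)

    def test_optimum_decreases_with_soc_at_high_soc(self, baseline):
        # beyond the interior peak the optimum decays toward its asymptote
        xs = np.linspace(60.0, 400.0, 40)
        vals = [engine.instantaneous_closed_form(x, baseline) for x in xs]
        assert np.all(np.diff(vals) < 0.0)


class TestEquilibriumOptimum:
    def test_matches_independent_nested_oracle(self, baseline):
        opt = engine.maximize_equilibrium(baseline)
        oracle = engine.numeric_oracle_maximize(
            lambda m: engine.equilibrium_objective(m, baseline),
            (0.0, baseline.m_e_max), grid_size=501, spacing="linear",
        )
        assert opt.value == pytest.approx(oracle.argmax, rel=1e-6)
        assert opt.feasible and opt.context > 0.0

    def test_below_instantaneous_at_own_equilibrium(self, baseline):
        opt = engine.maximize_equilibrium(baseline)
        inst = engine.instantaneous_closed_form(opt.context, baseline)
        assert opt.value <= inst

    def test_converges_to_instantaneous_at_large_input(self, baseline):
        p = baseline.replace(input_rate=300.0)
        opt = engine.maximize_equilibrium(p)
        inst = engine.instantaneous_closed_form(opt.context, p)
        assert opt.value == pytest.approx(inst, rel=0.01)

    def test_infeasible_when_input_too_small(self, baseline):
        p = baseline.replace(input_rate=1e-5)
        opt = engine.maximize_equilibrium(p)
        assert not opt.feasible and opt.value == 0.0


class TestInvasionFitness:
    def test_neutral_on_diagonal(self, random_fixtures):
        rng = np.random.default_rng(3)
        for p in random_fixtures:
            m = rng.uniform(0.05, 0.8) * p.m_e_max
            assert abs(engine.invasion_fitness(m, m, p)) < 1e-10

    def test_hand_value(self, fix_params):
        s = engine.invasion_fitness(4.0, 9.0, fix_params, PowerLawKernel(0.5))
        assert s == pytest.approx(-2.0, rel=1e-12)

    def test_without_competition_enzymes_are_pure_cost(self, fix_params):
        k0 = PowerLawKernel(0.0)
        for m_em in (2.0, 4.0, 6.0):
            s = engine.invasion_fitness(4.0, m_em, fix_params, k0)
            assert s == pytest.approx(-fix_params.eps_e * (m_em - 4.0), rel=1e-10)

    def test_requires_resident_equilibrium(self, fix_params):
        p = fix_params.replace(input_rate=0.0)
        with pytest.raises(engine.ResidentEquilibriumError):
            engine.invasion_fitness(4.0, 4.5, p)


class TestSelectionGradient:
    def test_zero_at_hand_derived_singular_point(self, fix_params):
        assert abs(engine.selection_gradient(4.0, fix_params)) < 1e-8

    def test_pure_cost_without_competition(self, fix_params):
        k0 = PowerLawKernel(0.0)
        for m in (1.0, 4.0, 7.0):
            g = engine.selection_gradient(m, fix_params, k0)
            assert g == pytest.approx(-fix_params.eps_e, rel=1e-8)

    def test_analytic_agrees_with_finite_difference(self, random_fixtures):
        rng = np.random.default_rng(11)
        for p in random_fixtures:
            m = rng.uniform(0.05, 0.8) * p.m_e_max
            fd = engine.selection_gradient(m, p, method="fd")
            an = engine.selection_gradient(m, p, method="analytic")
            assert fd == pytest.approx(an, rel=1e-6, abs=1e-10)


class TestSingularStrategy:
    def test_hand_derived_css(self, fix_params):
        ss = engine.find_singular_strategy(fix_params)
        assert ss is not None
        assert ss.value == pytest.approx(4.0, rel=1e-10)
        assert ss.gradient_residual < 1e-10
        assert ss.ess_curvature == pytest.approx(-0.25, rel=1e-4)
        assert ss.is_ess and ss.is_convergence_stable and ss.is_css

    def test_superlinear_advantage_is_never_ess(self, fix_params):
        ss = engine.find_singular_strategy(fix_params, PowerLawKernel(1.3))
        if ss is not None:
            assert not ss.is_ess
            assert ss.ess_curvature > 0.0

    def test_no_interior_strategy_without_competition(self, fix_params):
        assert engine.find_singular_strategy(fix_params, PowerLawKernel(0.0)) is None

    def test_substitution_sequence_converges_to_css(self, fix_params):
        """Repeated successful invasions from a perturbed resident walk the
        trait monotonically toward the singular strategy."""
        for m in (3.0, 5.5):
            traits = [m]
            for _ in range(200):
                step = 1.02 if engine.selection_gradient(traits[-1], fix_params) > 0 else 1 / 1.02
                cand = traits[-1] * step
                if engine.invasion_fitness(traits[-1], cand, fix_params) <= 0:
                    break
                traits.append(cand)
            gaps = np.abs(np.array(traits) - 4.0)
            # monotone approach until within one mutation step of the CSS,
            # where fixed-size steps can only straddle it
            k = int(np.argmax(gaps < 0.1)) or len(gaps)
            assert np.all(np.diff(gaps[: k + 1]) < 0.0)
            assert gaps.min() < 0.1

    def test_css_flag_consistency(self, random_fixtures):
        for p in random_fixtures[:10]:
            ss = engine.find_singular_strategy(p)
            if ss is not None:
                assert ss.is_css == (ss.is_ess and ss.is_convergence_stable)


class TestInvasionSimulation:
    def test_neutral_for_identical_traits(self, fix_params):
        out = engine.simulate_invasion(4.0, 4.0, 1e-4, fix_params)
        assert out.outcome == "neutral"
        assert abs(out.per_capita_growth) < 1e-8

    def test_mutant_above_css_is_repelled(self, fix_params):
        out = engine.simulate_invasion(4.0, 4.5, 1e-4, fix_params)
        assert out.outcome == "repelled"
        assert engine.invasion_fitness(4.0, 4.5, fix_params) < 0.0

    def test_directional_selection_toward_css(self, fix_params):
        # resident below the singular point at 4: a mutant between them invades
        out = engine.simulate_invasion(3.5, 3.8, 1e-4, fix_params)
        assert out.outcome == "invades"
        assert engine.selection_gradient(3.5, fix_params) > 0.0

    def test_sign_agreement_with_invasion_fitness(self, random_fixtures):
        rng = np.random.default_rng(5)
        for p in random_fixtures[:8]:
            m_er = rng.uniform(0.2, 0.6) * p.m_e_max
            m_em = m_er * rng.uniform(0.85, 1.15)
            s = engine.invasion_fitness(m_er, m_em, p)
            out = engine.simulate_invasion(m_er, m_em, 1e-4, p)
            if abs(s) > 1e-7:
                assert out.outcome == ("invades" if s > 0 else "repelled")

    def test_rejects_large_mutation_or_common_mutant(self, fix_params):
        with pytest.raises(ValueError, match="mutant_fraction"):
            engine.simulate_invasion(4.0, 4.1, 0.1, fix_params)
        with pytest.raises(ValueError, match="m_em"):
            engine.simulate_invasion(4.0, 9.0, 1e-4, fix_params)


class TestGradientAdaptation:
    def test_stationary_at_self_consistent_optimum(self, baseline):
        from soceeo import experiments

        m_star, x_star = experiments.self_consistent_instantaneous(baseline)
        traj = engine.gradient_adaptation(
            model.SystemState(x_star, 0.0, 0.0), m_star, 10.0, baseline, (0.0, 50.0)
        )
        assert np.abs(traj["m_e"] - m_star).max() < 1e-4 * m_star
        assert np.abs(traj["x_s"] - x_star).max() < 1e-6 * x_star

    def test_fast_adaptation_tracks_instantaneous_optimum(self, baseline):
        # trait dynamics ~1000x faster than the SOC relaxation rate
        x0 = 40.0
        traj = engine.gradient_adaptation(
            model.SystemState(x0, 0.0, 0.0), 0.01, 100.0, baseline, (0.0, 80.0)
        )
        tail = traj[traj["t"] > 20.0]
        for _, row in tail.iloc[::20].iterrows():
            inst = engine.instantaneous_closed_form(row["x_s"], baseline)
            assert row["m_e"] == pytest.approx(inst, rel=0.01)

    def test_slow_adaptation_recovers_fixed_trait(self, baseline):
        traj = engine.gradient_adaptation(
            model.SystemState(40.0, 0.0, 0.0), 0.05, 1e-8, baseline, (0.0, 50.0)
        )
        assert np.abs(traj["m_e"] - 0.05).max() < 1e-4 * 0.05


class TestCompetitionKernel:
    @settings(max_examples=60, derandomize=True)
    @given(m=st.floats(1e-6, 1e3), c0=st.floats(0.0, 3.0))
    def test_diagonal_is_exactly_one(self, m, c0):
        assert PowerLawKernel(c0)(m, m) == 1.0

    def test_monotonicity_around_diagonal(self):
        k = PowerLawKernel(0.5)
        assert k(4.0, 5.0) > 1.0 > k(4.0, 3.0)
        assert k(5.0, 4.5) < k(4.0, 4.5)
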