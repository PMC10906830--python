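"""Reputation update map, aggregates, and equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereorecip.core import (
    PopulationStructure,
    Strategy,
    StrategyMix,
    assessment_probabilities,
    default_params,
    named_norm,
)
from stereorecip.reputation import (
    ReputationState,
    SolverSettings,
    reputation_update_map,
    solve_reputation_equilibrium,
    view_aggregates,
)

from conftest import scalar_fixed_point


def uniform_state(n, K, g_ind, g_st):
    return ReputationState(
        np.full((n, K, K), g_ind, dtype=float), np.full((K, K), g_st, dtype=float)
    )


class TestViewAggregates:
    def test_all_good_state_gives_unit_aggregates(self):
        mix = StrategyMix.monomorphic_disc(0.3)
        struct = PopulationStructure()
        agg = view_aggregates(uniform_state(1, 2, 1.0, 1.0), mix, struct)
        for arr in (agg.g_grp, agg.g_dot, agg.g_star, agg.g_a1, agg.g_a2, agg.g_a3, agg.g_a4):
            assert np.allclose(arr, 1.0)

    def test_uniform_state_factorizes(self):
        g, s = 0.7, 0.4
        mix = StrategyMix.monomorphic_disc(0.5)
        agg = view_aggregates(uniform_state(1, 2, g, s), mix, PopulationStructure())
        assert np.allclose(agg.g_a1, g * g)
        assert np.allclose(agg.g_a2, g * s)
        assert np.allclose(agg.g_a3, s * g)
        assert np.allclose(agg.g_a4, s * s)

    def test_population_view_is_group_weighted_mean(self):
        mix = StrategyMix.monomorphic_disc(0.0)
        state = uniform_state(1, 2, 0.5, 0.5)
        state.g_ind[0, 0, :] = 0.9
        state.g_ind[0, 1, :] = 0.5
        agg = view_aggregates(state, mix, PopulationStructure())
        assert np.allclose(agg.g_dot, 0.7)

    def test_aggregate_bounds(self):
        rng = np.random.default_rng(7)
        mix = StrategyMix([Strategy("ALLC"), Strategy("DISC", 0.6)], [0.3, 0.7])
        state = ReputationState(rng.random((2, 2, 2)), rng.random((2, 2)))
        agg = view_aggregates(state, mix, PopulationStructure())
        for arr in (agg.g_a1, agg.g_a2, agg.g_a3, agg.g_a4):
            assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_dimension_mismatch_raises(self):
        mix = StrategyMix.monomorphic_disc(0.0)
        state = uniform_state(2, 2, 0.5, 0.5)  # two strategy rows, one strategy
        with pytest.raises(ValueError, match="dimension mismatch"):
            view_aggregates(state, mix, PopulationStructure())


class TestUpdateMap:
    def test_error_free_all_good_is_fixed_point(self):
        params = default_params(u_a=0.0, u_e=0.0)
        mix = StrategyMix.monomorphic_disc(0.0)
        state = uniform_state(1, 2, 1.0, 1.0)
        new = reputation_update_map(state, mix, params)
        assert np.allclose(new.g_ind, 1.0)
        assert np.allclose(new.g_st, 1.0)

    @pytest.mark.parametrize("scale", ["private", "group-wise", "public"])
    def test_alld_row_mixes_P_GD_P_BD(self, scale):
        params = default_params(individual_scale=scale, stereotype_scale=scale)
        mix = StrategyMix.monomorphic(Strategy("ALLD"))
        for g in (0.2, 0.5, 0.8):
            new = reputation_update_map(uniform_state(1, 2, g, g), mix, params)
            assert np.allclose(new.g_ind, g * 0.02 + (1 - g) * 0.98)

    def test_allc_row_mixes_eps(self):
        params = default_params()
        mix = StrategyMix.monomorphic(Strategy("ALLC"))
        eps = 0.9608
        for g in (0.3, 0.6):
            new = reputation_update_map(uniform_state(1, 2, g, g), mix, params)
            assert np.allclose(new.g_ind, g * eps + (1 - g) * (1 - eps))


class TestEquilibrium:
    def test_alld_and_allc_equilibrate_at_half(self):
        for kind in ("ALLD", "ALLC"):
            mix = StrategyMix.monomorphic(Strategy(kind))
            eq = solve_reputation_equilibrium(mix, default_params())
            assert np.allclose(eq.state.g_ind, 0.5, atol=1e-8)

    def test_disc_public_closed_form(self):
        mix = StrategyMix.monomorphic_disc(0.0)
        eq = solve_reputation_equilibrium(mix, default_params())
        assert np.allclose(eq.state.g_ind, 0.98 / 1.0192, atol=1e-8)

    def test_disc_private_matches_bisection_oracle(self):
        # the monomorphic private system reduces to one scalar equation in g
        P = assessment_probabilities(named_norm("SternJudging"), 0.02, 0.02)

        def update(g):
            return (
                g * g * P.P_GC
                + (g - g * g) * (P.P_GD + P.P_BC)
                + (1 - g) ** 2 * P.P_BD
            )

        oracle = scalar_fixed_point(update)
        params = default_params(individual_scale="private", stereotype_scale="private")
        mix = StrategyMix.monomorphic_disc(0.0)
        eq = solve_reputation_equilibrium(mix, params)
        # individual reputations all equal the scalar root
        assert np.allclose(eq.state.g_ind, oracle, atol=1e-8)

    def test_residual_reported_below_tolerance(self):
        mix = StrategyMix.monomorphic_disc(0.4)
        settings_ = SolverSettings(tol=1e-10)
        eq = solve_reputation_equilibrium(mix, default_params(), settings_)
        assert eq.residual < 1e-10

    def test_neutral_family_flagged_for_error_free_allc(self):
        params = default_params(u_a=0.0, u_e=0.0)
        mix = StrategyMix.monomorphic(Strategy("ALLC"))
        eq = solve_reputation_equilibrium(mix, params)
        assert eq.neutral
        assert np.allclose(eq.state.g_ind, 0.5)  # returns the initialization

    def test_warm_start_deterministic(self):
        mix = StrategyMix.monomorphic_disc(0.6)
        params = default_params(individual_scale="group-wise")
        eq1 = solve_reputation_equilibrium(mix, params)
        eq2 = solve_reputation_equilibrium(mix, params)
        assert np.array_equal(eq1.state.g_ind, eq2.state.g_ind)


class TestEquilibriumProperties:
    @given(
        p=st.floats(0.0, 1.0),
        f_allc=st.floats(0.0, 1.0),
        f_alld=st.floats(0.0, 1.0),
        u_a=st.floats(0.01, 0.4),
        u_e=st.floats(0.01, 0.4),
        norm_name=st.sampled_from(["SternJudging", "SimpleStanding", "Scoring", "Shunning"]),
        ind=st.sampled_from(["private", "group-wise", "public"]),
        stt=st.sampled_from(["private", "group-wise", "public"]),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_random_draws_converge_in_bounds(self, p, f_allc, f_alld, u_a, u_e, norm_name, ind, stt):
        total = 1.0 + f_allc + f_alld
        mix = StrategyMix(
            [Strategy("DISC", p), Strategy("ALLC"), Strategy("ALLD")],
            [1.0 / total, f_allc / total, f_alld / total],
        )
        params = default_params(norm_name, ind, stt, u_a=u_a, u_e=u_e)
        settings_ = SolverSettings(tol=1e-10)
        eq = solve_reputation_equilibrium(mix, params, settings_)
        assert eq.residual < 1e-10
        assert np.all(eq.state.g_ind >= 0.0) and np.all(eq.state.g_ind <= 1.0)
        assert np.all(eq.state.g_st >= 0.0) and np.all(eq.state.g_st <= 1.0)

    def test_group_exchange_symmetry(self):
        params = default_params(individual_scale="group-wise", stereotype_scale="private")
        mix = StrategyMix([Strategy("DISC", 0.35), Strategy("ALLD")], [0.8, 0.2])
        eq = solve_reputation_equilibrium(mix, params)
        perm = [1, 0]
        g = eq.state.g_ind
        assert np.allclose(g, g[:, perm][:, :, perm], atol=1e-9)
        s = eq.state.g_st
        assert np.allclose(s, s[perm][:, perm], atol=1e-9)

    def test_public_views_are_observer_independent(self):
        params = default_params(individual_scale="public", stereotype_scale="public")
        mix = StrategyMix([Strategy("DISC", 0.7), Strategy("ALLC")], [0.6, 0.4])
        eq = solve_reputation_equilibrium(mix, params)
        assert np.allclose(eq.state.g_ind[:, :, 0], eq.state.g_ind[:, :, 1], atol=1e-9)
        assert np.allclose(eq.state.g_st[:, 0], eq.state.g_st[:, 1], atol=1e-9)

    def test_error_free_public_stern_judging_keeps_all_good(self):
        params = default_params(u_a=0.0, u_e=0.0)
        for p in (0.0, 0.5, 1.0):
            mix = StrategyMix.monomorphic_disc(p)
            init = uniform_state(1, 2, 1.0, 1.0)
            eq = solve_reputation_equilibrium(mix, params, init_state=init)
            assert np.allclose(eq.state.g_ind, 1.0)
            assert np.allclose(eq.state.g_st, 1.0)
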