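"""Invasion fitness, selection gradients, singular points, sweeps, PIPs."""

import numpy as np
import pytest

from stereorecip.core import Strategy, StrategyMix, default_params
from stereorecip.adaptive import (
    bifurcation_sweep,
    classify_regime,
    find_singular_points,
    invasion_fitness,
    pip_grid,
    selection_gradient,
)
from stereorecip.payoffs import strategy_fitness
from stereorecip.reputation import solve_reputation_equilibrium


class TestInvasionFitness:
    def test_identical_types_are_neutral(self, sj_combo):
        for p in (0.0, 0.4, 1.0):
            res = invasion_fitness(p, p, sj_combo.with_(eta=0.3))
            assert abs(res.fitness_diff) < 1e-10

    def test_private_private_neutral_without_access_cost(self, sj_private):
        # with free individual reputations, stereotyping is neither favored
        # nor disfavored under fully private monitoring
        for p_R in (0.1, 0.5, 0.9):
            for p_Q in (0.2, 0.8):
                res = invasion_fitness(p_R, p_Q, sj_private.with_(eta=0.0))
                assert abs(res.fitness_diff) < 1e-9

    def test_public_public_lower_propensity_invades_at_moderate_cost(self, sj_public):
        res = invasion_fitness(0.1, 0.2, sj_public.with_(eta=0.3))
        assert res.fitness_diff < 0.0
        res = invasion_fitness(0.2, 0.1, sj_public.with_(eta=0.3))
        assert res.fitness_diff > 0.0

    def test_rare_invader_limit_matches_small_frequency_solve(self, sj_public):
        # independent oracle: embed the invader at f_Q = 1e-6 and compare signs
        # and magnitude of the fitness difference
        params = sj_public.with_(eta=0.3)
        p_R, p_Q = 0.1, 0.2
        exact = invasion_fitness(p_R, p_Q, params).fitness_diff
        mix = StrategyMix(
            [Strategy("DISC", p_R), Strategy("DISC", p_Q)], [1 - 1e-6, 1e-6]
        )
        eq = solve_reputation_equilibrium(mix, params)
        table = strategy_fitness(mix, eq.state, params)
        fit = table.aggregate(params.nu)
        approx = fit[1] - fit[0]
        assert np.sign(approx) == np.sign(exact)
        assert approx == pytest.approx(exact, rel=1e-3)

    def test_background_frequencies_validated(self, sj_public):
        with pytest.raises(ValueError, match="background"):
            invasion_fitness(0.2, 0.3, sj_public, background=[(Strategy("ALLD"), 1.2)])


class TestSelectionGradient:
    def test_zero_everywhere_private_no_cost(self, sj_private):
        for p in np.linspace(0.1, 0.9, 5):
            assert abs(selection_gradient(p, sj_private.with_(eta=0.0))) < 1e-8

    def test_private_gradient_equals_eta(self, sj_private):
        # under fully private monitoring the only systematic payoff difference
        # between nearby propensities is the access-cost saving
        for eta in (0.1, 0.2):
            g = selection_gradient(0.5, sj_private.with_(eta=eta))
            assert g == pytest.approx(eta, abs=1e-6)

    def test_antisymmetry_near_diagonal(self, sj_public):
        params = sj_public.with_(eta=0.3)
        h = 1e-3
        p = 0.4
        fwd = invasion_fitness(p, p + h, params).fitness_diff
        bwd = invasion_fitness(p + h, p, params).fitness_diff
        assert fwd == pytest.approx(-bwd, abs=5e-3 * max(abs(fwd), 1e-6) + 1e-9)


class TestSingularPoints:
    def test_public_public_eta03_only_p0_attracts(self, sj_public):
        pts = find_singular_points(sj_public.with_(eta=0.3), annotate=False)
        attractors = [pt for pt in pts if pt.attractive]
        assert len(attractors) == 1
        assert attractors[0].p_star == 0.0
        assert classify_regime(pts) == "p0_only"

    def test_public_public_eta035_bistable_with_high_interior_attractor(self, sj_public):
        pts = find_singular_points(sj_public.with_(eta=0.35), annotate=False)
        interior_attr = [pt for pt in pts if pt.attractive and not pt.boundary]
        assert len(interior_attr) == 1
        assert interior_attr[0].p_star == pytest.approx(0.85, abs=0.03)
        # separated from p=0 by a repeller
        repellers = [pt for pt in pts if not pt.attractive and not pt.boundary]
        assert any(0 < r.p_star < interior_attr[0].p_star for r in repellers)
        assert classify_regime(pts) == "bistable"

    def test_groupwise_bistability_between_extremes(self):
        params = default_params(
            individual_scale="group-wise", stereotype_scale="group-wise", eta=0.3
        )
        pts = find_singular_points(params, annotate=False)
        p0 = next(pt for pt in pts if pt.boundary and pt.p_star == 0.0)
        p1 = next(pt for pt in pts if pt.boundary and pt.p_star == 1.0)
        assert p0.attractive and p1.attractive
        interior = [pt for pt in pts if not pt.boundary]
        assert any(not pt.attractive for pt in interior)

    def test_annotation_attaches_cooperation(self, sj_public):
        pts = find_singular_points(sj_public.with_(eta=0.3), resolution=21, annotate=True)
        for pt in pts:
            assert 0.0 <= pt.cooperation <= 1.0


class TestSweepAndPip:
    def test_private_attractor_is_one_for_positive_costs(self, sj_private):
        branch = bifurcation_sweep(
            sj_private, "eta", np.array([0.05, 0.1, 0.2]), annotate=False, resolution=51
        )
        for pts in branch.points:
            attractors = [pt.p_star for pt in pts if pt.attractive]
            assert attractors == [1.0]

    def test_private_individual_public_stereotype_gradual_rise(self):
        # stable stereotyping level rises from 0 toward 1 with access cost,
        # passing through interior attractors
        params = default_params(individual_scale="private", stereotype_scale="public")
        etas = np.array([0.0, 0.1, 0.2, 0.3, 0.5])
        branch = bifurcation_sweep(params, "eta", etas, annotate=False, resolution=51)
        levels = []
        for pts in branch.points:
            attractors = [pt.p_star for pt in pts if pt.attractive]
            assert len(attractors) >= 1
            levels.append(max(attractors))
        assert all(b >= a - 1e-6 for a, b in zip(levels, levels[1:]))
        assert any(0.05 < lv < 0.95 for lv in levels)

    def test_alld_background_keeps_regime_structure(self, sj_public):
        background = [(Strategy("ALLD"), 0.2)]
        pts_low = find_singular_points(
            sj_public.with_(eta=0.1), background, resolution=51, annotate=False
        )
        assert classify_regime(pts_low) == "p0_only"
        pts_high = find_singular_points(
            sj_public.with_(eta=0.9), background, resolution=51, annotate=False
        )
        assert any(pt.attractive and pt.p_star > 0.5 for pt in pts_high)

    def test_pip_diagonal_false_and_gradient_consistency(self, sj_public):
        params = sj_public.with_(eta=0.3)
        grid, matrix = pip_grid(params, resolution=11)
        assert not matrix.diagonal().any()
        # near-diagonal invasion direction matches the gradient sign
        for r in range(1, len(grid) - 1):
            g = selection_gradient(grid[r], params)
            if g < -1e-8:
                assert matrix[r, r - 1]
                assert not matrix[r, r + 1]
            elif g > 1e-8:
                assert matrix[r, r + 1]
                assert not matrix[r, r - 1]

    def test_pip_all_false_private_free_access(self, sj_private):
        _, matrix = pip_grid(sj_private.with_(eta=0.0), resolution=6)
        assert not matrix.any()
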