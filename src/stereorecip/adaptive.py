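"""Adaptive dynamics of the stereotype-use propensity p.

A resident population of discriminators with propensity ``p_R`` (optionally
alongside a fixed background of other strategies, e.g. 20% unconditional
defectors) sets the reputation environment.  A rare invading discriminator
with propensity ``p_Q`` does not perturb that environment: her individual
reputation is an explicit function of the resident aggregates, so invasion
fitness can be computed exactly at invader frequency zero.  Selection
gradients, singular points, and bifurcation sweeps over model parameters are
built on top of that primitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ModelParams, Strategy, StrategyMix
from .payoffs import CooperationSummary, cooperation_rates, strategy_fitness
from .reputation import (
    EquilibriumResult,
    ReputationState,
    SolverSettings,
    solve_reputation_equilibrium,
)

__all__ = [
    "InvasionResult",
    "SingularPoint",
    "BifurcationBranch",
    "invasion_fitness",
    "selection_gradient",
    "find_singular_points",
    "bifurcation_sweep",
    "pip_grid",
    "GRADIENT_STEP",
]

#: Finite-difference step for the selection gradient (central differences;
#: one-sided steps of the same size at the boundaries of [0, 1]).
GRADIENT_STEP = 1e-3


@dataclass
class InvasionResult:
    """Invasion fitness of a rare mutant propensity against a resident."""

    p_R: float
    p_Q: float
    fitness_diff: float  # sum_J nu_J (Pi_Q^J - Pi_R^J) at f_Q -> 0
    background: tuple[tuple[str, float, float], ...] = ()  # (kind, p, f)


@dataclass
class SingularPoint:
    """A root of the selection gradient (or a boundary of [0, 1])."""

    p_star: float
    attractive: bool
    boundary: bool = False
    degenerate: bool = False  # gradient touches zero without a sign change
    cooperation: float = float("nan")
    ingroup_gap: float = float("nan")


@dataclass
class BifurcationBranch:
    """Singular points along a one-parameter sweep."""

    parameter: str
    grid: np.ndarray
    points: list[list[SingularPoint]] = field(default_factory=list)
    regimes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for value, pts, regime in zip(self.grid, self.points, self.regimes):
            for pt in pts:
                rows.append(
                    {
                        self.parameter: float(value),
                        "p_star": pt.p_star,
                        "attractive": pt.attractive,
                        "boundary": pt.boundary,
                        "cooperation": pt.cooperation,
                        "ingroup_gap": pt.ingroup_gap,
                        "regime": regime,
                    }
                )
        return pd.DataFrame(rows)


def _background_strategies(
    background: list[tuple[Strategy, float]] | None,
) -> tuple[list[Strategy], list[float]]:
    if not background:
        return [], []
    strategies = [s for s, _ in background]
    freqs = [float(f) for _, f in background]
    if any(f < 0 for f in freqs) or sum(freqs) >= 1.0:
        raise ValueError("background frequencies must be non-negative and sum to < 1")
    return strategies, freqs


class _ResidentEnvironment:
    """Resident(+background) equilibrium with zero-frequency invader slots.

    The invader is appended to the strategy set with frequency exactly zero:
    she contributes nothing to the aggregates, while her own reputation row is
    still produced by the update map, so the fixed point simultaneously gives
    the resident environment and the invader's reputation embedded in it.
    """

    def __init__(
        self,
        p_R: float,
        params: ModelParams,
        background: list[tuple[Strategy, float]] | None = None,
        settings: SolverSettings | None = None,
        warm: ReputationState | None = None,
    ):
        bg_strats, bg_freqs = _background_strategies(background)
        f_R = 1.0 - sum(bg_freqs)
        self.p_R = float(p_R)
        self.params = params
        self.resident_index = 0
        self.strategies = [Strategy("DISC", p_R)] + bg_strats
        self.freqs = [f_R] + bg_freqs
        self.settings = settings
        self.mix = StrategyMix(self.strategies, self.freqs)
        self.eq: EquilibriumResult = solve_reputation_equilibrium(
            self.mix, params, settings, init_state=warm
        )

    def invader_fitness_diffs(self, p_Q_values: np.ndarray) -> np.ndarray:
        """Invasion fitness for several mutant propensities at once."""
        p_Q_values = np.atleast_1d(np.asarray(p_Q_values, dtype=float))
        invaders = [Strategy("DISC", float(q)) for q in p_Q_values]
        full_mix = StrategyMix(
            self.strategies + invaders, self.freqs + [0.0] * len(invaders)
        )
        # Zero-frequency strategies do not feed back on the aggregates, so the
        # resident equilibrium extends to the full mix after one update pass.
        n_res = len(self.strategies)
        K = self.params.K
        g_ind = np.empty((full_mix.n, K, K))
        g_ind[:n_res] = self.eq.state.g_ind
        g_ind[n_res:] = 0.5
        state = ReputationState(g_ind, self.eq.state.g_st.copy())
        from .reputation import reputation_update_map

        state = reputation_update_map(state, full_mix, self.params)
        # resident rows are already at the fixed point; invader rows are now
        # exact functions of the converged aggregates
        state.g_ind[:n_res] = self.eq.state.g_ind
        state.g_st[:, :] = self.eq.state.g_st

        table = strategy_fitness(full_mix, state, self.params)
        nu = self.params.nu
        fitness = table.aggregate(nu)
        resident_fitness = fitness[self.resident_index]
        return fitness[n_res:] - resident_fitness


def invasion_fitness(
    p_R: float,
    p_Q: float,
    params: ModelParams,
    background: list[tuple[Strategy, float]] | None = None,
    settings: SolverSettings | None = None,
) -> InvasionResult:
    """Growth rate of a rare ``p_Q`` discriminator in a ``p_R`` resident.

    Positive values mean the mutant invades.  Identical propensities are
    exactly neutral.
    """
    env = _ResidentEnvironment(p_R, params, background, settings)
    diff = float(env.invader_fitness_diffs(np.array([p_Q]))[0])
    bg = tuple((s.kind, s.p, f) for (s, f) in (background or []))
    return InvasionResult(p_R=float(p_R), p_Q=float(p_Q), fitness_diff=diff, background=bg)


def selection_gradient(
    p: float,
    params: ModelParams,
    background: list[tuple[Strategy, float]] | None = None,
    h: float = GRADIENT_STEP,
    settings: SolverSettings | None = None,
    _env: "_ResidentEnvironment | None" = None,
) -> float:
    """d/dp_Q of invasion fitness at p_Q = p_R = p (finite differences).

    Central differences in the interior; one-sided differences of step ``h``
    at the boundaries.  The resident equilibrium is solved once and reused
    for both mutant evaluations.
    """
    env = _env if _env is not None else _ResidentEnvironment(p, params, background, settings)
    lo = max(0.0, p - h)
    hi = min(1.0, p + h)
    diffs = env.invader_fitness_diffs(np.array([lo, hi]))
    return float((diffs[1] - diffs[0]) / (hi - lo))


def _gradient_on_grid(
    grid: np.ndarray,
    params: ModelParams,
    background,
    settings: SolverSettings | None,
    warm: ReputationState | None = None,
) -> tuple[np.ndarray, ReputationState | None]:
    grads = np.empty_like(grid)
    for k, p in enumerate(grid):
        env = _ResidentEnvironment(float(p), params, background, settings, warm=warm)
        warm = env.eq.state
        grads[k] = selection_gradient(float(p), params, background, _env=env)
    return grads, warm


def _annotate(point: SingularPoint, params: ModelParams, background, settings) -> SingularPoint:
    bg_strats, bg_freqs = _background_strategies(background)
    mix = StrategyMix(
        [Strategy("DISC", point.p_star)] + bg_strats, [1.0 - sum(bg_freqs)] + bg_freqs
    )
    eq = solve_reputation_equilibrium(mix, params, settings)
    summary: CooperationSummary = cooperation_rates(mix, eq.state, params)
    point.cooperation = summary.overall
    gap = summary.in_group - summary.out_group
    point.ingroup_gap = gap if np.isfinite(gap) else 0.0
    return point


def find_singular_points(
    params: ModelParams,
    background: list[tuple[Strategy, float]] | None = None,
    resolution: int = 101,
    settings: SolverSettings | None = None,
    annotate: bool = True,
    p_tol: float = 1e-4,
    zero_tol: float = 1e-9,
) -> list[SingularPoint]:
    """Locate and classify singular points of the adaptive dynamics of p.

    The selection gradient is evaluated on a uniform grid over [0, 1]; each
    interior sign change is bracketed and bisected to ``p_tol``.  A sign
    change from + to - is an attractive (convergence-stable) singular point,
    - to + a repulsive one.  The boundaries are classified from the adjacent
    gradient sign: p=0 is attractive iff the gradient is negative near 0, and
    p=1 iff it is positive near 1.  Gradients within ``zero_tol`` of zero are
    treated as neutral; a grid on which the gradient is neutral everywhere
    yields no singular points (every propensity drifts).
    """
    if resolution < 3:
        raise ValueError("resolution must be at least 3")
    grid = np.linspace(0.0, 1.0, resolution)
    grads, _ = _gradient_on_grid(grid, params, background, settings)

    sign = np.where(grads > zero_tol, 1, np.where(grads < -zero_tol, -1, 0))
    points: list[SingularPoint] = []

    if np.all(sign == 0):
        return points

    # boundary classification from the nearest non-neutral gradient
    def first_sign(seq):
        for s in seq:
            if s != 0:
                return s
        return 0

    s0 = first_sign(sign)
    s1 = first_sign(sign[::-1])
    points.append(SingularPoint(p_star=0.0, attractive=(s0 < 0), boundary=True))
    points.append(SingularPoint(p_star=1.0, attractive=(s1 > 0), boundary=True))

    def grad_at(p: float) -> float:
        return selection_gradient(float(p), params, background, settings=settings)

    # interior sign changes: bisect each bracket
    idx = np.nonzero(sign)[0]
    for a_i, b_i in zip(idx[:-1], idx[1:]):
        sa, sb = sign[a_i], sign[b_i]
        if sa == sb:
            continue
        lo, hi = grid[a_i], grid[b_i]
        glo = grads[a_i]
        while hi - lo > p_tol:
            mid = 0.5 * (lo + hi)
            gm = grad_at(mid)
            if np.sign(gm) == np.sign(glo):
                lo, glo = mid, gm
            else:
                hi = mid
        p_star = 0.5 * (lo + hi)
        points.append(SingularPoint(p_star=float(p_star), attractive=(sa > 0 and sb < 0)))

    # gradient touching zero without sign change -> degenerate, flagged only
    for k in range(1, resolution - 1):
        if sign[k] == 0 and sign[k - 1] != 0 and sign[k + 1] == sign[k - 1]:
            points.append(
                SingularPoint(p_star=float(grid[k]), attractive=False, degenerate=True)
            )

    points.sort(key=lambda pt: pt.p_star)
    if annotate:
        points = [
            _annotate(pt, params, background, settings) if not pt.degenerate else pt
            for pt in points
        ]
    return points


def classify_regime(points: list[SingularPoint]) -> str:
    """Regime label for a set of singular points.

    ``neutral``: no selection on p anywhere; ``p0_only``: p=0 is the only
    attractor; ``bistable``: p=0 attractive alongside a second attractor;
    ``high_only``: attractors exist but p=0 is not among them.
    """
    if not points:
        return "neutral"
    attractors = [pt for pt in points if pt.attractive]
    p0_attracting = any(pt.boundary and pt.p_star == 0.0 and pt.attractive for pt in points)
    if p0_attracting and len(attractors) == 1:
        return "p0_only"
    if p0_attracting:
        return "bistable"
    return "high_only"


def bifurcation_sweep(
    params: ModelParams,
    parameter: str = "eta",
    grid: np.ndarray | None = None,
    background: list[tuple[Strategy, float]] | None = None,
    resolution: int = 101,
    settings: SolverSettings | None = None,
    annotate: bool = True,
) -> BifurcationBranch:
    """Singular points as a function of one model parameter (default eta)."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    branch = BifurcationBranch(parameter=parameter, grid=grid)
    for value in grid:
        swept = params.with_(**{parameter: float(value)})
        pts = find_singular_points(
            swept, background, resolution=resolution, settings=settings, annotate=annotate
        )
        branch.points.append(pts)
        branch.regimes.append(classify_regime(pts))
    return branch


def pip_grid(
    params: ModelParams,
    resolution: int = 21,
    background: list[tuple[Strategy, float]] | None = None,
    settings: SolverSettings | None = None,
    zero_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise invasibility plot: can mutant p_Q invade resident p_R?

    Returns ``(grid, matrix)`` where ``matrix[r, q]`` is True iff the
    invasion fitness of ``p_Q = grid[q]`` against ``p_R = grid[r]`` is
    strictly positive.  The diagonal is neutral, hence False.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    grid = np.linspace(0.0, 1.0, resolution)
    matrix = np.zeros((resolution, resolution), dtype=bool)
    warm = None
    for r, p_R in enumerate(grid):
        env = _ResidentEnvironment(float(p_R), params, background, settings, warm=warm)
        warm = env.eq.state
        diffs = env.invader_fitness_diffs(grid)
        matrix[r, :] = diffs > zero_tol
        matrix[r, r] = False
    return grid, matrix
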