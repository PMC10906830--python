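"""Mean-field reputation dynamics and their self-consistent equilibrium.

Given a strategy mix, the population-level state of reputations is summarized
by two arrays of good-standing probabilities:

* ``g_ind[i, J, I]`` -- the probability that a strategy-``i`` member of group
  ``J`` has a good *individual* reputation in the eyes of group ``I``;
* ``g_st[J, I]`` -- the probability that group ``J`` has a good *stereotyped*
  reputation in the eyes of group ``I``.

One round of synchronous reputation updating maps a state to a new state;
the equilibrium is a fixed point of that map, found here by damped fixed-point
iteration.  The update for a discriminating donor depends on whether her view
of the recipient coincides with the observer's view, which is controlled by
the monitoring-scale agreement indicators and, where views can differ, by
second-moment "agreement" aggregates over recipient classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AssessmentProbabilities,
    ModelParams,
    PopulationStructure,
    StrategyMix,
    assessment_probabilities,
)

__all__ = [
    "ReputationState",
    "ViewAggregates",
    "SolverSettings",
    "EquilibriumResult",
    "SolverError",
    "view_aggregates",
    "reputation_update_map",
    "solve_reputation_equilibrium",
    "disc_individual_row",
]


class SolverError(RuntimeError):
    """Fixed-point iteration failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ReputationState:
    """Good-standing probabilities for every (strategy, donor group, observer group)."""

    g_ind: np.ndarray  # (n_strategies, K, K), indexed [i, J, I]
    g_st: np.ndarray  # (K, K), indexed [J, I]

    @staticmethod
    def uniform(n_strategies: int, K: int, value: float = 0.5) -> "ReputationState":
        return ReputationState(
            g_ind=np.full((n_strategies, K, K), value, dtype=float),
            g_st=np.full((K, K), value, dtype=float),
        )

    def copy(self) -> "ReputationState":
        return ReputationState(self.g_ind.copy(), self.g_st.copy())

    def clip(self) -> "ReputationState":
        return ReputationState(np.clip(self.g_ind, 0.0, 1.0), np.clip(self.g_st, 0.0, 1.0))


@dataclass
class ViewAggregates:
    """Population aggregates of a reputation state.

    ``g_grp[L, I]`` is the frequency-weighted fraction of group ``L`` with a
    good individual reputation in the eyes of group ``I``; ``g_dot[I]`` and
    ``g_star[I]`` are the group-size-weighted population fractions viewed as
    good individually, respectively stereotypically, by group ``I``.  The four
    ``g_a*`` terms are the probabilities that a donor's and an observer's
    views of a random third party agree on "good", for the four combinations
    of (donor uses individual/stereotyped info) x (observer assesses
    individual/stereotyped reputations).
    """

    g_grp: np.ndarray  # (K, K) [L, I]
    g_dot: np.ndarray  # (K,)
    g_star: np.ndarray  # (K,)
    g_a1: np.ndarray  # (K, K) [J, I]
    g_a2: np.ndarray
    g_a3: np.ndarray
    g_a4: np.ndarray


@dataclass(frozen=True)
class SolverSettings:
    """Damped fixed-point iteration controls.

    ``damping`` is the relaxation weight lambda in ``x <- (1-lambda) x +
    lambda F(x)``; full steps (lambda=1) can cycle on involutive maps such as
    the error-free all-defector update, so the default is 0.5.  ``init`` fills
    every reputation entry of the starting state.
    """

    tol: float = 1e-12
    max_iter: int = 100_000
    damping: float = 0.5
    init: float = 0.5

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")


@dataclass
class EquilibriumResult:
    state: ReputationState
    aggregates: ViewAggregates
    residual: float
    n_iter: int
    neutral: bool = False  # every state is fixed (degenerate identity map)


def view_aggregates(
    state: ReputationState, mix: StrategyMix, structure: PopulationStructure
) -> ViewAggregates:
    """Compute the population aggregates entering the update map and fitness."""
    n, K, K2 = state.g_ind.shape
    if n != mix.n or K != structure.K or K2 != structure.K or state.g_st.shape != (K, K):
        raise ValueError(
            f"dimension mismatch: g_ind {state.g_ind.shape}, g_st {state.g_st.shape}, "
            f"{mix.n} strategies, K={structure.K}"
        )
    nu = structure.nu_array
    f = mix.f
    # g_grp[L, I] = sum_i f_i g_ind[i, L, I]
    g_grp = np.einsum("i,ilk->lk", f, state.g_ind)
    g_dot = nu @ g_grp  # (I,)
    g_star = nu @ state.g_st  # (I,)
    # g_a1[J, I] = sum_L nu_L sum_i f_i g_ind[i, L, I] g_ind[i, L, J]
    g_a1 = np.einsum("i,l,ila,ilb->ba", f, nu, state.g_ind, state.g_ind)
    # g_a2[J, I] = sum_L nu_L g_grp[L, I] g_st[L, J]
    g_a2 = np.einsum("l,la,lb->ba", nu, g_grp, state.g_st)
    # g_a3[J, I] = sum_L nu_L g_st[L, I] g_grp[L, J]
    g_a3 = np.einsum("l,la,lb->ba", nu, state.g_st, g_grp)
    # g_a4[J, I] = sum_L nu_L g_st[L, I] g_st[L, J]
    g_a4 = np.einsum("l,la,lb->ba", nu, state.g_st, state.g_st)
    return ViewAggregates(g_grp, g_dot, g_star, g_a1, g_a2, g_a3, g_a4)


def disc_individual_row(
    p: float,
    agg: ViewAggregates,
    P: AssessmentProbabilities,
    A: np.ndarray,
) -> np.ndarray:
    """Updated individual reputation ``g'[J, I]`` of a discriminator with propensity p.

    With probability 1-p the donor consults the recipient's individual
    reputation.  If her view coincides with the observer's (agreement
    indicator ``A[I, J]`` = 1) the donor is assessed as intending C toward
    good and D toward bad recipients; otherwise the joint good/good
    probability is the agreement aggregate ``g_a1`` and the four
    (observer view, donor intent) combinations are weighted accordingly.
    With probability p the donor consults the recipient's group stereotype,
    which agrees with the observer's individual view with probability
    ``g_a2``.
    """
    gd = agg.g_dot  # indexed by observer I
    gs = agg.g_star
    a1, a2 = agg.g_a1, agg.g_a2
    # aligned branch: donor's view == observer's view
    aligned = gd[None, :] * P.P_GC + (1.0 - gd[None, :]) * P.P_BD
    # independent-views branch (joint probabilities via g_a1)
    ind = (
        a1 * P.P_GC
        + (gd[None, :] - a1) * P.P_GD
        + (gd[:, None] - a1) * P.P_BC
        + (1.0 - gd[None, :] - gd[:, None] + a1) * P.P_BD
    )
    # stereotype-consulting branch (donor stereotype vs observer individual view)
    st = (
        a2 * P.P_GC
        + (gd[None, :] - a2) * P.P_GD
        + (gs[:, None] - a2) * P.P_BC
        + (1.0 - gd[None, :] - gs[:, None] + a2) * P.P_BD
    )
    A_JI = A.T  # A[I, J] -> indexed [J, I]
    return (1.0 - p) * (A_JI * aligned + (1.0 - A_JI) * ind) + p * st


def _tag_individual_row(agg: ViewAggregates, P: AssessmentProbabilities, nu: np.ndarray) -> np.ndarray:
    """Updated individual reputation of a TAG (in-group cooperator) donor.

    TAG intends to cooperate exactly with recipients from her own group, so
    the observer assesses intent C against in-group recipients and intent D
    against out-group recipients, using the observer's individual view of the
    recipient.
    """
    K = len(nu)
    g = agg.g_grp  # [L, I]
    coop = g * P.P_GC + (1.0 - g) * P.P_BC  # assessed as C toward group L
    defe = g * P.P_GD + (1.0 - g) * P.P_BD
    out = np.empty((K, K))
    total_def = nu @ defe  # (I,)
    for J in range(K):
        out[J, :] = nu[J] * coop[J, :] + (total_def - nu[J] * defe[J, :])
    return out


def _tag_stereotype_row(g_st: np.ndarray, P: AssessmentProbabilities, nu: np.ndarray) -> np.ndarray:
    """Contribution of a TAG donor sampled from group J to the stereotype update."""
    K = len(nu)
    coop = g_st * P.P_GC + (1.0 - g_st) * P.P_BC  # [L, I]
    defe = g_st * P.P_GD + (1.0 - g_st) * P.P_BD
    out = np.empty((K, K))
    total_def = nu @ defe
    for J in range(K):
        out[J, :] = nu[J] * coop[J, :] + (total_def - nu[J] * defe[J, :])
    return out


def reputation_update_map(
    state: ReputationState, mix: StrategyMix, params: ModelParams
) -> ReputationState:
    """One synchronous application of the reputation update to a state."""
    agg = view_aggregates(state, mix, params.structure)
    return _update_from_aggregates(state, agg, mix, params)


def _update_from_aggregates(
    state: ReputationState,
    agg: ViewAggregates,
    mix: StrategyMix,
    params: ModelParams,
) -> ReputationState:
    K = params.K
    nu = params.nu
    P = assessment_probabilities(params.norm, params.u_a, params.u_e)
    A = params.monitoring.A(K)
    B = params.monitoring.B(K)

    gd = agg.g_dot
    gs = agg.g_star

    new_ind = np.empty_like(state.g_ind)
    for i, strat in enumerate(mix.strategies):
        if strat.kind == "ALLC":
            row = gd * P.P_GC + (1.0 - gd) * P.P_BC  # (I,)
            new_ind[i] = np.broadcast_to(row, (K, K))
        elif strat.kind == "ALLD":
            row = gd * P.P_GD + (1.0 - gd) * P.P_BD
            new_ind[i] = np.broadcast_to(row, (K, K))
        elif strat.kind == "DISC":
            new_ind[i] = disc_individual_row(strat.p, agg, P, A)
        elif strat.kind == "TAG":
            new_ind[i] = _tag_individual_row(agg, P, nu)
        else:  # pragma: no cover
            raise ValueError(f"unknown strategy kind {strat.kind}")

    # Stereotype update: the observer samples one donor from group J; the
    # donor's strategy is drawn from the population mix, and the observer
    # applies the norm to her stereotype view of the recipient's group.
    a3, a4 = agg.g_a3, agg.g_a4
    allc_row = gs * P.P_GC + (1.0 - gs) * P.P_BC  # (I,)
    alld_row = gs * P.P_GD + (1.0 - gs) * P.P_BD
    new_st = np.zeros((K, K))
    tag_row = None
    for i, strat in enumerate(mix.strategies):
        fi = mix.f[i]
        if strat.kind == "ALLC":
            new_st += fi * np.broadcast_to(allc_row, (K, K))
        elif strat.kind == "ALLD":
            new_st += fi * np.broadcast_to(alld_row, (K, K))
        elif strat.kind == "DISC":
            p = strat.p
            ind_branch = (
                a3 * P.P_GC
                + (gs[None, :] - a3) * P.P_GD
                + (gd[:, None] - a3) * P.P_BC
                + (1.0 - gs[None, :] - gd[:, None] + a3) * P.P_BD
            )
            st_mismatch = (
                a4 * P.P_GC
                + (gs[None, :] - a4) * P.P_GD
                + (gs[:, None] - a4) * P.P_BC
                + (1.0 - gs[None, :] - gs[:, None] + a4) * P.P_BD
            )
            st_aligned = gs[None, :] * P.P_GC + (1.0 - gs[None, :]) * P.P_BD
            B_JI = B.T
            new_st += fi * (
                (1.0 - p) * ind_branch
                + p * ((1.0 - B_JI) * st_mismatch + B_JI * st_aligned)
            )
        elif strat.kind == "TAG":
            if tag_row is None:
                tag_row = _tag_stereotype_row(state.g_st, P, nu)
            new_st += fi * tag_row

    return ReputationState(new_ind, new_st)


def solve_reputation_equilibrium(
    mix: StrategyMix,
    params: ModelParams,
    settings: SolverSettings | None = None,
    init_state: ReputationState | None = None,
) -> EquilibriumResult:
    """Solve the self-consistent reputation system by damped iteration.

    Parameters
    ----------
    mix, params:
        Strategy mix and model parameterization.
    settings:
        Iteration controls; defaults to ``SolverSettings()``.
    init_state:
        Optional warm start.  When the map admits multiple fixed points the
        one reached depends on the starting state; the default is a uniform
        fill at ``settings.init``.

    Returns
    -------
    EquilibriumResult
        Converged state, its aggregates, the final sup-norm residual
        ``||F(x) - x||_inf``, the iteration count, and a ``neutral`` flag set
        when the update map is (numerically) the identity, so that every
        state is a fixed point and the initialization is returned as-is.

    Raises
    ------
    SolverError
        If the residual does not fall below ``tol`` within ``max_iter``
        iterations; the exception carries the last residual so callers can
        retry with stronger damping.
    """
    if settings is None:
        settings = SolverSettings()
    K = params.K
    state = (
        init_state.copy()
        if init_state is not None
        else ReputationState.uniform(mix.n, K, settings.init)
    )
    lam = settings.damping

    def residual_of(s: ReputationState, new: ReputationState) -> float:
        return max(
            float(np.max(np.abs(new.g_ind - s.g_ind))),
            float(np.max(np.abs(new.g_st - s.g_st))),
        )

    new = reputation_update_map(state, mix, params)
    res = residual_of(state, new)
    if res < settings.tol:
        # Possibly a degenerate identity map (e.g. error-free unconditional
        # cooperators under Stern Judging): probe a second state.
        probe = ReputationState(
            np.abs(state.g_ind - 0.17), np.abs(state.g_st - 0.17)
        )
        probe_new = reputation_update_map(probe, mix, params)
        neutral = residual_of(probe, probe_new) < settings.tol
        agg = view_aggregates(state, mix, params.structure)
        return EquilibriumResult(state, agg, res, 0, neutral=neutral)

    for it in range(1, settings.max_iter + 1):
        state = ReputationState(
            (1.0 - lam) * state.g_ind + lam * new.g_ind,
            (1.0 - lam) * state.g_st + lam * new.g_st,
        ).clip()
        new = reputation_update_map(state, mix, params)
        res = residual_of(state, new)
        if res < settings.tol:
            agg = view_aggregates(state, mix, params.structure)
            return EquilibriumResult(state, agg, res, it)
    raise SolverError(
        f"reputation solver did not converge within {settings.max_iter} iterations "
        f"(residual {res:.3e}); consider stronger damping",
        residual=res,
    )


def state_to_records(state: ReputationState, mix: StrategyMix) -> list[dict]:
    """Tidy export: one record per (strategy, donor group, observer group).

    Group indices are 1-based in the output.
    """
    records = []
    n, K, _ = state.g_ind.shape
    for i in range(n):
        for J in range(K):
            for I in range(K):
                records.append(
                    {
                        "strategy": mix.labels[i],
                        "donor_group": J + 1,
                        "observer_group": I + 1,
                        "g": float(state.g_ind[i, J, I]),
                    }
                )
    for J in range(K):
        for I in range(K):
            records.append(
                {
                    "strategy": "stereotype",
                    "donor_group": J + 1,
                    "observer_group": I + 1,
                    "g": float(state.g_st[J, I]),
                }
            )
    return records
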