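"""Strategy fitness and cooperation rates at a reputation equilibrium.

Fitness is the expected per-round payoff of a strategy class: benefits
received from donors who view the focal individual (or her group) as good,
minus the cost of the focal individual's own cooperative acts and the access
cost of individual-reputation lookups.  Cooperation rates summarize intended
cooperation filtered through execution errors, broken down by donor and
recipient group; they depend only on the equilibrium reputations, not on the
payoff parameters b, c, or eta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ModelParams, StrategyMix
from .reputation import (
    EquilibriumResult,
    ReputationState,
    SolverSettings,
    solve_reputation_equilibrium,
    view_aggregates,
)

__all__ = [
    "FitnessTable",
    "CooperationSummary",
    "strategy_fitness",
    "cooperation_rates",
    "cooperation_curve",
    "mean_population_fitness",
]


@dataclass
class FitnessTable:
    """Per-round expected payoffs ``Pi[i, I]`` and group means ``Pi_bar[I]``."""

    Pi: np.ndarray  # (n_strategies, K)
    Pi_bar: np.ndarray  # (K,)

    def aggregate(self, nu: np.ndarray) -> np.ndarray:
        """Group-size-weighted fitness of each strategy, sum_I nu_I Pi[i, I]."""
        return self.Pi @ nu


@dataclass
class CooperationSummary:
    """Realized cooperation probabilities by (donor group, recipient group)."""

    by_pair: np.ndarray  # (K, K), [donor I, recipient J]
    overall: float
    in_group: float
    out_group: float


def _intent_matrix(mix: StrategyMix, state: ReputationState, params: ModelParams) -> np.ndarray:
    """``intent[j, i, I, J]``: probability that a strategy-``j`` donor from
    group ``J`` intends to cooperate with a strategy-``i`` recipient from
    group ``I``."""
    n, K = mix.n, params.K
    intent = np.zeros((n, n, K, K))
    for j, strat in enumerate(mix.strategies):
        if strat.kind == "ALLC":
            intent[j] = 1.0
        elif strat.kind == "ALLD":
            intent[j] = 0.0
        elif strat.kind == "DISC":
            p = strat.p
            # donor group J's view of recipient (i, I): individual g_ind[i, I, J]
            # with prob 1-p, stereotype g_st[I, J] with prob p
            intent[j] = (1.0 - p) * state.g_ind + p * state.g_st[None, :, :]
        elif strat.kind == "TAG":
            eye = np.eye(K)
            intent[j] = np.broadcast_to(eye[None, :, :], (n, K, K))
    return intent


def strategy_fitness(
    mix: StrategyMix, state: ReputationState, params: ModelParams
) -> FitnessTable:
    """Per-round fitness of each strategy in each group.

    A focal strategy-``i`` individual in group ``I`` receives ``b`` from every
    donor who intends to cooperate with her and succeeds (probability
    ``1 - u_e``); she pays ``c`` for every cooperative act she herself
    executes and, if discriminating, the access cost ``eta`` whenever she
    consults an individual reputation (probability ``1 - p`` per
    interaction, charged regardless of the action taken).
    """
    n, K = mix.n, params.K
    if state.g_ind.shape != (n, K, K):
        raise ValueError(
            f"state/mix mismatch: g_ind shape {state.g_ind.shape}, "
            f"expected {(n, K, K)}"
        )
    nu = params.nu
    f = mix.f
    agg = view_aggregates(state, mix, params.structure)
    intent = _intent_matrix(mix, state, params)

    # benefit[i, I] = b * sum_J nu_J sum_j f_j intent[j, i, I, J]
    benefit = params.b * np.einsum("j,J,jiIJ->iI", f, nu, intent)

    Pi = np.empty((n, K))
    for i, strat in enumerate(mix.strategies):
        if strat.kind == "ALLC":
            cost = params.c
            access = 0.0
        elif strat.kind == "ALLD":
            cost = 0.0
            access = 0.0
        elif strat.kind == "DISC":
            p = strat.p
            cost = params.c * ((1.0 - p) * agg.g_dot + p * agg.g_star)  # (I,)
            access = params.eta * (1.0 - p)
        elif strat.kind == "TAG":
            cost = params.c * nu  # in-group recipients only, (I,)
            access = 0.0
        Pi[i, :] = (1.0 - params.u_e) * (benefit[i, :] - cost) - access

    Pi_bar = f @ Pi
    return FitnessTable(Pi=Pi, Pi_bar=Pi_bar)


def cooperation_rates(
    mix: StrategyMix, state: ReputationState, params: ModelParams
) -> CooperationSummary:
    """Realized donor-to-recipient cooperation probabilities.

    ``by_pair[I, J]`` is the probability that a random donor from group ``I``
    cooperates with a random recipient from group ``J``: unconditional
    cooperators always intend to cooperate, discriminators intend to
    cooperate when their scale-appropriate view of the recipient is good
    (individual view with probability ``1 - p``, group stereotype with
    probability ``p``), and every intention succeeds with probability
    ``1 - u_e``.  Independent of b, c, and eta.
    """
    K = params.K
    nu = params.nu
    agg = view_aggregates(state, mix, params.structure)
    by_pair = np.zeros((K, K))
    for i, strat in enumerate(mix.strategies):
        fi = mix.f[i]
        if strat.kind == "ALLC":
            by_pair += fi
        elif strat.kind == "DISC":
            p = strat.p
            # donor group I's view of recipients in group J
            by_pair += fi * ((1.0 - p) * agg.g_grp.T + p * state.g_st.T)
        elif strat.kind == "TAG":
            by_pair += fi * np.eye(K)
    by_pair *= 1.0 - params.u_e

    w = np.outer(nu, nu)
    overall = float(np.sum(w * by_pair))
    diag = np.eye(K, dtype=bool)
    in_group = float(np.sum(w[diag] * by_pair[diag]) / np.sum(w[diag]))
    if K > 1:
        out_group = float(np.sum(w[~diag] * by_pair[~diag]) / np.sum(w[~diag]))
    else:
        out_group = float("nan")
    return CooperationSummary(
        by_pair=by_pair, overall=overall, in_group=in_group, out_group=out_group
    )


def mean_population_fitness(table: FitnessTable, nu: np.ndarray) -> float:
    """Population mean fitness sum_I nu_I Pi_bar[I]."""
    return float(nu @ table.Pi_bar)


def cooperation_curve(
    params: ModelParams,
    p_grid: np.ndarray,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Equilibrium cooperation in monomorphic discriminator populations vs p.

    Solves one reputation equilibrium per grid point (warm-starting along the
    grid) and returns a data frame with columns ``p``, ``overall``,
    ``in_group``, ``out_group``.
    """
    rows = []
    warm = None
    for p in np.asarray(p_grid, dtype=float):
        mix = StrategyMix.monomorphic_disc(float(p))
        eq: EquilibriumResult = solve_reputation_equilibrium(
            mix, params, settings, init_state=warm
        )
        warm = eq.state
        summary = cooperation_rates(mix, eq.state, params)
        rows.append(
            {
                "p": float(p),
                "overall": summary.overall,
                "in_group": summary.in_group,
                "out_group": summary.out_group,
            }
        )
    return pd.DataFrame(rows)
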