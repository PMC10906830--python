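"""Finite-population stochastic simulator.

A population of ``N`` discriminators, split into ``K`` groups, plays repeated
donation games.  Every round, each individual interacts with everyone in the
population (including herself), once as a donor and once as a recipient; a
discriminating donor consults the recipient's individual reputation with
probability ``1 - p`` (paying the access cost eta) and the recipient's group
stereotype otherwise.  After all games of a round, reputation views are
updated synchronously: each observer samples one interaction per donor (for
individual reputations) and one interaction of a random donor per group (for
stereotypes) and applies the social norm, with assessment errors.  After each
generation of rounds, strategies are updated by Fermi pairwise comparison of
per-generation payoffs, and the stereotype propensity of a random individual
mutates locally.

The number of view tables matches the monitoring scale: a single broadcast
view under public monitoring, one per group under group-wise monitoring, and
one per individual under private monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import MonitoringConfig, SocialNorm, named_norm

__all__ = [
    "ABMConfig",
    "ABMState",
    "ABMRecord",
    "init_population",
    "play_round",
    "update_reputations",
    "imitate_and_mutate",
    "run_abm",
    "simulate_fixed_p",
]


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of one stochastic simulation run.

    Defaults follow the reference setup: N=50 discriminators in two equal
    groups, 2500 rounds per generation, 5 imitation pairs, mutation
    probability u_s = 10/N = 0.2 with step size 0.05.  ``payoff_games``
    rescales the per-round average payoff to a per-generation payoff (the
    cumulative payoff over that many games) before the Fermi comparison.
    """

    N: int = 50
    K: int = 2
    norm: SocialNorm = field(default_factory=lambda: named_norm("SternJudging"))
    monitoring: MonitoringConfig = field(default_factory=MonitoringConfig)
    b: float = 3.0
    c: float = 1.0
    eta: float = 0.0
    u_e: float = 0.02
    u_a: float = 0.02
    rounds_per_generation: int = 2500
    n_update_pairs: int = 5
    w: float = 1.0
    u_s: float = 0.2
    sigma_p: float = 0.05
    generations: int = 100
    p0: float = 0.5
    payoff_games: int = 100
    sample_every: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N: population size must be >= 2, got {self.N}")
        if not 1 <= self.K <= self.N:
            raise ValueError(f"K: need 1 <= K <= N, got {self.K}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"p0: initial propensity must lie in [0, 1], got {self.p0}")

    def with_(self, **kwargs) -> "ABMConfig":
        return replace(self, **kwargs)


def _n_observers(scale: str, N: int, K: int) -> int:
    return {"public": 1, "group-wise": K, "private": N}[scale]


@dataclass
class ABMState:
    """Mutable per-agent simulation state."""

    p: np.ndarray  # (N,) propensities
    group: np.ndarray  # (N,) group index per agent
    views_ind: np.ndarray  # (n_obs_ind, N) boolean: True = good
    views_st: np.ndarray  # (n_obs_st, K) boolean
    payoff: np.ndarray  # (N,) accumulated payoff this generation
    rng: np.random.Generator
    rounds_played: int = 0

    def observer_row_ind(self, cfg: ABMConfig) -> np.ndarray:
        """Index of the individual-reputation view table each agent consults."""
        scale = cfg.monitoring.individual_scale
        if scale == "public":
            return np.zeros(cfg.N, dtype=int)
        if scale == "group-wise":
            return self.group
        return np.arange(cfg.N)

    def observer_row_st(self, cfg: ABMConfig) -> np.ndarray:
        scale = cfg.monitoring.stereotype_scale
        if scale == "public":
            return np.zeros(cfg.N, dtype=int)
        if scale == "group-wise":
            return self.group
        return np.arange(cfg.N)


@dataclass
class ABMRecord:
    generation: int
    mean_p: float
    sd_p: float
    cooperation: float
    mean_payoff: float


def init_population(config: ABMConfig, rng: np.random.Generator | None = None) -> ABMState:
    """Initialize agents, views, and payoffs.

    All agents start with the same propensity ``p0``; every reputation bit is
    independently good with probability 1/2.  Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N, K = config.N, config.K
    group = (np.arange(N) * K) // N  # equal split, contiguous blocks
    n_obs_ind = _n_observers(config.monitoring.individual_scale, N, K)
    n_obs_st = _n_observers(config.monitoring.stereotype_scale, N, K)
    return ABMState(
        p=np.full(N, config.p0, dtype=float),
        group=group,
        views_ind=rng.random((n_obs_ind, N)) < 0.5,
        views_st=rng.random((n_obs_st, K)) < 0.5,
        payoff=np.zeros(N),
        rng=rng,
    )


def play_round(state: ABMState, config: ABMConfig) -> tuple[np.ndarray, float]:
    """Play one full round of donation games (all ordered pairs, incl. self).

    Returns the realized-action matrix ``realized[donor, recipient]``
    (True = cooperation happened) for the observers, and the realized
    cooperation fraction of the round.  Payoffs are accumulated in place:
    donors pay ``c`` per executed cooperation and ``eta`` per
    individual-reputation lookup (whatever the resulting action), recipients
    gain ``b`` per received cooperation.
    """
    rng = state.rng
    N = config.N
    row_ind = state.observer_row_ind(config)
    row_st = state.observer_row_st(config)

    use_ind = rng.random((N, N)) < (1.0 - state.p)[:, None]
    v_ind = state.views_ind[row_ind, :]  # (N donors, N recipients)
    v_st = state.views_st[row_st, :][:, state.group]  # donor's stereotype of rec's group
    intend = np.where(use_ind, v_ind, v_st)
    realized = intend & (rng.random((N, N)) >= config.u_e)

    state.payoff += config.b * realized.sum(axis=0)  # as recipient
    state.payoff -= config.c * realized.sum(axis=1)  # as donor
    state.payoff -= config.eta * use_ind.sum(axis=1)
    state.rounds_played += 1
    return realized, float(realized.mean())


def _assess(action_C: np.ndarray, rec_good: np.ndarray, norm: SocialNorm, u_a: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply a second-order norm elementwise, with assessment-error flips."""
    q = np.where(
        action_C,
        np.where(rec_good, 1.0, norm.q_C),
        np.where(rec_good, 0.0, norm.q_D),
    )
    good = rng.random(q.shape) < q
    flip = rng.random(q.shape) < u_a
    return good ^ flip


def update_reputations(state: ABMState, realized: np.ndarray, config: ABMConfig) -> None:
    """Synchronously refresh all individual and stereotype views.

    Each individual-reputation observer samples, independently per donor, one
    of the donor's interactions from the round and judges the realized action
    against the observer's own pre-update view of the recipient.  Each
    stereotype observer samples one donor per group and one of her
    interactions, and judges it against the observer's stereotype of the
    recipient's group.
    """
    rng = state.rng
    N, K = config.N, config.K
    n_obs_ind = state.views_ind.shape[0]
    n_obs_st = state.views_st.shape[0]

    # individual reputations: one sampled recipient per (observer, donor)
    rec = rng.integers(0, N, size=(n_obs_ind, N))
    act = realized[np.arange(N)[None, :], rec]
    rec_good = state.views_ind[np.arange(n_obs_ind)[:, None], rec]
    new_ind = _assess(act, rec_good, config.norm, config.u_a, rng)

    # stereotypes: one sampled donor per (observer, group), one interaction
    new_st = np.empty_like(state.views_st)
    for k in range(K):
        members = np.nonzero(state.group == k)[0]
        donors = members[rng.integers(0, len(members), size=n_obs_st)]
        recs = rng.integers(0, N, size=n_obs_st)
        act_st = realized[donors, recs]
        rec_good_st = state.views_st[np.arange(n_obs_st), state.group[recs]]
        new_st[:, k] = _assess(act_st, rec_good_st, config.norm, config.u_a, rng)

    state.views_ind = new_ind
    state.views_st = new_st


def imitate_and_mutate(state: ABMState, config: ABMConfig) -> None:
    """Fermi pairwise-comparison imitation of p, then local mutation.

    Payoffs are converted to per-generation values (average per-round payoff
    scaled to ``payoff_games`` games).  ``n_update_pairs`` ordered random
    pairs (i, j) are drawn; j adopts i's propensity with probability
    ``1 / (1 + exp(-w (pi_i - pi_j)))``.  Then, with probability ``u_s``, one
    random agent's p is perturbed by N(0, sigma_p^2) and clipped to [0, 1].
    Generation payoffs are reset.
    """
    rng = state.rng
    N = config.N
    rounds = max(state.rounds_played, 1)
    # per-game average payoff, scaled to a cumulative payoff over payoff_games
    pi = state.payoff / (rounds * N) * config.payoff_games

    for _ in range(config.n_update_pairs):
        i, j = rng.integers(0, N, size=2)
        prob = expit(config.w * (pi[i] - pi[j]))
        if rng.random() < prob:
            state.p[j] = state.p[i]

    if rng.random() < config.u_s:
        agent = rng.integers(0, N)
        state.p[agent] = float(np.clip(state.p[agent] + rng.normal(0.0, config.sigma_p), 0.0, 1.0))

    state.payoff[:] = 0.0
    state.rounds_played = 0


def run_abm(
    config: ABMConfig,
    use_kernel: bool | None = None,
    stop_when_p_below: float = -1.0,
) -> pd.DataFrame:
    """Run the full generation loop and return the sampled time series.

    Columns: ``generation``, ``mean_p``, ``sd_p``, ``cooperation`` (realized
    fraction over the generation's games), ``mean_payoff`` (per-generation
    scale).  Bit-reproducible for a fixed config (the seed is part of it).

    By default the compiled generation kernel is used when numba is
    available; pass ``use_kernel=False`` to force the pure-numpy loop (the
    two paths implement the same process but consume different random
    streams).  ``stop_when_p_below`` ends the run early (at a sampling
    point) once the population mean propensity drops below the threshold,
    which is useful for first-passage experiments near an absorbing
    attractor.
    """
    from ._abm_kernel import HAVE_NUMBA, _evolve_kernel

    if use_kernel is None:
        use_kernel = HAVE_NUMBA
    if use_kernel:
        state = init_population(config)
        out = _evolve_kernel(
            state.p.copy(),
            state.group.astype(np.int64),
            state.views_ind.copy(),
            state.views_st.copy(),
            state.observer_row_ind(config).astype(np.int64),
            state.observer_row_st(config).astype(np.int64),
            config.N,
            config.K,
            config.norm.q_C,
            config.norm.q_D,
            config.b,
            config.c,
            config.eta,
            config.u_e,
            config.u_a,
            config.rounds_per_generation,
            config.n_update_pairs,
            config.w,
            config.u_s,
            config.sigma_p,
            config.payoff_games,
            config.generations,
            config.sample_every,
            config.seed,
            stop_when_p_below,
        )
        return pd.DataFrame(
            out, columns=["generation", "mean_p", "sd_p", "cooperation", "mean_payoff"]
        ).astype({"generation": int})

    state = init_population(config)
    records: list[ABMRecord] = []
    for gen in range(config.generations):
        coop_total = 0.0
        for _ in range(config.rounds_per_generation):
            realized, frac = play_round(state, config)
            update_reputations(state, realized, config)
            coop_total += frac
        mean_payoff = float(
            np.mean(state.payoff / (config.rounds_per_generation * config.N))
            * config.payoff_games
        )
        if gen % config.sample_every == 0:
            records.append(
                ABMRecord(
                    generation=gen,
                    mean_p=float(state.p.mean()),
                    sd_p=float(state.p.std()),
                    cooperation=coop_total / config.rounds_per_generation,
                    mean_payoff=mean_payoff,
                )
            )
            if records[-1].mean_p < stop_when_p_below:
                break
        imitate_and_mutate(state, config)
    return pd.DataFrame([r.__dict__ for r in records])


def simulate_fixed_p(
    config: ABMConfig,
    rounds: int,
    burn_in: int = 0,
) -> np.ndarray:
    """Simulate reputations and games at fixed, homogeneous p.

    No imitation or mutation: every agent keeps ``p0`` throughout.  Returns
    the realized cooperation fraction per post-burn-in round, for comparison
    against the mean-field equilibrium prediction.
    """
    state = init_population(config)
    fracs = []
    for r in range(burn_in + rounds):
        realized, frac = play_round(state, config)
        update_reputations(state, realized, config)
        if r >= burn_in:
            fracs.append(frac)
        state.payoff[:] = 0.0
        state.rounds_played = 0
    return np.asarray(fracs)
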