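"""Compiled inner loop for the stochastic simulator.

The generation loop (games, synchronous reputation updates, Fermi imitation,
local mutation) is implemented as a single jitted kernel so that simulations
with thousands of rounds per generation remain tractable.  The kernel mirrors
the per-operation functions in :mod:`stereorecip.abm`.

Randomness comes from an inline splitmix64-seeded xorshift64* stream: the
kernel draws on the order of 10^9 uniforms per run, and an inline generator
is several times faster than the library generator inside a jit region.  The
stream is seeded per call, so runs are reproducible for a fixed
configuration.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by run_abm
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return deco


_U64 = np.uint64
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    x ^= x >> _U64(12)
    x ^= (x << _U64(25)) & _U64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> _U64(27)
    state[0] = x
    return (x * _U64(0x2545F4914F6CDD1D)) & _U64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _uniform(state):
    return float(_next_u64(state) >> _U64(11)) * _INV_2_53


@njit(cache=True, inline="always")
def _randbelow(state, n):
    return int(_uniform(state) * n)


@njit(cache=True)
def _seed_state(seed):
    # splitmix64 of the seed, avoiding the all-zero state
    z = (_U64(seed) + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = z ^ (z >> _U64(31))
    state = np.empty(1, dtype=np.uint64)
    state[0] = z if z != _U64(0) else _U64(0xDEADBEEFCAFEBABE)
    return state


@njit(cache=True)
def _evolve_kernel(
    p,
    group,
    views_ind,
    views_st,
    row_ind,
    row_st,
    N,
    K,
    q_C,
    q_D,
    b,
    c,
    eta,
    u_e,
    u_a,
    rounds,
    n_update_pairs,
    w,
    u_s,
    sigma_p,
    payoff_games,
    generations,
    sample_every,
    seed,
    stop_below,
):
    rng = _seed_state(seed)
    n_obs_ind = views_ind.shape[0]
    n_obs_st = views_st.shape[0]
    realized = np.zeros((N, N), dtype=np.bool_)
    payoff = np.zeros(N)
    new_ind = np.zeros((n_obs_ind, N), dtype=np.bool_)
    new_st = np.zeros((n_obs_st, K), dtype=np.bool_)

    # precompute group membership lists for stereotype donor sampling
    members = np.empty((K, N), dtype=np.int64)
    sizes = np.zeros(K, dtype=np.int64)
    for i in range(N):
        k = group[i]
        members[k, sizes[k]] = i
        sizes[k] += 1

    n_samples = (generations + sample_every - 1) // sample_every
    out = np.zeros((n_samples, 5))
    s = 0

    for gen in range(generations):
        for i in range(N):
            payoff[i] = 0.0
        coop_sum = 0.0
        for _ in range(rounds):
            # donation games: every ordered pair, including self
            n_coop = 0
            for i in range(N):
                keep = 1.0 - p[i]
                ri = row_ind[i]
                rs = row_st[i]
                for r in range(N):
                    if _uniform(rng) < keep:
                        good = views_ind[ri, r]
                        payoff[i] -= eta
                    else:
                        good = views_st[rs, group[r]]
                    if good and _uniform(rng) >= u_e:
                        realized[i, r] = True
                        payoff[i] -= c
                        payoff[r] += b
                        n_coop += 1
                    else:
                        realized[i, r] = False
            coop_sum += n_coop / (N * N)

            # synchronous reputation updates
            for o in range(n_obs_ind):
                for d in range(N):
                    r = _randbelow(rng, N)
                    act = realized[d, r]
                    rec_good = views_ind[o, r]
                    if act:
                        q = 1.0 if rec_good else q_C
                    else:
                        q = 0.0 if rec_good else q_D
                    good = _uniform(rng) < q
                    if _uniform(rng) < u_a:
                        good = not good
                    new_ind[o, d] = good
            for o in range(n_obs_st):
                for k in range(K):
                    d = members[k, _randbelow(rng, sizes[k])]
                    r = _randbelow(rng, N)
                    act = realized[d, r]
                    rec_good = views_st[o, group[r]]
                    if act:
                        q = 1.0 if rec_good else q_C
                    else:
                        q = 0.0 if rec_good else q_D
                    good = _uniform(rng) < q
                    if _uniform(rng) < u_a:
                        good = not good
                    new_st[o, k] = good
            for o in range(n_obs_ind):
                for d in range(N):
                    views_ind[o, d] = new_ind[o, d]
            for o in range(n_obs_st):
                for k in range(K):
                    views_st[o, k] = new_st[o, k]

        if gen % sample_every == 0:
            mean_p = 0.0
            for i in range(N):
                mean_p += p[i]
            mean_p /= N
            var_p = 0.0
            mean_pay = 0.0
            for i in range(N):
                var_p += (p[i] - mean_p) ** 2
                mean_pay += payoff[i]
            var_p /= N
            mean_pay = mean_pay / N / (rounds * N) * payoff_games
            out[s, 0] = gen
            out[s, 1] = mean_p
            out[s, 2] = np.sqrt(var_p)
            out[s, 3] = coop_sum / rounds
            out[s, 4] = mean_pay
            s += 1
            if mean_p < stop_below:
                return out[:s]

        # Fermi pairwise-comparison imitation on per-generation payoffs
        for _ in range(n_update_pairs):
            i = _randbelow(rng, N)
            j = _randbelow(rng, N)
            pi_i = payoff[i] / (rounds * N) * payoff_games
            pi_j = payoff[j] / (rounds * N) * payoff_games
            x = -w * (pi_i - pi_j)
            if x > 35.0:
                prob = 0.0
            elif x < -35.0:
                prob = 1.0
            else:
                prob = 1.0 / (1.0 + np.exp(x))
            if _uniform(rng) < prob:
                p[j] = p[i]

        # local mutation of one agent's propensity (Box-Muller normal step)
        if _uniform(rng) < u_s:
            agent = _randbelow(rng, N)
            u1 = _uniform(rng)
            while u1 <= 1e-300:
                u1 = _uniform(rng)
            z = np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * _uniform(rng))
            val = p[agent] + sigma_p * z
            if val < 0.0:
                val = 0.0
            elif val > 1.0:
                val = 1.0
            p[agent] = val

    return out[:s]
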