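"""Replicator dynamics of competing strategies on the simplex.

Strategy frequencies evolve as ``df_i/dt = f_i sum_J nu_J (Pi_i^J -
Pibar^J)`` under the timescale-separation assumption: reputations are
re-equilibrated at every right-hand-side evaluation.  The module provides the
vector field, trajectory integration, equilibrium enumeration with linear
stability, and flow fields on a barycentric grid (the data behind simplex
phase portraits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from .core import ModelParams, Strategy, StrategyMix
from .payoffs import strategy_fitness
from .reputation import ReputationState, SolverSettings, solve_reputation_equilibrium

__all__ = [
    "EquilibriumRecord",
    "Trajectory",
    "ReplicatorField",
    "replicator_rhs",
    "integrate_trajectory",
    "classify_equilibria",
    "simplex_flow_field",
]

#: Eigenvalue real parts within this band are flagged neutral.
EIG_TOL = 1e-8


@dataclass
class EquilibriumRecord:
    """An equilibrium of the replicator dynamics with its local stability."""

    f: np.ndarray
    kind: str  # "vertex" | "edge" | "interior"
    eigenvalues: np.ndarray
    stable: bool
    neutral: bool = False

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.f > 1e-9)[0]


@dataclass
class Trajectory:
    t: np.ndarray
    f: np.ndarray  # (n_times, n_strategies)
    converged: bool
    terminal_speed: float


class ReplicatorField:
    """The replicator vector field for a fixed strategy set.

    Holds a warm-start reputation state so that consecutive right-hand-side
    evaluations (as in ODE integration) reuse the previous equilibrium.
    """

    def __init__(
        self,
        strategies: list[Strategy] | tuple[Strategy, ...],
        params: ModelParams,
        settings: SolverSettings | None = None,
        clamp: dict[int, float] | None = None,
    ):
        self.strategies = tuple(strategies)
        self.params = params
        self.settings = settings
        self._warm: ReputationState | None = None
        #: optional fixed-frequency strategies (index -> frequency); their
        #: rates are forced to zero so the free strategies evolve over the
        #: remaining share of the population.
        self.clamp = dict(clamp or {})

    @property
    def n(self) -> int:
        return len(self.strategies)

    def fitness(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Group-aggregated fitness of every strategy and the mean fitness."""
        mix = StrategyMix(self.strategies, f)
        eq = solve_reputation_equilibrium(mix, self.params, self.settings, init_state=self._warm)
        self._warm = eq.state
        table = strategy_fitness(mix, eq.state, self.params)
        nu = self.params.nu
        fit = table.aggregate(nu)  # sum_J nu_J Pi_i^J
        mean = float(nu @ table.Pi_bar)
        return fit, mean

    def rhs(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        fit, _ = self.fitness(f)
        phi = float(f @ fit)
        v = f * (fit - phi)
        if self.clamp:
            free = np.ones(self.n, dtype=bool)
            for idx in self.clamp:
                free[idx] = False
                v[idx] = 0.0
            # renormalize selection over the free share so the clamped total
            # is conserved
            f_free = f[free]
            fit_free = fit[free]
            total_free = f_free.sum()
            if total_free > 0:
                phi_free = float(f_free @ fit_free) / total_free
                v[free] = f_free * (fit_free - phi_free)
        return v


def replicator_rhs(
    f: np.ndarray,
    strategies: list[Strategy],
    params: ModelParams,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Velocity of the strategy frequencies at simplex point ``f``."""
    return ReplicatorField(strategies, params, settings).rhs(np.asarray(f, dtype=float))


def integrate_trajectory(
    f0: np.ndarray,
    strategies: list[Strategy],
    params: ModelParams,
    horizon: float = 500.0,
    settings: SolverSettings | None = None,
    speed_tol: float = 1e-9,
    clamp: dict[int, float] | None = None,
    max_points: int = 200,
) -> Trajectory:
    """Integrate the replicator dynamics from ``f0`` over ``[0, horizon]``.

    The trajectory is renormalized onto the simplex after each output step;
    integration stops early once the vector field's speed drops below
    ``speed_tol``.
    """
    f0 = np.asarray(f0, dtype=float)
    if abs(f0.sum() - 1.0) > 1e-9 or np.any(f0 < -1e-12):
        raise ValueError("f0 must lie on the probability simplex")
    field = ReplicatorField(strategies, params, settings, clamp=clamp)

    def rhs(_t, y):
        y = np.clip(y, 0.0, 1.0)
        s = y.sum()
        if s > 0:
            y = y / s
        return field.rhs(y)

    def slow(_t, y):
        return float(np.linalg.norm(rhs(_t, y))) - speed_tol

    slow.terminal = True
    slow.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        f0,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        events=slow,
        t_eval=np.linspace(0.0, horizon, max_points),
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    ts = sol.t
    fs = sol.y.T
    if sol.t_events[0].size:  # append the early-stopping point
        ts = np.append(ts, sol.t_events[0][-1])
        fs = np.vstack([fs, sol.y_events[0][-1]])
    fs = np.clip(fs, 0.0, 1.0)
    fs /= fs.sum(axis=1, keepdims=True)
    terminal_speed = float(np.linalg.norm(field.rhs(fs[-1])))
    return Trajectory(t=ts, f=fs, converged=terminal_speed < 10 * speed_tol, terminal_speed=terminal_speed)


def _transverse_eigenvalues(field: ReplicatorField, f: np.ndarray, support: np.ndarray) -> list[float]:
    """Invasion eigenvalues of the strategies absent from the support.

    For replicator dynamics the eigenvalue transverse to a face, in the
    direction of a missing strategy k, is its rare-invader growth rate
    ``Fit_k(f*) - mean fitness(f*)``.
    """
    fit, _ = field.fitness(f)
    phi = float(f @ fit)
    return [float(fit[k] - phi) for k in range(field.n) if k not in support]


def _within_face_eigenvalues(
    field: ReplicatorField, f: np.ndarray, support: np.ndarray, h: float = 1e-5
) -> list[float]:
    """Eigenvalues of the Jacobian restricted to the supporting face.

    The face is parameterized by the support frequencies minus one (the last
    support coordinate absorbs the constraint); central finite differences
    stay inside the face for equilibria in its relative interior.
    """
    m = len(support)
    if m <= 1:
        return []
    free = support[:-1]
    last = support[-1]

    def embed(x: np.ndarray) -> np.ndarray:
        y = np.zeros(field.n)
        y[free] = x
        y[last] = 1.0 - x.sum() - sum(field.clamp.values())
        for idx, val in field.clamp.items():
            y[idx] = val
        return y

    x0 = f[free]
    J = np.empty((m - 1, m - 1))
    for a in range(m - 1):
        xp = x0.copy()
        xp[a] += h
        xm = x0.copy()
        xm[a] -= h
        vp = field.rhs(embed(xp))[free]
        vm = field.rhs(embed(xm))[free]
        J[:, a] = (vp - vm) / (2 * h)
    return [float(np.real(ev)) for ev in np.linalg.eigvals(J)]


def _classify(field: ReplicatorField, f: np.ndarray, kind: str) -> EquilibriumRecord:
    support = np.nonzero(f > 1e-9)[0]
    eigs = np.array(
        _within_face_eigenvalues(field, f, support)
        + _transverse_eigenvalues(field, f, support)
    )
    neutral = bool(np.any(np.abs(eigs) <= EIG_TOL)) if eigs.size else True
    stable = bool(np.all(eigs < -EIG_TOL)) if eigs.size else False
    return EquilibriumRecord(f=f, kind=kind, eigenvalues=eigs, stable=stable, neutral=neutral)


def classify_equilibria(
    strategies: list[Strategy],
    params: ModelParams,
    settings: SolverSettings | None = None,
    edge_resolution: int = 41,
    interior_resolution: int = 20,
) -> list[EquilibriumRecord]:
    """Enumerate and classify equilibria of the replicator dynamics.

    Vertices are always equilibria.  Edge equilibria are located by scanning
    the fitness difference of the two edge strategies for sign changes and
    bisecting.  Interior equilibria (three or more strategies) are located by
    a barycentric residual scan followed by a derivative-free polish.
    Stability is classified by the real parts of the linearization spectrum:
    within-face directions by central finite differences and transverse
    directions by rare-invader growth rates.
    """
    n = len(strategies)
    field = ReplicatorField(strategies, params, settings)
    records: list[EquilibriumRecord] = []

    for i in range(n):
        f = np.zeros(n)
        f[i] = 1.0
        records.append(_classify(field, f, "vertex"))

    for i, j in combinations(range(n), 2):
        xs = np.linspace(0.0, 1.0, edge_resolution)[1:-1]

        def edge_diff(x: float) -> float:
            f = np.zeros(n)
            f[i], f[j] = x, 1.0 - x
            fit, _ = field.fitness(f)
            return float(fit[i] - fit[j])

        vals = np.array([edge_diff(x) for x in xs])
        for a in range(len(xs) - 1):
            if vals[a] == 0.0 or np.sign(vals[a]) == np.sign(vals[a + 1]):
                continue
            lo, hi, glo = xs[a], xs[a + 1], vals[a]
            while hi - lo > 1e-8:
                mid = 0.5 * (lo + hi)
                gm = edge_diff(mid)
                if np.sign(gm) == np.sign(glo):
                    lo, glo = mid, gm
                else:
                    hi = mid
            x = 0.5 * (lo + hi)
            f = np.zeros(n)
            f[i], f[j] = x, 1.0 - x
            records.append(_classify(field, f, "edge"))

    if n >= 3:
        records.extend(_interior_equilibria(field, interior_resolution))

    return _dedupe(records)


def _interior_equilibria(field: ReplicatorField, resolution: int) -> list[EquilibriumRecord]:
    n = field.n
    found: list[np.ndarray] = []

    def residual(x: np.ndarray) -> float:
        f = np.append(x, 1.0 - x.sum())
        if np.any(f <= 1e-6):
            return 1e6
        return float(np.linalg.norm(field.rhs(f)))

    # coarse barycentric scan (first n-1 coordinates)
    grid = np.linspace(0.05, 0.95, resolution)
    if n == 3:
        candidates = [
            np.array([a, b])
            for a in grid
            for b in grid
            if a + b < 0.98
        ]
    else:
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(n), size=resolution * resolution)
        candidates = [r[:-1] for r in raw if np.all(r > 0.05)]
    scored = sorted(candidates, key=residual)[:5]
    for x0 in scored:
        if residual(x0) >= 1e6:
            continue
        res = minimize(residual, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        if res.fun < 1e-7:
            f = np.append(res.x, 1.0 - res.x.sum())
            if np.all(f > 1e-6):
                found.append(f)
    return [_classify(field, f, "interior") for f in found]


def _dedupe(records: list[EquilibriumRecord], tol: float = 1e-6) -> list[EquilibriumRecord]:
    out: list[EquilibriumRecord] = []
    for rec in records:
        if any(np.max(np.abs(rec.f - r.f)) < tol for r in out):
            continue
        out.append(rec)
    return out


def simplex_flow_field(
    strategies: list[Strategy],
    params: ModelParams,
    density: int = 10,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Replicator velocities on a barycentric grid of interior points.

    ``density`` is the number of subdivisions per edge; interior grid points
    have all barycentric coordinates strictly positive.
    """
    if density < 2:
        raise ValueError("density must be at least 2")
    n = len(strategies)
    if n != 3:
        raise ValueError("flow fields are tabulated for three-strategy simplices")
    field = ReplicatorField(strategies, params, settings)
    labels = [s.label for s in strategies]
    rows = []
    for a in range(1, density):
        for b in range(1, density - a):
            c = density - a - b
            if c < 1:
                continue
            f = np.array([a, b, c], dtype=float) / density
            v = field.rhs(f)
            row = {f"f_{labels[k]}": f[k] for k in range(3)}
            row.update({f"v_{labels[k]}": v[k] for k in range(3)})
            rows.append(row)
    return pd.DataFrame(rows)
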