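# Methods

## Model

We study indirect reciprocity in an infinite population partitioned into `K`
non-overlapping groups with fractions `ν_k` (default: two equal groups).
Individuals repeatedly play one-shot donation games with everyone: the donor
either pays a cost `c` to give the recipient a benefit `b > c`, or defects.
Behavioral strategies are unconditional cooperation (ALLC), unconditional
defection (ALLD), discrimination (`p`DISC), and optionally unconditional
in-group cooperation (TAG). A discriminating donor conditions on the
recipient's standing: with probability `1 − p` she consults the recipient's
*individual* reputation — paying an access cost `η ≥ 0` per interaction — and
with probability `p` the *stereotyped* reputation of the recipient's group,
which is free. Intended cooperation fails (becomes defection) with the
execution-error probability `u_e`.

Reputations are binary (good/bad) and assigned by observers under a
second-order social norm parameterized by `(q_C, q_D)`: cooperation with a
good-standing recipient always earns good standing, defection against a good
recipient always earns bad standing, and `q_C` (`q_D`) give the probability
that cooperation with (defection against) a *bad* recipient earns good
standing. The four named presets are Stern Judging (0, 1), Simple Standing
(1, 1), Scoring (1, 0), and Shunning (0, 0). We accept arbitrary
`(q_C, q_D) ∈ [0,1]²` so that generalized norms can be explored, but only the
four presets are named. Every assessment is flipped with the assessment-error
probability `u_a`. Error rates above 1/2 are rejected: they would invert the
meaning of an assessment, a regime the model is not intended to describe.

An individual reputation is assigned by observing one random interaction of
the donor; a stereotyped reputation is assigned to a whole group by observing
one random interaction of one randomly sampled group member. Either kind of
reputation can be monitored at three scales — private (every individual holds
her own view), group-wise (one shared view per group), or public (one shared
view for the whole population) — giving nine monitoring-system combinations.

## Mean-field reputation equilibria

The state of reputations is summarized by `g_ind[i, J, I]`, the probability
that a strategy-`i` member of group `J` is viewed as good by group `I`, and
`g_st[J, I]`, the probability that group `J` has a good stereotype in group
`I`'s eyes. Combining donor intent with the observer's view of the recipient
yields the assessment kernel

    P_GC = (1 − u_e)(1 − u_a) + u_e·u_a ≡ ε,   P_GD = u_a,
    P_BC = q_C(ε − u_a) + q_D(1 − ε − u_a) + u_a,
    P_BD = q_D(1 − 2u_a) + u_a,

the probability that a donor intending action `Y ∈ {C, D}` toward a recipient
the observer views as `X ∈ {G, B}` is assigned a good reputation. Whether the
donor's view of the recipient coincides with the observer's is governed by
the monitoring scale: always under public monitoring, within groups under
group-wise monitoring, and never identically under private monitoring, where
residual correlation is captured by second-moment agreement aggregates
(probabilities that two independently drawn views of a random third party are
both good, for the four combinations of donor/observer information types).
The synchronous update of all `g` values is a polynomial map of the state;
its fixed point is the reputation equilibrium, consistent with the standard
assumption that reputations equilibrate much faster than strategy
frequencies.

**Solver.** Damped fixed-point iteration `x ← (1 − λ)x + λF(x)` with λ = 0.5,
a uniform initial fill of 0.5, sup-norm residual tolerance 1e−12, and an
iteration cap of 1e5. Undamped iteration cycles on involutive maps (the
error-free all-defector update is `g' = 1 − g`), and λ = 0.5 converges on
every configuration we exercise. Degenerate cases:

* Error-free unconditional cooperators under Stern Judging make the update
  the identity; the solver detects this by probing a second state and flags
  the result as a neutral fixed-point family, returning the initialization.
* The map can have multiple fixed points (this is what produces bistability
  in the adaptive dynamics); the solver exposes the initial state so sweeps
  can continue branches. The uniform 0.5 fill is the canonical root.
* As `u_a, u_e → 0` the contraction factor approaches 1 and convergence slows
  like `O(1/u)`; property tests therefore draw error rates bounded away from
  zero, while the error-free limits are covered by dedicated closed-form
  tests.

For monomorphic populations the system collapses to at most two scalar
equations, which is how the closed forms used in tests arise; e.g. a
non-stereotyping discriminator population under public individual monitoring
satisfies `g = g·P_GC + (1 − g)·P_BD`, giving `g* = P_BD/(1 − P_GC + P_BD) =
0.98/1.0192 ≈ 0.9615` at `u_a = u_e = 0.02` under Stern Judging.

## Fitness and cooperation

Per-round expected payoffs combine the benefit received from donors who view
the focal individual (or her group) as good, the cost of own successful
cooperative acts, and the access cost `η(1 − p)` for discriminators. The
TAG extension receives `b` from donors whose rule endorses it and pays
`c·ν_I` (its in-group share of recipients) times the execution success rate;
its reputation rows treat it as intending cooperation exactly toward
in-group recipients. Cooperation summaries (overall, within-group,
between-group, and the full donor-group × recipient-group matrix) depend only
on equilibrium reputations and `u_e`, not on `b`, `c`, or `η`. The donor's
decision view is her scale-appropriate one: the shared view under public or
group-wise monitoring, and the mean-field marginal under private monitoring.
In-group and out-group rates are `ν`-weighted within each class of ordered
group pairs.

## Replicator dynamics

Strategy frequencies are group-common (global imitation) and evolve as
`ḟ_i = f_i Σ_J ν_J (Π_i^J − Π̄^J)`. The reputation equilibrium is recomputed
at every right-hand-side evaluation, warm-started from the previous solve.
Trajectories use adaptive Runge–Kutta (rtol 1e−8) with renormalization onto
the simplex and early stopping once the field speed drops below 1e−9.

Equilibria are enumerated structurally: all vertices; edge equilibria by
scanning the two-strategy fitness difference for sign changes and bisecting;
interior equilibria by a barycentric residual scan polished with Nelder–Mead.
Stability combines two exact decompositions of the linearization: directions
within the supporting face use central finite differences (step 1e−5), which
remain inside the face for relative-interior points, and directions
transverse to the face use the rare-invader growth rate `Fit_k − Φ`, which
for replicator dynamics equals the corresponding Jacobian eigenvalue. (A
naive central difference on the full projection would step outside the
simplex at vertices and edges.) Eigenvalue real parts within ±1e−8 are
flagged neutral rather than classified. A clamped-background variant holds
selected strategies at fixed frequencies (e.g. 20% ALLD) and renormalizes
selection over the free share.

## Adaptive dynamics of the stereotype propensity

A rare mutant discriminator with propensity `p_Q` in a resident `p_R`
population does not perturb the resident reputation field, and — because the
discriminator update row depends only on population aggregates — her
equilibrium reputation is an explicit function of the resident equilibrium.
We therefore embed the invader at frequency exactly zero: the strategy is
appended to the mix with `f = 0`, the fixed point simultaneously yields the
resident field and the invader's reputations, and invasion fitness is the
group-weighted payoff difference. A small-frequency solve at `f_Q = 1e−6` is
retained in the tests as an independent cross-check.

The selection gradient is a central finite difference of invasion fitness in
`p_Q` at `p_Q = p_R = p` with step `h = 1e−3` (one-sided at the boundaries of
[0, 1]); identical propensities are exactly neutral by construction, so the
gradient inherits no cancellation error from the resident solve. Singular
points are located by evaluating the gradient on a uniform grid (default 101
points), bracketing interior sign changes, and bisecting to 1e−4 in `p`; a
`+` to `−` change is an attractive (convergence-stable) point, `−` to `+`
repulsive, and a gradient that touches zero without changing sign is
recorded as degenerate rather than singular. Boundary attractors are read
off the adjacent gradient sign. Classification is by convergence stability
throughout, matching the attractive/repulsive dichotomy used for the model's
predictions. Each singular point is annotated with the cooperation level and
in/out-group gap of the corresponding monomorphic population.

Bifurcation sweeps re-run the singular-point finder along a parameter grid
(default: `η` over [0, 1], 101 points) and classify each value as
`p0_only`, `bistable`, `high_only`, or `neutral`. Under the headline
parameter set (Stern Judging, public/public, b=3, c=1, u=0.02) the sweep
reproduces a backward bifurcation: a high-stereotyping interior attractor
(p* ≈ 0.84 at η = 0.35) appears at η = 0.35 on a 0.005-step grid, coexisting
with the attractor at p = 0.

## Stochastic simulator

The finite-population model follows the mean-field process literally: `N`
discriminators (default 50) in `K` equal groups play all ordered pairs
(including self-play, which cancels in payoff comparisons), every round,
with binary view tables whose number matches the monitoring scale (1 public,
`K` group-wise, `N` private rows). After each round every observer samples
one interaction per donor (individual reputations) and one interaction of
one random donor per group (stereotypes), applies the norm against her own
pre-update view of the recipient, flips the result with probability `u_a`,
and all views are replaced synchronously. After `rounds_per_generation`
rounds, payoffs are converted to a per-generation value — the per-game
average scaled to a cumulative payoff over `payoff_games = 100` games — and
5 random ordered pairs imitate by the Fermi rule with selection intensity
`w` (default 1.0; the reference analysis does not fix it). With probability
`u_s = 10/N = 0.2` one agent's `p` mutates by N(0, 0.05²), clipped to
[0, 1], since `p` is a probability.

Two implementation paths exist: per-operation numpy functions (the
documented API and reference path) and a numba-jitted generation kernel used
by `run_abm` for long runs. Both implement the same process but consume
different random streams; both are validated against the mean-field
cooperation prediction. The kernel uses an inline splitmix64-seeded
xorshift64* uniform generator (the kernel draws ~10⁹ uniforms per run and
the library generator dominates runtime inside the jit region); this stream
drives only Monte Carlo noise, and runs are bit-reproducible for a fixed
configuration.

**Problem sizes.** The reference setup uses 2,500 rounds per generation.
Our simulation experiments use 50–1,000 rounds per generation with up to
~8,000 generations and early stopping when the population mean `p` is
absorbed near an attractor. The trade-off is explicit: the payoff noise seen
by the Fermi rule scales like `1/√rounds`, so the per-event selection bias
scales like `gradient × Δp × √rounds`, while compute scales like
`rounds × generations`; distance covered per unit compute therefore favors
few rounds and many generations, with reliability (drift versus diffusion)
governed by the total compute. At 100 rounds per generation, public/public,
η = 0.3, all of 8 calibration runs starting from p = 0.5 reached p < 0.05
within 8,000 generations.

**What the simulator does and does not emulate.** It reproduces the model's
information structure exactly (sampled observations, synchronous updates,
binary views) and adds demographic noise, mutation, and imitation noise. It
does not model strategy-kind evolution (only `p` evolves among
discriminators), group migration, or any intrinsic in-group bias; agreement
with the mean-field predictions supports the timescale-separation analysis,
not the realism of those excluded features.

## Numerical conventions

* Group indices are 0-based internally and 1-based in exported tables.
* Reputation solver: tol 1e−12 (sup norm), damping 0.5, init 0.5.
* Gradient step 1e−3; singular-point bisection tolerance 1e−4 in `p`;
  gradients within 1e−9 of zero treated as neutral on grids.
* Replicator stability threshold 1e−8 on eigenvalue real parts; duplicate
  equilibria merged within 1e−6.
* All CSV outputs carry headers; NDJSON is used for simulation time series.

## Known limitations

* The mean-field solver is a plain damped iteration; extremely small error
  rates (< ~1e−3) converge slowly. No Anderson acceleration is attempted.
* Interior equilibrium search for four or more strategies uses random
  Dirichlet candidates rather than a systematic grid.
* The adaptive-dynamics classification does not separate evolutionary (ESS)
  stability from convergence stability; the model's predictions are stated
  in terms of the latter.
* Cross-norm competition (observers holding different norms) is out of
  scope.
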