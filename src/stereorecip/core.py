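"""Model configuration: social norms, monitoring scales, population structure,
strategies, and the assessment-probability kernel.

The model describes an infinite population split into ``K`` non-overlapping
groups.  Individuals play one-shot donation games (pay cost ``c`` to give
benefit ``b``) and condition their behavior on reputations.  A reputation is
either *individual* (assigned to a single donor from her own action) or
*stereotyped* (assigned to a whole group from the action of one randomly
sampled member).  Each kind of reputation is monitored at one of three
scales -- private, group-wise, or public -- giving nine monitoring-system
combinations.

Second-order social norms are parameterized by ``(q_C, q_D)``: the
probabilities that cooperating with, respectively defecting against, a
recipient the observer views as *bad* earns the donor a good standing.
Cooperating with a good recipient always earns good standing and defecting
against a good recipient always earns bad standing (before assessment
errors).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SocialNorm",
    "MonitoringConfig",
    "PopulationStructure",
    "Strategy",
    "StrategyMix",
    "ModelParams",
    "AssessmentProbabilities",
    "named_norm",
    "assessment_probabilities",
    "agreement_indicator",
    "NORM_PRESETS",
    "SCALES",
    "default_params",
]

Scale = Literal["private", "group-wise", "public"]

SCALES: tuple[str, ...] = ("private", "group-wise", "public")

#: Canonical (q_C, q_D) pairs of the four named second-order norms.
NORM_PRESETS: dict[str, tuple[float, float]] = {
    "SternJudging": (0.0, 1.0),
    "SimpleStanding": (1.0, 1.0),
    "Scoring": (1.0, 0.0),
    "Shunning": (0.0, 0.0),
}


class ConfigurationError(ValueError):
    """Raised when a model configuration value is invalid."""


@dataclass(frozen=True)
class SocialNorm:
    """A second-order social norm in the (q_C, q_D) family.

    Parameters
    ----------
    name:
        Label of the norm (one of the four presets, or a custom label).
    q_C:
        Probability that cooperating with a bad recipient yields good standing.
    q_D:
        Probability that defecting against a bad recipient yields good standing.
    """

    name: str
    q_C: float
    q_D: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_C <= 1.0 and 0.0 <= self.q_D <= 1.0):
            raise ConfigurationError(
                f"norm: q_C and q_D must lie in [0, 1], got ({self.q_C}, {self.q_D})"
            )


def named_norm(name: str) -> SocialNorm:
    """Return one of the four preset norms by (case-insensitive) label.

    >>> named_norm("SternJudging")
    SocialNorm(name='SternJudging', q_C=0.0, q_D=1.0)
    """
    key = name.replace(" ", "").replace("-", "").replace("_", "").lower()
    for canonical, (q_C, q_D) in NORM_PRESETS.items():
        if canonical.lower() == key:
            return SocialNorm(canonical, q_C, q_D)
    raise ConfigurationError(
        f"norm: unknown norm {name!r}; valid options are {sorted(NORM_PRESETS)}"
    )


def agreement_indicator(scale: str, I: int, J: int) -> float:
    """Agreement indicator between observer group ``I`` and donor group ``J``.

    Encodes whether the donor's view of a recipient coincides with the
    observer's view under the given monitoring scale: always under public
    monitoring, within groups only under group-wise monitoring, and never
    under private monitoring (where residual agreement is captured by the
    correlation aggregates instead).
    """
    if scale == "private":
        return 0.0
    if scale == "group-wise":
        return 1.0 if I == J else 0.0
    if scale == "public":
        return 1.0
    raise ConfigurationError(
        f"monitoring scale: unknown scale {scale!r}; valid options are {list(SCALES)}"
    )


@dataclass(frozen=True)
class MonitoringConfig:
    """Monitoring scales for individual and stereotyped reputations."""

    individual_scale: str = "public"
    stereotype_scale: str = "public"

    def __post_init__(self) -> None:
        for key, scale in (
            ("individual_scale", self.individual_scale),
            ("stereotype_scale", self.stereotype_scale),
        ):
            if scale not in SCALES:
                raise ConfigurationError(
                    f"{key}: unknown scale {scale!r}; valid options are {list(SCALES)}"
                )

    def A(self, K: int) -> np.ndarray:
        """Agreement matrix ``A[I, J]`` for individual reputations."""
        return _agreement_matrix(self.individual_scale, K)

    def B(self, K: int) -> np.ndarray:
        """Agreement matrix ``B[I, J]`` for stereotyped reputations."""
        return _agreement_matrix(self.stereotype_scale, K)


def _agreement_matrix(scale: str, K: int) -> np.ndarray:
    return np.array(
        [[agreement_indicator(scale, I, J) for J in range(K)] for I in range(K)]
    )


@dataclass(frozen=True)
class PopulationStructure:
    """Partition of the population into ``K`` groups with fractions ``nu``."""

    K: int = 2
    nu: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float)
        if self.K < 1 or nu.shape != (self.K,):
            raise ConfigurationError(
                f"nu: expected {self.K} group fractions, got shape {nu.shape}"
            )
        if np.any(nu <= 0):
            raise ConfigurationError("nu: group fractions must be positive")
        if abs(nu.sum() - 1.0) > 1e-12:
            raise ConfigurationError(f"nu: group fractions must sum to 1, got {nu.sum()}")
        object.__setattr__(self, "nu", tuple(float(x) for x in nu))

    @property
    def nu_array(self) -> np.ndarray:
        return np.asarray(self.nu, dtype=float)


STRATEGY_KINDS = ("ALLC", "ALLD", "DISC", "TAG")


@dataclass(frozen=True)
class Strategy:
    """A behavioral strategy.

    ``p`` is the stereotype-use propensity and is meaningful only for DISC
    (the probability of consulting the recipient's group stereotype instead
    of her individual reputation); it is stored as 0 for the other kinds.
    TAG is an unconditional in-group cooperator.
    """

    kind: str
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ConfigurationError(
                f"strategy kind: unknown kind {self.kind!r}; valid: {STRATEGY_KINDS}"
            )
        if not 0.0 <= self.p <= 1.0:
            raise ConfigurationError(f"strategy p: must lie in [0, 1], got {self.p}")
        if self.kind != "DISC" and self.p != 0.0:
            object.__setattr__(self, "p", 0.0)

    @property
    def label(self) -> str:
        if self.kind == "DISC":
            return f"{self.p:g}DISC"
        return self.kind


@dataclass
class StrategyMix:
    """An ordered strategy set with (group-common) frequencies."""

    strategies: tuple[Strategy, ...]
    f: np.ndarray

    def __init__(self, strategies: Sequence[Strategy], f: Sequence[float]):
        self.strategies = tuple(strategies)
        self.f = np.asarray(f, dtype=float)
        if self.f.shape != (len(self.strategies),):
            raise ConfigurationError(
                f"strategies/f: {len(self.strategies)} strategies but "
                f"frequency vector of shape {self.f.shape}"
            )
        if np.any(self.f < -1e-12):
            raise ConfigurationError("f: frequencies must be non-negative")
        if abs(self.f.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"f: frequencies must sum to 1, got {self.f.sum()}")

    @property
    def n(self) -> int:
        return len(self.strategies)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strategies]

    def with_frequencies(self, f: Sequence[float]) -> "StrategyMix":
        return StrategyMix(self.strategies, f)

    @staticmethod
    def monomorphic(strategy: Strategy) -> "StrategyMix":
        return StrategyMix((strategy,), (1.0,))

    @staticmethod
    def monomorphic_disc(p: float) -> "StrategyMix":
        return StrategyMix.monomorphic(Strategy("DISC", p))


@dataclass(frozen=True)
class ModelParams:
    """Full parameterization of one mean-field model instance.

    Defaults follow the headline parameter set used throughout the analysis:
    b=3, c=1, two equal groups, u_e = u_a = 0.02, Stern Judging with fully
    public monitoring, and no access cost.
    """

    norm: SocialNorm = field(default_factory=lambda: named_norm("SternJudging"))
    monitoring: MonitoringConfig = field(default_factory=MonitoringConfig)
    structure: PopulationStructure = field(default_factory=PopulationStructure)
    b: float = 3.0
    c: float = 1.0
    eta: float = 0.0
    u_e: float = 0.02
    u_a: float = 0.02

    def __post_init__(self) -> None:
        if not self.b > self.c > 0:
            raise ConfigurationError(f"b/c: require b > c > 0, got b={self.b}, c={self.c}")
        if self.eta < 0:
            raise ConfigurationError(f"eta: access cost must be >= 0, got {self.eta}")
        for key, u in (("u_e", self.u_e), ("u_a", self.u_a)):
            if not 0.0 <= u <= 0.5:
                raise ConfigurationError(f"{key}: error rate must lie in [0, 1/2], got {u}")

    @property
    def K(self) -> int:
        return self.structure.K

    @property
    def nu(self) -> np.ndarray:
        return self.structure.nu_array

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_params(
    norm: str = "SternJudging",
    individual_scale: str = "public",
    stereotype_scale: str = "public",
    **kwargs,
) -> ModelParams:
    """Convenience constructor for the standard two-group parameter set."""
    return ModelParams(
        norm=named_norm(norm),
        monitoring=MonitoringConfig(individual_scale, stereotype_scale),
        **kwargs,
    )


@dataclass(frozen=True)
class AssessmentProbabilities:
    """Probabilities that a donor is assigned a good reputation.

    ``P_XY`` is the probability that a donor who *intends* action
    ``Y in {C, D}`` toward a recipient the observer views as
    ``X in {G(ood), B(ad)}`` ends up with a good reputation, after both
    execution errors (rate ``u_e``) and assessment errors (rate ``u_a``).
    ``eps`` is the probability that an intended cooperation with a
    good-standing recipient is endorsed.
    """

    eps: float
    P_GC: float
    P_GD: float
    P_BC: float
    P_BD: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.P_GC, self.P_GD, self.P_BC, self.P_BD)


def assessment_probabilities(
    norm: SocialNorm, u_a: float, u_e: float
) -> AssessmentProbabilities:
    """Assessment kernel for a norm at given error rates.

    An intended cooperation with a good-viewed recipient is endorsed when the
    act succeeds and is judged correctly, or fails and is misjudged:
    ``eps = (1 - u_e)(1 - u_a) + u_e * u_a``.  Intended defection against a
    good-viewed recipient is condemned up to assessment error
    (``P_GD = u_a``).  Toward bad-viewed recipients the norm's ``q_C``/``q_D``
    entries apply, again filtered through both error processes.
    """
    for key, u in (("u_a", u_a), ("u_e", u_e)):
        if not 0.0 <= u <= 0.5:
            raise ConfigurationError(f"{key}: error rate must lie in [0, 1/2], got {u}")
    eps = (1.0 - u_e) * (1.0 - u_a) + u_e * u_a
    P_GC = eps
    P_GD = u_a
    P_BC = norm.q_C * (eps - u_a) + norm.q_D * (1.0 - eps - u_a) + u_a
    P_BD = norm.q_D * (1.0 - 2.0 * u_a) + u_a
    return AssessmentProbabilities(eps=eps, P_GC=P_GC, P_GD=P_GD, P_BC=P_BC, P_BD=P_BD)
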