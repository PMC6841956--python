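"""The stage game: a continuous public goods game with quality-dependent costs.

In each round, every member of a group of size ``g`` invests an amount
``a_i`` into a joint project.  All members share the benefit, a concave
quadratic function of the group-mean investment, while each pays an
individual cost that is convex in its own investment and decreases with its
individual quality ``q_i`` (higher quality means cheaper investment, via a
negative investment-quality interaction).

The same formulas are used for two kinds of payoff: the *fitness* payoff,
evaluated at an individual's true quality ``q_i``, and the *perceived*
reward driving learning, evaluated at its perceived quality
``p_i = q_i + d_i`` where ``d_i`` is a cognitive bias.  Perceived qualities
may be negative but never exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

from .errors import ConfigError

__all__ = [
    "PayoffParams",
    "GroupComposition",
    "FIG1_PAYOFF",
    "group_mean",
    "benefit",
    "benefit_prime",
    "cost",
    "cost_prime",
    "payoff",
    "payoffs",
]


@dataclass(frozen=True)
class PayoffParams:
    """Coefficients of the quadratic benefit and cost functions.

    Benefit of the group-mean investment ``ā``:
        ``B(ā) = B0 + B1·ā + ½·B2·ā²``          (B1 > 0, B2 < 0)
    Cost of an individual investment ``a`` at quality ``q``:
        ``K(a, q) = K1·a + ½·K11·a² + K12·a·q`` (K1 > 0, K11 > 0, K12 < 0)

    The benefit is concave with its maximum at ``a_max = −B1/B2``; the cost
    is convex and increasing in ``a`` (for the relevant range) and, because
    K12 < 0, rises more steeply for lower-quality individuals.
    """

    B0: float
    B1: float
    B2: float
    K1: float
    K11: float
    K12: float

    def __post_init__(self) -> None:
        violations = []
        if not self.B1 > 0:
            violations.append("B1 > 0")
        if not self.B2 < 0:
            violations.append("B2 < 0")
        if not self.K1 > 0:
            violations.append("K1 > 0")
        if not self.K11 > 0:
            violations.append("K11 > 0")
        if not self.K12 < 0:
            violations.append("K12 < 0")
        if violations:
            raise ConfigError(
                "payoff parameter sign constraints violated: "
                + ", ".join(violations)
            )

    @property
    def a_max(self) -> float:
        """Investment at which the benefit is maximal, ``−B1/B2``."""
        return -self.B1 / self.B2


#: The parameter set used throughout for illustration (benefit intercept 1,
#: benefit maximal at ā = 2, unit cost curvature, unit quality interaction).
FIG1_PAYOFF = PayoffParams(B0=1.0, B1=4.0, B2=-2.0, K1=1.0, K11=1.0, K12=-1.0)


@dataclass(frozen=True)
class GroupComposition:
    """Group size plus true and perceived qualities of its members.

    True qualities ``q_i`` lie in [0, 1].  Perceived qualities ``p_i``
    satisfy ``p_i ≤ 1`` and may be negative (a negative bias means the
    individual behaves as if investment were costlier than it really is).
    """

    q: np.ndarray
    p: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        q = np.atleast_1d(np.asarray(self.q, dtype=float))
        p = self.p
        p = q.copy() if p is None else np.atleast_1d(np.asarray(p, dtype=float))
        if q.size == 0:
            raise ConfigError("group must contain at least one individual")
        if q.shape != p.shape:
            raise ConfigError(
                f"q and p must have equal length, got {q.shape} and {p.shape}"
            )
        if np.any((q < 0) | (q > 1)):
            raise ConfigError("true qualities must lie in [0, 1]")
        if np.any(p > 1):
            raise ConfigError("perceived qualities must satisfy p <= 1")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "p", p)

    @property
    def g(self) -> int:
        """Group size."""
        return self.q.size

    @classmethod
    def from_bias(cls, q: ArrayLike, d: ArrayLike) -> "GroupComposition":
        """Build a composition from true qualities and biases, ``p = min(q+d, 1)``."""
        q = np.atleast_1d(np.asarray(q, dtype=float))
        d = np.broadcast_to(np.asarray(d, dtype=float), q.shape)
        return cls(q=q, p=np.minimum(q + d, 1.0))


def group_mean(actions: ArrayLike) -> float:
    """Arithmetic mean investment of the group, ``ā = (1/g)·Σ a_i``."""
    a = np.atleast_1d(np.asarray(actions, dtype=float))
    if a.size == 0:
        raise ValueError("cannot take the group mean of an empty action profile")
    return float(a.mean())


def benefit(a_bar: ArrayLike, params: PayoffParams):
    """Shared benefit ``B(ā) = B0 + B1·ā + ½·B2·ā²`` (concave, peak at a_max)."""
    a_bar = np.asarray(a_bar, dtype=float)
    out = params.B0 + params.B1 * a_bar + 0.5 * params.B2 * a_bar**2
    return out if out.ndim else float(out)


def benefit_prime(a_bar: ArrayLike, params: PayoffParams):
    """Marginal benefit ``B′(ā) = B1 + B2·ā``."""
    a_bar = np.asarray(a_bar, dtype=float)
    out = params.B1 + params.B2 * a_bar
    return out if out.ndim else float(out)


def cost(a: ArrayLike, q: ArrayLike, params: PayoffParams):
    """Individual cost ``K(a, q) = K1·a + ½·K11·a² + K12·a·q``.

    ``q`` may be a true or a perceived quality; a unit of investment is
    cheaper at higher quality because K12 < 0.
    """
    a = np.asarray(a, dtype=float)
    q = np.asarray(q, dtype=float)
    out = params.K1 * a + 0.5 * params.K11 * a**2 + params.K12 * a * q
    return out if out.ndim else float(out)


def cost_prime(a: ArrayLike, q: ArrayLike, params: PayoffParams):
    """Marginal cost ``∂K/∂a = K1 + K11·a + K12·q``."""
    a = np.asarray(a, dtype=float)
    q = np.asarray(q, dtype=float)
    out = params.K1 + params.K11 * a + params.K12 * q
    return out if out.ndim else float(out)


def payoff(i: int, actions: ArrayLike, quality: float, params: PayoffParams) -> float:
    """Payoff ``W_i = B(ā) − K(a_i, quality)`` to member ``i``.

    Pass the true quality for the fitness payoff or the perceived quality
    for the reward the individual learns from.
    """
    a = np.atleast_1d(np.asarray(actions, dtype=float))
    if not 0 <= i < a.size:
        raise IndexError(f"player index {i} out of range for group of size {a.size}")
    return float(benefit(group_mean(a), params) - cost(a[i], quality, params))


def payoffs(actions: ArrayLike, qualities: ArrayLike, params: PayoffParams) -> np.ndarray:
    """Vector of payoffs for all group members at the given qualities."""
    a = np.atleast_1d(np.asarray(actions, dtype=float))
    q = np.atleast_1d(np.asarray(qualities, dtype=float))
    if a.shape != q.shape:
        raise ValueError("actions and qualities must have equal length")
    return benefit(group_mean(a), params) - cost(a, q, params)
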