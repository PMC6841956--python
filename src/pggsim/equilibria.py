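"""One-shot Nash equilibrium and the evolutionarily stable cognitive bias.

The stage game is concave (quadratic benefit of the group mean, convex
quadratic individual cost), so it has a unique Nash equilibrium, which is
where the learning dynamics settle.  The first-order conditions

    (1/g)·B′(ā*) = K1 + K11·a*_i + K12·x_i ,   i = 1..g

are linear in the actions for any quality vector ``x`` (true or perceived),
giving the closed form

    a*_i = e0 + e1·x_i + e2·Σ_{j≠i} x_j

with e1 > 0 (higher quality invests more) and, for g > 1, e2 < 0 (an
individual invests less when partners are of higher quality).  Summing the
conditions yields ``ā* = (B1 − g·K1 − K12·Σx)/(g·K11 − B2)`` and
back-substitution gives the coefficients.

Because learning converges to the one-shot equilibrium of the *perceived*
game, selection acts on the perceived quality ``p_i``.  The selection
gradient of the fitness payoff with respect to ``p_i`` at the equilibrium is

    dW_i/dp_i = K12·(p_i − q_i)·e1 + (1/g)·B′(ā*(p))·(g−1)·e2 ,

which is negative at ``p = q`` whenever g > 1: an unbiased individual can
gain by perceiving its quality as lower than it is, because its partners
then learn to invest more.  Setting the gradient to zero for all members
simultaneously (all share one bias d in the quadratic case) gives a bias
that is linear in the group-mean quality, ``d* = β0 + β1·q̄``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike
from scipy.optimize import brentq

from .errors import ConfigError, ConvergenceError
from .game_core import (
    PayoffParams,
    benefit_prime,
    cost_prime,
    group_mean,
    payoffs,
)

__all__ = [
    "NashCoefficients",
    "NashSolution",
    "BiasCoefficients",
    "nash_coefficients",
    "nash_investments",
    "nash_best_response_oracle",
    "selection_gradient",
    "ess_bias_line",
    "ess_bias_root",
    "predicted_mean_bias",
]


@dataclass(frozen=True)
class NashCoefficients:
    """Linear-form coefficients ``a*_i = e0 + e1·x_i + e2·Σ_{j≠i} x_j``."""

    e0: float
    e1: float
    e2: float
    g: int


@dataclass(frozen=True)
class NashSolution:
    """Equilibrium action profile, its group mean, and expected payoffs."""

    a_star: np.ndarray
    a_bar_star: float
    expected_payoffs: np.ndarray


@dataclass(frozen=True)
class BiasCoefficients:
    """ESS bias line ``d* = beta0 + beta1·q̄`` (both zero for g = 1)."""

    beta0: float
    beta1: float
    g: int

    def bias(self, q_bar: ArrayLike):
        """Evaluate the stable bias at group-mean quality ``q_bar``."""
        q_bar = np.asarray(q_bar, dtype=float)
        out = self.beta0 + self.beta1 * q_bar
        return out if out.ndim else float(out)


def nash_coefficients(params: PayoffParams, g: int) -> NashCoefficients:
    """Closed-form coefficients of the linear Nash map for group size ``g``.

    Derived by summing the g first-order conditions (which yields ā* as a
    linear function of the quality total) and substituting back into the
    per-individual condition.
    """
    if not (isinstance(g, int) and g >= 1):
        raise ConfigError("group size must be an integer >= 1")
    D = g * params.K11 - params.B2
    if D <= 0:
        raise ConfigError("degenerate denominator g*K11 - B2 <= 0")
    e0 = (params.B1 / g - params.K1) / params.K11 + (
        params.B2 / (g * params.K11)
    ) * (params.B1 - g * params.K1) / D
    e1 = -params.K12 * (g * g * params.K11 - (g - 1) * params.B2) / (
        params.K11 * g * D
    )
    e2 = 0.0 if g == 1 else -params.B2 * params.K12 / (g * params.K11 * D)
    return NashCoefficients(e0=e0, e1=e1, e2=e2, g=g)


def nash_investments(
    coeffs: NashCoefficients, qualities: ArrayLike, params: PayoffParams
) -> NashSolution:
    """Equilibrium investments and payoffs for a quality vector.

    ``qualities`` may be true or perceived; the expected payoffs returned
    are evaluated at that same vector.
    """
    x = np.atleast_1d(np.asarray(qualities, dtype=float))
    if x.size != coeffs.g:
        raise ValueError(
            f"quality vector of length {x.size} for coefficients with g={coeffs.g}"
        )
    a = coeffs.e0 + coeffs.e1 * x + coeffs.e2 * (x.sum() - x)
    return NashSolution(
        a_star=a,
        a_bar_star=group_mean(a),
        expected_payoffs=payoffs(a, x, params),
    )


def nash_best_response_oracle(
    params: PayoffParams,
    qualities: ArrayLike,
    tol: float = 1e-10,
    damping: float = 0.5,
    max_iter: int = 100_000,
    start: ArrayLike | None = None,
) -> NashSolution:
    """Equilibrium by damped simultaneous best-response iteration.

    Each player's best response to the others' total investment has a
    closed form (one-dimensional concave quadratic optimisation); iterating
    with damping converges to the unique fixed point.  Serves as an
    independent numerical check on :func:`nash_investments`.
    """
    x = np.atleast_1d(np.asarray(qualities, dtype=float))
    g = x.size
    a = np.zeros(g) if start is None else np.array(start, dtype=float)
    denom = params.K11 - params.B2 / g**2
    for _ in range(max_iter):
        others = a.sum() - a
        br = (
            params.B1 / g + params.B2 * others / g**2 - params.K1 - params.K12 * x
        ) / denom
        a_new = a + damping * (br - a)
        if np.max(np.abs(a_new - a)) < tol:
            a = a_new
            break
        a = a_new
    else:
        raise ConvergenceError("best-response iteration did not converge")
    return NashSolution(
        a_star=a, a_bar_star=group_mean(a), expected_payoffs=payoffs(a, x, params)
    )


def selection_gradient(
    params: PayoffParams,
    g: int,
    q: ArrayLike,
    p: ArrayLike,
    i: int,
) -> float:
    """Derivative of the fitness payoff of member ``i`` w.r.t. its perceived quality.

    Evaluated at the Nash equilibrium of the perceived game: a marginal
    change in ``p_i`` shifts own equilibrium investment by ``e1`` (paying a
    marginal cost mismatch ``K12·(p_i − q_i)`` per unit) and every
    partner's investment by ``e2``, each partner shift being worth
    ``(1/g)·B′(ā*)`` of shared benefit.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if q.size != g or p.size != g:
        raise ValueError("q and p must have length g")
    if not 0 <= i < g:
        raise IndexError(f"member index {i} out of range")
    coeffs = nash_coefficients(params, g)
    sol = nash_investments(coeffs, p, params)
    bracket = cost_prime(sol.a_star[i], p[i], params) - cost_prime(
        sol.a_star[i], q[i], params
    )
    social = (
        (g - 1) * coeffs.e2 * benefit_prime(sol.a_bar_star, params) / g
    )
    return float(bracket * coeffs.e1 + social)


def ess_bias_line(params: PayoffParams, g: int) -> BiasCoefficients:
    """Coefficients of the stable-bias line ``d* = beta0 + beta1·q̄``.

    With quadratic payoffs the zero-gradient condition depends on the
    perceived qualities only through the group mean, so all members share
    one bias d and the condition is a scalar linear fixed point in d.  For
    solitary individuals (g = 1) the only solution is zero bias.
    """
    if not (isinstance(g, int) and g >= 1):
        raise ConfigError("group size must be an integer >= 1")
    if g == 1:
        return BiasCoefficients(beta0=0.0, beta1=0.0, g=1)
    c = nash_coefficients(params, g)
    D = g * params.K11 - params.B2
    # B'(ā*(q̄+d)) = B1 + B2·(B1 − g·K1)/D − (B2·K12·g/D)·(q̄ + d)
    slope_p = -params.B2 * params.K12 * g / D  # d B'/d(q̄+d)
    const = params.B1 + params.B2 * (params.B1 - g * params.K1) / D
    social = (g - 1) * c.e2 / g
    # gradient(d) = K12·e1·d + social·(const + slope_p·(q̄ + d)) = 0
    M = params.K12 * c.e1 + social * slope_p
    if M == 0:
        raise ConfigError("degenerate bias-line solve (zero coefficient)")
    beta0 = -social * const / M
    beta1 = -social * slope_p / M
    return BiasCoefficients(beta0=beta0, beta1=beta1, g=g)


def ess_bias_root(
    params: PayoffParams, g: int, q_bar: float, bracket: tuple[float, float] = (-5.0, 5.0)
) -> float:
    """Stable bias at ``q_bar`` by numeric root-finding on the gradient.

    Independent check on :func:`ess_bias_line`: solves
    ``selection_gradient = 0`` for a common bias d in a homogeneous group
    of quality ``q_bar`` without using the closed-form line.
    """
    if g == 1:
        return 0.0
    q = np.full(g, q_bar)

    def grad(d: float) -> float:
        p = q + d  # common bias; p may exceed 1 transiently during root search
        coeffs = nash_coefficients(params, g)
        sol = nash_investments(coeffs, p, params)
        bracket_term = params.K12 * d
        social = (g - 1) * coeffs.e2 * benefit_prime(sol.a_bar_star, params) / g
        return bracket_term * coeffs.e1 + social

    return float(brentq(grad, *bracket, xtol=1e-14))


def predicted_mean_bias(
    params: PayoffParams,
    g: int,
    quality_values: ArrayLike,
    weights: ArrayLike | None = None,
) -> float:
    """Population-average stable bias over random group compositions.

    Qualities are drawn iid from ``quality_values`` with the given weights
    (uniform by default), so ``E[q̄] = E[q]`` and the average of the linear
    bias line is ``beta0 + beta1·E[q]``.
    """
    values = np.atleast_1d(np.asarray(quality_values, dtype=float))
    if values.size == 0:
        raise ConfigError("quality set must be non-empty")
    if weights is None:
        w = np.full(values.size, 1.0 / values.size)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float))
        if w.shape != values.shape:
            raise ConfigError("weights must match quality set in length")
        if not np.isclose(w.sum(), 1.0):
            raise ConfigError("quality weights must sum to 1")
    line = ess_bias_line(params, g)
    return float(line.beta0 + line.beta1 * float(values @ w))
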