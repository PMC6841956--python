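"""Actor-critic reinforcement learning within a group over repeated rounds.

Each individual holds a critic ``w`` (its running estimate of the reward per
round) and an actor parameterised by ``theta``, the mean of a Gaussian
policy with fixed exploration SD ``sigma``.  Each round every member draws
an action ``a ~ Normal(theta, sigma²)``, receives the perceived reward
``R = B(ā) − K(a, p)`` (evaluated at its *perceived* quality ``p``), and
updates

    delta = R − w                      (TD / prediction error)
    w    += alpha_w · delta            (critic)
    theta += alpha_theta · delta · (a − theta)/sigma²   (policy gradient)

Rounds are independent episodes: no discounting, no eligibility traces
across rounds, and sigma is held constant.  The expected per-round change
in ``theta`` is ``alpha_theta`` times the covariance of the TD error and
the eligibility ``(a − theta)/sigma²``, which is what drives the policy
toward higher expected reward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ConfigError
from .game_core import GroupComposition, PayoffParams, benefit, cost

__all__ = [
    "LearningConfig",
    "LearnerState",
    "RoundRecord",
    "LearningTrajectory",
    "sample_action",
    "td_error",
    "update_value",
    "eligibility",
    "update_policy",
    "step_round",
    "run_learning",
    "couple_rates",
]


@dataclass(frozen=True)
class LearningConfig:
    """Parameters of the actor-critic learner.

    Parameters
    ----------
    sigma
        Exploration SD of the Gaussian policy (action units).  Kept
        constant; exploration is what lets the learner discover better
        actions.
    alpha_w, alpha_theta
        Learning rates of the critic and the actor.  For ``w`` and
        ``theta`` to traverse comparable ranges over the same number of
        rounds these should satisfy ``alpha_theta ≈ alpha_w · sigma``
        (see :func:`couple_rates`).
    T
        Number of investment rounds per interaction.
    w_init, theta_init
        Starting values of the critic and the policy mean.
    clamp_actions
        If true, sampled actions are clamped above at the benefit-maximal
        investment ``a_max = −B1/B2`` (a guard; at the default parameters
        equilibrium actions stay well below it).
    """

    sigma: float = 0.05
    alpha_w: float = 0.04
    alpha_theta: float = 0.002
    T: int = 2000
    w_init: float = 1.0
    theta_init: float = 0.2
    clamp_actions: bool = False

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigError("sigma must be positive")
        if not (self.alpha_w > 0 and self.alpha_theta > 0):
            raise ConfigError("learning rates must be positive")
        if not (isinstance(self.T, int) and self.T >= 1):
            raise ConfigError("T must be an integer >= 1")


class LearnerState(NamedTuple):
    """Critic estimate ``w`` and policy mean ``theta`` of one learner."""

    w: float
    theta: float


@dataclass(frozen=True)
class RoundRecord:
    """Everything that happened in one round (vectors of length g)."""

    t: int
    actions: np.ndarray
    rewards: np.ndarray
    deltas: np.ndarray
    states: tuple[LearnerState, ...]  # post-update


@dataclass
class LearningTrajectory:
    """Full record of a T-round learning interaction.

    Array attributes have shape ``(T, g)``; row ``t-1`` holds round ``t``.
    ``w`` and ``theta`` are the post-update values of that round.
    """

    composition: GroupComposition
    config: LearningConfig
    actions: np.ndarray
    rewards: np.ndarray
    deltas: np.ndarray
    w: np.ndarray
    theta: np.ndarray

    @property
    def records(self) -> list[RoundRecord]:
        return [
            RoundRecord(
                t=t + 1,
                actions=self.actions[t],
                rewards=self.rewards[t],
                deltas=self.deltas[t],
                states=tuple(
                    LearnerState(self.w[t, i], self.theta[t, i])
                    for i in range(self.composition.g)
                ),
            )
            for t in range(self.actions.shape[0])
        ]

    def final_window(self, window: int = 500) -> dict[str, np.ndarray]:
        """Means and SDs of ``theta`` and ``w`` over the last ``window`` rounds."""
        window = min(window, self.theta.shape[0])
        th = self.theta[-window:]
        w = self.w[-window:]
        return {
            "theta_mean": th.mean(axis=0),
            "theta_sd": th.std(axis=0),
            "w_mean": w.mean(axis=0),
            "w_sd": w.std(axis=0),
        }


def sample_action(
    state: LearnerState, config: LearningConfig, rng: np.random.Generator
) -> float:
    """Draw an investment from the Gaussian policy ``Normal(theta, sigma²)``."""
    return float(state.theta + config.sigma * rng.standard_normal())


def td_error(reward: float, state: LearnerState) -> float:
    """Prediction error ``delta = R − w``."""
    return reward - state.w


def update_value(state: LearnerState, delta: float, config: LearningConfig) -> LearnerState:
    """Critic update ``w ← w + alpha_w · delta``; the policy mean is untouched."""
    return state._replace(w=state.w + config.alpha_w * delta)


def eligibility(action: float, state: LearnerState, config: LearningConfig) -> float:
    """Score of the Gaussian policy, ``zeta = (a − theta)/sigma²``.

    This is the gradient of the log policy density with respect to
    ``theta``; its expectation under the policy is zero.
    """
    if not config.sigma > 0:
        raise ConfigError("eligibility undefined for sigma = 0")
    return (action - state.theta) / config.sigma**2


def update_policy(
    state: LearnerState, delta: float, elig: float, config: LearningConfig
) -> LearnerState:
    """Actor update ``theta ← theta + alpha_theta · delta · zeta``."""
    return state._replace(theta=state.theta + config.alpha_theta * delta * elig)


def _round_arrays(
    w: np.ndarray,
    theta: np.ndarray,
    z: np.ndarray,
    composition: GroupComposition,
    payoff_params: PayoffParams,
    config: LearningConfig,
):
    """One synchronous round on arrays; z are standard-normal draws, one per member."""
    a = theta + config.sigma * z
    if config.clamp_actions:
        a = np.minimum(a, payoff_params.a_max)
    rewards = benefit(a.mean(), payoff_params) - cost(a, composition.p, payoff_params)
    deltas = rewards - w
    w_new = w + config.alpha_w * deltas
    zeta = (a - theta) / config.sigma**2
    theta_new = theta + config.alpha_theta * deltas * zeta
    return a, rewards, deltas, w_new, theta_new


def step_round(
    states: Sequence[LearnerState],
    composition: GroupComposition,
    payoff_params: PayoffParams,
    config: LearningConfig,
    rng: np.random.Generator | None = None,
    *,
    z: np.ndarray | None = None,
) -> tuple[list[LearnerState], RoundRecord]:
    """Play one round and update every learner.

    All actions are sampled from the pre-round states (synchronous update);
    rewards are computed with each member's *perceived* quality; each
    learner then applies the critic update followed by the actor update
    using its own TD error and eligibility.

    ``z`` may supply the standard-normal draws directly (one per member),
    e.g. for replay; otherwise they are drawn from ``rng``.
    """
    g = composition.g
    if len(states) != g:
        raise ValueError(f"{len(states)} learner states for group of size {g}")
    if z is None:
        if rng is None:
            raise ValueError("either rng or z must be provided")
        z = rng.standard_normal(g)
    z = np.asarray(z, dtype=float)
    if z.shape != (g,):
        raise ValueError(f"z must have shape ({g},)")
    w = np.array([s.w for s in states], dtype=float)
    theta = np.array([s.theta for s in states], dtype=float)
    a, rewards, deltas, w_new, theta_new = _round_arrays(
        w, theta, z, composition, payoff_params, config
    )
    new_states = [LearnerState(float(wi), float(ti)) for wi, ti in zip(w_new, theta_new)]
    record = RoundRecord(t=0, actions=a, rewards=rewards, deltas=deltas, states=tuple(new_states))
    return new_states, record


def run_learning(
    composition: GroupComposition,
    payoff_params: PayoffParams,
    config: LearningConfig,
    rng: np.random.Generator,
) -> LearningTrajectory:
    """Run the full T-round interaction and record the trajectory.

    Each individual's exploration noise comes from its own substream
    spawned from ``rng``, so a learner's draw sequence does not depend on
    the group size.
    """
    g = composition.g
    streams = rng.spawn(g)
    z = np.column_stack([s.standard_normal(config.T) for s in streams])
    w = np.full(g, config.w_init)
    theta = np.full(g, config.theta_init)
    T = config.T
    actions = np.empty((T, g))
    rewards = np.empty((T, g))
    deltas = np.empty((T, g))
    w_hist = np.empty((T, g))
    theta_hist = np.empty((T, g))
    for t in range(T):
        a, r, d, w, theta = _round_arrays(
            w, theta, z[t], composition, payoff_params, config
        )
        actions[t] = a
        rewards[t] = r
        deltas[t] = d
        w_hist[t] = w
        theta_hist[t] = theta
    return LearningTrajectory(
        composition=composition,
        config=config,
        actions=actions,
        rewards=rewards,
        deltas=deltas,
        w=w_hist,
        theta=theta_hist,
    )


def couple_rates(
    alpha_w: float,
    sigma: float,
    delta_w_range: float = 1.0,
    delta_theta_range: float = 1.0,
) -> float:
    """Actor learning rate matched to the critic rate.

    For ``w`` and ``theta`` to move over ranges ``Δw`` and ``Δθ`` in a
    comparable number of rounds, the rates should satisfy
    ``alpha_w·Δθ ∼ (alpha_theta/sigma)·Δw`` (a policy step is of order
    ``alpha_theta·delta/sigma`` because ``|a − theta| ≈ sigma``).  Returns
    ``alpha_theta = alpha_w · sigma · Δθ/Δw``; with both ranges ≈ 1 this is
    simply ``alpha_w · sigma``.
    """
    if not (alpha_w > 0 and sigma > 0 and delta_w_range > 0 and delta_theta_range > 0):
        raise ConfigError("couple_rates requires positive arguments")
    return alpha_w * sigma * delta_theta_range / delta_w_range
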