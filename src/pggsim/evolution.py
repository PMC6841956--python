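"""Individual-based evolution of the cognitive bias trait.

Discrete, non-overlapping generations of hermaphrodites, each carrying one
diploid locus whose allelic effects sum to the bias ``d_i``.  The life
cycle per generation:

1. newborns are sorted into random groups of size ``g`` and assigned random
   true qualities from a finite set; each perceives ``p_i = min(q_i + d_i, 1)``;
2. every group runs T rounds of actor-critic learning, rewards computed at
   the *perceived* qualities;
3. each individual's Darwinian fitness is its average *true*-quality payoff
   over the rounds;
4. the next generation is formed by fitness-proportional mating: two
   parents drawn independently per offspring (selfing allowed), each
   transmitting one of its two alleles; transmitted alleles mutate with
   probability ``mu`` by a Normal(0, mut_sd) increment.

Selection favours a negative bias for g > 1 because a learner that
overestimates its investment cost invests less, and its partners learn to
partially compensate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike

from ._kernels import learn_groups
from .actor_critic import LearningConfig
from .equilibria import nash_coefficients
from .errors import ConfigError, DegenerateSelectionError
from .game_core import PayoffParams

__all__ = [
    "EvoConfig",
    "Population",
    "GenerationSummary",
    "initial_population",
    "assign_qualities",
    "form_groups",
    "run_generation",
    "reproduce",
    "run_evolution",
]


@dataclass(frozen=True)
class EvoConfig:
    """Configuration of the evolutionary simulation.

    ``N`` individuals (a multiple of the group size ``g``) evolve for ``G``
    generations.  Qualities are redrawn every generation, iid from
    ``quality_values`` with ``quality_weights`` (uniform if omitted).
    ``mu`` is the per-transmitted-allele mutation probability and
    ``mut_sd`` the SD of the normal mutant increment.  The population
    starts monomorphic with bias ``d_init``.  Fitness values are floored at
    ``fitness_floor`` before proportional selection (payoffs are positive
    in practice at the default game parameters).

    With ``warm_start`` (the default), each newborn's policy mean starts at
    its own equilibrium investment in an average group — the linear Nash
    form evaluated at its perceived quality and the population mean
    perceived quality — instead of the common ``learning.theta_init``.  Lifetime fitness is
    the average payoff over a *finite* number of rounds, so the share of
    rounds spent far from the learning equilibrium matters: starting from
    a distant arbitrary point, a biased learner cuts its investment before
    its partners have learned to compensate, a lag cost that dilutes and
    shifts selection on the bias.  The theory this simulation probes
    concerns the converged learning outcome, so the default removes most
    of that transient; set ``warm_start=False`` to study short, cold-start
    interactions instead.
    """

    N: int
    g: int
    quality_values: tuple[float, ...]
    G: int = 1000
    learning: LearningConfig = field(default_factory=lambda: LearningConfig(T=3000))
    quality_weights: tuple[float, ...] | None = None
    mu: float = 0.001
    mut_sd: float = 0.04
    d_init: float = 0.0
    fitness_floor: float = 1e-6
    warm_start: bool = True

    def __post_init__(self) -> None:
        if not (isinstance(self.N, int) and self.N >= 1):
            raise ConfigError("N must be a positive integer")
        if not (isinstance(self.g, int) and self.g >= 1):
            raise ConfigError("g must be a positive integer")
        if self.N % self.g != 0:
            raise ConfigError(f"N={self.N} is not a multiple of g={self.g}")
        if not (0.0 <= self.mu <= 1.0):
            raise ConfigError("mu must lie in [0, 1]")
        if self.mut_sd < 0:
            raise ConfigError("mut_sd must be >= 0")
        if not (isinstance(self.G, int) and self.G >= 1):
            raise ConfigError("G must be a positive integer")
        vals = tuple(float(v) for v in self.quality_values)
        if len(vals) == 0:
            raise ConfigError("quality_values must be non-empty")
        if any(v < 0 or v > 1 for v in vals):
            raise ConfigError("quality values must lie in [0, 1]")
        object.__setattr__(self, "quality_values", vals)
        if self.quality_weights is not None:
            wts = tuple(float(w) for w in self.quality_weights)
            if len(wts) != len(vals):
                raise ConfigError("quality_weights must match quality_values")
            if any(w < 0 for w in wts) or not np.isclose(sum(wts), 1.0):
                raise ConfigError("quality_weights must be non-negative and sum to 1")
            object.__setattr__(self, "quality_weights", wts)

    @property
    def mean_quality(self) -> float:
        """Expected quality of a random individual, E[q]."""
        vals = np.asarray(self.quality_values, dtype=float)
        if self.quality_weights is None:
            return float(vals.mean())
        return float(vals @ np.asarray(self.quality_weights, dtype=float))


@dataclass
class Population:
    """State of the evolving population (arrays of length N).

    ``alleles`` has shape (N, 2); the bias trait is their sum.  ``q``,
    ``p`` and ``fitness`` are filled in over the life cycle; ``groups``
    holds the current grouping as an (N/g, g) index array.
    """

    alleles: np.ndarray
    q: np.ndarray | None = None
    p: np.ndarray | None = None
    fitness: np.ndarray | None = None
    groups: np.ndarray | None = None

    @property
    def N(self) -> int:
        return self.alleles.shape[0]

    @property
    def d(self) -> np.ndarray:
        """Bias trait values, the additive sum of the two alleles."""
        return self.alleles.sum(axis=1)


@dataclass(frozen=True)
class GenerationSummary:
    """Per-generation population statistics."""

    generation: int
    mean_d: float
    sd_d: float
    mean_p: float
    sd_p: float
    mean_fitness: float


def typical_investment(
    payoff_params: PayoffParams, config: EvoConfig, p_bar: float | None = None
) -> float:
    """Nash investment of a homogeneous group at a typical perceived quality.

    Used as the warm-start policy mean: the investment currently typical of
    the population, ``ā* = (B1 − g·K1 − K12·g·p̄) / (g·K11 − B2)`` with
    ``p̄`` the population mean perceived quality (the mean true quality of
    the quality distribution when no population is available yet).
    """
    if p_bar is None:
        p_bar = config.mean_quality
    g = config.g
    return float(
        (payoff_params.B1 - g * payoff_params.K1 - payoff_params.K12 * g * p_bar)
        / (g * payoff_params.K11 - payoff_params.B2)
    )


def initial_population(config: EvoConfig) -> Population:
    """Monomorphic starting population with bias ``d_init`` (split over alleles)."""
    alleles = np.full((config.N, 2), config.d_init / 2.0)
    return Population(alleles=alleles)


def assign_qualities(
    population: Population, config: EvoConfig, rng: np.random.Generator
) -> Population:
    """Draw iid true qualities and set perceived ``p = min(q + d, 1)``."""
    values = np.asarray(config.quality_values, dtype=float)
    weights = (
        None if config.quality_weights is None else np.asarray(config.quality_weights)
    )
    q = rng.choice(values, size=population.N, p=weights)
    population.q = q
    population.p = np.minimum(q + population.d, 1.0)
    return population


def form_groups(
    population: Population, config: EvoConfig, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random partition into N/g groups; stored on the population."""
    if population.N % config.g != 0:
        raise ConfigError("population size not divisible by group size")
    groups = rng.permutation(population.N).reshape(-1, config.g)
    population.groups = groups
    return groups


def run_generation(
    population: Population,
    config: EvoConfig,
    payoff_params: PayoffParams,
    rng: np.random.Generator,
    generation: int = 0,
) -> tuple[Population, GenerationSummary]:
    """Run learning in every group and assign Darwinian fitness.

    Rewards during learning use perceived qualities; fitness is each
    individual's mean payoff over the T rounds at its true quality.
    """
    if population.q is None or population.p is None:
        raise ValueError("assign_qualities must run before run_generation")
    if population.groups is None:
        raise ValueError("form_groups must run before run_generation")
    lc = config.learning
    if config.warm_start:
        # Each newborn starts at its own perceived-quality-adjusted typical
        # investment: its equilibrium action in an average group.  The start
        # then tracks the target to first order in the individual's bias,
        # leaving only the partner-composition transient.
        coeffs = nash_coefficients(payoff_params, config.g)
        p_bar = float(population.p.mean())
        theta_start = (
            coeffs.e0
            + coeffs.e1 * population.p
            + coeffs.e2 * (config.g - 1) * p_bar
        )
    else:
        theta_start = np.full(population.N, lc.theta_init)
    order = population.groups.ravel()
    z = rng.standard_normal((lc.T, population.N))
    _, _, fit = learn_groups(
        z,
        population.p[order],
        population.q[order],
        config.g,
        payoff_params.B0,
        payoff_params.B1,
        payoff_params.B2,
        payoff_params.K1,
        payoff_params.K11,
        payoff_params.K12,
        lc.sigma,
        lc.alpha_w,
        lc.alpha_theta,
        lc.w_init,
        theta_start[order],
        lc.clamp_actions,
        payoff_params.a_max,
    )
    fitness = np.empty(population.N)
    fitness[order] = fit
    population.fitness = fitness
    d = population.d
    summary = GenerationSummary(
        generation=generation,
        mean_d=float(d.mean()),
        sd_d=float(d.std()),
        mean_p=float(population.p.mean()),
        sd_p=float(population.p.std()),
        mean_fitness=float(fitness.mean()),
    )
    return population, summary


def reproduce(
    population: Population, config: EvoConfig, rng: np.random.Generator
) -> Population:
    """Form the next generation by fitness-proportional mating with mutation.

    For each of N offspring, two parents are drawn independently with
    probability proportional to floored fitness; each parent transmits one
    of its two alleles uniformly at random, and each transmitted allele
    mutates with probability ``mu`` by adding a Normal(0, mut_sd) draw.
    """
    if population.fitness is None:
        raise ValueError("fitness must be assigned before reproduction")
    f = population.fitness
    if np.all(f <= 0):
        raise DegenerateSelectionError("no individual has positive fitness")
    wts = np.maximum(f, config.fitness_floor)
    probs = wts / wts.sum()
    N = population.N
    parents = rng.choice(N, size=(N, 2), p=probs)
    which = rng.integers(0, 2, size=(N, 2))
    alleles = population.alleles[parents, which]
    mutates = rng.random((N, 2)) < config.mu
    increments = rng.normal(0.0, config.mut_sd, size=(N, 2)) if config.mut_sd > 0 else np.zeros((N, 2))
    alleles = alleles + np.where(mutates, increments, 0.0)
    return Population(alleles=alleles)


def run_evolution(
    config: EvoConfig,
    payoff_params: PayoffParams,
    rng: np.random.Generator | int,
) -> tuple[list[GenerationSummary], Population]:
    """Iterate the full life cycle for G generations.

    Returns the per-generation summaries and the final generation's
    population (with its qualities, grouping and fitness still attached).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    population = initial_population(config)
    summaries: list[GenerationSummary] = []
    for gen in range(1, config.G + 1):
        assign_qualities(population, config, rng)
        form_groups(population, config, rng)
        population, summary = run_generation(
            population, config, payoff_params, rng, generation=gen
        )
        summaries.append(summary)
        if gen < config.G:
            population = reproduce(population, config, rng)
    return summaries, population
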