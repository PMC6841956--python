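"""Individual-based evolution: life cycle, inheritance, selection and drift."""

import numpy as np
import pytest

from pggsim import EvoConfig, FIG1_PAYOFF, GroupComposition, LearningConfig
from pggsim._kernels import learn_groups
from pggsim.actor_critic import LearnerState, step_round
from pggsim.errors import ConfigError, DegenerateSelectionError
from pggsim.evolution import (
    Population,
    assign_qualities,
    form_groups,
    initial_population,
    reproduce,
    run_generation,
    run_evolution,
    typical_investment,
)


def small_config(**kw):
    base = dict(
        N=40,
        g=2,
        quality_values=(0.0, 1.0),
        G=3,
        mu=0.05,
        mut_sd=0.04,
        learning=LearningConfig(T=50),
    )
    base.update(kw)
    return EvoConfig(**base)


class TestKernel:
    def test_matches_pure_python_rounds_exactly(self, fig1_params):
        """The compiled population kernel reproduces the reference
        per-round implementation bit-for-bit on shared draws."""
        rng = np.random.default_rng(3)
        g, T = 3, 300
        q = np.array([0.0, 0.5, 1.0])
        p = np.array([-0.3, 0.5, 0.9])
        comp = GroupComposition(q=q, p=p)
        config = LearningConfig(T=T)
        z = rng.standard_normal((T, g))
        states = [LearnerState(config.w_init, config.theta_init)] * g
        fit = np.zeros(g)
        from pggsim import payoffs

        for t in range(T):
            states, rec = step_round(states, comp, fig1_params, config, z=z[t])
            fit += payoffs(rec.actions, q, fig1_params)
        fit /= T
        w, theta, kfit = learn_groups(
            z, p, q, g,
            fig1_params.B0, fig1_params.B1, fig1_params.B2,
            fig1_params.K1, fig1_params.K11, fig1_params.K12,
            config.sigma, config.alpha_w, config.alpha_theta,
            config.w_init, np.full(g, config.theta_init),
            False, fig1_params.a_max,
        )
        assert np.allclose(w, [s.w for s in states], atol=1e-12)
        assert np.allclose(theta, [s.theta for s in states], atol=1e-12)
        assert np.allclose(kfit, fit, atol=1e-12)

    def test_groups_are_independent(self, fig1_params):
        """Adding a second group leaves the first group's outcome unchanged
        when it sees the same draws."""
        config = LearningConfig(T=100)
        z1 = np.random.default_rng(1).standard_normal((100, 2))
        z2 = np.hstack([z1, np.random.default_rng(2).standard_normal((100, 2))])
        args = (
            fig1_params.B0, fig1_params.B1, fig1_params.B2,
            fig1_params.K1, fig1_params.K11, fig1_params.K12,
            config.sigma, config.alpha_w, config.alpha_theta,
            config.w_init, False, fig1_params.a_max,
        )
        q1 = np.array([0.0, 1.0])
        q2 = np.array([0.0, 1.0, 0.5, 0.5])
        th0_1 = np.full(2, config.theta_init)
        th0_2 = np.full(4, config.theta_init)
        w_a, th_a, f_a = learn_groups(z1, q1, q1, 2, *args[:-2], th0_1, *args[-2:])
        w_b, th_b, f_b = learn_groups(z2, q2, q2, 2, *args[:-2], th0_2, *args[-2:])
        assert np.array_equal(th_a, th_b[:2])
        assert np.array_equal(f_a, f_b[:2])


class TestLifeCycleSteps:
    def test_quality_frequencies_binomial(self):
        config = small_config(N=20000, quality_values=(0.0, 1.0))
        pop = initial_population(config)
        assign_qualities(pop, config, np.random.default_rng(0))
        freq = (pop.q == 1.0).mean()
        assert abs(freq - 0.5) < 3 * np.sqrt(0.25 / config.N)

    def test_point_mass_qualities(self):
        config = small_config(quality_values=(1.0,))
        pop = initial_population(config)
        assign_qualities(pop, config, np.random.default_rng(0))
        assert np.all(pop.q == 1.0)

    def test_perceived_quality_clamped_at_one(self):
        config = small_config(quality_values=(1.0,), d_init=0.5)
        pop = initial_population(config)
        assign_qualities(pop, config, np.random.default_rng(0))
        assert np.all(pop.p == 1.0)

    def test_groups_partition_population(self):
        config = small_config(N=12, g=3)
        pop = initial_population(config)
        groups = form_groups(pop, config, np.random.default_rng(1))
        assert groups.shape == (4, 3)
        assert sorted(groups.ravel()) == list(range(12))

    def test_singleton_groups_for_solitary_life(self):
        config = small_config(N=6, g=1)
        pop = initial_population(config)
        groups = form_groups(pop, config, np.random.default_rng(1))
        assert groups.shape == (6, 1)

    def test_pairing_probability_uniform(self):
        """P(two named individuals share a pair) = (g-1)/(N-1) under a
        uniformly random partition."""
        config = small_config(N=4, g=2)
        pop = initial_population(config)
        together = 0
        n_trials = 3000
        rng = np.random.default_rng(9)
        for _ in range(n_trials):
            groups = form_groups(pop, config, rng)
            rows = {tuple(sorted(r)) for r in groups}
            together += any({0, 1} == set(r) for r in rows)
        expect = 1 / 3
        se = np.sqrt(expect * (1 - expect) / n_trials)
        assert abs(together / n_trials - expect) < 4 * se

    def test_indivisible_population_rejected(self):
        with pytest.raises(ConfigError):
            small_config(N=41)


class TestReproduction:
    def _fitted_pop(self, alleles, fitness):
        pop = Population(alleles=np.asarray(alleles, dtype=float))
        pop.fitness = np.asarray(fitness, dtype=float)
        return pop

    def test_neutral_monomorphic_is_invariant(self):
        config = small_config(mu=0.0)
        pop = self._fitted_pop(np.full((40, 2), 0.3), np.ones(40))
        child = reproduce(pop, config, np.random.default_rng(0))
        assert np.all(child.alleles == 0.3)

    def test_zero_variance_mutation_changes_nothing(self):
        config = small_config(mu=1.0, mut_sd=0.0)
        alleles = np.random.default_rng(1).normal(size=(40, 2))
        pop = self._fitted_pop(alleles, np.ones(40))
        child = reproduce(pop, config, np.random.default_rng(2))
        assert set(np.round(child.alleles.ravel(), 12)) <= set(
            np.round(alleles.ravel(), 12)
        )

    def test_parentage_proportional_to_fitness(self):
        """Two clonal lineages at fitness 2:1 contribute alleles 2/3 vs 1/3."""
        config = small_config(N=300, mu=0.0)
        alleles = np.zeros((300, 2))
        alleles[:150] = 0.5  # lineage A: d = 1, fitness 2
        fitness = np.where(np.arange(300) < 150, 2.0, 1.0)
        rng = np.random.default_rng(7)
        shares = []
        for _ in range(40):
            child = reproduce(self._fitted_pop(alleles, fitness), config, rng)
            shares.append((child.alleles == 0.5).mean())
        mean_share = np.mean(shares)
        se = np.std(shares) / np.sqrt(len(shares))
        assert abs(mean_share - 2 / 3) < 4 * max(se, 1e-3)

    def test_all_non_positive_fitness_is_degenerate(self):
        config = small_config()
        pop = self._fitted_pop(np.zeros((40, 2)), np.full(40, -1.0))
        with pytest.raises(DegenerateSelectionError):
            reproduce(pop, config, np.random.default_rng(0))

    def test_neutral_drift_spreads_replicates(self):
        """With equal fitness the mean trait performs an unbiased random
        walk: across replicates the grand mean stays centred while the
        between-replicate variance grows."""
        config = small_config(N=60, mu=0.0)
        rng0 = np.random.default_rng(11)
        start = rng0.normal(0.0, 0.5, size=(60, 2))
        early, late = [], []
        for seed in range(30):
            pop = Population(alleles=start.copy())
            rng = np.random.default_rng(200 + seed)
            for gen in range(20):
                pop.fitness = np.ones(60)
                pop = reproduce(pop, config, rng)
                if gen == 2:
                    early.append(pop.d.mean())
            late.append(pop.d.mean())
        assert np.var(late) > np.var(early)
        assert abs(np.mean(late) - start.sum(axis=1).mean()) < 0.2


class TestGenerations:
    def test_low_quality_member_profits_from_compensation(self, fig1_params):
        """In unbiased (0,1) pairs the low-quality member's lifetime payoff
        exceeds its partner's, as at the Nash point (3.16 vs 2.66)."""
        config = small_config(N=200, learning=LearningConfig(T=2000), warm_start=False)
        pop = initial_population(config)
        pop.q = np.tile([0.0, 1.0], 100)
        pop.p = pop.q.copy()
        pop.groups = np.arange(200).reshape(100, 2)
        _, summary = run_generation(pop, config, fig1_params, np.random.default_rng(1))
        low = pop.fitness[0::2].mean()
        high = pop.fitness[1::2].mean()
        assert low > high

    def test_solitary_fitness_near_optimum(self, fig1_params):
        """A lone q=1 individual's mean payoff approaches the solitary
        optimum W(4/3) ~ 3.667, short of it by the exploration loss."""
        config = EvoConfig(
            N=60, g=1, quality_values=(1.0,), G=1, mu=0.0, mut_sd=0.0,
            learning=LearningConfig(T=3000),
        )
        pop = initial_population(config)
        assign_qualities(pop, config, np.random.default_rng(0))
        form_groups(pop, config, np.random.default_rng(1))
        _, summary = run_generation(pop, config, fig1_params, np.random.default_rng(2))
        from pggsim import benefit, cost

        w_opt = benefit(4 / 3, fig1_params) - cost(4 / 3, 1.0, fig1_params)
        assert summary.mean_fitness == pytest.approx(w_opt, abs=0.05)
        assert summary.mean_fitness < w_opt

    def test_monomorphic_without_mutation_stays_fixed(self, fig1_params):
        config = small_config(mu=0.0, G=4)
        summaries, pop = run_evolution(config, fig1_params, rng=5)
        assert all(s.mean_d == 0.0 and s.sd_d == 0.0 for s in summaries)
        assert np.all(pop.d == 0.0)

    def test_population_size_constant(self, fig1_params):
        config = small_config(G=3)
        summaries, pop = run_evolution(config, fig1_params, rng=8)
        assert pop.N == config.N
        assert len(summaries) == config.G

    def test_warm_start_uses_typical_investment(self, fig1_params):
        config = small_config(quality_values=(1.0,))
        assert typical_investment(fig1_params, config) == pytest.approx(1.0)
        config2 = small_config(quality_values=(0.0, 0.25, 0.5, 0.75, 1.0))
        assert typical_investment(fig1_params, config2) == pytest.approx(0.75)


class TestBiasEvolves:
    def _last_window_mean_d(self, fig1_params, g, seed):
        config = EvoConfig(
            N=600, g=g, quality_values=(0.5,), G=500, mu=0.05, mut_sd=0.04,
            learning=LearningConfig(T=1000),
        )
        summaries, _ = run_evolution(config, fig1_params, rng=seed)
        return np.mean([s.mean_d for s in summaries[-150:]])

    def test_negative_bias_emerges_in_pairs(self, fig1_params):
        """Scaled run with strong mutation: the population-mean bias of
        paired individuals becomes clearly negative."""
        mean_d = np.mean(
            [self._last_window_mean_d(fig1_params, 2, s) for s in (21, 22)]
        )
        assert mean_d < -0.15

    def test_solitary_bias_stays_centred(self, fig1_params):
        """For g = 1 selection on the bias is stabilising around zero."""
        mean_d = np.mean(
            [self._last_window_mean_d(fig1_params, 1, s) for s in (21, 22)]
        )
        assert abs(mean_d) < 0.12
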