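# pggsim

Actor-critic reinforcement learning in a repeated public goods game, the
one-shot Nash equilibrium it converges to, and the evolution of cognitive
bias in the perceived cost of investing.

## The model

A group of `g` individuals plays `T` rounds of a continuous public goods
game. In round `t` member `i` invests `a_it`; everyone receives the shared
benefit of the group mean investment ā and pays an individual cost that
depends on its quality `q_i ∈ [0, 1]`:

    B(ā)      = B0 + B1·ā + ½·B2·ā²          (B1 > 0, B2 < 0: concave)
    K(a, q)   = K1·a + ½·K11·a² + K12·a·q    (K1, K11 > 0, K12 < 0: convex,
                                              cheaper at higher quality)
    W_i       = B(ā) − K(a_i, q_i)

Each member learns how much to invest with a one-state actor-critic: a
critic `w_i` tracking expected reward via the TD error `δ = R − w`, and a
Gaussian policy `a ~ Normal(θ_i, σ²)` updated along the policy gradient,
`θ ← θ + α_θ·δ·(a − θ)/σ²`. This learning is myopic: it converges to the
one-shot Nash equilibrium of the game defined by the rewards the learner
*perceives*, and never exploits the fact that partners respond across
rounds. For the quadratic game the equilibrium is linear in the qualities,

    a*_i = e0 + e1·x_i + e2·Σ_{j≠i} x_j        (e1 > 0, e2 < 0),

with higher-quality members investing more and everyone investing less
when partners are of higher quality.

Because partners *do* compensate over rounds, an individual whose reward
system understates its quality (a cognitive bias `d_i = p_i − q_i < 0`,
i.e. an overestimated investment cost) under-invests, its partners learn to
invest more, and it gains Darwinian fitness. Selection on the perceived
quality `p_i` therefore has a negative gradient at `p = q` whenever
`g > 1`, and the evolutionarily stable bias is linear in the group mean
quality: `d* = β0 + β1·q̄` (zero for solitary individuals). The package
implements this analytic theory and an individual-based simulation in which
a diploid locus encoding `d_i` evolves under mutation, drift and
fitness-proportional mating.

## Worked example

```python
>>> import numpy as np, pggsim as pg
>>> pg.nash_coefficients(pg.FIG1_PAYOFF, g=2)
NashCoefficients(e0=0.5, e1=0.75, e2=-0.25, g=2)
>>> sol = pg.nash_investments(pg.nash_coefficients(pg.FIG1_PAYOFF, 2), [0, 1], pg.FIG1_PAYOFF)
>>> sol.a_star, sol.expected_payoffs
(array([0.25, 1.25]), array([3.15625, 2.65625]))
```

A quality-(0, 1) pair should learn its way to those investments:

```python
>>> comp = pg.GroupComposition(q=np.array([0.0, 1.0]))
>>> traj = pg.run_learning(comp, pg.FIG1_PAYOFF, pg.LearningConfig(T=3000),
...                        np.random.default_rng(1))
>>> np.round(traj.final_window(500)["theta_mean"], 3)
array([0.234, 1.226])
```

The low-quality member ends up investing ~0.25 and, thanks to its partner's
compensation, earns the *higher* payoff (3.16 vs 2.66). The stable bias
line for pairs is

```python
>>> pg.ess_bias_line(pg.FIG1_PAYOFF, g=2)
BiasCoefficients(beta0=-0.6, beta1=0.2, g=2)
>>> pg.predicted_mean_bias(pg.FIG1_PAYOFF, 2, [0.0, 0.25, 0.5, 0.75, 1.0])
-0.5
```

so a population of pairs with qualities drawn uniformly from
{0, 0.25, 0.5, 0.75, 1} should evolve a mean bias of −0.50: on average
individuals behave as if their quality were half a unit lower than it is.

## Command line

```sh
pggsim nash   --scenario fig1 --out out/        # equilibrium coefficients/profile
pggsim ess    --scenario fig3b --out out/       # bias line + predicted mean bias
pggsim learn  --scenario fig1 --seed 1 --out out/   # one group's trajectory TSV
pggsim evolve --scenario fig3a --seed 1 --out out/  # generations of bias evolution
```

Scenario presets (`fig1`, `fig2`, `fig3a`, `fig3b`, `fig4-g{2,3,5}`) carry
the reference parameter sets; every run writes a `provenance.json` that
separates preset values from package defaults. Outputs are byte-identical
across reruns with the same seed.

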