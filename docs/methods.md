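# Methods

## Stage game

Each round of the public goods game pays member `i`

    W_i = B(ā) − K(a_i, x_i),
    B(ā) = B0 + B1·ā + ½·B2·ā²,     K(a, x) = K1·a + ½·K11·a² + K12·a·x,

where `ā` is the group mean investment and `x_i` is a quality. The sign
constraints (B1, K1, K11 > 0; B2, K12 < 0) make the benefit strictly
concave with its peak at `a_max = −B1/B2` and the cost strictly convex and
cheaper per unit at higher quality. The same formula serves two roles: with
the true quality `q_i` it is the Darwinian fitness payoff; with the
perceived quality `p_i = q_i + d_i` it is the reward that drives learning.
The two differ by exactly `K12·(q_i − p_i)·a_i`, the perceived extra cost
of investing. True qualities live in [0, 1]; perceived qualities satisfy
`p ≤ 1` and may be negative. The default parameter set
(B0=1, B1=4, B2=−2, K1=1, K11=1, K12=−1) is the reference illustration set
used by all presets.

Actions are real numbers and are not restricted by default; Gaussian
exploration can make them negative, and they are scored by the same
formulas. An optional `clamp_actions` flag caps sampled actions at `a_max`
as a guard; with the default parameters equilibrium investments lie well
inside (0, a_max), so the cap is not a behaviour.

## Actor-critic learning

Each learner holds a critic `w` and a Gaussian policy `Normal(θ, σ²)` with
constant exploration SD σ. Per round (all members synchronous, actions
sampled from pre-round states):

    δ = R − w,   w ← w + α_w·δ,   θ ← θ + α_θ·δ·(a − θ)/σ².

Rounds are independent episodes — no discounting, no traces. The expected
policy step equals `α_θ·Cov(δ, ζ)` with eligibility `ζ = (a − θ)/σ²`, which
is what makes θ climb the perceived-reward gradient; at the learning
equilibrium the time-averaged δ is zero and θ fluctuates around the
one-shot Nash investment of the perceived game.

Defaults (σ=0.05, α_w=0.04, α_θ=0.002, start (w, θ)=(1.0, 0.2)) are the
reference scenario values; the actor/critic rates satisfy `α_θ ≈ α_w·σ` so both
parameters traverse order-one ranges over comparable numbers of rounds
(`couple_rates` computes the matched rate for other ranges). The critic
relaxes with time constant `1/α_w` = 25 rounds; the policy is roughly ten
times slower, converging over several hundred rounds. Single-interaction
runs default to T=2000 rounds.

The RNG contract: one master `numpy` Generator; `run_learning` spawns one
substream per individual, so a learner's exploration sequence does not
depend on group size. Identical seeds give bit-identical trajectories.

## Equilibria

The game is strictly concave, so the one-shot Nash equilibrium is unique
and satisfies `(1/g)·B′(ā*) = ∂K/∂a(a*_i, x_i)`. For the quadratic case
the system is linear: summing the g conditions gives
`ā* = (B1 − g·K1 − K12·Σx)/(g·K11 − B2)`, and back-substitution gives
`a*_i = e0 + e1·x_i + e2·Σ_{j≠i} x_j` with

    e1 = −K12·(g²·K11 − (g−1)·B2) / (K11·g·D),   e2 = −B2·K12/(g·K11·D),
    D  = g·K11 − B2.

Both coefficients were re-derived here and are cross-checked in the test
suite against (i) a direct linear solve of the first-order system and
(ii) damped simultaneous best-response iteration (damping 0.5, tolerance
1e−10, cap 1e5 iterations — each best response is an exact 1-D quadratic
optimum, and strict concavity makes the damped iteration a contraction in
practice; insensitivity to the starting profile is the uniqueness check).

Selection on perceived quality, evaluated at the perceived-game
equilibrium, has gradient

    dW_i/dp_i = K12·(p_i − q_i)·e1 + (1/g)·B′(ā*(p))·(g−1)·e2,

negative at `p = q` for all `g > 1`. Setting it to zero for all members
simultaneously (the quadratic structure forces a common bias) yields a
scalar linear fixed point whose solution is the bias line
`d* = β0 + β1·q̄`; a numeric root-finder on the gradient (`ess_bias_root`,
scipy brentq) provides the independent check. For pairs at the default
parameters, (β0, β1) = (−0.6, 0.2): a uniformly mixed population over the
quality set {0, 0.25, 0.5, 0.75, 1} has predicted mean bias
β0 + β1·0.5 = −0.50, and an all-top-quality population −0.4. The bias
magnitude shrinks monotonically toward zero as g grows.

## Individual-based evolution

Discrete non-overlapping generations of N hermaphrodites, one diploid
locus, trait `d = allele1 + allele2` (mutational increments are applied
per transmitted allele, so the stationary mean is insensitive to
sum-vs-mean scaling given a free mutant SD). Per generation: iid qualities
from a finite set, uniformly random groups of size g, T learning rounds
with rewards at perceived qualities, fitness = mean *true*-quality payoff
over the T rounds, then N offspring each from two independently drawn
parents with probability ∝ fitness (selfing allowed; fitness floored at
1e−6 against pathological negative payoffs, which do not occur at the
default parameters). Populations start monomorphic at d = 0.

### Interaction length and the warm start

Lifetime fitness averages over a *finite* interaction, so rounds spent far
from the learning equilibrium carry real weight. If every newborn starts
its policy at a fixed faraway point, a biased individual cuts its
investment before partners have learned to compensate; this lag cost is
proportional to the bias and its fitness share decays only as 1/T, which
weakens selection for the bias and shifts the selection zero toward zero
bias unless T is enormous (order 10⁴ rounds at the default learning
rates). The analytic theory, by contrast, concerns the converged learning
outcome.

The evolution module therefore defaults to a quality-dependent warm
start: each newborn's policy mean begins at its own equilibrium
investment in an average group, `e0 + e1·p_i + e2·(g−1)·p̄`, with `p̄` the
population mean perceived quality. This is the natural reading of an
innate investment tendency shaped by the same perception that shapes
rewards: individuals start near the behaviour typical for their (perceived)
state, and learning then adjusts them to their actual partners. Because
the start tracks the learning target to first order in the individual's
own bias, the remaining transient is only the partner-composition part:
the genuinely irreducible lag of partners *learning* to compensate for an
unfamiliar group member, which is the very mechanism that pays for the
bias. Its fitness share still decays as 1/T, so evolutionary runs default
to T = 3000 rounds, long enough that the converged regime dominates while
a full desk-scale run stays in minutes. Setting `warm_start=False`
recovers common cold starts from `theta_init` and, at short T,
demonstrably weaker evolved biases — an interesting regime in its own
right (short interactions select for less bias), but not the one the
analytic predictions address. Even with the warm start, a finite
interaction leaves the realized stable bias a few hundredths short of the
infinite-horizon prediction; the acceptance checks quantify this.

### Simulation sizes

Desk-scale defaults are N = 2400 (a tenth of the full-scale reference population, N = 24000),
G = 1000 generations at mutation rate 0.05, and for the slow-mutation
scenario (mu = 0.001) G = 3000 with T = 1500; these sizes keep a full run
in minutes while leaving the mutation–selection–drift equilibrium
resolvable. At N = 2400 the population mean bias wanders by a few
hundredths around its stationary value, hence time-averaged windows
(last 200–500 generations) and, for slow mutation, averages across three
seeds. Full-scale presets (N = 24000) are provided but are not exercised
by the test suite.

## What the synthetic populations do and do not show

All data are generated by the model itself; there is no empirical input.
The simulations emulate exactly the life cycle described above (finite quality
sets, iid group formation, proportional mating) and so test internal
consistency between the learning dynamics, the analytic equilibrium theory
and the evolutionary outcome. They do not test robustness to features of
real social systems outside the model: assortment or repeated partnerships
across generations, quality inheritance, perception noise, non-quadratic
payoffs (the Nash solver accepts general qualities but the simulator is
the quadratic special case), or learning rules with memory across
episodes.

## Numerical choices

- Population-scale learning runs in a numba-compiled kernel fed with
  pregenerated standard-normal draws; the test suite verifies exact
  (1e−12) agreement with the pure-NumPy per-round implementation on shared
  draws.
- Value update precedes policy update within a round; both consume the
  same δ, so the order is a convention.
- Perceived qualities are clamped at 1 when built from `q + d`; nothing
  clamps them below.
- Best-response iteration and the bias-line fixed point fail loudly
  (ConvergenceError / ConfigError) on degenerate parameter sets
  (`g·K11 − B2 ≤ 0` cannot occur under the sign constraints).
- TSV output uses shortest round-trip float repr, so equal seeds give
  byte-identical files.

## Known limitations

- The warm start uses the population mean perceived quality; in strongly
  structured populations (multimodal bias distributions) no single start
  point is typical, and the residual transient grows with the spread.
- Fitness-proportional selection assumes positive payoffs; scenarios
  engineered to give widespread negative lifetime payoffs would be
  dominated by the fitness floor.
- The vector-autoregressive structure of fluctuations around the learning
  equilibrium is out of scope; `run_learning` records full trajectories if
  such analyses are wanted downstream.
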