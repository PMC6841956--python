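import numpy as np
import pytest

from pggsim import FIG1_PAYOFF, GroupComposition, LearningConfig


@pytest.fixture(scope="session")
def fig1_params():
    """The quadratic payoff parameters used throughout for illustration."""
    return FIG1_PAYOFF


@pytest.fixture(scope="session")
def fig1_learning():
    return LearningConfig(sigma=0.05, alpha_w=0.04, alpha_theta=0.002)


@pytest.fixture(scope="session")
def pair_01(fig1_params, fig1_learning):
    """A converged two-player learning run with qualities (0, 1)."""
    from pggsim import run_learning

    comp = GroupComposition(q=np.array([0.0, 1.0]))
    config = LearningConfig(
        sigma=fig1_learning.sigma,
        alpha_w=fig1_learning.alpha_w,
        alpha_theta=fig1_learning.alpha_theta,
        T=3000,
    )
    rng = np.random.default_rng(12345)
    return run_learning(comp, fig1_params, config, rng)


def random_valid_params(rng):
    """Draw a payoff parameter set satisfying all sign constraints."""
    from pggsim import PayoffParams

    return PayoffParams(
        B0=rng.uniform(0.0, 2.0),
        B1=rng.uniform(0.5, 6.0),
        B2=-rng.uniform(0.5, 4.0),
        K1=rng.uniform(0.2, 3.0),
        K11=rng.uniform(0.3, 3.0),
        K12=-rng.uniform(0.2, 2.0),
    )
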