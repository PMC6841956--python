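"""Compiled hot loop for population-scale learning.

Same round arithmetic as ``actor_critic._round_arrays``, run for all groups
of a population at once from pregenerated standard-normal draws; tested for
exact agreement with the pure-NumPy path on shared draws.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def learn_groups(
    z,  # (T, N) standard-normal draws; individuals in group-contiguous order
    p,  # (N,) perceived qualities (drive rewards/learning)
    q,  # (N,) true qualities (drive fitness)
    g,
    B0, B1, B2, K1, K11, K12,
    sigma, alpha_w, alpha_theta,
    w0, theta0,  # theta0: (N,) per-individual starting policy means
    clamp, a_max,
):
    """Run T learning rounds for N/g groups; return final (w, theta, mean true payoff)."""
    T, N = z.shape
    M = N // g
    w = np.full(N, w0)
    theta = theta0.copy()
    fit = np.zeros(N)
    a = np.empty(g)
    inv_var = 1.0 / (sigma * sigma)
    for t in range(T):
        for m in range(M):
            base = m * g
            s = 0.0
            for k in range(g):
                ak = theta[base + k] + sigma * z[t, base + k]
                if clamp and ak > a_max:
                    ak = a_max
                a[k] = ak
                s += ak
            abar = s / g
            ben = B0 + B1 * abar + 0.5 * B2 * abar * abar
            for k in range(g):
                i = base + k
                ak = a[k]
                base_cost = K1 * ak + 0.5 * K11 * ak * ak
                reward = ben - (base_cost + K12 * ak * p[i])
                delta = reward - w[i]
                w[i] += alpha_w * delta
                theta[i] += alpha_theta * delta * (ak - theta[i]) * inv_var
                fit[i] += ben - (base_cost + K12 * ak * q[i])
    return w, theta, fit / T
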