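"""Independent oracles used only by the tests."""

import numba
import numpy as np


@numba.njit(cache=True)
def euler_first_passage(v, a, z_rel, n, dt, seed):
    """Euler-Maruyama simulation of the Wiener first-passage problem.

    Returns (times, upper_flags).  Brute-force oracle for the analytic
    density and for the grid-based sampler; never used by the package.
    Discrete monitoring misses excursions beyond the boundary between
    steps, so the boundaries are pulled inward by the Broadie-Glasserman-Kou
    continuity correction 0.5826 * sigma * sqrt(dt).
    """
    np.random.seed(seed)
    times = np.empty(n)
    upper = np.empty(n, dtype=np.bool_)
    sqdt = np.sqrt(dt)
    c = 0.5826 * sqdt
    hi = a - c
    lo = c
    for i in range(n):
        x = z_rel * a
        t = 0.0
        while True:
            x += v * dt + sqdt * np.random.normal()
            t += dt
            if x >= hi:
                upper[i] = True
                break
            if x <= lo:
                upper[i] = False
                break
        times[i] = t
    return times, upper
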