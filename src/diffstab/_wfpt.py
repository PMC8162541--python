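"""Numba kernels for the Wiener first-passage-time density.

The density of the first passage through the *lower* boundary of a Wiener
process with drift ``v``, boundary separation ``a``, relative start ``w``
and unit diffusion scale is evaluated by switching between the small-time
and large-time series expansions, truncated so that the absolute error on
the standardized density is below ``err`` (default 1e-7).  The switch picks
whichever series needs fewer terms at the given standardized time.
"""

import math

import numba
import numpy as np

# absolute truncation error on the standardized density
_ERR = 1e-7


@numba.njit(cache=True, fastmath=False)
def _f_standardized(tt, w, err):
    """Density of first passage at the lower boundary for a=1, v=0, time tt."""
    # number of terms required by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # number of terms required by the large-time expansion
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:  # small-time series
        K = int(math.ceil(ks))
        acc = 0.0
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            y = w + 2.0 * k
            acc += y * math.exp(-y * y / (2.0 * tt))
        return acc / math.sqrt(2.0 * math.pi * tt * tt * tt)
    # large-time series
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@numba.njit(cache=True, fastmath=False)
def logpdf_lower(t, v, a, w):
    """Log density of first passage through the lower boundary at decision time t."""
    if t <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return -np.inf
    tt = t / (a * a)
    f = _f_standardized(tt, w, _ERR)
    if f < 1e-300:
        f = 1e-300
    return math.log(f) - math.log(a * a) - v * a * w - v * v * t / 2.0


@numba.njit(cache=True, fastmath=False)
def logpdf_upper(t, v, a, w):
    """Upper boundary: reflect (v -> -v, w -> 1-w)."""
    return logpdf_lower(t, -v, a, 1.0 - w)


@numba.njit(cache=True, fastmath=False)
def pdf_grid(ts, v, a, w, upper):
    """Density evaluated on a time grid (decision time, one boundary)."""
    out = np.empty(ts.shape[0])
    for i in range(ts.shape[0]):
        if upper:
            out[i] = math.exp(logpdf_upper(ts[i], v, a, w))
        else:
            out[i] = math.exp(logpdf_lower(ts[i], v, a, w))
    return out


@numba.njit(cache=True, fastmath=False)
def prob_upper(v, a, w):
    """Absorption probability at the upper boundary (sigma = 1)."""
    z = w * a
    if abs(v) < 1e-10:
        return w
    # stable evaluation of (1 - exp(-2 v z)) / (1 - exp(-2 v a))
    num = -math.expm1(-2.0 * v * z)
    den = -math.expm1(-2.0 * v * a)
    return num / den


@numba.njit(cache=True, fastmath=False)
def trials_loglik(rt, correct, cond, nu0, a0, tp, tm, dnu, da):
    """Summed Wiener log likelihood of one person's trials.

    ``cond`` holds condition indices 0..9; indices 0..8 read the free effect
    entries, index 9 uses the negated sum (sum-to-zero effect coding).
    Correct responses hit the upper boundary (non-decision time tp), errors
    the lower boundary (tm).
    """
    s_nu = 0.0
    s_a = 0.0
    for c in range(dnu.shape[0]):
        s_nu += dnu[c]
        s_a += da[c]
    total = 0.0
    for j in range(rt.shape[0]):
        c = cond[j]
        if c < dnu.shape[0]:
            v = nu0 + dnu[c]
            a = a0 + da[c]
        else:
            v = nu0 - s_nu
            a = a0 - s_a
        if a <= 0.0:
            return -np.inf
        if correct[j]:
            t = rt[j] - tp
            lp = logpdf_upper(t, v, a, 0.5)
        else:
            t = rt[j] - tm
            lp = logpdf_lower(t, v, a, 0.5)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total
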