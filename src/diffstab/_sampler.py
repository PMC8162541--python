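"""Numba kernels for the within-person Metropolis sweeps of the hierarchical fit.

Persons are conditionally independent given the group-level parameters, so a
sweep proposes one block update per person (pre-generated proposal increments
and uniform variates are passed in) and accepts/rejects against the person's
trial likelihood plus hierarchical prior.  Columns of the person parameter
matrix P (n_persons x 22): 0=nu0, 1=a0, 2=tau_correct, 3=tau_error,
4:13 = free drift condition effects, 13:22 = free boundary condition effects.
"""

import numba
import numpy as np

from ._wfpt import trials_loglik


@numba.njit(cache=True)
def person_logliks(rt, correct, cond, offsets, P):
    n = offsets.shape[0] - 1
    out = np.empty(n)
    for i in range(n):
        s, e = offsets[i], offsets[i + 1]
        out[i] = trials_loglik(
            rt[s:e], correct[s:e], cond[s:e],
            P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4:13], P[i, 13:22],
        )
    return out


@numba.njit(cache=True)
def sweep_base(rt, correct, cond, offsets, P, ll, prop, logu,
               mu_nu, sig_nu, mu_a, sig_a, mu_tc, sig_tc, mu_te, sig_te):
    """Joint update of (nu0, a0, tau+, tau-) per person."""
    n = offsets.shape[0] - 1
    acc = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        nu0 = P[i, 0] + prop[i, 0]
        a0 = P[i, 1] + prop[i, 1]
        tp = P[i, 2] + prop[i, 2]
        tm = P[i, 3] + prop[i, 3]
        if a0 <= 0.0 or tp < 0.0 or tm < 0.0:
            continue
        s, e = offsets[i], offsets[i + 1]
        new_ll = trials_loglik(
            rt[s:e], correct[s:e], cond[s:e], nu0, a0, tp, tm, P[i, 4:13], P[i, 13:22]
        )
        if new_ll == -np.inf:
            continue
        dpr = (
            ((P[i, 0] - mu_nu) ** 2 - (nu0 - mu_nu) ** 2) / (2.0 * sig_nu * sig_nu)
            + ((P[i, 1] - mu_a) ** 2 - (a0 - mu_a) ** 2) / (2.0 * sig_a * sig_a)
            + ((P[i, 2] - mu_tc) ** 2 - (tp - mu_tc) ** 2) / (2.0 * sig_tc * sig_tc)
            + ((P[i, 3] - mu_te) ** 2 - (tm - mu_te) ** 2) / (2.0 * sig_te * sig_te)
        )
        if logu[i] < new_ll - ll[i] + dpr:
            P[i, 0], P[i, 1], P[i, 2], P[i, 3] = nu0, a0, tp, tm
            ll[i] = new_ll
            acc[i] = 1
    return acc


@numba.njit(cache=True)
def sweep_effects(rt, correct, cond, offsets, P, ll, prop, logu,
                  col0, eff_mean, eff_sd):
    """Joint update of one 9-dim effect block (cols col0..col0+8) per person.

    ``eff_mean`` holds the group-level free effects; person deviations share
    the spread ``eff_sd``.
    """
    n = offsets.shape[0] - 1
    acc = np.zeros(n, dtype=np.uint8)
    newv = np.empty(9)
    for i in range(n):
        dpr = 0.0
        for c in range(9):
            old = P[i, col0 + c]
            newv[c] = old + prop[i, c]
            dpr += ((old - eff_mean[c]) ** 2 - (newv[c] - eff_mean[c]) ** 2) / (
                2.0 * eff_sd * eff_sd
            )
        # swap in proposal, evaluate, swap back on reject
        s, e = offsets[i], offsets[i + 1]
        if col0 == 4:
            new_ll = trials_loglik(
                rt[s:e], correct[s:e], cond[s:e],
                P[i, 0], P[i, 1], P[i, 2], P[i, 3], newv, P[i, 13:22],
            )
        else:
            new_ll = trials_loglik(
                rt[s:e], correct[s:e], cond[s:e],
                P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4:13], newv,
            )
        if new_ll == -np.inf:
            continue
        if logu[i] < new_ll - ll[i] + dpr:
            for c in range(9):
                P[i, col0 + c] = newv[c]
            ll[i] = new_ll
            acc[i] = 1
    return acc


@numba.njit(cache=True)
def shift_col_logliks(rt, correct, cond, offsets, P, col, delta):
    """Per-person likelihoods after adding ``delta`` to one base column.

    Supports the translation move for the error non-decision time, whose
    person values are pinned to the group mean when errors are rare.
    """
    n = offsets.shape[0] - 1
    out = np.empty(n)
    vals = np.empty(4)
    for i in range(n):
        for c in range(4):
            vals[c] = P[i, c]
        vals[col] += delta
        if vals[1] <= 0.0 or vals[2] < 0.0 or vals[3] < 0.0:
            out[i] = -np.inf
            return out
        s, e = offsets[i], offsets[i + 1]
        out[i] = trials_loglik(
            rt[s:e], correct[s:e], cond[s:e],
            vals[0], vals[1], vals[2], vals[3], P[i, 4:13], P[i, 13:22],
        )
        if out[i] == -np.inf:
            return out
    return out


@numba.njit(cache=True)
def shift_logliks(rt, correct, cond, offsets, P, col0, delta):
    """Per-person likelihoods after shifting one effect family by ``delta``.

    Used by the joint translation move that displaces the group effect means
    and every person's effects together (person deviations stay fixed), which
    decorrelates the group means from the person-level random effects.
    """
    n = offsets.shape[0] - 1
    out = np.empty(n)
    eff = np.empty(9)
    for i in range(n):
        for c in range(9):
            eff[c] = P[i, col0 + c] + delta[c]
        s, e = offsets[i], offsets[i + 1]
        if col0 == 4:
            out[i] = trials_loglik(
                rt[s:e], correct[s:e], cond[s:e],
                P[i, 0], P[i, 1], P[i, 2], P[i, 3], eff, P[i, 13:22],
            )
        else:
            out[i] = trials_loglik(
                rt[s:e], correct[s:e], cond[s:e],
                P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4:13], eff,
            )
        if out[i] == -np.inf:
            return out
    return out
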