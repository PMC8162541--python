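"""Small adaptive-Metropolis building blocks shared by the model fitters."""

from __future__ import annotations

import numpy as np


def mh_scalar(value: float, logpost, scale: float, rng: np.random.Generator,
              lower: float = -np.inf, upper: float = np.inf):
    """One random-walk Metropolis step on a scalar; returns (value, accepted)."""
    prop = value + scale * rng.standard_normal()
    if prop <= lower or prop >= upper:
        return value, False
    lp_new = logpost(prop)
    if lp_new == -np.inf:
        return value, False
    lp_old = logpost(value)
    if np.log(rng.random()) < lp_new - lp_old:
        return prop, True
    return value, False


class ScalarAdapter:
    """Robbins-Monro step-size adaptation toward a target acceptance rate."""

    def __init__(self, scale: float = 0.1, target: float = 0.44):
        self.log_scale = np.log(scale)
        self.target = target
        self.t = 0

    @property
    def scale(self) -> float:
        return float(np.exp(self.log_scale))

    def update(self, accepted) -> None:
        self.t += 1
        gamma = 1.0 / np.sqrt(self.t + 10.0)
        self.log_scale += gamma * (float(accepted) - self.target)


def adaptive_metropolis(
    log_post,
    x0: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    n_burnin: int = 0,
    target: float = 0.234,
    init_scale: float = 0.1,
    adapt_until: int | None = None,
):
    """Haario-style adaptive Metropolis in d dimensions.

    Proposal covariance = (2.38^2/d) * running empirical covariance, with a
    scalar step-size multiplier tuned toward the target acceptance rate.
    Returns (retained draws, retained log posteriors, acceptance rate).
    """
    d = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at the initial point")
    adapt_until = n_iter if adapt_until is None else adapt_until

    mean = x.copy()
    cov = np.eye(d) * init_scale**2
    chol = np.linalg.cholesky(cov)
    log_s = 0.0
    out = np.empty((n_iter - n_burnin, d))
    out_lp = np.empty(n_iter - n_burnin)
    n_acc = 0
    for it in range(n_iter):
        z = rng.standard_normal(d)
        prop = x + np.exp(log_s) * (chol @ z)
        lp_prop = log_post(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
            if it >= n_burnin:
                n_acc += 1
        if it < adapt_until:
            gamma = 1.0 / (it + 20.0) ** 0.6
            log_s += gamma * (float(accept) - target)
            delta = x - mean
            mean += gamma * delta
            cov += gamma * (np.outer(delta, delta) - cov)
            if it % 25 == 24:
                sc = 2.38**2 / d
                try:
                    chol = np.linalg.cholesky(sc * cov + 1e-12 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
        if it >= n_burnin:
            out[it - n_burnin] = x
            out_lp[it - n_burnin] = lp
    return out, out_lp, n_acc / max(n_iter - n_burnin, 1)
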