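"""Bayesian latent growth curve models on person x time posterior medians.

The model for one diffusion parameter has a latent intercept I (loadings
fixed at 1 for all four waves) and a latent slope S with loadings
(0, 1, l3, l4), l3 and l4 free.  Marginally the four observed values are
multivariate normal with mean ``mu_I + mu_S * lambda`` and covariance
``Lambda Phi Lambda' + diag(eps)``.  Persons with partial time points
contribute through their observed margins (full-information likelihood);
listwise deletion is available as a switch.

A two-pass fixing procedure mirrors common practice: if the 95% CI of the
intercept-slope covariance includes zero it is fixed to zero and the model
refitted; if in that refit the slope variance is estimated as (effectively)
zero it is fixed too.  Approximate fit is summarized by posterior-mean
Bayesian CFI and GammaHat computed from the per-draw ML discrepancy against
the saturated and independence models on the complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats

from .diagnostics import rhat as _rhat

N_TIME = 4
FREE_NAMES = ("mu_I", "mu_S", "lam3", "lam4", "var_I", "var_S", "cov_IS",
              "eps1", "eps2", "eps3", "eps4")


class GrowthError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthSpec:
    n_chains: int = 3
    n_iter: int = 16000
    n_burnin: int = 4000
    #: fix sigma_IS when its 95% CI includes zero
    fix_cov_if_ci_includes_zero: bool = True
    #: fix the slope variance when its posterior median is indistinguishable
    #: from zero (below this fraction of the intercept-variance median)
    slope_var_zero_fraction: float = 0.03
    listwise: bool = False
    seed: int = 0


@dataclass
class GrowthModelFit:
    estimates: pd.DataFrame          # parameter, mean, sd, ci_low, ci_high, fixed
    standardized: pd.DataFrame       # completely standardized solution
    loadings_slope: tuple            # posterior means (0, 1, l3, l4)
    fixed_cov: bool
    fixed_slope_var: bool
    bcfi: float
    bgammahat: float
    converged: bool
    n_persons: int
    draws: dict = field(repr=False, default_factory=dict)

    def estimate(self, name: str) -> float:
        return float(self.estimates.set_index("parameter").loc[name, "mean"])

    def ci(self, name: str) -> tuple[float, float]:
        row = self.estimates.set_index("parameter").loc[name]
        return float(row["ci_low"]), float(row["ci_high"])


def _prepare(wide: pd.DataFrame, listwise: bool) -> np.ndarray:
    y = np.asarray(wide, dtype=float)
    if y.shape[1] != N_TIME:
        raise GrowthError(f"expected {N_TIME} time-point columns, got {y.shape[1]}")
    obs = np.isfinite(y)
    y = y[obs.sum(axis=1) >= (N_TIME if listwise else 1)]
    n2 = int((np.isfinite(y).sum(axis=1) >= 2).sum())
    if n2 < 50:
        raise GrowthError(f"need >= 50 persons with >= 2 observed waves, got {n2}")
    return y


class _Likelihood:
    """FIML log likelihood grouped by missingness pattern."""

    def __init__(self, y: np.ndarray):
        obs = np.isfinite(y)
        keys = obs @ (1 << np.arange(N_TIME))
        self.groups = []
        for key in np.unique(keys):
            rows = y[keys == key]
            mask = obs[keys == key][0]
            self.groups.append((mask, rows[:, mask]))

    def __call__(self, mean: np.ndarray, cov: np.ndarray) -> float:
        total = 0.0
        for mask, rows in self.groups:
            m = mean[mask]
            c = cov[np.ix_(mask, mask)]
            try:
                L = np.linalg.cholesky(c)
            except np.linalg.LinAlgError:
                return -np.inf
            dev = rows - m
            z = np.linalg.solve(L, dev.T)
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            k = rows.shape[1]
            total += -0.5 * (
                rows.shape[0] * (k * np.log(2 * np.pi) + logdet) + np.sum(z * z)
            )
        return float(total)


def _implied(theta: np.ndarray, fixed_cov: bool, fixed_slope_var: bool):
    mu_I, mu_S, l3, l4 = theta[0], theta[1], theta[2], theta[3]
    var_I, var_S, cov_IS = theta[4], theta[5], theta[6]
    eps = theta[7:11]
    if fixed_slope_var:
        var_S, cov_IS = 0.0, 0.0
    elif fixed_cov:
        cov_IS = 0.0
    lam = np.array([0.0, 1.0, l3, l4])
    mean = mu_I + mu_S * lam
    cov = var_I + cov_IS * (lam[:, None] + lam[None, :]) + var_S * np.outer(lam, lam)
    cov = cov + np.diag(eps)
    return mean, cov, lam


def _fit_once(y, fixed_cov, fixed_slope_var, spec, rng_seed):
    """One MCMC pass: conjugate Gibbs with latent (I, S) augmentation.

    The model is linear-Gaussian, so every full conditional is available in
    closed form: person latents given parameters, latent means given
    latents, the latent covariance (inverse-Wishart, or independent
    inverse-gammas when the intercept-slope covariance is fixed at zero),
    the free slope loadings (Bayesian regression on the latent slopes) and
    the residual variances (inverse-gamma).  Missing waves drop out of the
    relevant sums, which realizes the full-information treatment.  Priors
    are weakly informative and scaled to the pooled sample variance.
    """
    lik = _Likelihood(y)
    pooled = y[np.isfinite(y)]
    s2 = float(np.var(pooled)) + 1e-12
    m = float(np.mean(pooled))
    obs = np.isfinite(y)
    n, _ = y.shape
    y0 = np.where(obs, y, 0.0)

    # hyperparameters of the weakly-informative priors
    mu_prior_var = 25.0 * s2
    lam_prior_mean, lam_prior_var = 1.0, 25.0
    # shapes near 1 keep the inverse-gamma tails heavy so the likelihood,
    # not the prior scale, determines the variance components
    a_eps, b_eps = 1.0, s2 / 100.0
    a_vi, b_vi = 1.0, s2 / 100.0
    a_vs, b_vs = 1.0, s2 / 100.0
    iw_df, iw_scale = 3.0, np.diag([s2 / 50.0, s2 / 50.0])

    keep = spec.n_iter - spec.n_burnin
    chains = np.empty((spec.n_chains, keep, 11))
    ss = np.random.SeedSequence(rng_seed)
    col_means = np.array([np.nanmean(y[:, t]) for t in range(N_TIME)])
    for c, child in enumerate(ss.spawn(spec.n_chains)):
        rng = np.random.default_rng(child)
        mu_I = col_means[0] + 0.05 * rng.standard_normal() * np.sqrt(s2)
        mu_S = (col_means[1] - col_means[0]) * (1 + 0.1 * rng.standard_normal())
        l3, l4 = 1.0 + 0.2 * rng.standard_normal(2)
        var_I = 0.7 * s2
        var_S = 0.0 if fixed_slope_var else 0.1 * s2
        cov_IS = 0.0
        eps = np.full(N_TIME, 0.3 * s2)
        I = np.where(obs[:, 0], y0[:, 0], col_means[0]).copy()
        S = np.full(n, mu_S)

        for it in range(spec.n_iter):
            lam = np.array([0.0, 1.0, l3, l4])
            # --- person latents -------------------------------------------
            if fixed_slope_var:
                prec = 1.0 / var_I + (obs / eps).sum(axis=1)
                mean_num = mu_I / var_I + (obs * (y0 - mu_S * lam) / eps).sum(axis=1)
                post_var = 1.0 / prec
                I = mean_num * post_var + np.sqrt(post_var) * rng.standard_normal(n)
                S = np.full(n, mu_S)
            else:
                Phi = np.array([[var_I, cov_IS], [cov_IS, var_S]])
                Phi_inv = np.linalg.inv(Phi)
                mu_vec = np.array([mu_I, mu_S])
                X = np.stack([np.ones(N_TIME), lam], axis=1)  # (4, 2)
                keys = obs @ (1 << np.arange(N_TIME))
                for key in np.unique(keys):
                    rows = keys == key
                    mask = obs[rows][0]
                    Xm = X[mask]
                    A = Phi_inv + Xm.T @ (Xm / eps[mask, None])
                    Apost = np.linalg.inv(A)
                    rhs = (Phi_inv @ mu_vec)[None, :] + (
                        y0[rows][:, mask] / eps[mask]
                    ) @ Xm
                    mean_latent = rhs @ Apost.T
                    L = np.linalg.cholesky(Apost)
                    z = rng.standard_normal((rows.sum(), 2))
                    draw = mean_latent + z @ L.T
                    I[rows], S[rows] = draw[:, 0], draw[:, 1]

            # --- latent means ---------------------------------------------
            if fixed_slope_var:
                pv = 1.0 / (n / var_I + 1.0 / mu_prior_var)
                mu_I = pv * (np.sum(I) / var_I + m / mu_prior_var)
                mu_I += np.sqrt(pv) * rng.standard_normal()
                # mu_S enters the mean structure directly
                prec = (obs * lam**2 / eps).sum() + 1.0 / mu_prior_var
                num = (obs * (y0 - I[:, None]) * lam / eps).sum()
                mu_S = num / prec + rng.standard_normal() / np.sqrt(prec)
                S = np.full(n, mu_S)
            else:
                Phi = np.array([[var_I, cov_IS], [cov_IS, var_S]])
                Phi_inv = np.linalg.inv(Phi)
                prec_mu = n * Phi_inv + np.eye(2) / mu_prior_var
                cov_mu = np.linalg.inv(prec_mu)
                mean_mu = cov_mu @ (
                    Phi_inv @ np.array([I.sum(), S.sum()])
                    + np.array([m, 0.0]) / mu_prior_var
                )
                draw = mean_mu + np.linalg.cholesky(cov_mu) @ rng.standard_normal(2)
                mu_I, mu_S = float(draw[0]), float(draw[1])

            # --- latent (co)variances -------------------------------------
            dI = I - mu_I
            if fixed_slope_var:
                var_I = _inv_gamma(rng, a_vi + n / 2.0, b_vi + 0.5 * np.sum(dI**2))
            else:
                dS = S - mu_S
                if fixed_cov:
                    var_I = _inv_gamma(rng, a_vi + n / 2.0, b_vi + 0.5 * np.sum(dI**2))
                    var_S = _inv_gamma(rng, a_vs + n / 2.0, b_vs + 0.5 * np.sum(dS**2))
                    cov_IS = 0.0
                else:
                    D = np.stack([dI, dS], axis=1)
                    scale_post = iw_scale + D.T @ D
                    Phi = stats.invwishart.rvs(df=iw_df + n, scale=scale_post, random_state=rng)
                    var_I, var_S, cov_IS = Phi[0, 0], Phi[1, 1], Phi[0, 1]

            # --- free slope loadings --------------------------------------
            for t, set_l in ((2, "l3"), (3, "l4")):
                o = obs[:, t]
                s_vec = S[o]
                prec = np.sum(s_vec**2) / eps[t] + 1.0 / lam_prior_var
                num = np.sum(s_vec * (y0[o, t] - I[o])) / eps[t] + lam_prior_mean / lam_prior_var
                val = num / prec + rng.standard_normal() / np.sqrt(prec)
                if set_l == "l3":
                    l3 = val
                else:
                    l4 = val

            # --- residual variances ---------------------------------------
            lam = np.array([0.0, 1.0, l3, l4])
            resid = y0 - I[:, None] - S[:, None] * lam
            for t in range(N_TIME):
                o = obs[:, t]
                eps[t] = _inv_gamma(
                    rng, a_eps + o.sum() / 2.0, b_eps + 0.5 * np.sum(resid[o, t] ** 2)
                )

            if it >= spec.n_burnin:
                chains[c, it - spec.n_burnin] = (
                    mu_I, mu_S, l3, l4, var_I, var_S, cov_IS, *eps
                )
    return chains, lik, s2


def _inv_gamma(rng, shape, scale):
    return float(scale / rng.gamma(shape))


def _fit_indices(chains, y, fixed_cov, fixed_slope_var, n_draws=400):
    """Posterior-mean bCFI / bGammaHat from the per-draw ML discrepancy."""
    complete = y[np.isfinite(y).all(axis=1)]
    n = complete.shape[0]
    if n < 10:
        return np.nan, np.nan
    S = np.cov(complete.T, ddof=0)
    mbar = complete.mean(axis=0)
    p = N_TIME
    sign, logdet_S = np.linalg.slogdet(S)
    n_free = 11 - (2 if fixed_slope_var else (1 if fixed_cov else 0))
    df_m = p * (p + 3) // 2 - n_free
    # independence baseline: diagonal covariance, free means
    chi_b = n * (np.sum(np.log(np.diag(S))) - logdet_S)
    df_b = p * (p + 3) // 2 - 2 * p

    flat = chains.reshape(-1, chains.shape[-1])
    idx = np.linspace(0, len(flat) - 1, min(n_draws, len(flat))).astype(int)

    def chi2(theta):
        mean, cov, _ = _implied(theta, fixed_cov, fixed_slope_var)
        try:
            cinv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            return np.nan
        _, logdet_c = np.linalg.slogdet(cov)
        dev = mbar - mean
        return n * (logdet_c + np.trace(S @ cinv) - logdet_S - p + dev @ cinv @ dev)

    chis = np.array([chi2(t) for t in flat[idx]])
    chis = chis[np.isfinite(chis)]
    if len(chis) == 0:
        return np.nan, np.nan
    # effective number of parameters: posterior-mean discrepancy minus the
    # plug-in discrepancy; corrects the uncertainty inflation of chi2(theta)
    pd_m = max(float(chis.mean() - chi2(flat[idx].mean(axis=0))), 0.0)
    cfis, gammas = [], []
    for chi_m in chis:
        ncp = chi_m - pd_m - df_m
        gammas.append(p / (p + 2 * max(ncp, 0.0) / n))
        denom = max(chi_b - df_b, ncp, 1e-12)
        cfis.append(1.0 - max(ncp, 0.0) / denom)
    return float(np.clip(np.mean(cfis), 0, 1)), float(np.clip(np.mean(gammas), 0, 1))


def _summaries(chains, fixed_cov, fixed_slope_var):
    rows = []
    for k, name in enumerate(FREE_NAMES):
        x = chains[:, :, k]
        fixed = (name == "cov_IS" and (fixed_cov or fixed_slope_var)) or (
            name == "var_S" and fixed_slope_var
        )
        if fixed:
            rows.append((name, 0.0, 0.0, 0.0, 0.0, True))
        else:
            lo, hi = np.quantile(x, [0.025, 0.975])
            rows.append((name, float(x.mean()), float(x.std()), float(lo), float(hi), False))
    return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "ci_low", "ci_high", "fixed"])


def _standardized(est: pd.DataFrame, fixed_slope_var: bool) -> pd.DataFrame:
    g = est.set_index("parameter")["mean"]
    lam = np.array([0.0, 1.0, g["lam3"], g["lam4"]])
    var_S = 0.0 if fixed_slope_var else g["var_S"]
    cov_IS = g["cov_IS"]
    eps = np.array([g[f"eps{t + 1}"] for t in range(N_TIME)])
    tot = g["var_I"] + 2 * lam * cov_IS + lam**2 * var_S + eps
    sd = np.sqrt(tot)
    rows = []
    for t in range(N_TIME):
        rows.append((f"loading_I_t{t + 1}", np.sqrt(g["var_I"]) / sd[t]))
        rows.append((f"loading_S_t{t + 1}", lam[t] * np.sqrt(var_S) / sd[t]))
        rows.append((f"residual_t{t + 1}", eps[t] / tot[t]))
    rows.append(("mean_I", g["mu_I"] / np.sqrt(g["var_I"])))
    rows.append(("mean_S", g["mu_S"] / np.sqrt(var_S) if var_S > 0 else np.inf * np.sign(g["mu_S"])))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def fit_growth_curve(
    wide: pd.DataFrame,
    spec: GrowthSpec | None = None,
) -> GrowthModelFit:
    """Fit the latent growth model to a persons x 4-waves table of medians.

    Applies the two-pass fixing rules (intercept-slope covariance, then
    slope variance) and reports unstandardized and standardized solutions
    plus posterior-mean bCFI / bGammaHat.  A fit with any free-parameter
    split-R-hat above 1.01 is flagged ``converged=False``.
    """
    spec = spec or GrowthSpec()
    y = _prepare(wide, spec.listwise)

    fixed_cov = False
    fixed_slope_var = False
    chains, lik, s2 = _fit_once(y, fixed_cov, fixed_slope_var, spec, spec.seed)
    lo, hi = np.quantile(chains[:, :, 6], [0.025, 0.975])
    if spec.fix_cov_if_ci_includes_zero and lo <= 0.0 <= hi:
        fixed_cov = True
        chains, lik, s2 = _fit_once(y, fixed_cov, fixed_slope_var, spec, spec.seed + 1)
        vs_med = np.median(chains[:, :, 5])
        var_I_med = np.median(chains[:, :, 4])
        if vs_med < spec.slope_var_zero_fraction * var_I_med:
            fixed_slope_var = True
            chains, lik, s2 = _fit_once(y, fixed_cov, fixed_slope_var, spec, spec.seed + 2)

    free_idx = [
        k for k, name in enumerate(FREE_NAMES)
        if not ((name == "cov_IS" and (fixed_cov or fixed_slope_var))
                or (name == "var_S" and fixed_slope_var))
    ]
    converged = all(_rhat(chains[:, :, k]) <= 1.01 for k in free_idx)

    est = _summaries(chains, fixed_cov, fixed_slope_var)
    bcfi, bgamma = _fit_indices(chains, y, fixed_cov, fixed_slope_var)
    lam = (0.0, 1.0, est.set_index("parameter").loc["lam3", "mean"],
           est.set_index("parameter").loc["lam4", "mean"])
    return GrowthModelFit(
        estimates=est,
        standardized=_standardized(est, fixed_slope_var),
        loadings_slope=lam,
        fixed_cov=fixed_cov or fixed_slope_var,
        fixed_slope_var=fixed_slope_var,
        bcfi=bcfi,
        bgammahat=bgamma,
        converged=converged,
        n_persons=y.shape[0],
        draws={name: chains[:, :, k] for k, name in enumerate(FREE_NAMES)},
    )
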