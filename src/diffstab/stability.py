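"""Stability and change analyses on person x time posterior medians.

Four analyses: rank-order stability (Bayesian correlations with a uniform
prior on rho and Savage-Dickey Bayes factors), mean-level change (group-level
posterior HDIs compared across time points), individual differences in
change (latent growth curves, in :mod:`diffstab.growth`), and profile
stability (within-person q correlations of z-standardized parameter
profiles).  Plus the Bayes-factor t-tests comparing dropouts to completers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate

PARAMS = ("nu", "a", "tau")
N_TIME = 4


class AnalysisError(ValueError):
    pass


# --------------------------------------------------------------------------
# Bayesian correlation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    mean: float
    ci_low: float
    ci_high: float
    bf10: float
    n: int

    def __post_init__(self):
        if not (-1.0 <= self.mean <= 1.0) or self.ci_low > self.ci_high:
            raise AnalysisError("invalid correlation result")

    def ci_string(self) -> str:
        return f"{self.mean:.2f} [{self.ci_low:.2f}–{self.ci_high:.2f}]"

    def bf_string(self) -> str:
        return ">999" if self.bf10 > 999 else f"{self.bf10:.2f}"


def _rho_posterior(r: float, n: int, grid: np.ndarray) -> np.ndarray:
    """Unnormalized posterior of rho under a uniform prior on (-1, 1).

    Uses the reduced likelihood of the sample correlation,
    p(r | rho, n) ∝ (1 - rho^2)^((n-1)/2) * (1 - rho*r)^(-(n - 3/2)),
    a standard large-n-accurate approximation of the exact sampling
    distribution of r.
    """
    logp = 0.5 * (n - 1) * np.log1p(-grid**2) - (n - 1.5) * np.log1p(-grid * r)
    logp -= logp.max()
    return np.exp(logp)


def bayesian_correlation(x, y) -> CorrelationResult:
    """Posterior of the correlation of paired data under a uniform prior.

    The posterior over rho is obtained by quadrature; BF10 is the
    Savage-Dickey density ratio at rho = 0 (prior density 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise AnalysisError(f"need n >= 3 complete pairs, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("correlation undefined: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])

    grid = np.linspace(-1 + 1e-9, 1 - 1e-9, 8001)
    post = _rho_posterior(r, n, grid)
    norm = np.trapezoid(post, grid)
    dens = post / norm
    cdf = integrate.cumulative_trapezoid(dens, grid, initial=0.0)
    cdf /= cdf[-1]
    mean = float(np.trapezoid(grid * dens, grid))
    lo = float(np.interp(0.025, cdf, grid))
    hi = float(np.interp(0.975, cdf, grid))
    dens0 = float(np.interp(0.0, grid, dens))
    bf10 = 0.5 / max(dens0, 1e-300)
    return CorrelationResult(mean, lo, hi, bf10, n)


TIME_PAIRS = tuple(combinations(range(N_TIME), 2))


def rank_order_matrix(
    medians: pd.DataFrame,
    parameter: str,
    subgroup: int | None = None,
    min_n: int = 3,
    small_n: int = 30,
) -> pd.DataFrame:
    """Pairwise-complete Bayesian correlations across all six time pairs.

    ``medians``: long table (participant_id, wave, nu, a, tau) with NaN for
    missing/excluded persons.  Pairs with fewer than ``min_n`` complete
    cases yield a missing cell; cells with n < ``small_n`` are flagged.
    """
    if parameter not in PARAMS:
        raise AnalysisError(f"unknown parameter {parameter!r}")
    df = medians
    if subgroup is not None:
        df = df[df["subgroup"] == subgroup]
    wide = df.pivot_table(index="participant_id", columns="wave", values=parameter)
    rows = []
    for i, j in TIME_PAIRS:
        if i not in wide.columns or j not in wide.columns:
            rows.append((i, j, *[np.nan] * 4, 0, True))
            continue
        pair = wide[[i, j]].dropna()
        if len(pair) < min_n:
            rows.append((i, j, *[np.nan] * 4, len(pair), True))
            continue
        res = bayesian_correlation(pair[i], pair[j])
        rows.append((i, j, res.mean, res.ci_low, res.ci_high, res.bf10, res.n, res.n < small_n))
    return pd.DataFrame(
        rows,
        columns=["wave_i", "wave_j", "rho", "ci_low", "ci_high", "bf10", "n", "small_n_flag"],
    )


# --------------------------------------------------------------------------
# Mean-level change
# --------------------------------------------------------------------------

def hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the sample (sorted-window).

    Ties between equally short windows are broken to the leftmost.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise AnalysisError(f"need >= 100 samples for an HDI, got {n}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))  # argmin takes the first (leftmost) minimum
    return float(x[i]), float(x[i + k])


def mean_level_comparison(group_draws: dict[int, np.ndarray], mass: float = 0.95) -> pd.DataFrame:
    """Pairwise HDI overlap of group-level posteriors across time points.

    ``group_draws``: wave -> draws of the group-level parameter.  Reports
    both HDIs, an overlap indicator and the posterior mean difference per
    time-point pair.
    """
    waves = sorted(group_draws)
    intervals = {w: hdi(group_draws[w], mass) for w in waves}
    rows = []
    for i, j in combinations(waves, 2):
        lo_i, hi_i = intervals[i]
        lo_j, hi_j = intervals[j]
        overlap = (lo_i <= hi_j) and (lo_j <= hi_i)
        diff = float(np.mean(group_draws[j]) - np.mean(group_draws[i]))
        rows.append((i, j, lo_i, hi_i, lo_j, hi_j, bool(overlap), diff))
    return pd.DataFrame(
        rows,
        columns=["wave_i", "wave_j", "hdi_low_i", "hdi_high_i",
                 "hdi_low_j", "hdi_high_j", "overlap", "mean_diff"],
    )


# --------------------------------------------------------------------------
# Profile stability
# --------------------------------------------------------------------------

def standardize_profiles(medians: pd.DataFrame) -> pd.DataFrame:
    """z-standardize each parameter within each time point across persons.

    Removes mean-level change so profiles encode relative standing; missing
    values stay missing.
    """
    out = medians.copy()
    for param in PARAMS:
        for wave, idx in out.groupby("wave").groups.items():
            col = out.loc[idx, param]
            vals = col.dropna()
            if len(vals) < 3:
                raise AnalysisError(f"need >= 3 persons for z-scores: {param} at wave {wave}")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise AnalysisError(f"zero variance for {param} at wave {wave}")
            out.loc[idx, param] = (col - vals.mean()) / sd
    return out


def q_profile_correlations(zscores: pd.DataFrame, wave_i: int, wave_j: int) -> pd.DataFrame:
    """Within-person Pearson correlation of the 3-parameter z-profiles.

    Only persons with all three parameters present at both waves get a q;
    zero-variance profiles yield a missing q (counted, not an error).
    """
    wi = zscores[zscores["wave"] == wave_i].set_index("participant_id")[list(PARAMS)]
    wj = zscores[zscores["wave"] == wave_j].set_index("participant_id")[list(PARAMS)]
    common = wi.dropna().index.intersection(wj.dropna().index)
    rows = []
    for pid in common:
        p1 = wi.loc[pid].to_numpy(dtype=float)
        p2 = wj.loc[pid].to_numpy(dtype=float)
        if np.std(p1) == 0 or np.std(p2) == 0:
            rows.append((pid, wave_i, wave_j, np.nan))
        else:
            rows.append((pid, wave_i, wave_j, float(np.corrcoef(p1, p2)[0, 1])))
    return pd.DataFrame(rows, columns=["participant_id", "wave_i", "wave_j", "q"])


def q_summary(zscores: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, median and N of q correlations for all six time pairs."""
    rows = []
    for i, j in TIME_PAIRS:
        q = q_profile_correlations(zscores, i, j)["q"].dropna()
        rows.append((i, j, q.mean(), q.std(ddof=1), q.median(), len(q)))
    return pd.DataFrame(rows, columns=["wave_i", "wave_j", "mean", "sd", "median", "n"])


# --------------------------------------------------------------------------
# Dropout Bayes-factor t-test
# --------------------------------------------------------------------------

def dropout_bayes_t_test(x_dropout, y_complete, cauchy_scale: float = np.sqrt(2) / 2) -> float:
    """Two-sample JZS Bayes factor (BF10) for a mean difference.

    Zero-centered Cauchy prior with the conventional sqrt(2)/2 scale on the
    standardized effect size; the null model fixes the effect at zero.
    """
    x = np.asarray(x_dropout, dtype=float)
    y = np.asarray(y_complete, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise AnalysisError("both groups need n >= 2")
    nu = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / nu
    if sp2 == 0:
        raise AnalysisError("zero pooled variance")
    n_eff = n1 * n2 / (n1 + n2)
    t = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 / n_eff)

    def integrand(g):
        c = 1.0 + n_eff * g * cauchy_scale**2
        log_lik = -0.5 * np.log(c) - 0.5 * (nu + 1) * np.log1p(t**2 / (c * nu))
        # g ~ InverseGamma(1/2, 1/2): Cauchy(0, scale) mixture representation
        log_pg = -0.5 * np.log(np.pi) - 1.5 * np.log(g) - 0.5 / g
        return np.exp(log_lik + log_pg)

    m1, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    log_m0 = -0.5 * (nu + 1) * np.log1p(t**2 / nu)
    return float(m1 / np.exp(log_m0))


def dropout_analysis(medians: pd.DataFrame) -> pd.DataFrame:
    """BF10 per parameter: wave-1 values of persons missing any later wave
    vs persons observed (non-missing) at every wave."""
    wide = medians.pivot_table(index="participant_id", columns="wave", values="nu")
    complete_ids = wide.dropna().index
    w1 = medians[medians["wave"] == 0].set_index("participant_id")
    rows = []
    for param in PARAMS:
        miss = w1.loc[~w1.index.isin(complete_ids), param].dropna()
        comp = w1.loc[w1.index.isin(complete_ids), param].dropna()
        bf = dropout_bayes_t_test(miss, comp)
        rows.append((param, bf, float(miss.mean() - comp.mean()), len(miss), len(comp)))
    return pd.DataFrame(rows, columns=["parameter", "bf10", "mean_diff", "n_dropout", "n_complete"])
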