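"""Per-time-point hierarchical Bayesian estimation of the Wiener diffusion model.

Model structure (one time point): every person has a drift intercept nu0, a
boundary-separation intercept a0, non-decision times tau+ (correct) and tau-
(error), and effect-coded condition offsets on drift and boundary (9 free
per family, the 10th the negated sum) — 22 person-level parameters.  Person
parameters are exchangeable draws from group-level Gaussians; condition
effects are hierarchical (group effect mean + person deviation with one
shared spread per family).  The starting point is fixed at 0.5 and
inter-trial variabilities at zero.

Estimation is Metropolis-within-Gibbs: per iteration one adaptive joint
update of each person's (nu0, a0, tau+, tau-) block with a per-person
covariance-adapted random-walk proposal, one update of each 9-dim effect
block, then conjugate (Gibbs) or scalar-Metropolis updates of the group
hyperparameters.  Person blocks are evaluated with a numba-compiled Wiener
first-passage likelihood.  The chain/burn-in geometry (default 4 chains x
6000 iterations, first 1000 discarded) is configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _sampler

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
from .ddm import CONDITIONS
from .sampling import ScalarAdapter, mh_scalar

HYPER_NAMES = (
    "mu_nu", "sigma_nu", "mu_a", "sigma_a",
    "mu_tau_c", "sigma_tau_c", "mu_tau_e", "sigma_tau_e",
    "sigma_eff_nu", "sigma_eff_a",
)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of the hierarchical model (fixed-by-design values).

    ``min_trials``: persons with fewer retained trials are dropped from the
    fit with a warning.  22 free person-level parameters per person:
    1 + 9 (drift) + 1 + 9 (boundary) + 1 (tau+) + 1 (tau-).
    """

    relative_start: float = 0.5
    n_free_effects: int = 9
    min_trials: int = 20

    @property
    def n_person_params(self) -> int:
        return 2 * (1 + self.n_free_effects) + 2


@dataclass(frozen=True)
class PriorSpec:
    """Hyperpriors of the group-level parameters.

    Weakly informative package defaults on the sigma=1 scale (location-scale
    family, location, scale): group drift mean ~ Normal(2, 3), group boundary
    mean ~ Gamma(shape 4, scale 0.5) (positive, mode near 1.5), group
    non-decision means ~ Normal(0.4, 0.3) truncated at 0, all group spreads
    half-normal.  Condition-effect group means ~ Normal(0, 1).
    """

    mu_nu: tuple = ("normal", 2.0, 3.0)
    sigma_nu: tuple = ("halfnormal", 1.0)
    mu_a: tuple = ("gamma", 4.0, 0.5)
    sigma_a: tuple = ("halfnormal", 1.0)
    mu_tau: tuple = ("truncnormal", 0.4, 0.3)
    sigma_tau: tuple = ("halfnormal", 0.2)
    effect_mean: tuple = ("normal", 0.0, 1.0)
    effect_sd: tuple = ("halfnormal", 0.5)

    def logpdf(self, name: str, value: float) -> float:
        spec = self._entry(name)
        kind = spec[0]
        if kind == "normal":
            m, s = spec[1], spec[2]
            return -0.5 * ((value - m) / s) ** 2 - math.log(s) - _LOG_SQRT_2PI
        if kind == "halfnormal":
            if value <= 0:
                return -np.inf
            s = spec[1]
            return math.log(2.0) - 0.5 * (value / s) ** 2 - math.log(s) - _LOG_SQRT_2PI
        if kind == "gamma":
            if value <= 0:
                return -np.inf
            k, theta = spec[1], spec[2]
            return (k - 1) * math.log(value) - value / theta - k * math.log(theta) - math.lgamma(k)
        if kind == "truncnormal":
            if value < 0:
                return -np.inf
            m, s = spec[1], spec[2]
            logz = math.log(1.0 - 0.5 * math.erfc(m / (s * math.sqrt(2.0))))
            return -0.5 * ((value - m) / s) ** 2 - math.log(s) - _LOG_SQRT_2PI - logz
        raise ValueError(f"unknown prior family {kind!r}")

    def _entry(self, name: str) -> tuple:
        if name in ("mu_tau_c", "mu_tau_e"):
            return self.mu_tau
        if name in ("sigma_tau_c", "sigma_tau_e"):
            return self.sigma_tau
        if name in ("sigma_eff_nu", "sigma_eff_a"):
            return self.effect_sd
        if name.startswith("eff_"):
            return self.effect_mean
        return getattr(self, name)


@dataclass
class PosteriorDraws:
    """Named posterior chains: parameter -> (n_chains, n_retained) array."""

    draws: dict[str, np.ndarray]
    n_chains: int
    n_iter: int
    n_burnin: int
    seed: int
    person_ids: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.n_burnin

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def person_param(self, family: str, pid) -> np.ndarray:
        return self.draws[f"{family}[{pid}]"]

    def to_frame(self) -> pd.DataFrame:
        """Long columnar form: parameter, chain, iteration, value."""
        recs = []
        for name, arr in self.draws.items():
            for c in range(arr.shape[0]):
                recs.append(
                    pd.DataFrame(
                        {
                            "parameter": name,
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]),
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def metadata(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_burnin": self.n_burnin,
            "seed": self.seed,
            "person_ids": list(map(int, self.person_ids)),
        }


@dataclass
class HierarchicalModel:
    """Data + spec bundle; exposes the joint log density for verification."""

    rt: np.ndarray
    correct: np.ndarray
    cond: np.ndarray
    offsets: np.ndarray
    person_ids: list
    spec: ModelSpec
    priors: PriorSpec
    excluded_persons: list = field(default_factory=list)

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    def trial_count(self, i: int) -> int:
        return int(self.offsets[i + 1] - self.offsets[i])

    def log_density(self, person_params: np.ndarray, hypers: dict) -> float:
        """Joint log density: trial likelihoods + person priors + hyperpriors.

        ``person_params``: (n_persons, 22) matrix with columns nu0, a0,
        tau+, tau-, 9 drift effects, 9 boundary effects.  Non-decision-time
        person priors are Gaussians restricted to [0, inf) without
        renormalization (the truncated mass is negligible at the relevant
        hyperparameter values).
        """
        P = np.asarray(person_params, dtype=float)
        ll = _sampler.person_logliks(self.rt, self.correct, self.cond, self.offsets, P)
        total = float(np.sum(ll))
        if not np.isfinite(total):
            return -np.inf
        h = hypers
        if np.any(P[:, 2] < 0) or np.any(P[:, 3] < 0) or np.any(P[:, 1] <= 0):
            return -np.inf
        total += float(np.sum(stats.norm.logpdf(P[:, 0], h["mu_nu"], h["sigma_nu"])))
        total += float(np.sum(stats.norm.logpdf(P[:, 1], h["mu_a"], h["sigma_a"])))
        total += float(np.sum(stats.norm.logpdf(P[:, 2], h["mu_tau_c"], h["sigma_tau_c"])))
        total += float(np.sum(stats.norm.logpdf(P[:, 3], h["mu_tau_e"], h["sigma_tau_e"])))
        eff_nu = np.asarray(h["eff_nu"], dtype=float)
        eff_a = np.asarray(h["eff_a"], dtype=float)
        total += float(np.sum(stats.norm.logpdf(P[:, 4:13], eff_nu, h["sigma_eff_nu"])))
        total += float(np.sum(stats.norm.logpdf(P[:, 13:22], eff_a, h["sigma_eff_a"])))
        for name in HYPER_NAMES:
            total += self.priors.logpdf(name, h[name])
        for c in range(9):
            total += self.priors.logpdf("eff_nu", eff_nu[c])
            total += self.priors.logpdf("eff_a", eff_a[c])
        return total


def condition_index(trials: pd.DataFrame) -> np.ndarray:
    """Map trait x congruency to the canonical 0..9 condition index."""
    labels = trials["trait"].astype(str) + ":" + trials["congruency"].astype(str)
    lut = {lab: i for i, lab in enumerate(CONDITIONS)}
    mapped = labels.map(lut)
    if mapped.isna().any():
        bad = sorted(set(labels) - set(CONDITIONS))
        raise FitError(f"unknown condition labels: {bad}")
    return mapped.to_numpy(dtype=np.int64)


def build_model(
    trials: pd.DataFrame,
    spec: ModelSpec | None = None,
    priors: PriorSpec | None = None,
) -> HierarchicalModel:
    """Assemble the per-time-point model from a preprocessed trial table."""
    spec = spec or ModelSpec()
    priors = priors or PriorSpec()
    if trials["participant_id"].nunique() < 2:
        raise FitError("hierarchical model needs at least 2 participants")
    cond = condition_index(trials)
    df = trials.assign(_cond=cond).sort_values(["participant_id"], kind="stable")
    counts = df.groupby("participant_id").size()
    small = counts[counts < spec.min_trials].index.tolist()
    if small:
        warnings.warn(
            f"excluding {len(small)} participant(s) with fewer than "
            f"{spec.min_trials} retained trials: {small}",
            stacklevel=2,
        )
        df = df[~df["participant_id"].isin(small)]
    person_ids = df["participant_id"].unique().tolist()
    sizes = df.groupby("participant_id", sort=False).size().to_numpy()
    offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
    return HierarchicalModel(
        rt=df["rt_s"].to_numpy(dtype=float),
        correct=df["correct"].to_numpy(dtype=np.bool_),
        cond=df["_cond"].to_numpy(dtype=np.int64),
        offsets=offsets,
        person_ids=person_ids,
        spec=spec,
        priors=priors,
        excluded_persons=small,
    )


def _ez_init(rt, correct, rng):
    """EZ-style moment inversion for starting values of one person."""
    pc = float(np.clip(np.mean(correct), 0.55, 0.98))
    rc = rt[correct]
    if len(rc) < 5:
        rc = rt
    mrt, vrt = float(np.mean(rc)), float(np.var(rc)) + 1e-4
    L = np.log(pc / (1 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / vrt
    v = float(np.clip(np.sign(pc - 0.5) * abs(x) ** 0.25, 0.3, 5.0))
    a = float(np.clip(L / v, 0.5, 4.0))
    mdt = (a / (2 * v)) * (1 - np.exp(-v * a)) / (1 + np.exp(-v * a))
    min_rt = float(np.min(rt))
    ter = float(np.clip(mrt - mdt, 0.05, 0.9 * min_rt))
    err = rt[~correct]
    tm = float(np.clip(ter + 0.3, 0.05, 0.9 * float(np.min(err)) if len(err) else ter + 0.3))
    # mild chain-specific jitter
    jit = 1.0 + 0.05 * rng.standard_normal(4)
    return v * jit[0], a * jit[1], ter * min(jit[2], 1.0), tm * min(jit[3], 1.0)


def _run_chain(model: HierarchicalModel, n_iter, n_burnin, rng, store):
    n = model.n_persons
    rt, correct, cond, offsets = model.rt, model.correct, model.cond, model.offsets
    priors = model.priors

    # --- initialization -----------------------------------------------------
    P = np.zeros((n, 22))
    for i in range(n):
        s, e = offsets[i], offsets[i + 1]
        if e > s:
            v, a, tp, tm = _ez_init(rt[s:e], correct[s:e], rng)
        else:  # person contributes no trials: generic start near the priors
            jit = 1.0 + 0.1 * rng.standard_normal(4)
            v, a, tp, tm = 2.0 * jit[0], 2.0 * jit[1], 0.3 * abs(jit[2]), 0.5 * abs(jit[3])
        P[i, :4] = v, a, tp, tm
    ll = _sampler.person_logliks(rt, correct, cond, offsets, P)
    for i in np.flatnonzero(~np.isfinite(ll)):
        s, e = offsets[i], offsets[i + 1]
        P[i, 2] = 0.5 * float(np.min(rt[s:e]))
        P[i, 3] = min(P[i, 3], P[i, 2])
        ll[i] = _sampler.person_logliks(rt, correct, cond, offsets, P)[i]
    bad = np.flatnonzero(~np.isfinite(ll))
    if bad.size:
        raise FitError(
            f"non-finite log density at initialization for person block(s) "
            f"{[model.person_ids[int(i)] for i in bad]}"
        )

    hypers = {
        "mu_nu": float(np.mean(P[:, 0])),
        "sigma_nu": float(np.std(P[:, 0]) + 0.1),
        "mu_a": float(np.mean(P[:, 1])),
        "sigma_a": float(np.std(P[:, 1]) + 0.1),
        "mu_tau_c": float(np.mean(P[:, 2])),
        "sigma_tau_c": float(np.std(P[:, 2]) + 0.02),
        "mu_tau_e": float(np.mean(P[:, 3])),
        "sigma_tau_e": float(np.std(P[:, 3]) + 0.02),
        "sigma_eff_nu": 0.1,
        "sigma_eff_a": 0.05,
        "eff_nu": np.zeros(9),
        "eff_a": np.zeros(9),
    }

    # --- proposal adaptation state -----------------------------------------
    base_mean = P[:, :4].copy()
    base_cov = np.tile(np.diag([0.05, 0.05, 0.005, 0.01]) ** 2, (n, 1, 1))
    base_chol = np.linalg.cholesky(base_cov)
    log_s_base = np.zeros(n)
    log_s_nu = np.full(n, np.log(0.06))
    log_s_a = np.full(n, np.log(0.03))
    shift_adapters = {"eff_nu": ScalarAdapter(scale=0.05, target=0.234),
                      "eff_a": ScalarAdapter(scale=0.02, target=0.234),
                      "tau_e": ScalarAdapter(scale=0.02, target=0.44)}
    adapters = {h: ScalarAdapter(scale=0.1) for h in HYPER_NAMES}
    sc = 2.38**2 / 4

    for it in range(n_iter):
        # person base blocks: two sweeps per iteration — the four base
        # parameters are the analysed output, so their chains get the most
        # mixing effort
        gamma = 1.0 / (it + 20.0) ** 0.6
        for _ in range(2):
            z = rng.standard_normal((n, 4))
            prop = np.exp(log_s_base)[:, None] * np.einsum("nij,nj->ni", base_chol, z)
            logu = np.log(rng.random(n))
            acc = _sampler.sweep_base(
                rt, correct, cond, offsets, P, ll, prop, logu,
                hypers["mu_nu"], hypers["sigma_nu"], hypers["mu_a"], hypers["sigma_a"],
                hypers["mu_tau_c"], hypers["sigma_tau_c"], hypers["mu_tau_e"], hypers["sigma_tau_e"],
            )
            log_s_base += gamma * (acc - 0.234)
            delta = P[:, :4] - base_mean
            base_mean += gamma * delta
            base_cov += gamma * (np.einsum("ni,nj->nij", delta, delta) - base_cov)
        if it % 25 == 24:
            try:
                base_chol = np.linalg.cholesky(sc * base_cov + 1e-10 * np.eye(4))
            except np.linalg.LinAlgError:
                pass

        # effect blocks
        for col0, log_s, eff_key, sd_key in (
            (4, log_s_nu, "eff_nu", "sigma_eff_nu"),
            (13, log_s_a, "eff_a", "sigma_eff_a"),
        ):
            propE = np.exp(log_s)[:, None] * rng.standard_normal((n, 9))
            logu = np.log(rng.random(n))
            accE = _sampler.sweep_effects(
                rt, correct, cond, offsets, P, ll, propE, logu,
                col0, hypers[eff_key], hypers[sd_key],
            )
            log_s += gamma * (accE - 0.234)

            # joint translation of group effect means + all person effects:
            # decorrelates the group means from the person random effects
            ad = shift_adapters[eff_key]
            delta = ad.scale * rng.standard_normal(9)
            new_ll = _sampler.shift_logliks(rt, correct, cond, offsets, P, col0, delta)
            pm, ps = model.priors._entry("eff_nu")[1], model.priors._entry("eff_nu")[2]
            new_eff = hypers[eff_key] + delta
            dprior = (
                np.sum((hypers[eff_key] - pm) ** 2) - np.sum((new_eff - pm) ** 2)
            ) / (2 * ps**2)
            accept = np.all(np.isfinite(new_ll)) and (
                np.log(rng.random()) < np.sum(new_ll) - np.sum(ll) + dprior
            )
            if accept:
                P[:, col0:col0 + 9] += delta
                hypers[eff_key] = new_eff
                ll[:] = new_ll
            ad.update(accept)

        # translation of the error-NDT family (group mean + all person
        # values together): person tau- values are pinned to the group mean
        # when errors are rare, which otherwise stalls both
        ad = shift_adapters["tau_e"]
        delta = ad.scale * rng.standard_normal()
        if hypers["mu_tau_e"] + delta > 0:
            new_ll = _sampler.shift_col_logliks(rt, correct, cond, offsets, P, 3, delta)
            dprior = priors.logpdf("mu_tau_e", hypers["mu_tau_e"] + delta) - priors.logpdf(
                "mu_tau_e", hypers["mu_tau_e"]
            )
            accept = np.all(np.isfinite(new_ll)) and (
                np.log(rng.random()) < np.sum(new_ll) - np.sum(ll) + dprior
            )
            if accept:
                P[:, 3] += delta
                hypers["mu_tau_e"] += delta
                ll[:] = new_ll
        else:
            accept = False
        ad.update(accept)

        # --- group-level updates -------------------------------------------
        _update_location(hypers, "mu_nu", P[:, 0], hypers["sigma_nu"], priors, rng, adapters)
        _update_scale(hypers, "sigma_nu", P[:, 0] - hypers["mu_nu"], priors, rng, adapters)
        _update_location(hypers, "mu_a", P[:, 1], hypers["sigma_a"], priors, rng, adapters)
        _update_scale(hypers, "sigma_a", P[:, 1] - hypers["mu_a"], priors, rng, adapters)
        _update_location(hypers, "mu_tau_c", P[:, 2], hypers["sigma_tau_c"], priors, rng, adapters)
        _update_scale(hypers, "sigma_tau_c", P[:, 2] - hypers["mu_tau_c"], priors, rng, adapters)
        _update_location(hypers, "mu_tau_e", P[:, 3], hypers["sigma_tau_e"], priors, rng, adapters)
        _update_scale(hypers, "sigma_tau_e", P[:, 3] - hypers["mu_tau_e"], priors, rng, adapters)

        for eff_key, sd_key, cols in (("eff_nu", "sigma_eff_nu", slice(4, 13)),
                                      ("eff_a", "sigma_eff_a", slice(13, 22))):
            # conjugate Gibbs for the 9 group effect means
            sd = hypers[sd_key]
            pm, ps = priors._entry("eff_nu")[1], priors._entry("eff_nu")[2]
            post_var = 1.0 / (n / sd**2 + 1.0 / ps**2)
            post_mean = post_var * (P[:, cols].sum(axis=0) / sd**2 + pm / ps**2)
            hypers[eff_key] = post_mean + np.sqrt(post_var) * rng.standard_normal(9)
            resid = P[:, cols] - hypers[eff_key]
            _update_scale(hypers, sd_key, resid.ravel(), priors, rng, adapters)

        if it >= n_burnin:
            k = it - n_burnin
            for h in HYPER_NAMES:
                store[h][k] = hypers[h]
            for c in range(9):
                store[f"eff_nu_{c}"][k] = hypers["eff_nu"][c]
                store[f"eff_a_{c}"][k] = hypers["eff_a"][c]
            store["_P"][k] = P[:, :4]
    return store


def _update_location(hypers, name, values, sigma, priors, rng, adapters):
    """Conjugate Gibbs when the hyperprior is normal, else adaptive MH."""
    spec = priors._entry(name)
    n = len(values)
    if spec[0] == "normal":
        m0, s0 = spec[1], spec[2]
        var = 1.0 / (n / sigma**2 + 1.0 / s0**2)
        mean = var * (values.sum() / sigma**2 + m0 / s0**2)
        hypers[name] = mean + np.sqrt(var) * rng.standard_normal()
        return
    ss_fn = lambda mu: -0.5 * np.sum((values - mu) ** 2) / sigma**2 + priors.logpdf(name, mu)
    ad = adapters[name]
    hypers[name], accepted = mh_scalar(hypers[name], ss_fn, ad.scale, rng)
    ad.update(accepted)


def _update_scale(hypers, name, resid, priors, rng, adapters):
    """Adaptive MH on log sigma with the configured hyperprior."""
    n = len(resid)
    ss = float(np.sum(resid**2))

    def logpost(log_sig):
        sig = np.exp(log_sig)
        return -n * log_sig - ss / (2 * sig**2) + priors.logpdf(name, sig) + log_sig

    ad = adapters[name]
    log_val = np.log(hypers[name])
    log_val, accepted = mh_scalar(log_val, logpost, ad.scale, rng)
    hypers[name] = float(np.exp(log_val))
    ad.update(accepted)


def run_mcmc(
    model: HierarchicalModel,
    n_chains: int = 4,
    n_iter: int = 6000,
    n_burnin: int = 1000,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the hierarchical posterior; identical seeds give identical draws.

    Retained draws per chain = ``n_iter - n_burnin``.
    """
    if n_burnin >= n_iter:
        raise FitError("n_burnin must be smaller than n_iter")
    n_keep = n_iter - n_burnin
    n = model.n_persons
    chains = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_chains):
        rng = np.random.default_rng(child)
        store = {h: np.empty(n_keep) for h in HYPER_NAMES}
        for c in range(9):
            store[f"eff_nu_{c}"] = np.empty(n_keep)
            store[f"eff_a_{c}"] = np.empty(n_keep)
        store["_P"] = np.empty((n_keep, n, 4), dtype=np.float32)
        chains.append(_run_chain(model, n_iter, n_burnin, rng, store))

    draws: dict[str, np.ndarray] = {}
    for name in chains[0]:
        if name == "_P":
            continue
        draws[name] = np.stack([c[name] for c in chains])
    persons = np.stack([c["_P"] for c in chains])  # (chains, keep, n, 4)
    for i, pid in enumerate(model.person_ids):
        draws[f"nu[{pid}]"] = persons[:, :, i, 0].astype(float)
        draws[f"a[{pid}]"] = persons[:, :, i, 1].astype(float)
        draws[f"tau_c[{pid}]"] = persons[:, :, i, 2].astype(float)
        draws[f"tau_e[{pid}]"] = persons[:, :, i, 3].astype(float)
    return PosteriorDraws(
        draws=draws, n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin,
        seed=seed, person_ids=list(model.person_ids),
    )


def extract_person_medians(
    draws: PosteriorDraws, person_ids: list | None = None
) -> pd.DataFrame:
    """Per-person posterior medians of the three analysed parameters.

    Only the drift intercept, boundary intercept and correct non-decision
    time are extracted; error non-decision times stay internal to the fit
    and never enter the stability analyses.  Persons absent from the fit get
    missing values.
    """
    ids = person_ids if person_ids is not None else draws.person_ids
    rows = []
    for pid in ids:
        if f"nu[{pid}]" in draws.draws:
            rows.append(
                (
                    pid,
                    float(np.median(draws.person_param("nu", pid))),
                    float(np.median(draws.person_param("a", pid))),
                    float(np.median(draws.person_param("tau_c", pid))),
                )
            )
        else:
            rows.append((pid, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["participant_id", "nu", "a", "tau"])
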