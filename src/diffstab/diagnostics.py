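"""MCMC convergence statistics, the joint exclusion rule, and posterior
predictive checks.

A person's parameter vector at one time point is accepted only if all four
person parameters (drift and boundary intercepts, both non-decision times)
pass rank-normalized split-R-hat <= 1.01 and bulk effective sample size
>= 400; failure of any one drops all four for that person-time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .ddm import CONDITIONS, ConditionEffects, DDMParameters, apply_condition_effects, simulate_trials
from .hierfit import PosteriorDraws

RHAT_MAX = 1.01
ESS_MIN = 400.0

PERSON_FAMILIES = ("nu", "a", "tau_c", "tau_e")


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class DiagnosticRecord:
    parameter: str
    rhat: float
    ess: float

    @property
    def passed(self) -> bool:
        return bool(self.rhat <= RHAT_MAX and self.ess >= ESS_MIN)


def _as_chains(draws: np.ndarray) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise DiagnosticsError("draws must be a (chains, iterations) array")
    if arr.shape[0] < 2:
        raise DiagnosticsError(
            "at least 2 chains are required; split a single chain in half first"
        )
    if arr.shape[1] < 4:
        raise DiagnosticsError("need at least 4 retained iterations per chain")
    return arr


def rhat(draws: np.ndarray) -> float:
    """Rank-normalized split-R-hat; exactly 1.0 for zero-variance chains."""
    arr = _as_chains(draws)
    if np.all(arr == arr.flat[0]):
        return 1.0
    return float(az.rhat(arr))


def bulk_ess(draws: np.ndarray) -> float:
    """Rank-normalized bulk effective sample size; 0 for a constant chain."""
    arr = _as_chains(draws)
    if np.all(arr == arr.flat[0]):
        return 0.0
    return float(az.ess(arr, method="bulk"))


def diagnose(draws: PosteriorDraws, parameters: list[str] | None = None) -> pd.DataFrame:
    """R-hat/ESS table for the given (default: all) parameters."""
    names = parameters if parameters is not None else list(draws.draws)
    rows = []
    for name in names:
        rec = DiagnosticRecord(name, rhat(draws[name]), bulk_ess(draws[name]))
        rows.append((name, rec.rhat, rec.ess, rec.passed))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess", "pass"])


def apply_exclusion_rules(
    draws: PosteriorDraws,
    rhat_max: float = RHAT_MAX,
    ess_min: float = ESS_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person joint convergence gate.

    Returns (person table, diagnostics table).  The person table has one row
    per participant with a ``converged`` flag: False as soon as any of the
    four person parameters fails the R-hat or ESS threshold, in which case
    all four are excluded together.
    """
    diag_rows = []
    person_rows = []
    for pid in draws.person_ids:
        ok = True
        for fam in PERSON_FAMILIES:
            arr = draws.person_param(fam, pid)
            r, e = rhat(arr), bulk_ess(arr)
            passed = bool(r <= rhat_max and e >= ess_min)
            diag_rows.append((pid, fam, r, e, passed))
            ok = ok and passed
        person_rows.append((pid, ok))
    diag = pd.DataFrame(diag_rows, columns=["participant_id", "parameter", "rhat", "ess", "pass"])
    persons = pd.DataFrame(person_rows, columns=["participant_id", "converged"])
    return persons, diag


def exclusion_fraction(persons: pd.DataFrame) -> float:
    """Fraction of person-parameter vectors dropped by the joint rule."""
    if len(persons) == 0:
        return 0.0
    return float(1.0 - persons["converged"].mean())


def _quartiles(x: np.ndarray) -> np.ndarray:
    return np.quantile(x, [0.25, 0.5, 0.75])


def posterior_predictive_check(
    draws: PosteriorDraws,
    trials: pd.DataFrame,
    n_draws: int = 500,
    seed: int = 0,
    min_errors: int = 11,
    effects: ConditionEffects | None = None,
) -> pd.DataFrame:
    """Observed vs predicted RT quartiles and error rates per person.

    For each of ``n_draws`` joint posterior samples the person's full trial
    design (their observed condition mix) is re-simulated; the prediction is
    the mean of the per-draw summaries.  Correct and error RT quartiles are
    reported separately; persons with fewer than ``min_errors`` observed
    errors are omitted from the error-RT rows (their error quantiles are too
    unstable to compare) but keep their error-rate row.
    """
    total = draws.n_chains * draws.n_retained
    if n_draws > total:
        raise DiagnosticsError(f"n_draws={n_draws} exceeds the {total} retained draws")
    rng = np.random.default_rng(seed)
    effects = effects if effects is not None else ConditionEffects.zero()
    sel = rng.choice(total, size=n_draws, replace=False)

    rows = []
    for pid, sub in trials.groupby("participant_id"):
        if f"nu[{pid}]" not in draws.draws:
            continue
        cond_counts = (
            (sub["trait"].astype(str) + ":" + sub["congruency"].astype(str))
            .value_counts()
            .to_dict()
        )
        nu = draws.person_param("nu", pid).ravel()[sel]
        a = draws.person_param("a", pid).ravel()[sel]
        tc = draws.person_param("tau_c", pid).ravel()[sel]
        te = draws.person_param("tau_e", pid).ravel()[sel]

        q_corr = np.zeros((n_draws, 3))
        q_err = np.zeros((n_draws, 3))
        n_err_draws = 0
        err_rate = np.zeros(n_draws)
        for d in range(n_draws):
            base = DDMParameters(nu[d], a[d], 0.5, tc[d], te[d])
            rts, corrs = [], []
            for label, cnt in cond_counts.items():
                p = apply_condition_effects(base, effects, label)
                r, c = simulate_trials(p, int(cnt), rng)
                rts.append(r)
                corrs.append(c)
            r = np.concatenate(rts)
            c = np.concatenate(corrs)
            err_rate[d] = 1.0 - c.mean()
            q_corr[d] = _quartiles(r[c]) if c.any() else np.nan
            if (~c).sum() >= min_errors:
                q_err[n_err_draws] = _quartiles(r[~c])
                n_err_draws += 1

        obs_rt = sub["rt_s"].to_numpy(dtype=float)
        obs_c = sub["correct"].to_numpy(dtype=bool)
        obs_err = int((~obs_c).sum())
        rows.append((pid, "error_rate", 1.0 - obs_c.mean(), float(err_rate.mean())))
        oq = _quartiles(obs_rt[obs_c])
        pq = np.nanmean(q_corr, axis=0)
        for k, lab in enumerate(("q25", "q50", "q75")):
            rows.append((pid, f"correct_rt_{lab}", float(oq[k]), float(pq[k])))
        if obs_err >= min_errors and n_err_draws > 0:
            oqe = _quartiles(obs_rt[~obs_c])
            pqe = q_err[:n_err_draws].mean(axis=0)
            for k, lab in enumerate(("q25", "q50", "q75")):
                rows.append((pid, f"error_rt_{lab}", float(oqe[k]), float(pqe[k])))
    return pd.DataFrame(rows, columns=["participant_id", "statistic", "observed", "predicted"])
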