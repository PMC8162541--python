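"""Synthetic longitudinal IAT-like cohorts with known ground truth.

Emulates the study design the analysis pipeline targets: five subgroups
(young/old x student/non-student) observed at four waves (months 0, 6, 12,
24), each person completing 5 trait IATs x 2 congruency blocks x 60 test
trials per wave.  Person-level diffusion parameters follow a latent
intercept/slope growth structure: ``value_t = I + S * lambda_t + e_t`` with
slope loadings (0, 1, l3, l4).  Error responses carry an additive
response-correction constant inside the error non-decision time.

The default generating values of the growth structures are the fitted
longitudinal estimates for drift rate, boundary separation and correct
non-decision time (see :func:`default_parameter_models`); they define the
study conditions every downstream stage is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import (
    CONDITIONS,
    ConditionEffects,
    DDMParameters,
    apply_condition_effects,
    simulate_trials,
)

PARAM_NAMES = ("nu", "a", "tau")
TIME_POINTS = (0, 6, 12, 24)  # months
N_TIME = 4

TRIAL_COLUMNS = [
    "participant_id",
    "subgroup",
    "age_group",
    "time_point",
    "trait",
    "congruency",
    "block_index",
    "trial_index",
    "warmup_flag",
    "recorded_flag",
    "correct",
    "rt_s",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration cannot be satisfied."""


@dataclass(frozen=True)
class LongitudinalParameterModel:
    """Latent intercept/slope growth structure for one diffusion parameter."""

    intercept_mean: float
    intercept_var: float
    slope_mean: float
    slope_var: float
    intercept_slope_cov: float = 0.0
    #: slope loadings per wave; the first two are fixed at (0, 1)
    loadings: tuple[float, float, float, float] = (0.0, 1.0, 1.0, 1.0)
    #: residual variances per wave
    residual_vars: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.intercept_var < 0 or self.slope_var < 0:
            raise ConfigurationError("latent variances must be >= 0")
        if any(e < 0 for e in self.residual_vars):
            raise ConfigurationError("residual variances must be >= 0")
        if self.loadings[0] != 0.0 or self.loadings[1] != 1.0:
            raise ConfigurationError("slope loadings must start (0, 1, ...)")
        lim = np.sqrt(self.intercept_var * self.slope_var)
        if abs(self.intercept_slope_cov) > lim + 1e-12:
            raise ConfigurationError("intercept-slope covariance exceeds variance bound")

    def mean_at(self, wave: int) -> float:
        return self.intercept_mean + self.slope_mean * self.loadings[wave]

    def true_correlation(self, wave_i: int, wave_j: int) -> float:
        """Closed-form correlation of true values between two waves."""
        li, lj = self.loadings[wave_i], self.loadings[wave_j]
        cov = (
            self.intercept_var
            + (li + lj) * self.intercept_slope_cov
            + li * lj * self.slope_var
        )
        vi = self.intercept_var + 2 * li * self.intercept_slope_cov + li * li * self.slope_var
        vj = self.intercept_var + 2 * lj * self.intercept_slope_cov + lj * lj * self.slope_var
        vi += self.residual_vars[wave_i]
        vj += self.residual_vars[wave_j]
        return cov / np.sqrt(vi * vj)


def default_parameter_models() -> dict[str, LongitudinalParameterModel]:
    """Default generating growth structures for nu, a and tau+ (SI units).

    Residual variances printed as 0.000 for tau are realized as 1e-4: the
    printed values are rounded and exact zeros would make all tau change
    deterministic.
    """
    return {
        "nu": LongitudinalParameterModel(
            intercept_mean=2.104, intercept_var=0.164,
            slope_mean=0.112, slope_var=0.026, intercept_slope_cov=0.0,
            loadings=(0.0, 1.0, 1.142, 1.297),
            residual_vars=(0.020, 0.036, 0.060, 0.082),
        ),
        "a": LongitudinalParameterModel(
            intercept_mean=2.053, intercept_var=0.274,
            slope_mean=-0.123, slope_var=0.0, intercept_slope_cov=0.0,
            loadings=(0.0, 1.0, 1.233, 1.334),
            residual_vars=(0.060, 0.020, 0.036, 0.045),
        ),
        "tau": LongitudinalParameterModel(
            intercept_mean=0.436, intercept_var=0.006,
            slope_mean=-0.010, slope_var=0.0, intercept_slope_cov=0.0,
            loadings=(0.0, 1.0, -0.358, 0.509),
            residual_vars=(0.001, 1e-4, 0.001, 0.002),
        ),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic cohort (defaults reproduce the study design)."""

    subgroup_sizes: tuple[int, ...] = (113, 109, 26, 63, 58)
    #: subgroup age-group labels ("young"/"old"); groups 4 and 5 are older adults
    subgroup_ages: tuple[str, ...] = ("young", "young", "young", "old", "old")
    age_young: tuple[float, float] = (21.57, 2.20)  # mean, SD
    age_old: tuple[float, float] = (67.76, 5.31)
    #: participants observed at each wave (non-increasing, nested dropout)
    retention: tuple[int, ...] = (369, 358, 327, 327)
    trials_per_block: int = 60
    #: additive response-correction constant: tau- = tau+ + c (s)
    correction_constant: float = 0.3
    #: congruent-block drift advantage (+delta congruent, -delta incongruent)
    drift_effect: float = 0.2
    #: boundary effect, opposite sign pattern to the drift effect
    boundary_effect: float = -0.05
    #: "car" = completely at random; "parameter" weights dropout toward
    #: persons with higher nu, a and tau (the pattern seen among droppers)
    dropout_mode: str = "car"
    dropout_weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.subgroup_sizes) != len(self.subgroup_ages):
            raise ConfigurationError("subgroup sizes and age labels must align")
        n1 = sum(self.subgroup_sizes)
        if self.retention[0] != n1:
            raise ConfigurationError(
                f"retention at wave 1 ({self.retention[0]}) must equal the summed "
                f"subgroup sizes ({n1})"
            )
        if any(
            self.retention[i] < self.retention[i + 1] for i in range(len(self.retention) - 1)
        ):
            raise ConfigurationError("retention must be non-increasing")
        if len(self.retention) != N_TIME:
            raise ConfigurationError("retention must list all four waves")

    @property
    def n_participants(self) -> int:
        return sum(self.subgroup_sizes)

    def condition_effects(self) -> ConditionEffects:
        dnu, da = [], []
        for label in CONDITIONS:
            sign = 1.0 if label.endswith(":congruent") else -1.0
            dnu.append(sign * self.drift_effect)
            da.append(sign * self.boundary_effect)
        return ConditionEffects(CONDITIONS, tuple(dnu), tuple(da))


@dataclass
class Trajectories:
    """Realized person-level parameter values plus their latent ground truth."""

    values: pd.DataFrame  # participant_id, subgroup, age_group, age, wave, time_point, nu, a, tau, tau_err, observed
    latents: pd.DataFrame  # participant_id, parameter, intercept, slope
    config: CohortConfig = field(repr=False, default=None)


def _draw_growth(model: LongitudinalParameterModel, n: int, rng: np.random.Generator,
                 lower: float | None, max_redraw: int = 1000):
    """Draw (I, S, values[4]) per person with truncation ``value > lower``."""
    cov = np.array(
        [[model.intercept_var, model.intercept_slope_cov],
         [model.intercept_slope_cov, model.slope_var]]
    )
    lam = np.asarray(model.loadings)
    res_sd = np.sqrt(np.asarray(model.residual_vars))
    I = np.empty(n)
    S = np.empty(n)
    vals = np.empty((n, N_TIME))
    need = np.ones(n, dtype=bool)
    for _ in range(max_redraw):
        m = int(need.sum())
        if m == 0:
            break
        latent = rng.multivariate_normal(
            [model.intercept_mean, model.slope_mean], cov, size=m,
            method="eigh", check_valid="ignore",
        )
        resid = rng.standard_normal((m, N_TIME)) * res_sd
        v = latent[:, [0]] + latent[:, [1]] * lam + resid
        ok = np.ones(m, dtype=bool) if lower is None else np.all(v > lower, axis=1)
        idx = np.flatnonzero(need)[ok]
        I[idx], S[idx] = latent[ok, 0], latent[ok, 1]
        vals[idx] = v[ok]
        need[idx] = False
    else:
        raise ConfigurationError("truncation region too improbable: redraw limit reached")
    return I, S, vals


def draw_person_trajectories(
    models: dict[str, LongitudinalParameterModel] | None = None,
    cohort: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> Trajectories:
    """Draw per-person nu/a/tau+ trajectories at the four waves.

    Draws violating ``a > 0.2`` or ``tau+ > 0.05`` are redrawn (whole-person
    truncation).  Returns realized values and the latent (I, S) per person
    and parameter for recovery tests, plus the dropout mask (``observed``).
    """
    models = models if models is not None else default_parameter_models()
    cohort = cohort if cohort is not None else CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cohort.n_participants

    lowers = {"nu": None, "a": 0.2, "tau": 0.05}
    draws = {}
    lat_rows = []
    for p in PARAM_NAMES:
        I, S, vals = _draw_growth(models[p], n, rng, lowers[p])
        draws[p] = vals
        for i in range(n):
            lat_rows.append((i, p, I[i], S[i]))

    subgroup = np.repeat(np.arange(1, len(cohort.subgroup_sizes) + 1), cohort.subgroup_sizes)
    age_group = np.repeat(list(cohort.subgroup_ages), cohort.subgroup_sizes)
    ages = np.where(
        age_group == "young",
        rng.normal(*cohort.age_young, size=n),
        rng.normal(*cohort.age_old, size=n),
    )

    observed = _dropout_mask(cohort, draws, rng)

    rows = []
    for i in range(n):
        for w in range(N_TIME):
            rows.append(
                (
                    i, subgroup[i], age_group[i], ages[i], w, TIME_POINTS[w],
                    draws["nu"][i, w], draws["a"][i, w], draws["tau"][i, w],
                    draws["tau"][i, w] + cohort.correction_constant,
                    bool(observed[i, w]),
                )
            )
    values = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "subgroup", "age_group", "age", "wave", "time_point",
            "nu", "a", "tau", "tau_err", "observed",
        ],
    )
    latents = pd.DataFrame(lat_rows, columns=["participant_id", "parameter", "intercept", "slope"])
    return Trajectories(values=values, latents=latents, config=cohort)


def _dropout_mask(cohort: CohortConfig, draws: dict, rng: np.random.Generator) -> np.ndarray:
    """Nested dropout reproducing the configured retention counts exactly."""
    n = cohort.n_participants
    observed = np.zeros((n, N_TIME), dtype=bool)
    current = np.arange(n)
    for w, keep in enumerate(cohort.retention):
        if keep < len(current):
            if cohort.dropout_mode == "parameter":
                # droppers tend to have higher nu, a and tau at wave 1
                z = sum(
                    (draws[p][current, 0] - draws[p][current, 0].mean())
                    / draws[p][current, 0].std()
                    for p in PARAM_NAMES
                )
                wgt = np.exp(-cohort.dropout_weight * z)  # stay-probability weight
                wgt /= wgt.sum()
                current = rng.choice(current, size=keep, replace=False, p=wgt)
            else:
                current = rng.choice(current, size=keep, replace=False)
            current = np.sort(current)
        observed[current, w] = True
    return observed


def generate_trials(
    traj: Trajectories,
    seed: int | np.random.Generator = 0,
    waves: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Simulate the full trial table for every observed person x wave.

    Per person and wave: 10 blocks (5 traits x 2 congruencies) of 60 test
    trials, 600 in total; the first trial of each block carries the warm-up
    flag.  Correctness and RT come from the Wiener process with the cohort's
    condition effects applied; every RT exceeds the applicable non-decision
    time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = traj.config
    effects = cohort.condition_effects()
    npb = cohort.trials_per_block

    frames = []
    vals = traj.values
    if waves is not None:
        vals = vals[vals["wave"].isin(waves)]
    vals = vals[vals["observed"]]
    for row in vals.itertuples(index=False):
        base = DDMParameters(
            drift=row.nu, boundary_separation=row.a, relative_start=0.5,
            ndt_correct=row.tau, ndt_error=row.tau_err,
        )
        for b, label in enumerate(CONDITIONS):
            p = apply_condition_effects(base, effects, label)
            rt, correct = simulate_trials(p, npb, rng)
            trait, congruency = label.split(":")
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": row.participant_id,
                        "subgroup": row.subgroup,
                        "age_group": row.age_group,
                        "time_point": row.time_point,
                        "trait": trait,
                        "congruency": congruency,
                        "block_index": b,
                        "trial_index": np.arange(npb),
                        "warmup_flag": np.arange(npb) == 0,
                        "recorded_flag": True,
                        "correct": correct,
                        "rt_s": np.round(rt, 6),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def inject_artifacts(
    trials: pd.DataFrame,
    fast_rate: float = 0.0,
    slow_rate: float = 0.0,
    unrecorded_rate: float = 0.0,
    low_accuracy_participants: tuple[int, ...] = (),
    low_accuracy: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Contaminate a trial table; returns (table, exact artifact counts).

    Fast guesses get RTs uniform on (0.05, 0.3) s, slow outliers uniform on
    (3.0, 5.0) s, unrecorded trials get ``recorded_flag = False``; listed
    participants have their correctness flags redrawn at ``low_accuracy``.
    Rates apply per trial, in [0, 0.5].
    """
    for r in (fast_rate, slow_rate, unrecorded_rate):
        if not 0.0 <= r <= 0.5:
            raise ConfigurationError("artifact rates must lie in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = trials.copy()
    n = len(out)
    counts = {"fast": 0, "slow": 0, "unrecorded": 0, "low_accuracy_participants": 0}
    if n == 0:
        return out, counts

    u = rng.random(n)
    fast = u < fast_rate
    slow = (u >= fast_rate) & (u < fast_rate + slow_rate)
    unrec = (u >= fast_rate + slow_rate) & (u < fast_rate + slow_rate + unrecorded_rate)
    out.loc[fast, "rt_s"] = np.round(rng.uniform(0.05, 0.2999, fast.sum()), 6)
    out.loc[slow, "rt_s"] = np.round(rng.uniform(3.0001, 5.0, slow.sum()), 6)
    out.loc[unrec, "recorded_flag"] = False
    counts["fast"] = int(fast.sum())
    counts["slow"] = int(slow.sum())
    counts["unrecorded"] = int(unrec.sum())

    for pid in low_accuracy_participants:
        mask = out["participant_id"] == pid
        out.loc[mask, "correct"] = rng.random(int(mask.sum())) < low_accuracy
        counts["low_accuracy_participants"] += 1
    return out, counts


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the trial table in the package CSV dialect (RTs at 6 decimals)."""
    trials.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"trial CSV missing columns: {sorted(missing)}")
    return df
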