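"""Wiener diffusion process primitives.

A two-choice decision is modelled as a Wiener process with drift ``nu``
starting at ``z_rel * a`` between absorbing boundaries 0 and ``a``; the upper
boundary codes the correct response, the lower the error response.  Observed
response time = decision time + the non-decision time of the realized outcome
(``ndt_correct`` for correct responses; ``ndt_error`` for errors, which in
IAT-style tasks additionally contains the time taken to correct the
response).  The diffusion scale is fixed at :data:`DIFFUSION_SCALE` = 1 and
inter-trial variabilities of drift, start and non-decision time are zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from . import _wfpt

#: Scale convention of the diffusion coefficient (evidence / sqrt(s)).
#: All drift and boundary magnitudes in this package assume this value.
DIFFUSION_SCALE = 1.0

#: Minimum decision time the trial simulator can emit (s).
MIN_DECISION_TIME = 1e-4

TRAITS = ("openness", "conscientiousness", "extraversion", "agreeableness", "neuroticism")
CONGRUENCY = ("congruent", "incongruent")
#: The 10 experimental conditions: 5 traits x 2 block congruencies.
CONDITIONS = tuple(f"{t}:{c}" for t in TRAITS for c in CONGRUENCY)

Boundary = Literal["upper", "lower"]


class ParameterError(ValueError):
    """Raised when diffusion parameters violate their domain."""


@dataclass(frozen=True)
class DDMParameters:
    """Parameters of one Wiener diffusion regime.

    drift
        Mean evidence accumulation rate nu (evidence/s); positive values
        favour the upper (correct) boundary.
    boundary_separation
        Distance a between the boundaries (evidence units); must be > 0.
    relative_start
        Starting point as a fraction of a; fixed at 0.5 throughout this
        package because the boundaries code correct vs error.
    ndt_correct, ndt_error
        Non-decision times tau+ / tau- (s) added to correct / error decision
        times.  tau- >= tau+ is typical (it absorbs response correction) but
        not required.
    """

    drift: float
    boundary_separation: float
    relative_start: float = 0.5
    ndt_correct: float = 0.0
    ndt_error: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.drift):
            raise ParameterError(f"drift must be finite, got {self.drift}")
        if not (self.boundary_separation > 0):
            raise ParameterError(f"boundary_separation must be > 0, got {self.boundary_separation}")
        if not (0.0 < self.relative_start < 1.0):
            raise ParameterError(f"relative_start must lie in (0, 1), got {self.relative_start}")
        if self.ndt_correct < 0 or self.ndt_error < 0:
            raise ParameterError("non-decision times must be >= 0")


@dataclass(frozen=True)
class ConditionEffects:
    """Effect-coded condition offsets on drift and boundary separation.

    Exactly 10 condition labels; both effect vectors sum to zero so the base
    parameters remain the grand mean across conditions.
    """

    labels: tuple[str, ...]
    drift_effects: tuple[float, ...]
    boundary_effects: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != 10:
            raise ParameterError(f"exactly 10 conditions required, got {len(self.labels)}")
        if len(self.drift_effects) != 10 or len(self.boundary_effects) != 10:
            raise ParameterError("effect vectors must have length 10")
        for name, eff in (("drift", self.drift_effects), ("boundary", self.boundary_effects)):
            s = float(np.sum(eff))
            if abs(s) > 1e-8:
                raise ParameterError(f"{name} effects must sum to zero (got {s:.3g})")

    @classmethod
    def zero(cls, labels: tuple[str, ...] = CONDITIONS) -> "ConditionEffects":
        return cls(labels, (0.0,) * 10, (0.0,) * 10)

    def index(self, condition: str) -> int:
        try:
            return self.labels.index(condition)
        except ValueError:
            raise ParameterError(f"unknown condition {condition!r}") from None


def apply_condition_effects(
    base: DDMParameters, effects: ConditionEffects, condition: str
) -> DDMParameters:
    """Shift drift and boundary separation by the condition's coded effect."""
    i = effects.index(condition)
    a = base.boundary_separation + effects.boundary_effects[i]
    if a <= 0:
        raise ParameterError(
            f"condition {condition!r}: boundary separation {a:.4g} <= 0 after applying effect"
        )
    return replace(
        base,
        drift=base.drift + effects.drift_effects[i],
        boundary_separation=a,
    )


def wfpt_logdensity(t, boundary: Boundary, params: DDMParameters):
    """Log first-passage density at decision time ``t`` (s) for one boundary."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("decision time must be > 0")
    v, a, w = params.drift, params.boundary_separation, params.relative_start
    upper = _check_boundary(boundary) == "upper"
    ts = np.atleast_1d(t)
    with np.errstate(divide="ignore"):
        out = np.log(_wfpt.pdf_grid(ts, v, a, w, upper))
    return out[0] if t.ndim == 0 else out


def wfpt_density(t, boundary: Boundary, params: DDMParameters):
    """First-passage density (1/s) at decision time ``t`` for one boundary.

    The density is defective: integrated over t it gives the boundary's
    absorption probability, and the two boundaries' integrals sum to 1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("decision time must be > 0")
    v, a, w = params.drift, params.boundary_separation, params.relative_start
    upper = _check_boundary(boundary) == "upper"
    ts = np.atleast_1d(t)
    out = _wfpt.pdf_grid(ts, v, a, w, upper)
    return out[0] if t.ndim == 0 else out


def choice_probability(params: DDMParameters, boundary: Boundary = "upper") -> float:
    """Closed-form absorption probability of one boundary.

    For the upper boundary with sigma = 1:
    ``(1 - exp(-2 nu z)) / (1 - exp(-2 nu a))`` with ``z = z_rel * a``,
    continuously extended to ``z_rel`` at nu = 0.
    """
    p_up = float(_wfpt.prob_upper(params.drift, params.boundary_separation, params.relative_start))
    return p_up if _check_boundary(boundary) == "upper" else 1.0 - p_up


def _check_boundary(boundary: str) -> str:
    if boundary not in ("upper", "lower"):
        raise ParameterError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    return boundary


class _GridSampler:
    """Inverse-CDF sampler of (decision time, boundary) on a cached time grid."""

    def __init__(self, params: DDMParameters, n_grid: int = 2048):
        v, a, w = params.drift, params.boundary_separation, params.relative_start
        self.p_upper = float(_wfpt.prob_upper(v, a, w))
        # expand the horizon until both defective CDFs have converged
        t_max = max(4.0 * a * a, 2.0)
        for _ in range(12):
            grid = np.geomspace(MIN_DECISION_TIME, t_max, n_grid)
            pdf_up = _wfpt.pdf_grid(grid, v, a, w, True)
            pdf_lo = _wfpt.pdf_grid(grid, v, a, w, False)
            tail = (pdf_up[-1] + pdf_lo[-1]) * t_max
            if tail < 1e-9:
                break
            t_max *= 2.0
        cdf_up = _cumtrapz(pdf_up, grid)
        cdf_lo = _cumtrapz(pdf_lo, grid)
        self.grid = grid
        # conditional CDFs, normalized on the grid
        self.cdf_up = cdf_up / cdf_up[-1] if cdf_up[-1] > 0 else cdf_up
        self.cdf_lo = cdf_lo / cdf_lo[-1] if cdf_lo[-1] > 0 else cdf_lo

    def sample(self, n: int, rng: np.random.Generator):
        correct = rng.random(n) < self.p_upper
        u = rng.random(n)
        t = np.empty(n)
        if correct.any():
            t[correct] = np.interp(u[correct], self.cdf_up, self.grid)
        if (~correct).any():
            t[~correct] = np.interp(u[~correct], self.cdf_lo, self.grid)
        return np.maximum(t, MIN_DECISION_TIME), correct


def _cumtrapz(y, x):
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


_SAMPLER_CACHE: dict[tuple, _GridSampler] = {}


def _sampler_for(params: DDMParameters) -> _GridSampler:
    key = (
        round(params.drift, 10),
        round(params.boundary_separation, 10),
        round(params.relative_start, 10),
    )
    s = _SAMPLER_CACHE.get(key)
    if s is None:
        if len(_SAMPLER_CACHE) > 4096:
            _SAMPLER_CACHE.clear()
        s = _GridSampler(params)
        _SAMPLER_CACHE[key] = s
    return s


def simulate_trials(params: DDMParameters, n: int, rng: np.random.Generator):
    """Simulate ``n`` trials; returns (observed RT array, correctness array).

    Observed RT = decision time + ndt_correct if the upper boundary was hit,
    + ndt_error otherwise.  Decision times below 0.1 ms are clamped.
    """
    sampler = _sampler_for(params)
    t, correct = sampler.sample(n, rng)
    rt = t + np.where(correct, params.ndt_correct, params.ndt_error)
    return rt, correct


def simulate_trial(params: DDMParameters, rng: np.random.Generator):
    """Simulate a single trial; returns (observed RT, correctness flag)."""
    rt, correct = simulate_trials(params, 1, rng)
    return float(rt[0]), bool(correct[0])
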