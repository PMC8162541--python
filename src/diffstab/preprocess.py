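"""Pre-fit trial exclusions with full accounting.

Fixed step order: non-recorded trials -> RT window (300-3000 ms, boundaries
retained) -> low-accuracy participants (3 IQR below the first quartile of
per-participant accuracy, per time point) -> warm-up trials (first trial of
each block).  Participant accuracy for the low-accuracy rule is computed on
recorded trials *before* RT filtering by default (it indexes raw task
accuracy across all five IATs); a switch computes it after RT filtering
instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RT_LOW = 0.3
RT_HIGH = 3.0


class PreprocessingError(ValueError):
    pass


@dataclass
class ExclusionLog:
    """Ordered per-step exclusion counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, reason: str, n_excluded: int, n_before: int) -> None:
        self.steps.append(
            {
                "step": step,
                "reason": reason,
                "n_excluded": int(n_excluded),
                "n_before": int(n_before),
                "fraction": (n_excluded / n_before) if n_before else 0.0,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "reason", "n_excluded", "n_before", "fraction"])

    def total_excluded(self, steps: tuple[str, ...] | None = None) -> int:
        return sum(s["n_excluded"] for s in self.steps if steps is None or s["step"] in steps)


def filter_recorded(trials: pd.DataFrame, log: ExclusionLog | None = None):
    """Drop trials not recorded for technical reasons."""
    log = log if log is not None else ExclusionLog()
    keep = trials["recorded_flag"].astype(bool)
    log.add("recorded", "not recorded", (~keep).sum(), len(trials))
    return trials[keep], log


def filter_rt_window(
    trials: pd.DataFrame,
    low: float = RT_LOW,
    high: float = RT_HIGH,
    log: ExclusionLog | None = None,
):
    """Retain trials with ``low <= RT <= high`` (boundary values retained)."""
    log = log if log is not None else ExclusionLog()
    if len(trials) == 0:
        log.add("rt_window", "rt below low", 0, 0)
        log.add("rt_window", "rt above high", 0, 0)
        return trials, log
    rt = trials["rt_s"].to_numpy(dtype=float)
    fast = rt < low
    slow = rt > high
    log.add("rt_window", "rt below low", fast.sum(), len(trials))
    log.add("rt_window", "rt above high", slow.sum(), len(trials))
    return trials[~(fast | slow)], log


def accuracy_by_participant(trials: pd.DataFrame) -> pd.Series:
    """Per-participant accuracy across all blocks/traits of one time point."""
    return trials.groupby("participant_id")["correct"].mean()


def low_accuracy_cutoff(accuracies: pd.Series) -> float:
    """Cutoff = Q1 - 3 IQR with linear-interpolation quantiles."""
    if len(accuracies) < 4:
        raise PreprocessingError(
            f"need >= 4 participants for stable quartiles, got {len(accuracies)}"
        )
    q1, q3 = np.quantile(accuracies.to_numpy(dtype=float), [0.25, 0.75])
    return float(q1 - 3.0 * (q3 - q1))


def exclude_low_accuracy(accuracies: pd.Series) -> tuple[list, float]:
    """Participants strictly below Q1 - 3 IQR of the accuracy distribution.

    Applied independently per time point; the caller passes one time point's
    accuracies.  Returns (excluded participant ids, cutoff).
    """
    cutoff = low_accuracy_cutoff(accuracies)
    excluded = accuracies.index[accuracies.to_numpy(dtype=float) < cutoff].tolist()
    return excluded, cutoff


def drop_warmup(trials: pd.DataFrame, log: ExclusionLog | None = None):
    """Remove the first trial of each (participant, time point, block)."""
    log = log if log is not None else ExclusionLog()
    if len(trials) == 0:
        log.add("warmup", "warm-up trial", 0, 0)
        return trials, log
    if "warmup_flag" in trials.columns:
        keep = ~trials["warmup_flag"].astype(bool)
    else:
        first = trials.groupby(["participant_id", "time_point", "block_index"])[
            "trial_index"
        ].transform("min")
        keep = trials["trial_index"] != first
    log.add("warmup", "warm-up trial", (~keep).sum(), len(trials))
    return trials[keep], log


def preprocess(
    trials: pd.DataFrame,
    low: float = RT_LOW,
    high: float = RT_HIGH,
    accuracy_after_rt_filter: bool = False,
) -> tuple[pd.DataFrame, ExclusionLog, dict]:
    """Full exclusion pipeline for a (possibly multi-time-point) trial table.

    Returns (retained trials, log, per-time-point low-accuracy exclusions).
    Conservation holds per step: retained + excluded = input of that step.
    """
    log = ExclusionLog()
    recorded, log = filter_recorded(trials, log)
    windowed, log = filter_rt_window(recorded, low, high, log)

    acc_basis = windowed if accuracy_after_rt_filter else recorded
    excluded_by_tp: dict = {}
    drop_ids = []
    for tp, sub in acc_basis.groupby("time_point"):
        acc = accuracy_by_participant(sub)
        excluded, cutoff = exclude_low_accuracy(acc)
        excluded_by_tp[tp] = {"excluded": excluded, "cutoff": cutoff}
        drop_ids.extend((tp, pid) for pid in excluded)

    if drop_ids:
        bad = pd.MultiIndex.from_tuples(drop_ids)
        mask = pd.MultiIndex.from_frame(windowed[["time_point", "participant_id"]]).isin(bad)
    else:
        mask = np.zeros(len(windowed), dtype=bool)
    log.add("low_accuracy", "participant accuracy < Q1 - 3 IQR", mask.sum(), len(windowed))
    kept = windowed[~mask]

    kept, log = drop_warmup(kept, log)
    return kept, log, excluded_by_tp
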