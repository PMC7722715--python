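"""Saccade-rate time courses and the pre-target saccade-rate statistic.

The saccade rate at a relative time t is the fraction of trials with a
saccade *onset* at t — among trials whose sample at t is valid (blink
exclusion) — multiplied by the sampling rate (1000 Hz), i.e. saccades
per second. The study's dependent measure is the mean rate over the
-100 to 0 ms window before target onset (inclusive endpoints, 101
samples at 1 ms resolution), per subject x condition x foreperiod cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SaccadeEvent, Trial, TrialSegment

__all__ = [
    "assign_condition",
    "RateTimecourse",
    "rate_timecourse",
    "mean_pretarget_sr",
    "smooth_for_display",
    "pretarget_sr_table",
]


def assign_condition(trial: Trial) -> str:
    """Trial condition from block type and foreperiod.

    Full-certainty blocks -> ``full_certainty``; high-certainty blocks ->
    ``high_certainty_frequent`` when the trial's foreperiod is the block's
    80% duration, else ``high_certainty_rare``; low-certainty blocks ->
    ``low_certainty``. Impossible combinations are rejected.
    """
    bt, fp = trial.block_type, trial.foreperiod_ms
    if bt == "full_certainty_1s":
        allowed = {1000}
        if fp in allowed:
            return "full_certainty"
    elif bt == "full_certainty_2s":
        if fp == 2000:
            return "full_certainty"
    elif bt == "high_certainty_1s":
        if fp == 1000:
            return "high_certainty_frequent"
        if fp == 2000:
            return "high_certainty_rare"
    elif bt == "high_certainty_2s":
        if fp == 2000:
            return "high_certainty_frequent"
        if fp == 1000:
            return "high_certainty_rare"
    elif bt == "low_certainty":
        if fp in (1000, 1500, 2000, 2500, 3000):
            return "low_certainty"
    else:
        raise ValueError(f"unknown block_type: {bt!r}")
    raise ValueError(f"impossible combination: {bt} with foreperiod {fp} ms")


@dataclass
class RateTimecourse:
    """Saccades/s per sample relative to a lock event, with per-sample
    valid-trial counts. rate = 0 wherever n_valid = 0 (by convention)."""

    time_ms: np.ndarray
    rate: np.ndarray
    n_valid: np.ndarray
    lock: str  # "cue" | "target"


def rate_timecourse(
    trials: list[tuple[TrialSegment, list[SaccadeEvent]]],
    lock: str = "cue",
) -> RateTimecourse:
    """Across-trial saccade-rate time course, locked to cue or target.

    Saccade *onsets* are counted (not durations); samples excluded by the
    blink mask contribute to neither numerator nor denominator.
    """
    if lock not in ("cue", "target"):
        raise ValueError("lock must be 'cue' or 'target'")
    if not trials:
        return RateTimecourse(
            time_ms=np.array([], dtype=int),
            rate=np.array([]),
            n_valid=np.array([], dtype=int),
            lock=lock,
        )
    if lock == "cue":
        t_min = -max(seg.pre_ms for seg, _ in trials)
        t_max = max(seg.trial.foreperiod_ms + seg.post_ms for seg, _ in trials)
    else:
        t_min = -max(seg.trial.foreperiod_ms + seg.pre_ms for seg, _ in trials)
        t_max = max(seg.post_ms for seg, _ in trials)
    axis = np.arange(t_min, t_max + 1)
    counts = np.zeros(len(axis))
    n_valid = np.zeros(len(axis))
    for seg, events in trials:
        shift = seg.pre_ms if lock == "cue" else seg.pre_ms + seg.trial.foreperiod_ms
        start = -shift - t_min  # index of segment sample 0 on the axis
        n_valid[start : start + len(seg)] += seg.valid_mask
        for ev in events:
            i = start + ev.onset_ms  # onset_ms is a segment index
            if 0 <= i < len(axis) and seg.valid_mask[ev.onset_ms]:
                counts[i] += 1
    rate = np.divide(
        counts, n_valid, out=np.zeros_like(counts), where=n_valid > 0
    ) * 1000.0
    return RateTimecourse(
        time_ms=axis, rate=rate, n_valid=n_valid.astype(int), lock=lock
    )


def mean_pretarget_sr(
    tc: RateTimecourse, window_ms: tuple[int, int] = (-100, 0)
) -> float:
    """Unweighted mean of the per-sample rate over the (inclusive) window.

    Returns NaN when no trial contributes a valid sample anywhere in the
    window (the cell is then not computable).
    """
    lo, hi = window_ms
    if lo > hi:
        raise ValueError("empty window")
    sel = (tc.time_ms >= lo) & (tc.time_ms <= hi)
    if not sel.any():
        raise ValueError("window outside time axis")
    if (tc.n_valid[sel] == 0).all():
        return float("nan")
    return float(np.mean(tc.rate[sel]))


def smooth_for_display(tc: RateTimecourse, window_ms: int = 50) -> RateTimecourse:
    """Centered moving average for plotting only — analysis statistics are
    never computed on smoothed traces. Kernel length is window_ms + 1
    (odd, symmetric)."""
    if window_ms < 1:
        raise ValueError("window_ms must be >= 1")
    k = window_ms + 1 if window_ms % 2 == 0 else window_ms
    kernel = np.ones(k) / k
    pad = k // 2
    padded = np.pad(tc.rate, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return RateTimecourse(
        time_ms=tc.time_ms.copy(),
        rate=smoothed,
        n_valid=tc.n_valid.copy(),
        lock=tc.lock,
    )


def pretarget_sr_table(
    subject_trials: dict,
    window_ms: tuple[int, int] = (-100, 0),
) -> pd.DataFrame:
    """Tidy subject x condition x foreperiod table of mean pre-target SR.

    ``subject_trials`` maps subject_id -> list of (TrialSegment, events).
    Cells with no valid pre-target samples get NaN.
    """
    rows = []
    for subject_id, trials in subject_trials.items():
        cells: dict[tuple[str, int], list] = {}
        for seg, events in trials:
            cond = assign_condition(seg.trial)
            cells.setdefault((cond, seg.trial.foreperiod_ms), []).append(
                (seg, events)
            )
        for (cond, fp), cell_trials in sorted(cells.items()):
            tc = rate_timecourse(cell_trials, lock="target")
            sr = mean_pretarget_sr(tc, window_ms)
            rows.append(
                {
                    "subject_id": subject_id,
                    "condition": cond,
                    "foreperiod_ms": fp,
                    "mean_sr": sr,
                }
            )
    return pd.DataFrame(rows)
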