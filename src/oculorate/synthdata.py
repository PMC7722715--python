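"""Synthetic trial schedules and binocular gaze with known ground truth.

The generator emulates a fixation experiment: on each trial a color cue
starts a foreperiod drawn from the block's distribution, and a brief
target follows. Gaze is built from

* a 2-D Gaussian random-walk fixational drift,
* microsaccades whose onsets follow an inhomogeneous Bernoulli process
  with a physiological refractory period, amplitudes on the
  amplitude/peak-velocity main sequence, and minimum-jerk waveforms,
* blinks that blank the pupil trace (20 ms raised-cosine ramps) and drop
  the position channels, and
* white measurement noise per eye.

Pre-target inhibition is injected by scaling the saccade rate with the
momentary *anticipation* — the conditional probability that the target
arrives within ``inhibition_window_ms``, given that it has not yet
appeared (see :func:`oculorate.hypotheses.anticipation`). With
``inhibition_depth`` = 0 the process is homogeneous at
``base_saccade_rate``; ``base_saccade_rate`` is the *realized*
steady-state onset rate (the underlying Bernoulli intensity is corrected
for the refractory dead time via the renewal relation
``lambda = r / (1 - r * tau_dead)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BLOCK_TYPES, GazeRecording, GroundTruth, Trial
from .hypotheses import BLOCK_DISTRIBUTIONS, ForeperiodDistribution, anticipation

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "build_schedule",
    "session_block_sequence",
    "simulate_gaze",
    "evaluate_detection",
    "StaircaseState",
    "run_staircase",
    "weibull_observer",
]

#: silent interval appended after each target (covers the +300 ms segment
#: margin plus a response-like period)
POST_TARGET_MS = 600

ITI_RANGE_MS = (700, 1200)


@dataclass(frozen=True)
class SimParams:
    """Generative knobs of the gaze simulator (defaults are the package's
    study conditions; see docs/methods.md)."""

    drift_sd: float = 0.05  # deg / sqrt(s), random-walk diffusion scale
    base_saccade_rate: float = 2.2  # realized saccades / s
    inhibition_depth: float = 0.85  # fractional rate reduction at full anticipation
    inhibition_window_ms: float = 300.0
    main_sequence_slope: float = 45.0  # (deg/s) / deg
    main_sequence_exponent: float = 1.0
    main_sequence_noise_sd: float = 0.1  # sd of multiplicative (log) velocity noise
    amplitude_median_deg: float = 0.4
    amplitude_log_sd: float = 0.35
    amplitude_range_deg: tuple[float, float] = (0.08, 1.5)
    min_isi_ms: float = 100.0  # refractory: offset -> next onset
    pupil_baseline: float = 1000.0
    blink_rate: float = 0.1  # blinks / s
    blink_duration_ms: float = 150.0
    blink_duration_sd_ms: float = 30.0
    noise_sd: float = 0.005  # deg, white measurement noise per eye
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_sd", "base_saccade_rate", "blink_rate", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.inhibition_depth <= 1.0:
            raise ValueError("inhibition_depth must be in [0, 1]")

    def mean_saccade_duration_ms(self) -> float:
        """Expected min-jerk duration 1875 * A / vp under the amplitude and
        main-sequence laws (lognormal moments, clipping ignored)."""
        mu = math.log(self.amplitude_median_deg)
        k = 1.0 - self.main_sequence_exponent
        e_apow = math.exp(k * mu + (k * self.amplitude_log_sd) ** 2 / 2.0)
        e_noise = math.exp(self.main_sequence_noise_sd**2 / 2.0)
        return 1875.0 / self.main_sequence_slope * e_apow * e_noise

    def dead_time_ms(self) -> float:
        return self.mean_saccade_duration_ms() + self.min_isi_ms


# ---------------------------------------------------------------------------
# Schedules


def build_schedule(
    block_type: str,
    n_trials: int,
    seed: int,
    start_ms: int = 0,
) -> list[Trial]:
    """Counterbalanced trial schedule for one block.

    Foreperiod counts are *exact* multinomial fractions of the block's
    distribution (not sampled); trial order is shuffled by ``seed`` and the
    inter-trial interval is drawn uniformly from 700-1200 ms.
    """
    if block_type not in BLOCK_TYPES:
        raise ValueError(f"unknown block_type: {block_type!r}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    dist = BLOCK_DISTRIBUTIONS[block_type]
    counts = {}
    for s, p in zip(dist.support, dist.probs):
        exact = n_trials * p
        if abs(exact - round(exact)) > 1e-9:
            divisor = _required_divisor(dist)
            raise ValueError(
                f"n_trials={n_trials} not divisible for {block_type}: "
                f"must be a multiple of {divisor}"
            )
        counts[s] = round(exact)
    fps = [s for s, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    rng.shuffle(fps)
    trials = []
    cursor = start_ms
    for i, fp in enumerate(fps):
        iti = int(rng.integers(ITI_RANGE_MS[0], ITI_RANGE_MS[1] + 1))
        cue = cursor + iti
        target = cue + int(fp)
        trials.append(
            Trial(
                trial_id=i,
                block_type=block_type,
                foreperiod_ms=int(fp),
                cue_onset_ms=cue,
                target_onset_ms=target,
                iti_ms=iti,
            )
        )
        cursor = target + POST_TARGET_MS
    return trials


def _required_divisor(dist: ForeperiodDistribution) -> int:
    from fractions import Fraction

    denom = 1
    for p in dist.probs:
        if p > 0:
            denom = np.lcm(denom, Fraction(p).limit_denominator(1000).denominator)
    return int(denom)


def session_block_sequence(rng: np.random.Generator | None = None) -> list[str]:
    """The 17-block session structure: one block of each full-certainty type
    and five of each other type, order shuffled (blocks of a type are run
    serially, so shuffling permutes the five type-groups)."""
    groups = [
        ["full_certainty_1s"],
        ["full_certainty_2s"],
        ["high_certainty_1s"] * 5,
        ["high_certainty_2s"] * 5,
        ["low_certainty"] * 5,
    ]
    if rng is not None:
        rng.shuffle(groups)
    return [b for g in groups for b in g]


# ---------------------------------------------------------------------------
# Gaze simulation


def _minjerk_increments(amplitude: float, duration_ms: int) -> np.ndarray:
    """Per-ms displacement increments of a minimum-jerk position profile."""
    tau = np.arange(duration_ms + 1) / duration_ms
    s = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return np.diff(s)


def _anticipation_profile(
    dist: ForeperiodDistribution, window_ms: float
) -> np.ndarray:
    """anticipation(tau) for tau = 0 .. max support - 1 (vector, cached)."""
    horizon = int(max(dist.support))
    taus = np.arange(horizon)
    out = np.empty(horizon)
    for i, tau in enumerate(taus):
        out[i] = anticipation(dist, float(tau), window_ms)
    return out


_ANTICIPATION_CACHE: dict[tuple, np.ndarray] = {}


def _cached_anticipation(dist: ForeperiodDistribution, window_ms: float) -> np.ndarray:
    key = (dist.support, dist.probs, float(window_ms))
    if key not in _ANTICIPATION_CACHE:
        _ANTICIPATION_CACHE[key] = _anticipation_profile(dist, window_ms)
    return _ANTICIPATION_CACHE[key]


def simulate_gaze(
    schedule: list[Trial],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[GazeRecording, GroundTruth]:
    """Simulate one block recording at 1000 Hz for a trial schedule.

    Returns the binocular recording and the ground-truth event channel
    (absolute times). Saccades are suppressed in and around blinks
    (no saccades mid-blink)."""
    if not schedule:
        raise ValueError("schedule must be nonempty")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = schedule[-1].target_onset_ms + POST_TARGET_MS + 1

    # --- target rate profile (realized saccades/s per ms) ---
    rate = np.full(n, params.base_saccade_rate)
    if params.inhibition_depth > 0:
        for tr in schedule:
            prof = _cached_anticipation(
                BLOCK_DISTRIBUTIONS[tr.block_type], params.inhibition_window_ms
            )
            span = tr.foreperiod_ms  # cue .. target-1
            rate[tr.cue_onset_ms : tr.target_onset_ms] = params.base_saccade_rate * (
                1.0 - params.inhibition_depth * prof[:span]
            )

    # --- blinks ---
    blink_intervals: list[tuple[int, int]] = []
    if params.blink_rate > 0:
        t = 0.0
        while True:
            t += rng.exponential(1000.0 / params.blink_rate)
            onset = int(t)
            dur = int(
                np.clip(
                    rng.normal(params.blink_duration_ms, params.blink_duration_sd_ms),
                    80,
                    400,
                )
            )
            if onset + dur + 25 >= n:
                break
            if blink_intervals and onset - blink_intervals[-1][1] < 300:
                continue
            blink_intervals.append((onset, onset + dur))

    saccade_forbidden = np.zeros(n, dtype=bool)
    for on, off in blink_intervals:
        saccade_forbidden[max(0, on - 50) : min(n, off + 51)] = True

    # --- saccade onsets: Bernoulli thinned by refractory dead time ---
    tau_dead_s = params.dead_time_ms() / 1000.0
    lam = rate / np.maximum(1.0 - rate * tau_dead_s, 0.1)  # Bernoulli intensity /s
    candidates = np.flatnonzero(rng.random(n) < lam / 1000.0)

    onsets: list[int] = []
    offsets: list[int] = []
    amps: list[float] = []
    vps: list[float] = []
    durs: list[int] = []
    inc = np.zeros((n, 2))
    cum_disp = np.zeros(2)
    drift_step = params.drift_sd * math.sqrt(1e-3)
    drift = (
        np.cumsum(rng.normal(0.0, drift_step, size=(n, 2)), axis=0)
        if params.drift_sd > 0
        else np.zeros((n, 2))
    )

    lo, hi = params.amplitude_range_deg
    next_allowed = 0
    for t0 in candidates:
        if t0 < next_allowed or saccade_forbidden[t0]:
            continue
        amp = float(
            np.clip(
                params.amplitude_median_deg
                * math.exp(rng.normal(0.0, params.amplitude_log_sd)),
                lo,
                hi,
            )
        )
        vp = (
            params.main_sequence_slope
            * amp**params.main_sequence_exponent
            * math.exp(rng.normal(0.0, params.main_sequence_noise_sd))
        )
        dur = max(10, int(round(1875.0 * amp / vp)))
        if t0 + dur >= n:
            continue
        # weakly corrective direction keeps gaze near fixation
        pos_now = drift[t0] + cum_disp
        if np.hypot(*pos_now) > 0.3:
            theta = math.atan2(-pos_now[1], -pos_now[0]) + rng.normal(0.0, math.pi / 6)
        else:
            theta = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        inc[t0 + 1 : t0 + dur + 1] += direction * _minjerk_increments(amp, dur)[:, None]
        cum_disp += direction * amp
        onsets.append(int(t0))
        offsets.append(int(t0 + dur))
        amps.append(amp)
        vps.append(float(vp))
        durs.append(dur)
        next_allowed = t0 + dur + int(params.min_isi_ms)

    gaze = drift + np.cumsum(inc, axis=0)

    # --- per-eye channels ---
    def eye_pos(col: int) -> np.ndarray:
        return gaze[:, col] + rng.normal(0.0, params.noise_sd, size=n)

    xL, yL = eye_pos(0), eye_pos(1)
    xR, yR = eye_pos(0), eye_pos(1)

    t_ms = np.arange(n)
    pupil_profile = params.pupil_baseline * (
        1.0 + 0.01 * np.sin(2.0 * math.pi * t_ms / 3000.0 + rng.uniform(0, 2 * math.pi))
    )
    env = np.ones(n)
    for on, off in blink_intervals:
        ramp_on = np.arange(max(0, on - 20), on)
        if len(ramp_on):
            env[ramp_on] = 0.5 * (1 + np.cos(math.pi * (ramp_on - (on - 20)) / 20.0))
        env[on : off + 1] = 0.0
        ramp_off = np.arange(off + 1, min(n, off + 21))
        if len(ramp_off):
            env[ramp_off] = 0.5 * (1 - np.cos(math.pi * (ramp_off - off) / 20.0))
    pupilL = (pupil_profile + rng.normal(0, 0.005 * params.pupil_baseline, n)) * env
    pupilR = (pupil_profile + rng.normal(0, 0.005 * params.pupil_baseline, n)) * env
    for on, off in blink_intervals:
        for arr in (xL, yL, xR, yR):
            arr[on : off + 1] = np.nan

    rec = GazeRecording(xL=xL, yL=yL, pupilL=pupilL, xR=xR, yR=yR, pupilR=pupilR)
    truth = GroundTruth(
        saccade_onsets_ms=np.asarray(onsets, dtype=np.int64),
        saccade_offsets_ms=np.asarray(offsets, dtype=np.int64),
        saccade_amplitudes_deg=np.asarray(amps),
        saccade_peak_velocities_dps=np.asarray(vps),
        blink_intervals_ms=blink_intervals,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Detection scoring against ground truth


def evaluate_detection(
    truth: GroundTruth,
    detected_by_segment: list[tuple[Trial, list]],
    tol_ms: int = 10,
    pre_ms: int = 300,
    post_ms: int = 300,
) -> dict:
    """Precision/recall of detected binocular saccades vs the truth channel.

    ``detected_by_segment`` pairs each trial with the segment's detected
    events (segment-relative onsets). Recall is computed over *scoreable*
    truth events — those whose full waveform lies inside a segment and
    outside blink exclusion zones; precision over all detections, matched
    one-to-one (greedy, within ``tol_ms``) to any truth onset.
    """
    det_abs = np.sort(
        np.array(
            [
                tr.cue_onset_ms - pre_ms + ev.onset_ms  # onset_ms is a segment index
                for tr, events in detected_by_segment
                for ev in events
            ],
            dtype=np.int64,
        )
    )
    truth_on = np.asarray(truth.saccade_onsets_ms)
    truth_off = np.asarray(truth.saccade_offsets_ms)

    excl = []
    for on, off in truth.blink_intervals_ms:
        excl.append((on - 200, off + 200))

    scoreable = np.zeros(len(truth_on), dtype=bool)
    for tr, _ in detected_by_segment:
        lo, hi = tr.cue_onset_ms - pre_ms, tr.target_onset_ms + post_ms
        inside = (truth_on >= lo + 2) & (truth_off <= hi - 2)
        scoreable |= inside
    for lo, hi in excl:
        scoreable &= ~((truth_on <= hi) & (truth_off >= lo))

    matched_truth = np.zeros(len(truth_on), dtype=bool)
    matched_det = np.zeros(len(det_abs), dtype=bool)
    j = 0
    for i, t in enumerate(truth_on):
        while j < len(det_abs) and det_abs[j] < t - tol_ms:
            j += 1
        k = j
        while k < len(det_abs) and det_abs[k] <= t + tol_ms:
            if not matched_det[k]:
                matched_det[k] = True
                matched_truth[i] = True
                break
            k += 1
    n_scoreable = int(scoreable.sum())
    recall = float(matched_truth[scoreable].mean()) if n_scoreable else float("nan")
    precision = float(matched_det.mean()) if len(det_abs) else float("nan")
    return {
        "n_truth_scoreable": n_scoreable,
        "n_detected": int(len(det_abs)),
        "recall": recall,
        "precision": precision,
    }


# ---------------------------------------------------------------------------
# 1-up 3-down staircase


@dataclass
class StaircaseState:
    current_tilt: float
    step_index: int
    reversal_count: int
    trial_count: int
    history: list[tuple[float, bool]] = field(default_factory=list)
    reversal_tilts: list[float] = field(default_factory=list)


def weibull_observer(
    threshold_deg: float = 1.0,
    slope: float = 3.0,
    guess: float = 0.5,
    lapse: float = 0.0,
):
    """2AFC Weibull psychometric function tilt -> P(correct)."""

    def p_correct(tilt: float) -> float:
        return guess + (1.0 - guess - lapse) * (
            1.0 - math.exp(-((tilt / threshold_deg) ** slope))
        )

    return p_correct


def run_staircase(
    observer,
    start_tilt: float = 15.0,
    seed: int = 0,
    step_log10: float = 0.1,
    max_reversals: int = 4,
    max_trials: int = 100,
    tilt_bounds: tuple[float, float] = (1e-3, 60.0),
) -> tuple[float, StaircaseState]:
    """1-up 3-down adaptive staircase with logarithmic steps.

    Tilt decreases one log step after 3 consecutive correct responses and
    increases one log step after any incorrect response; the run ends after
    ``max_reversals`` reversals or ``max_trials`` trials. The returned
    threshold is the final tilt, which sits at the 1-up-3-down convergence
    point (~79.4% correct for a smooth observer).
    """
    if start_tilt <= 0:
        raise ValueError("start_tilt must be positive")
    probe = [observer(x) for x in np.geomspace(0.1, max(start_tilt, 1.0), 8)]
    if any(b < a - 1e-9 for a, b in zip(probe, probe[1:])):
        logger.warning("observer is not monotone nondecreasing in tilt")
    rng = np.random.default_rng(seed)
    factor = 10.0**step_log10
    tilt = float(start_tilt)
    state = StaircaseState(
        current_tilt=tilt, step_index=0, reversal_count=0, trial_count=0
    )
    streak = 0
    last_dir = 0
    for _ in range(max_trials):
        correct = bool(rng.random() < observer(tilt))
        state.history.append((tilt, correct))
        state.trial_count += 1
        move = 0
        if correct:
            streak += 1
            if streak == 3:
                move, streak = -1, 0
        else:
            streak = 0
            move = +1
        if move:
            if last_dir and move != last_dir:
                state.reversal_count += 1
                state.reversal_tilts.append(tilt)
            last_dir = move
            tilt = float(np.clip(tilt * factor**move, *tilt_bounds))
            state.step_index += 1
            if state.reversal_count >= max_reversals:
                break
    state.current_tilt = tilt
    return tilt, state
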