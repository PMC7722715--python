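"""Filtering, segmentation, blink detection and exclusion masks.

The cleaning chain mirrors standard video-oculography practice: position
channels are zero-phase low-pass filtered at 60 Hz, the recording is cut
into per-trial segments from 300 ms before the cue to 300 ms after the
target, blinks are found from missing-data spans plus a binocular pupil
deviation criterion (> 2.5 SD from the segment mean for >= 3 consecutive
samples), and samples within 200 ms of any blink are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .core import BlinkEvent, GazeRecording, Trial, TrialSegment

logger = logging.getLogger(__name__)

__all__ = [
    "lowpass_filter",
    "segment",
    "detect_blinks",
    "exclusion_mask",
    "preprocess_recording",
]

#: minimum finite-run length that the zero-phase filter is applied to
#: (sosfiltfilt needs padding; shorter runs pass through unfiltered)
_MIN_FILTER_RUN = 24


def _filter_channel(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    """Filter each contiguous finite run separately; NaN spans are preserved."""
    out = x.copy()
    finite = np.isfinite(x)
    if finite.all():
        return sosfiltfilt(sos, x)
    edges = np.flatnonzero(np.diff(finite.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, len(x)]
    for s, e in zip(starts, ends):
        if finite[s] and e - s >= _MIN_FILTER_RUN:
            out[s:e] = sosfiltfilt(sos, x[s:e])
    return out


def lowpass_filter(
    recording: GazeRecording, cutoff_hz: float = 60.0, order: int = 4
) -> GazeRecording:
    """Zero-phase (forward-backward) Butterworth low-pass on the position
    channels; pupil channels pass through untouched."""
    fs = recording.sampling_rate
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return GazeRecording(
        xL=_filter_channel(recording.xL, sos),
        yL=_filter_channel(recording.yL, sos),
        pupilL=recording.pupilL,
        xR=_filter_channel(recording.xR, sos),
        yR=_filter_channel(recording.yR, sos),
        pupilR=recording.pupilR,
        sampling_rate=fs,
    )


def segment(
    recording: GazeRecording,
    schedule: list[Trial],
    pre_ms: int = 300,
    post_ms: int = 300,
) -> list[TrialSegment]:
    """Cut one segment per trial: [cue - pre_ms, target + post_ms], both
    endpoints inclusive. Trials whose window exceeds the recording are
    dropped with a logged warning."""
    segments = []
    n = len(recording)
    dropped = 0
    for tr in schedule:
        lo = tr.cue_onset_ms - pre_ms
        hi = tr.target_onset_ms + post_ms  # inclusive
        if lo < 0 or hi >= n:
            dropped += 1
            continue
        sl = slice(lo, hi + 1)
        segments.append(
            TrialSegment(
                trial=tr,
                xL=recording.xL[sl].copy(),
                yL=recording.yL[sl].copy(),
                pupilL=recording.pupilL[sl].copy(),
                xR=recording.xR[sl].copy(),
                yR=recording.yR[sl].copy(),
                pupilR=recording.pupilR[sl].copy(),
                pre_ms=pre_ms,
                post_ms=post_ms,
            )
        )
    if dropped:
        logger.warning("segment: dropped %d trial(s) outside recording bounds", dropped)
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs as inclusive (start, stop) index pairs."""
    if not mask.any():
        return []
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    return [(int(s), int(e - 1)) for s, e in zip(idx[::2], idx[1::2])]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive intervals; touching or overlapping ones merge."""
    merged: list[list[int]] = []
    for on, off in sorted(intervals):
        if merged and on <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])
    return [(a, b) for a, b in merged]


def detect_blinks(
    seg: TrialSegment,
    sd_criterion: float = 2.5,
    min_samples: int = 3,
) -> list[BlinkEvent]:
    """Blinks = missing-data spans plus binocular pupil excursions.

    The deviation criterion flags samples where *both* eyes' pupil size
    deviates from the segment mean by more than ``sd_criterion`` standard
    deviations for at least ``min_samples`` consecutive samples; mean and
    SD are computed per eye over non-missing samples only. Overlapping or
    touching events are merged. Event times are segment indices (0-based
    sample offsets from segment start).
    """
    missing = ~seg.finite_mask()
    if missing.all():
        return [BlinkEvent(onset_ms=0, offset_ms=len(seg) - 1, source="missing_data")]

    intervals = [(on, off, "missing_data") for on, off in _runs(missing)]

    dev_both = np.zeros(len(seg), dtype=bool)
    ok = True
    devs = []
    for pupil in (seg.pupilL, seg.pupilR):
        vals = pupil[~missing]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0.0:
            ok = False
            break
        devs.append(np.abs(pupil - mu) > sd_criterion * sd)
    if ok:
        dev_both = devs[0] & devs[1] & ~missing
    for on, off in _runs(dev_both):
        if off - on + 1 >= min_samples:
            intervals.append((on, off, "pupil_deviation"))

    merged = _merge_intervals([(on, off) for on, off, _ in intervals])
    out = []
    for on, off in merged:
        sources = {
            src for o, f, src in intervals if o <= off and f >= on
        }
        src = "missing_data" if "missing_data" in sources else "pupil_deviation"
        out.append(BlinkEvent(onset_ms=on, offset_ms=off, source=src))
    return out


def exclusion_mask(
    seg: TrialSegment,
    blinks: list[BlinkEvent],
    margin_ms: int = 200,
) -> np.ndarray:
    """Per-sample validity: False inside each blink and within ``margin_ms``
    on both sides (clipped at segment bounds), False on missing samples,
    True elsewhere."""
    mask = seg.finite_mask()
    n = len(seg)
    for b in blinks:
        lo = max(0, b.onset_ms - margin_ms)
        hi = min(n - 1, b.offset_ms + margin_ms)
        mask[lo : hi + 1] = False
    return mask


def preprocess_recording(
    recording: GazeRecording,
    schedule: list[Trial],
    cutoff_hz: float = 60.0,
    blink_sd: float = 2.5,
    blink_min_samples: int = 3,
    margin_ms: int = 200,
) -> list[TrialSegment]:
    """Full cleaning chain: filter -> segment -> blinks -> exclusion mask.

    Each returned segment has ``valid_mask`` set.
    """
    filtered = lowpass_filter(recording, cutoff_hz=cutoff_hz)
    segments = segment(filtered, schedule)
    for seg_ in segments:
        blinks = detect_blinks(seg_, sd_criterion=blink_sd, min_samples=blink_min_samples)
        seg_.valid_mask = exclusion_mask(seg_, blinks, margin_ms=margin_ms)
    return segments
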