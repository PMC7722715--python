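"""Binocular saccade detection by robust velocity thresholding.

Velocity is obtained with a centered 5-sample moving-average kernel; each
velocity component is standardized by its segment median and a
median-based robust SD, and samples whose standardized-velocity norm
stays above a robust threshold for at least six consecutive valid samples
form a monocular saccade. Saccades present in both eyes simultaneously
are merged into binocular events, and an event starting within 50 ms of
the previous offset is discarded as an overshoot. The amplitude vs
peak-velocity correlation (main sequence) serves as detection QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import SaccadeEvent, TrialSegment

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorParams",
    "compute_velocity",
    "detect_monocular",
    "binocular_conjunction",
    "detect_in_segment",
    "main_sequence",
]


@dataclass(frozen=True)
class DetectorParams:
    lambda_sd: float = 6.0
    min_duration_samples: int = 6
    isi_ms: float = 50.0
    velocity_window_samples: int = 5
    #: "norm_median": threshold = median(|z|) + lambda * robust SD(|z|);
    #: "elliptic": classic criterion |z| > lambda.
    threshold_mode: str = "norm_median"

    def __post_init__(self) -> None:
        if min(self.lambda_sd, self.min_duration_samples, self.isi_ms,
               self.velocity_window_samples) <= 0:
            raise ValueError("all detector parameters must be positive")


def compute_velocity(
    position: np.ndarray, sampling_rate: float = 1000.0, window: int = 5
) -> np.ndarray:
    """(n, 2) velocity in deg/s from an (n, 2) position trace.

    Centered moving-window finite difference (the classic 5-sample kernel
    v_t = (x_{t+2} + x_{t+1} - x_{t-1} - x_{t-2}) / (6 dt)); at the edges
    the window shrinks symmetrically (3-sample kernel, then zero).
    """
    position = np.asarray(position, dtype=float)
    n = len(position)
    if n <= window:
        raise ValueError(f"trace length {n} must exceed window {window}")
    dt = 1.0 / sampling_rate
    v = np.zeros_like(position)
    if window >= 5:
        v[2:-2] = (
            position[4:] + position[3:-1] - position[1:-3] - position[:-4]
        ) / (6.0 * dt)
        for i in (1, n - 2):
            v[i] = (position[i + 1] - position[i - 1]) / (2.0 * dt)
    else:  # 3-sample kernel throughout
        v[1:-1] = (position[2:] - position[:-2]) / (2.0 * dt)
    return v


def _robust_sigma(x: np.ndarray) -> float:
    """Median-based SD estimator sqrt(median(x^2) - median(x)^2)."""
    med = float(np.median(x))
    var = float(np.median(x**2)) - med**2
    return float(np.sqrt(max(var, 0.0)))


def standardized_speed(velocity: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Norm of component-wise robustly standardized velocity (NaN where a
    component is not finite)."""
    z = np.full_like(velocity, np.nan)
    for c in range(velocity.shape[1]):
        vc = velocity[:, c]
        ref = vc[valid & np.isfinite(vc)]
        if len(ref) == 0:
            return np.full(len(velocity), np.nan)
        med = float(np.median(ref))
        sig = _robust_sigma(ref)
        if sig == 0.0:
            return np.full(len(velocity), np.nan)
        z[:, c] = (vc - med) / sig
    return np.hypot(z[:, 0], z[:, 1])


def detect_monocular(
    position: np.ndarray,
    valid_mask: np.ndarray,
    params: DetectorParams = DetectorParams(),
    sampling_rate: float = 1000.0,
    eye: str = "left",
) -> list[SaccadeEvent]:
    """Monocular saccades from one eye's (n, 2) position trace.

    Detection marks runs of >= ``min_duration_samples`` consecutive valid
    samples whose standardized speed exceeds the threshold; onset/offset
    are the run boundaries, amplitude is the straight-line displacement
    between onset and offset positions, peak velocity the maximum speed
    within the run. Events overlapping invalid samples never arise because
    runs are restricted to valid samples. Returns an empty list (logged)
    when the mask is all-invalid or velocity variance is zero.
    """
    position = np.asarray(position, dtype=float)
    valid = np.asarray(valid_mask, dtype=bool)
    if len(position) != len(valid):
        raise ValueError("velocity and mask must have equal length")
    if not valid.any():
        return []
    velocity = compute_velocity(
        position, sampling_rate, window=params.velocity_window_samples
    )
    rho = standardized_speed(velocity, valid)
    if np.isnan(rho[valid]).all():
        logger.info("detect_monocular: degenerate velocity statistics; no detections")
        return []

    if params.threshold_mode == "norm_median":
        ref = rho[valid & np.isfinite(rho)]
        med = float(np.median(ref))
        sig = 1.4826 * float(np.median(np.abs(ref - med)))
        if sig == 0.0:
            logger.info("detect_monocular: zero norm spread; no detections")
            return []
        thr = med + params.lambda_sd * sig
    elif params.threshold_mode == "elliptic":
        thr = params.lambda_sd
    else:
        raise ValueError(f"unknown threshold_mode: {params.threshold_mode!r}")

    above = np.zeros(len(rho), dtype=bool)
    finite = np.isfinite(rho)
    above[finite] = rho[finite] > thr
    above &= valid

    speed = np.hypot(velocity[:, 0], velocity[:, 1])
    events = []
    idx = np.flatnonzero(np.diff(np.r_[0, above.astype(np.int8), 0]))
    for s, e in zip(idx[::2], idx[1::2] - 1):
        if e - s + 1 < params.min_duration_samples:
            continue
        amp = float(np.hypot(*(position[e] - position[s])))
        events.append(
            SaccadeEvent(
                onset_ms=int(s),
                offset_ms=int(e),
                amplitude_deg=amp,
                peak_velocity_dps=float(np.nanmax(speed[s : e + 1])),
                eye=eye,
            )
        )
    return events


def binocular_conjunction(
    left: list[SaccadeEvent],
    right: list[SaccadeEvent],
    params: DetectorParams = DetectorParams(),
) -> list[SaccadeEvent]:
    """Keep saccades present in both eyes; enforce the inter-saccade gap.

    Left/right events with >= 1 sample of temporal overlap pair into one
    binocular event (onset = earlier onset, offset = later offset,
    amplitude and peak velocity averaged across eyes). A retained event
    whose onset follows the previous retained offset by less than
    ``isi_ms`` is discarded as an overshoot.
    """
    pairs = []
    used_right: set[int] = set()
    for ev in left:
        for j, rv in enumerate(right):
            if j in used_right:
                continue
            if rv.onset_ms > ev.offset_ms:
                break
            if rv.offset_ms >= ev.onset_ms:  # overlap >= 1 sample
                used_right.add(j)
                pairs.append(
                    SaccadeEvent(
                        onset_ms=min(ev.onset_ms, rv.onset_ms),
                        offset_ms=max(ev.offset_ms, rv.offset_ms),
                        amplitude_deg=(ev.amplitude_deg + rv.amplitude_deg) / 2.0,
                        peak_velocity_dps=(
                            ev.peak_velocity_dps + rv.peak_velocity_dps
                        )
                        / 2.0,
                        eye="binocular",
                    )
                )
                break
    pairs.sort(key=lambda e: e.onset_ms)
    kept: list[SaccadeEvent] = []
    for ev in pairs:
        if kept and ev.onset_ms - kept[-1].offset_ms < params.isi_ms:
            continue
        kept.append(ev)
    return kept


def detect_in_segment(
    seg: TrialSegment, params: DetectorParams = DetectorParams()
) -> list[SaccadeEvent]:
    """Binocular saccades of one trial segment.

    Event times are segment indices; subtract ``seg.pre_ms`` for
    cue-relative ms.
    """
    left = detect_monocular(
        seg.position("left"), seg.valid_mask, params, eye="left"
    )
    right = detect_monocular(
        seg.position("right"), seg.valid_mask, params, eye="right"
    )
    return binocular_conjunction(left, right, params)


def main_sequence(events: list[SaccadeEvent]) -> tuple[float, int]:
    """Pearson r between amplitude and peak velocity, with n.

    Returns (nan, n) when fewer than 3 events or zero amplitude variance —
    the correlation is then flagged as not computable.
    """
    n = len(events)
    if n < 3:
        return float("nan"), n
    amp = np.array([e.amplitude_deg for e in events])
    vp = np.array([e.peak_velocity_dps for e in events])
    if np.std(amp) == 0.0 or np.std(vp) == 0.0:
        return float("nan"), n
    r = float(np.corrcoef(amp, vp)[0, 1])
    return r, n
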