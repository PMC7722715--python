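"""Shared data containers for the gaze-analysis pipeline.

All times are in milliseconds. Recordings are sampled at 1000 Hz, so a
sample index equals a millisecond offset from the start of the recording.
Positions are in degrees of visual angle, pupil size in arbitrary units
(missing data encoded as NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Block types, keyed by the foreperiod distribution they impose.
BLOCK_TYPES = (
    "full_certainty_1s",
    "full_certainty_2s",
    "high_certainty_1s",
    "high_certainty_2s",
    "low_certainty",
)

#: Trial conditions for analysis (block type x foreperiod frequency).
CONDITIONS = (
    "full_certainty",
    "high_certainty_frequent",
    "high_certainty_rare",
    "low_certainty",
)

FOREPERIODS_MS = (1000, 1500, 2000, 2500, 3000)


@dataclass(frozen=True)
class Trial:
    """One scheduled trial: cue onset, foreperiod and target onset are
    absolute times within the block recording."""

    trial_id: int
    block_type: str
    foreperiod_ms: int
    cue_onset_ms: int
    target_onset_ms: int
    iti_ms: int

    def __post_init__(self) -> None:
        if self.target_onset_ms - self.cue_onset_ms != self.foreperiod_ms:
            raise ValueError("target_onset_ms - cue_onset_ms must equal foreperiod_ms")


@dataclass
class GazeRecording:
    """Binocular sample stream at a fixed sampling rate.

    Channels are equal-length 1-D float arrays; missing samples are NaN.
    """

    xL: np.ndarray
    yL: np.ndarray
    pupilL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    pupilR: np.ndarray
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        n = len(self.xL)
        for name in ("yL", "pupilL", "xR", "yR", "pupilR"):
            if len(getattr(self, name)) != n:
                raise ValueError("all channels must have equal length")

    def __len__(self) -> int:
        return len(self.xL)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self), dtype=np.int64)

    def position(self, eye: str) -> np.ndarray:
        """(n, 2) position trace for 'left' or 'right' eye."""
        if eye == "left":
            return np.column_stack([self.xL, self.yL])
        if eye == "right":
            return np.column_stack([self.xR, self.yR])
        raise ValueError(f"unknown eye: {eye!r}")


@dataclass
class TrialSegment:
    """Samples from -300 ms pre-cue to +300 ms post-target, inclusive at
    both endpoints (foreperiod + 601 samples). ``time_ms`` is relative to
    cue onset (t = 0 at cue)."""

    trial: Trial
    xL: np.ndarray
    yL: np.ndarray
    pupilL: np.ndarray
    xR: np.ndarray
    yR: np.ndarray
    pupilR: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    pre_ms: int = 300
    post_ms: int = 300

    def __post_init__(self) -> None:
        n = self.trial.foreperiod_ms + self.pre_ms + self.post_ms + 1
        if len(self.xL) != n:
            raise ValueError(
                f"segment length {len(self.xL)} != foreperiod + {self.pre_ms + self.post_ms + 1}"
            )
        if self.valid_mask is None:
            self.valid_mask = self.finite_mask()
        if len(self.valid_mask) != n:
            raise ValueError("valid_mask length must equal segment length")

    def __len__(self) -> int:
        return len(self.xL)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(-self.pre_ms, self.trial.foreperiod_ms + self.post_ms + 1)

    @property
    def cue_index(self) -> int:
        return self.pre_ms

    @property
    def target_index(self) -> int:
        return self.pre_ms + self.trial.foreperiod_ms

    def position(self, eye: str) -> np.ndarray:
        if eye == "left":
            return np.column_stack([self.xL, self.yL])
        if eye == "right":
            return np.column_stack([self.xR, self.yR])
        raise ValueError(f"unknown eye: {eye!r}")

    def finite_mask(self) -> np.ndarray:
        """Samples where every channel is present."""
        return (
            np.isfinite(self.xL)
            & np.isfinite(self.yL)
            & np.isfinite(self.xR)
            & np.isfinite(self.yR)
            & np.isfinite(self.pupilL)
            & np.isfinite(self.pupilR)
        )


@dataclass(frozen=True)
class BlinkEvent:
    """Detected blink, in segment-relative ms (inclusive interval)."""

    onset_ms: int
    offset_ms: int
    source: str  # "missing_data" | "pupil_deviation"

    def __post_init__(self) -> None:
        if self.offset_ms < self.onset_ms:
            raise ValueError("blink offset before onset")


@dataclass(frozen=True)
class SaccadeEvent:
    """Detected saccade, in segment-relative ms (inclusive interval)."""

    onset_ms: int
    offset_ms: int
    amplitude_deg: float
    peak_velocity_dps: float
    eye: str  # "left" | "right" | "binocular"

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must follow onset")


@dataclass
class GroundTruth:
    """Truth channel of the simulator: every injected event, in absolute
    recording time."""

    saccade_onsets_ms: np.ndarray
    saccade_offsets_ms: np.ndarray
    saccade_amplitudes_deg: np.ndarray
    saccade_peak_velocities_dps: np.ndarray
    blink_intervals_ms: list[tuple[int, int]]

    def __post_init__(self) -> None:
        on = np.asarray(self.saccade_onsets_ms)
        if np.any(np.diff(on) < 0):
            raise ValueError("saccade onsets must be sorted")
        if np.any(np.asarray(self.saccade_amplitudes_deg) <= 0):
            raise ValueError("amplitudes must be positive")

    @property
    def n_saccades(self) -> int:
        return len(self.saccade_onsets_ms)
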