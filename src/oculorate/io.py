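"""Plain-text readers/writers for recordings, schedules and events.

Gaze CSV dialect: columns time_ms, xL_deg, yL_deg, pupilL, xR_deg,
yR_deg, pupilR with missing samples as empty fields. A minimal EyeLink
ASC importer reads binocular sample lines (timestamp, xL, yL, pL, xR,
yR, pR; '.' marks missing); message/event lines are skipped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GazeRecording, GroundTruth, SaccadeEvent, Trial

__all__ = [
    "write_gaze_csv",
    "read_gaze_csv",
    "write_schedule_csv",
    "read_schedule_csv",
    "write_events_csv",
    "write_ground_truth_csv",
    "read_asc_samples",
]

_GAZE_COLS = ["time_ms", "xL_deg", "yL_deg", "pupilL", "xR_deg", "yR_deg", "pupilR"]


def write_gaze_csv(recording: GazeRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_ms": recording.time_ms,
            "xL_deg": recording.xL,
            "yL_deg": recording.yL,
            "pupilL": recording.pupilL,
            "xR_deg": recording.xR,
            "yR_deg": recording.yR,
            "pupilR": recording.pupilR,
        }
    )
    df.to_csv(path, index=False, na_rep="")


def read_gaze_csv(path: str | Path) -> GazeRecording:
    df = pd.read_csv(path)
    missing = [c for c in _GAZE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV missing columns: {missing}")
    return GazeRecording(
        xL=df["xL_deg"].to_numpy(float),
        yL=df["yL_deg"].to_numpy(float),
        pupilL=df["pupilL"].to_numpy(float),
        xR=df["xR_deg"].to_numpy(float),
        yR=df["yR_deg"].to_numpy(float),
        pupilR=df["pupilR"].to_numpy(float),
    )


def write_schedule_csv(schedule: list[Trial], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "block_type": t.block_type,
                "foreperiod_ms": t.foreperiod_ms,
                "cue_onset_ms": t.cue_onset_ms,
                "target_onset_ms": t.target_onset_ms,
                "iti_ms": t.iti_ms,
            }
            for t in schedule
        ]
    ).to_csv(path, index=False)


def read_schedule_csv(path: str | Path) -> list[Trial]:
    df = pd.read_csv(path)
    return [
        Trial(
            trial_id=int(r.trial_id),
            block_type=str(r.block_type),
            foreperiod_ms=int(r.foreperiod_ms),
            cue_onset_ms=int(r.cue_onset_ms),
            target_onset_ms=int(r.target_onset_ms),
            iti_ms=int(r.iti_ms),
        )
        for r in df.itertuples()
    ]


def write_events_csv(
    events_by_trial: list[tuple[int, list[SaccadeEvent]]], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": trial_id,
                "onset_ms": e.onset_ms,
                "offset_ms": e.offset_ms,
                "amplitude_deg": e.amplitude_deg,
                "peak_velocity_dps": e.peak_velocity_dps,
                "eye": e.eye,
            }
            for trial_id, events in events_by_trial
            for e in events
        ],
        columns=[
            "trial_id",
            "onset_ms",
            "offset_ms",
            "amplitude_deg",
            "peak_velocity_dps",
            "eye",
        ],
    ).to_csv(path, index=False)


def write_ground_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {
            "kind": "saccade",
            "onset_ms": int(on),
            "offset_ms": int(off),
            "amplitude_deg": float(a),
        }
        for on, off, a in zip(
            truth.saccade_onsets_ms,
            truth.saccade_offsets_ms,
            truth.saccade_amplitudes_deg,
        )
    ] + [
        {"kind": "blink", "onset_ms": on, "offset_ms": off, "amplitude_deg": np.nan}
        for on, off in truth.blink_intervals_ms
    ]
    pd.DataFrame(rows, columns=["kind", "onset_ms", "offset_ms", "amplitude_deg"]).to_csv(
        path, index=False, na_rep=""
    )


def read_asc_samples(path: str | Path) -> GazeRecording:
    """Minimal EyeLink ASC import: binocular sample lines only.

    A sample line starts with a numeric timestamp followed by
    xL yL pupilL xR yR pupilR; '.' (or a missing field) marks missing
    data. All other lines (messages, event records) are skipped. Full ASC
    message parsing is out of scope.
    """
    cols: list[list[float]] = [[] for _ in range(6)]
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0][0].isdigit():
                continue
            vals = parts[1:7]
            if len(vals) < 6:
                continue
            for i, v in enumerate(vals):
                try:
                    cols[i].append(float(v))
                except ValueError:
                    cols[i].append(float("nan"))
    xL, yL, pL, xR, yR, pR = (np.asarray(c) for c in cols)
    return GazeRecording(xL=xL, yL=yL, pupilL=pL, xR=xR, yR=yR, pupilR=pR)
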