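"""Reading and writing the package's interchange formats.

Tracks travel as CSV with columns ``track_id, frame, t_s, x_um, y_um,
z_um`` (one row per frame); segmented runs as CSV with per-run direction
and speed; fitted results as JSON.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import TrackFormatError
from .processing import Run
from .tracks import TRACK_COLUMNS, Track, TrackSet

__all__ = ["read_tracks", "write_tracks", "write_runs", "read_runs", "write_json"]

RUN_COLUMNS = [
    "track_id", "start_s", "end_s", "duration_s",
    "dir_x", "dir_y", "dir_z", "mean_speed", "censored",
]


def read_tracks(path) -> TrackSet:
    """Load a track CSV into a :class:`TrackSet`.

    Rows are grouped by ``track_id`` and sorted by ``frame``.  Missing
    columns, non-numeric fields and duplicate (track_id, frame) pairs
    raise :class:`TrackFormatError` naming the offending lines (1-based,
    counting the header as line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    numeric = ["frame", "t_s", "x_um", "y_um", "z_um"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1) & df[numeric].notna().any(axis=1)
    bad |= df[numeric].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise TrackFormatError(f"{path}: non-numeric or missing fields at lines {lines}")
    df[numeric] = coerced
    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise TrackFormatError(f"{path}: duplicate (track_id, frame) at lines {lines}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        tracks.append(
            Track(
                tid,
                grp["t_s"].to_numpy(),
                grp[["x_um", "y_um", "z_um"]].to_numpy(),
                frames=grp["frame"].to_numpy(dtype=int),
            )
        )
    return TrackSet(tracks)


def write_tracks(tracks: TrackSet, path) -> None:
    tracks.to_frame().to_csv(path, index=False, float_format="%.12g")


def write_runs(runs: Iterable[Run], path) -> None:
    rows = [
        {
            "track_id": r.track_id,
            "start_s": r.start,
            "end_s": r.end,
            "duration_s": r.duration,
            "dir_x": r.mean_direction[0],
            "dir_y": r.mean_direction[1],
            "dir_z": r.mean_direction[2],
            "mean_speed": r.mean_speed,
            "censored": r.censored,
        }
        for r in runs
    ]
    pd.DataFrame(rows, columns=RUN_COLUMNS).to_csv(path, index=False)


def read_runs(path) -> list[Run]:
    df = pd.read_csv(path)
    missing = [c for c in RUN_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing run columns {missing}")
    return [
        Run(
            track_id=row.track_id,
            start=int(row.start_s),
            end=int(row.end_s),
            duration=float(row.duration_s),
            mean_direction=np.array([row.dir_x, row.dir_y, row.dir_z]),
            mean_speed=float(row.mean_speed),
            censored=bool(row.censored),
        )
        for row in df.itertuples()
    ]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, default=_jsonable)
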