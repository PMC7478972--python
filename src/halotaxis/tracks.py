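"""Track containers: a single cell's 3D time series and sets thereof.

A :class:`Track` stores positions in micrometres in the lab frame, sampled
at (nominally) uniform intervals.  Derived per-frame quantities -- the unit
tangent ``a(t)``, the instantaneous speed ``v_t`` and the track-mean speed
-- are computed lazily from finite differences of the positions.  Tangents
and speeds are defined on frame intervals, so a track of N frames has N-1
of each; the tangent is undefined at the final frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateTrackError, TrackFormatError

__all__ = ["Track", "TrackSet"]

#: column order of the interchange CSV format
TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "z_um"]


@dataclass(eq=False)
class Track:
    """One cell's 3D trajectory.

    Parameters
    ----------
    track_id : identifier of the cell/track.
    times : array of sample times in seconds, strictly increasing.
    positions : (N, 3) array of lab-frame positions in micrometres.
    frames : optional original frame indices (used to locate gaps in raw
        data); defaults to 0..N-1.
    meta : free-form provenance dictionary (e.g. ground-truth reversal
        times for synthetic tracks).
    """

    track_id: object
    times: np.ndarray
    positions: np.ndarray
    frames: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrackFormatError("positions must be an (N, 3) array")
        if self.times.shape[0] != self.positions.shape[0]:
            raise TrackFormatError("times and positions length mismatch")
        if self.times.size < 2:
            raise TrackFormatError("a track needs at least 2 frames")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.positions)
        ):
            raise TrackFormatError("non-finite coordinates in track")
        if np.any(np.diff(self.times) <= 0):
            raise TrackFormatError("timestamps must be strictly increasing")
        if self.frames is None:
            self.frames = np.arange(self.times.size)
        else:
            self.frames = np.asarray(self.frames)
        self._cache: dict = {}

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def dt(self) -> float:
        """Median frame interval in seconds."""
        return float(np.median(np.diff(self.times)))

    @property
    def is_uniform(self) -> bool:
        """True if sampling is uniform to within 1e-9 s."""
        d = np.diff(self.times)
        return bool(np.all(np.abs(d - d[0]) < 1e-9))

    # -- derived kinematics --------------------------------------------
    @property
    def step_vectors(self) -> np.ndarray:
        """(N-1, 3) displacement per frame interval, micrometres."""
        if "steps" not in self._cache:
            self._cache["steps"] = np.diff(self.positions, axis=0)
        return self._cache["steps"]

    @property
    def speeds(self) -> np.ndarray:
        """Instantaneous speeds v_t on frame intervals, um/s."""
        if "speeds" not in self._cache:
            d = np.linalg.norm(self.step_vectors, axis=1)
            self._cache["speeds"] = d / np.diff(self.times)
        return self._cache["speeds"]

    @property
    def mean_speed(self) -> float:
        """Track-mean speed <v>_t in um/s."""
        return float(np.mean(self.speeds))

    @property
    def tangents(self) -> np.ndarray:
        """(N-1, 3) unit tangents a(t); undefined at the final frame."""
        if "tangents" not in self._cache:
            steps = self.step_vectors
            norms = np.linalg.norm(steps, axis=1, keepdims=True)
            norms = np.where(norms == 0.0, np.nan, norms)
            self._cache["tangents"] = steps / norms
        return self._cache["tangents"]

    # ------------------------------------------------------------------
    def msd(self, lags_frames: Sequence[int]) -> np.ndarray:
        """Time-averaged mean-squared displacement at integer frame lags."""
        out = np.empty(len(lags_frames))
        pos = self.positions
        for i, m in enumerate(lags_frames):
            if m < 1 or m >= self.n_frames:
                raise DegenerateTrackError(f"lag {m} outside track of {self.n_frames} frames")
            d = pos[m:] - pos[:-m]
            out[i] = np.mean(np.sum(d * d, axis=1))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Interchange representation (one row per frame)."""
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": self.frames,
                "t_s": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "z_um": self.positions[:, 2],
            }
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Track({self.track_id!r}, {self.n_frames} frames, "
            f"{self.duration:.2f} s)"
        )


class TrackSet:
    """An ordered collection of :class:`Track` objects."""

    def __init__(self, tracks: Sequence[Track]):
        self.tracks = list(tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]

    def to_frame(self) -> pd.DataFrame:
        if not self.tracks:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat([t.to_frame() for t in self.tracks], ignore_index=True)

    def pooled_speeds(self) -> np.ndarray:
        """All instantaneous speeds pooled across tracks."""
        if not self.tracks:
            return np.empty(0)
        return np.concatenate([t.speeds for t in self.tracks])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TrackSet({len(self.tracks)} tracks)"
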