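"""Raw-track conditioning, motility classification, reversal detection.

The processing chain mirrors the holographic-tracking analysis this
package models: linear interpolation across short detection gaps, cubic
smoothing splines per coordinate, rejection of short tracks, a
mean-squared-displacement test separating swimmers from diffusers, and a
heuristic reversal statistic

    Xi(t) = |a(t) . a(t+1)| / dt * [1 - v_t / <v>_t]

built from the unit tangent ``a`` and the instantaneous speed ``v_t``
relative to the track mean ``<v>_t``.  During a steady run the bracket is
near zero; at a reversal the smoothed trajectory folds back on itself and
the speed dips towards zero, so Xi spikes (its maximum possible value is
1/dt).  Note the printed form relies entirely on the speed dip: at a
perfect reversal |a.a'| is ~1 just as during a run.  An alternative
variant replacing |a.a'| with the angular speed arccos(a.a')/dt is
available (``variant="angular"``); both are calibrated on synthetic
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.stats import norm

from .errors import DegenerateTrackError, ParameterError, TrackFormatError
from .tracks import Track, TrackSet

__all__ = [
    "smooth_and_filter",
    "process_tracks",
    "classify_motile",
    "reversal_statistic",
    "segment_runs",
    "fit_run_durations",
    "fit_speed_distribution",
    "Run",
    "ReversalSeries",
    "RunDurationFit",
    "SpeedFit",
]

log = logging.getLogger(__name__)

#: default curvature penalty of the cubic smoothing spline (um^2 s^3).
#: Calibrated on synthetic ground truth at the study conditions (50 Hz,
#: 0.4/0.5 um noise, ~2 um/s swimmers): values in [0.3, 3] recover
#: generating speeds to within 10%; 1.0 is the centre of that plateau.
DEFAULT_SPLINE_PENALTY = 1.0

#: "auto" reversal threshold = this multiple of the per-track median |Xi|,
#: with an absolute floor of AUTO_THRESHOLD_FLOOR / dt (i.e. the speed must
#: dip by at least that fraction of the track mean).  Calibrated on
#: synthetic ground truth (see segment_runs).
AUTO_THRESHOLD_MULTIPLIER = 3.0
AUTO_THRESHOLD_FLOOR = 0.25


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class Run:
    """A straight-swimming segment between reorientation events."""

    track_id: object
    start: int  #: first frame index of the run
    end: int  #: last frame index (exclusive for tangents)
    duration: float  #: s
    mean_direction: np.ndarray  #: unit 3-vector
    mean_speed: float  #: um/s
    censored: bool = False  #: True if cut by the track boundary

    def __post_init__(self):
        if self.end <= self.start:
            raise ParameterError("run must have end > start")
        if self.duration <= 0:
            raise ParameterError("run duration must be positive")


@dataclass
class ReversalSeries:
    """Per-frame Xi values and the detected reversal frames."""

    xi: np.ndarray  #: 1/s, for tangent pairs (i, i+m); see reversal_statistic
    dt: float
    variant: str = "speed"
    baseline_frames: int = 1
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def event_times(self) -> np.ndarray:
        return self.events * self.dt


@dataclass(frozen=True)
class RunDurationFit:
    """Exponential maximum-likelihood fit of run durations."""

    mean: float  #: tau_run, s
    stderr: float  #: mean / sqrt(n)
    n_runs: int


@dataclass(frozen=True)
class SpeedFit:
    """Gaussian fit to pooled instantaneous speeds."""

    mean: float  #: um/s
    sd: float  #: um/s
    n: int


# ---------------------------------------------------------------------------
# smoothing and filtering


def _split_on_gaps(track: Track, max_gap: int):
    """Split a raw track at sampling gaps longer than ``max_gap`` frames.

    Returns a list of (times, positions) pieces with gaps of up to
    ``max_gap`` missing frames linearly interpolated onto the uniform
    grid.
    """
    t, pos = track.times, track.positions
    dt = float(np.min(np.diff(t)))
    n_missing = np.rint(np.diff(t) / dt).astype(int) - 1
    pieces = []
    start = 0
    for i, m in enumerate(n_missing):
        if m > max_gap:
            pieces.append((t[start : i + 1], pos[start : i + 1]))
            start = i + 1
    pieces.append((t[start:], pos[start:]))

    out = []
    for tt, pp in pieces:
        if tt.size < 2:
            continue
        n = int(round((tt[-1] - tt[0]) / dt)) + 1
        grid = tt[0] + np.arange(n) * dt
        interp = np.column_stack(
            [np.interp(grid, tt, pp[:, k]) for k in range(3)]
        )
        out.append((grid, interp))
    return out, dt


def smooth_and_filter(
    raw: Track,
    max_gap: int = 5,
    min_duration: float = 3.0,
    spline_penalty: float = DEFAULT_SPLINE_PENALTY,
) -> list[Track]:
    """Condition a raw track: interpolate gaps, spline-smooth, reject short.

    Gaps of up to ``max_gap`` missing frames are filled by linear
    interpolation; longer gaps split the track.  Each coordinate is then
    smoothed with a penalised cubic smoothing spline (curvature penalty
    ``spline_penalty``).  The default penalty is calibrated on synthetic
    ground truth so that finite-difference speeds of the smoothed track
    recover the generating swim speed; at the study's noise levels the
    smoothed track then sits within ~0.2 um RMS of the noise-free path
    and the residual RMS is close to the localisation noise.  Pieces
    shorter than ``min_duration`` seconds are rejected with a logged
    reason.

    Returns a list of smoothed :class:`Track` pieces (possibly empty).
    Raises :class:`TrackFormatError` for non-monotone timestamps.
    """
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    if np.any(np.diff(raw.times) <= 0):
        raise TrackFormatError("timestamps must be strictly increasing")
    pieces, dt = _split_on_gaps(raw, max_gap)
    out = []
    for idx, (t, pos) in enumerate(pieces):
        dur = t[-1] - t[0]
        if dur < min_duration:
            log.info(
                "rejecting %s piece %d: duration %.2f s < %.2f s",
                raw.track_id, idx, dur, min_duration,
            )
            continue
        smoothed = np.empty_like(pos)
        for k in range(3):
            try:
                spl = make_smoothing_spline(t, pos[:, k], lam=spline_penalty)
                smoothed[:, k] = spl(t)
            except Exception:  # very short/degenerate piece: keep raw
                smoothed[:, k] = pos[:, k]
        tid = raw.track_id if len(pieces) == 1 else f"{raw.track_id}.{idx}"
        out.append(Track(tid, t, smoothed, meta=dict(raw.meta)))
    return out


def process_tracks(
    tracks: TrackSet,
    max_gap: int = 5,
    min_duration: float = 3.0,
    spline_penalty: float = DEFAULT_SPLINE_PENALTY,
    drop_diffusing: bool = True,
) -> tuple[TrackSet, dict]:
    """Smooth and filter a whole track set; optionally drop diffusers.

    Returns the surviving smoothed tracks and a report dictionary with
    discard counts.
    """
    kept, report = [], {"input": len(tracks), "short": 0, "diffusing": 0}
    for tr in tracks:
        pieces = smooth_and_filter(tr, max_gap, min_duration, spline_penalty)
        if not pieces:
            report["short"] += 1
            continue
        for p in pieces:
            if drop_diffusing and classify_motile(p) == "diffusing":
                report["diffusing"] += 1
                continue
            kept.append(p)
    report["kept"] = len(kept)
    return TrackSet(kept), report


# ---------------------------------------------------------------------------
# motility classification


def classify_motile(
    track: Track,
    window: tuple[float, float] = (1.0, 5.0),
    threshold: float = 1.5,
) -> str:
    """Label a smoothed track ``swimming`` or ``diffusing``.

    Fits the log-log slope alpha of the time-averaged MSD over lag times
    ``window`` (seconds).  Ballistic swimmers give alpha ~ 2, diffusers
    alpha ~ 1; the default decision threshold is 1.5.  The window starts
    at 1 s because spline smoothing makes even a diffuser's trajectory
    locally ballistic below the smoothing scale (calibrated on synthetic
    swimmers vs diffusers: slopes separate cleanly on [1, 5] s).  Tracks
    too short for the window are labelled ``indeterminate``.
    """
    dt = track.dt
    lo = max(1, int(round(window[0] / dt)))
    hi = int(round(window[1] / dt))
    if hi >= track.n_frames or hi <= lo:
        return "indeterminate"
    lags = np.unique(np.geomspace(lo, hi, 12).astype(int))
    msd = track.msd(lags)
    good = msd > 0
    if good.sum() < 3:
        return "indeterminate"
    alpha = np.polyfit(np.log(lags[good] * dt), np.log(msd[good]), 1)[0]
    return "swimming" if alpha >= threshold else "diffusing"


# ---------------------------------------------------------------------------
# reversal statistic and run segmentation


def reversal_statistic(
    track: Track, variant: str = "speed", baseline: float | None = None
) -> ReversalSeries:
    """Compute the per-frame reversal statistic Xi.

    ``variant="speed"`` is the printed form
    ``|a(t).a(t+1)|/dt * [1 - v_t/<v>_t]``; ``variant="angular"`` replaces
    the first factor with the angular speed ``arccos(a(t).a(t+m))/(m dt)``
    so that direction changes contribute directly.  For the angular
    variant, ``baseline`` sets the comparison lag ``m dt`` in seconds
    (default: adjacent frames); a longer baseline averages out helical
    wobble and localisation noise, which helps for slow swimmers whose
    frame-to-frame displacement is far below the noise floor.

    Xi[i] compares tangents i and i+m and is bookkept at frame i; values
    exist for i in 0..N-2-m.
    """
    if track.n_frames < 3:
        raise DegenerateTrackError("need >= 3 frames for the reversal statistic")
    vbar = track.mean_speed
    if vbar == 0:
        raise DegenerateTrackError("zero mean speed: Xi undefined")
    a = track.tangents
    dt = track.dt
    m = 1 if baseline is None else max(1, int(round(baseline / dt)))
    if m >= a.shape[0]:
        raise DegenerateTrackError("baseline exceeds track length")
    dots = np.einsum("ij,ij->i", a[:-m], a[m:])
    if variant == "speed":
        front = np.abs(dots) / (m * dt)
    elif variant == "angular":
        front = np.arccos(np.clip(dots, -1.0, 1.0)) / (m * dt)
    else:
        raise ParameterError("variant must be 'speed' or 'angular'")
    # the speed dip of a reversal sits midway between the compared tangents
    mid = m // 2
    v = track.speeds[mid : mid + front.size]
    xi = front * (1.0 - v / vbar)
    return ReversalSeries(xi=xi, dt=dt, variant=variant, baseline_frames=m)


def _pick_events(xi: np.ndarray, threshold: float, min_sep: int) -> np.ndarray:
    """Local maxima of xi above threshold, at least min_sep frames apart."""
    above = np.flatnonzero(xi > threshold)
    if above.size == 0:
        return np.empty(0, dtype=int)
    # cluster contiguous/nearby threshold crossings, keep each cluster's peak
    events = []
    cluster = [above[0]]
    for i in above[1:]:
        if i - cluster[-1] <= min_sep:
            cluster.append(i)
        else:
            events.append(cluster[int(np.argmax(xi[cluster]))])
            cluster = [i]
    events.append(cluster[int(np.argmax(xi[cluster]))])
    # enforce separation between surviving peaks (keep the larger)
    events.sort()
    merged: list[int] = []
    for e in events:
        if merged and e - merged[-1] < min_sep:
            if xi[e] > xi[merged[-1]]:
                merged[-1] = e
        else:
            merged.append(e)
    return np.asarray(merged, dtype=int)


def segment_runs(
    track: Track,
    series: ReversalSeries | None = None,
    threshold: float | str = "auto",
    min_separation: float = 1.0,
    variant: str = "speed",
    baseline: float | None = None,
) -> tuple[list[Run], ReversalSeries]:
    """Split a track into runs at reversal events.

    Frames where Xi exceeds the threshold (local maxima, minimum event
    separation ``min_separation`` seconds) are reversal events; runs are
    the segments between consecutive events.  ``threshold="auto"`` uses
    ``AUTO_THRESHOLD_MULTIPLIER`` times the track's median |Xi|, which is
    robust to the per-track speed scale; the multiplier (3) is calibrated
    on synthetic ground truth at the study conditions, where it recovers
    both the programmed event rate and the mean run duration.  The first
    and last runs touch the track boundary and are flagged ``censored``;
    duration statistics should exclude them.
    """
    if series is None:
        series = reversal_statistic(track, variant=variant, baseline=baseline)
    xi = series.xi
    if threshold == "auto":
        med = float(np.median(np.abs(xi)))
        floor = AUTO_THRESHOLD_FLOOR / (series.dt * series.baseline_frames)
        thr = max(AUTO_THRESHOLD_MULTIPLIER * med, floor)
    else:
        thr = float(threshold)
    min_sep = max(1, int(round(min_separation / series.dt)))
    events = _pick_events(xi, thr, min_sep)
    series.events = events

    # xi[i] compares tangents i and i+m: the event sits mid-interval
    offset = (series.baseline_frames + 1) // 2
    bounds = np.concatenate(([0], events + offset, [track.n_frames - 1]))
    runs = []
    n_ev = events.size
    for j in range(len(bounds) - 1):
        s, e = int(bounds[j]), int(bounds[j + 1])
        if e <= s:
            continue
        direction = track.step_vectors[s:e].sum(axis=0)
        nrm = np.linalg.norm(direction)
        if nrm == 0:
            continue
        censored = (j == 0) or (j == len(bounds) - 2)
        runs.append(
            Run(
                track_id=track.track_id,
                start=s,
                end=e,
                duration=float(track.times[e] - track.times[s]),
                mean_direction=direction / nrm,
                mean_speed=float(np.mean(track.speeds[s:e])),
                censored=censored if n_ev > 0 else True,
            )
        )
    return runs, series


# ---------------------------------------------------------------------------
# distribution fits


def fit_run_durations(durations) -> RunDurationFit:
    """Exponential MLE of the mean run duration.

    The MLE of an exponential mean is the sample mean; its standard error
    is mean/sqrt(n).
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ParameterError("no run durations to fit")
    if np.any(d <= 0):
        raise ParameterError("run durations must be positive")
    mean = float(np.mean(d))
    return RunDurationFit(mean=mean, stderr=mean / np.sqrt(d.size), n_runs=d.size)


def fit_speed_distribution(speeds) -> SpeedFit:
    """Gaussian fit (mean, sd) to pooled instantaneous speeds."""
    v = np.asarray(speeds, dtype=float)
    if v.size < 10:
        raise ParameterError("need at least 10 speed samples")
    if np.std(v) == 0:
        raise DegenerateTrackError("zero-variance speed sample")
    mu, sd = norm.fit(v)
    return SpeedFit(mean=float(mu), sd=float(sd), n=v.size)
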