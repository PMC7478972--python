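"""Direction autocorrelation and the helical-plus-Brownian model fit.

For a purely Brownian swimming direction the correlation decays as
``C_B(tau) = exp(-2 D_r tau)``.  Helically swimming cells superimpose a
periodic component: the tangent precesses at angular frequency ``omega``
around a slowly diffusing axis at fixed pitch angle ``theta``, giving

    C(tau) = exp(-2 D_r tau) [ cos^2 theta + sin^2 theta cos(omega tau) ].

Fitting the plain exponential to helical data over-estimates D_r, because
the rapid helical wobble is booked as extra rotational diffusion; the full
model separates the two.  The directional memory time is
``tau_r = 1 / (2 D_r)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateTrackError, FitError, ParameterError
from .tracks import Track

__all__ = [
    "CorrelationCurve",
    "direction_correlation",
    "HelicalCorrelationModel",
    "HelicalCorrelationResults",
    "fit_helical_correlation",
    "rotational_relaxation",
    "LogNormalFit",
    "fit_lognormal",
]


@dataclass(frozen=True)
class CorrelationCurve:
    """Direction correlation C(tau) on a lag grid, with sample counts."""

    lags: np.ndarray  #: s
    values: np.ndarray  #: dimensionless
    counts: np.ndarray  #: number of tangent pairs per lag

    def __post_init__(self):
        if not (len(self.lags) == len(self.values) == len(self.counts)):
            raise ParameterError("curve arrays must have equal length")


def _lag_grid(dt: float, max_lag: float, dense_until: float = 2.0) -> np.ndarray:
    """Integer frame lags: every frame up to ``dense_until`` s, then
    logarithmic up to ``max_lag`` (controls cost on long tracks)."""
    max_m = int(np.floor(max_lag / dt))
    dense = np.arange(0, min(max_m, int(round(dense_until / dt))) + 1)
    if max_m > dense[-1]:
        n_log = 40
        logs = np.unique(
            np.geomspace(dense[-1] + 1, max_m, n_log).astype(int)
        )
        return np.concatenate([dense, logs])
    return dense


def direction_correlation(
    track: Track,
    max_lag: float,
    events: np.ndarray | None = None,
    exclusion: float = 1.0,
    lags_frames: np.ndarray | None = None,
) -> CorrelationCurve:
    """Average tangent autocorrelation C(tau) = <a(t) . a(t+tau)>.

    Averaging is restricted to pairs of frames lying within the same run:
    ``events`` (reversal frame indices, e.g. from
    :func:`halotaxis.processing.segment_runs`) split the track, and frames
    within ``exclusion`` seconds of an event are dropped so the
    reorientation transient does not contaminate the estimate.

    ``max_lag`` may not exceed half the track duration; lags for which no
    valid pairs remain are truncated from the returned curve.
    """
    if max_lag > track.duration / 2 + 1e-9:
        raise ParameterError("max_lag exceeds half the track duration")
    dt = track.dt
    a = track.tangents
    n = a.shape[0]
    valid = ~np.any(np.isnan(a), axis=1)
    run_id = np.zeros(n, dtype=int)
    if events is not None and len(events) > 0:
        ev = np.asarray(events, dtype=int)
        run_id = np.searchsorted(ev, np.arange(n), side="right")
        excl = max(0, int(round(exclusion / dt)))
        for e in ev:
            valid[max(0, e - excl) : e + excl + 1] = False
    if lags_frames is None:
        lags_frames = _lag_grid(dt, max_lag)
    lags_out, vals, counts = [], [], []
    for m in lags_frames:
        m = int(m)
        if m >= n:
            break
        if m == 0:
            ok = valid
            dots = np.ones(int(ok.sum()))
        else:
            ok = valid[:-m] & valid[m:] & (run_id[:-m] == run_id[m:])
            dots = np.einsum("ij,ij->i", a[:-m][ok], a[m:][ok])
        if dots.size == 0:
            continue
        lags_out.append(m * dt)
        vals.append(float(np.mean(dots)))
        counts.append(dots.size)
    if not lags_out:
        raise DegenerateTrackError("no valid tangent pairs for the correlation")
    return CorrelationCurve(
        np.asarray(lags_out), np.asarray(vals), np.asarray(counts)
    )


# ---------------------------------------------------------------------------
# model fit


def _helical_model(lags, D_r, omega, theta):
    c2 = np.cos(theta) ** 2
    return np.exp(-2.0 * D_r * lags) * (c2 + (1 - c2) * np.cos(omega * lags))


class HelicalCorrelationResults:
    """Fit results for the helical direction-correlation model.

    Attributes: ``D_r`` (1/s), ``omega`` (rad/s), ``theta`` (rad),
    ``tau_r = 1/(2 D_r)`` (s, inf when D_r = 0), ``rms`` residual
    (weighted), ``n_lags``.
    """

    def __init__(self, model, D_r, omega, theta, rms):
        self.model = model
        self.D_r = float(D_r)
        self.omega = float(omega)
        self.theta = float(theta)
        self.rms = float(rms)
        self.n_lags = model.curve.lags.size

    @property
    def tau_r(self) -> float:
        return rotational_relaxation(self.D_r) if self.D_r > 0 else np.inf

    def predict(self, lags=None) -> np.ndarray:
        lags = self.model.curve.lags if lags is None else np.asarray(lags)
        return _helical_model(lags, self.D_r, self.omega, self.theta)

    def summary(self) -> str:
        lines = [
            "Helical direction-correlation fit",
            "  C(tau) = exp(-2 D_r tau) [cos^2(theta) + sin^2(theta) cos(omega tau)]",
            f"  n lags          : {self.n_lags}",
            f"  D_r   [1/s]     : {self.D_r:.4g}",
            f"  omega [rad/s]   : {self.omega:.4g}",
            f"  theta [rad]     : {self.theta:.4g}",
            f"  tau_r [s]       : {self.tau_r:.4g}",
            f"  residual RMS    : {self.rms:.3g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - thin plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.lags, c.values, ".", label="measured")
        grid = np.linspace(c.lags[0], c.lags[-1], 400)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.set_xlabel(r"lag $\tau$ (s)")
        ax.set_ylabel(r"$C(\tau)$")
        ax.legend()
        return ax


class HelicalCorrelationModel:
    """Least-squares model for C(tau) with multi-start over omega.

    Parameters
    ----------
    curve : measured :class:`CorrelationCurve`.
    weighted : weight residuals by sqrt(per-lag pair counts) (default).
    n_starts : number of omega starting points, log-spaced between one
        cycle per curve span and the Nyquist angular frequency of the lag
        grid -- the oscillation frequency is unknown a priori and the
        objective has local minima in omega.
    """

    def __init__(self, curve: CorrelationCurve, weighted: bool = True, n_starts: int = 8):
        if curve.lags.size < 10:
            raise ParameterError("need >= 10 lags to fit the helical model")
        self.curve = curve
        self.weighted = weighted
        self.n_starts = n_starts
        self._w = np.sqrt(curve.counts) if weighted else np.ones_like(curve.values)
        self._w = self._w / self._w.max()

    def _residuals(self, p):
        D_r, omega, theta = p
        return self._w * (
            _helical_model(self.curve.lags, D_r, omega, theta) - self.curve.values
        )

    def fit(self, helical: bool = True) -> HelicalCorrelationResults:
        """Fit the model; ``helical=False`` forces theta = 0 (pure Brownian)."""
        lags, vals = self.curve.lags, self.curve.values
        span = lags[-1] - lags[0] if lags[-1] > lags[0] else 1.0
        dt = np.min(np.diff(np.unique(lags))) if lags.size > 1 else 1.0
        # crude initial decay rate from the last positive value
        pos = vals > 0.05
        if pos.any() and lags[pos][-1] > 0:
            D0 = max(1e-4, -np.log(max(vals[pos][-1], 1e-3)) / (2 * lags[pos][-1]))
        else:
            D0 = 0.1

        if not helical:
            def res_b(p):
                return self._w * (np.exp(-2.0 * p[0] * lags) - vals)

            sol = least_squares(res_b, [D0], bounds=([0.0], [np.inf]))
            rms = np.sqrt(np.mean(sol.fun**2))
            return HelicalCorrelationResults(self, sol.x[0], 0.0, 0.0, rms)

        omega_lo = 2.0 * np.pi / span
        omega_hi = np.pi / dt
        starts = np.geomspace(omega_lo, min(omega_hi, 1e3), self.n_starts)
        best = None
        failures = []
        for w0 in starts:
            try:
                sol = least_squares(
                    self._residuals,
                    [D0, w0, 0.3],
                    bounds=([0.0, 0.0, 0.0], [np.inf, omega_hi, np.pi / 2]),
                )
            except Exception as exc:  # pragma: no cover - scipy failure path
                failures.append(str(exc))
                continue
            if not sol.success:
                failures.append(sol.message)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise FitError(
                "helical correlation fit failed for all starts",
                diagnostics={"messages": failures, "starts": starts.tolist()},
            )
        rms = np.sqrt(np.mean(best.fun**2))
        return HelicalCorrelationResults(self, *best.x, rms)


def fit_helical_correlation(
    curve: CorrelationCurve, weighted: bool = True
) -> HelicalCorrelationResults:
    """Convenience wrapper: build the model and fit it."""
    return HelicalCorrelationModel(curve, weighted=weighted).fit()


def rotational_relaxation(D_r: float) -> float:
    """Directional memory time tau_r = 1/(2 D_r) (s)."""
    if D_r <= 0:
        raise ParameterError("D_r must be positive")
    return 1.0 / (2.0 * D_r)


# ---------------------------------------------------------------------------
# population summary


@dataclass(frozen=True)
class LogNormalFit:
    """Log-normal MLE for a population of positive values (e.g. D_r)."""

    location: float  #: mean of log values (mu)
    shape: float  #: std of log values (sigma)
    n: int

    @property
    def mode(self) -> float:
        return float(np.exp(self.location - self.shape**2))

    @property
    def median(self) -> float:
        return float(np.exp(self.location))


def fit_lognormal(values) -> LogNormalFit:
    """Maximum-likelihood log-normal fit; the modal value is
    exp(location - shape^2)."""
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ParameterError("need at least 10 values")
    if np.any(v <= 0):
        raise ParameterError("log-normal fit requires positive values")
    logs = np.log(v)
    return LogNormalFit(
        location=float(np.mean(logs)), shape=float(np.std(logs)), n=v.size
    )
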