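"""Synthetic 3D swimmer trajectories with the statistics of haloarchaea.

The generator emulates the features of holographically tracked halophilic
archaea that the downstream analysis relies on:

* slow helical "run and reverse" swimming at ~2 um/s;
* exponentially distributed run durations (mean ~12-15 s), produced by a
  Poisson reversal process that flips the swimming axis by 180 degrees;
* rotational diffusion of the swimming axis at D_r ~ 0.08 1/s and a small
  translational diffusion of the cell body;
* small-amplitude helical motion: the instantaneous tangent makes a fixed
  pitch angle ``theta`` with a slowly diffusing helix axis and precesses
  about it at angular frequency ``omega``.  The helix radius implied by
  these parameters is ``r = v0 sin(theta) / omega``;
* 50 Hz sampling and i.i.d. Gaussian localisation noise (0.4 um lateral,
  0.5 um axial), added after the kinematics.

With no rotational diffusion and no noise the track is an exact circular
helix whose direction correlation is ``cos^2 theta + sin^2 theta
cos(omega tau)``.  Reversals flip the helix axis exactly while preserving
helix handedness.  Localisation noise inflates finite-difference speeds
enormously at 50 Hz (sqrt(2)*0.4 um / 0.02 s >> v0), so speed statistics
are only meaningful on smoothed tracks -- see
:func:`halotaxis.processing.smooth_and_filter`.

Optionally, the reversal rate can be biased chemotactically through the
same linear-response model used by the Brownian-dynamics simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError
from .response import ChemotacticMemory, ResponseParams, _modulate
from .tracks import Track, TrackSet

__all__ = [
    "GeneratorConfig",
    "generate_run_durations",
    "generate_swimmer_track",
    "generate_population",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic swimmer.

    Defaults are the conditions measured for the Boulby Mine *Haloferax*
    isolate: v0 = 1.9 um/s, tau_run = 14.7 s, D_r = 0.081 1/s, 50 Hz
    sampling, localisation noise 0.4 um lateral / 0.5 um axial.  The helix
    parameters (theta = 0.3 rad, omega = 3 rad/s) are representative
    modal values; D_t = 0.15 um^2/s comes from the Perrin model of the
    effective cell ellipsoid.
    """

    swim_speed: float = 1.9  # v0, um/s
    mean_run_duration: float = 14.7  # tau_run, s
    rotational_diffusivity: float = 0.081  # D_r, 1/s
    translational_diffusivity: float = 0.15  # D_t, um^2/s
    helix_pitch_angle: float = 0.3  # theta, rad
    helix_angular_frequency: float = 3.0  # omega, rad/s
    frame_rate: float = 50.0  # Hz
    noise_lateral: float = 0.4  # sigma_xy, um
    noise_axial: float = 0.5  # sigma_z, um
    duration: float = 60.0  # s
    seed: int = 0

    def __post_init__(self):
        if self.swim_speed < 0:
            raise ParameterError("swim_speed must be >= 0")
        if self.mean_run_duration <= 0:
            raise ParameterError("mean_run_duration must be > 0")
        if self.rotational_diffusivity < 0 or self.translational_diffusivity < 0:
            raise ParameterError("diffusivities must be >= 0")
        if not 0 <= self.helix_pitch_angle < np.pi / 2:
            raise ParameterError("helix_pitch_angle must be in [0, pi/2)")
        if self.helix_angular_frequency < 0:
            raise ParameterError("helix_angular_frequency must be >= 0")
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be > 0")
        if self.noise_lateral < 0 or self.noise_axial < 0:
            raise ParameterError("noise levels must be >= 0")

    @property
    def helix_radius(self) -> float:
        """Implied helix radius r = v0 sin(theta)/omega (um)."""
        if self.helix_angular_frequency == 0:
            return 0.0
        return (
            self.swim_speed
            * np.sin(self.helix_pitch_angle)
            / self.helix_angular_frequency
        )


def generate_run_durations(mean_duration: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. exponential run durations with the given mean (s)."""
    if mean_duration <= 0:
        raise ParameterError("mean_duration must be positive")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.exponential(mean_duration, size=int(n))


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(v: np.ndarray) -> np.ndarray:
    helper = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e = np.cross(v, helper)
    return e / np.linalg.norm(e)


def generate_swimmer_track(
    config: GeneratorConfig,
    *,
    chemotaxis: ResponseParams | None = None,
    gradient=(1.0, 0.0, 0.0),
    reversal_times=None,
    rng: np.random.Generator | None = None,
    track_id="synthetic-0",
) -> Track:
    """Generate one helical run-reverse trajectory.

    Parameters
    ----------
    config : kinematic parameters; ``config.seed`` is used unless an
        explicit ``rng`` is passed (as :func:`generate_population` does).
    chemotaxis : optional response parameters; when given, the reversal
        rate is modulated by the concentration history in the linear
        gradient ``gradient`` (concentration = position . gradient).
        ``sensitivity`` must be set on the params.
    reversal_times : optional explicit reversal times (s); overrides the
        Poisson process (useful as ground truth in tests).
    track_id : identifier stored on the returned :class:`Track`.

    The returned track's ``meta`` carries the ground-truth reversal times
    (``"reversal_times"``) and the noise-free positions
    (``"true_positions"``).
    """
    dt = 1.0 / config.frame_rate
    n_frames = int(round(config.duration * config.frame_rate)) + 1
    if n_frames < 2:
        raise ParameterError("duration must cover at least 2 frames")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    theta, omega = config.helix_pitch_angle, config.helix_angular_frequency
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    v0 = config.swim_speed
    sig_rot = np.sqrt(2.0 * config.rotational_diffusivity * dt)
    sig_trans = np.sqrt(2.0 * config.translational_diffusivity * dt)
    base_rate = 1.0 / config.mean_run_duration

    # body frame: helix axis h and transported perpendicular pair (e1, e2)
    h = _random_unit(rng)
    e1 = _perpendicular(h)
    e2 = np.cross(h, e1)
    phi = rng.uniform(0.0, 2.0 * np.pi)

    grad = np.asarray(gradient, dtype=float)
    mem = None
    if chemotaxis is not None and chemotaxis.mode != "none":
        mem = ChemotacticMemory(chemotaxis, dt, c0=0.0)

    scheduled = None
    if reversal_times is not None:
        scheduled = np.sort(np.asarray(reversal_times, dtype=float))

    # pre-draw the per-frame randomness in bulk
    rot_kicks = rng.normal(scale=sig_rot, size=(n_frames, 3)) if sig_rot > 0 else None
    trans_kicks = (
        rng.normal(scale=sig_trans, size=(n_frames, 3)) if sig_trans > 0 else None
    )
    rev_uniforms = rng.uniform(size=n_frames)

    pos = np.zeros((n_frames, 3))
    r = np.zeros(3)
    times = np.arange(n_frames) * dt
    reversals = []
    next_scheduled = 0
    for i in range(n_frames):
        pos[i] = r
        if i == n_frames - 1:
            break
        t = times[i]
        # reversal?
        if scheduled is not None:
            flip = (
                next_scheduled < scheduled.size
                and t <= scheduled[next_scheduled] < t + dt
            )
            if flip:
                next_scheduled += 1
        else:
            rate = base_rate
            if mem is not None:
                integral = mem.update(float(r @ grad))
                rate, _ = _modulate(base_rate, integral, chemotaxis.mode)
                rate = float(rate)
            flip = rev_uniforms[i] < rate * dt
        if flip:
            h = -h
            e2 = -e2  # keep the frame right-handed and the helix handedness
            reversals.append(t)
        # rotational diffusion of the axis, with parallel transport of e1
        if rot_kicks is not None:
            h_new = h + rot_kicks[i]
            h_new /= np.linalg.norm(h_new)
            e1 = e1 - (e1 @ h_new) * h_new
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(h_new, e1)
            h = h_new
        tangent = cos_t * h + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
        phi += omega * dt
        r = r + v0 * dt * tangent
        if trans_kicks is not None:
            r = r + trans_kicks[i]

    true_pos = pos.copy()
    if config.noise_lateral > 0 or config.noise_axial > 0:
        noise = np.empty_like(pos)
        noise[:, :2] = rng.normal(scale=config.noise_lateral, size=(n_frames, 2))
        noise[:, 2] = rng.normal(scale=config.noise_axial, size=n_frames)
        pos = pos + noise

    return Track(
        track_id,
        times,
        pos,
        meta={
            "reversal_times": np.asarray(
                reversals if scheduled is None else scheduled
            ),
            "true_positions": true_pos,
            "config": config,
        },
    )


def generate_population(
    config: GeneratorConfig,
    n_cells: int,
    seed: int | None = None,
    *,
    chemotaxis: ResponseParams | None = None,
    gradient=(1.0, 0.0, 0.0),
) -> TrackSet:
    """Generate ``n_cells`` independent tracks.

    Per-cell generators are spawned deterministically from the master seed
    (``seed`` argument, falling back to ``config.seed``), so the same
    (config, seed) pair always produces bit-identical output.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    master = config.seed if seed is None else seed
    children = np.random.SeedSequence(master).spawn(int(n_cells))
    tracks = [
        generate_swimmer_track(
            config,
            chemotaxis=chemotaxis,
            gradient=gradient,
            rng=np.random.default_rng(children[i]),
            track_id=f"synthetic-{i}",
        )
        for i in range(n_cells)
    ]
    return TrackSet(tracks)
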