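"""Track conditioning, motility classification, reversal segmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from halotaxis import (
    GeneratorConfig,
    Track,
    classify_motile,
    fit_run_durations,
    fit_speed_distribution,
    generate_population,
    generate_swimmer_track,
    process_tracks,
    reversal_statistic,
    segment_runs,
    smooth_and_filter,
)
from halotaxis.errors import (
    DegenerateTrackError,
    ParameterError,
    TrackFormatError,
)


def _straight_track(n=200, v=2.0, dt=0.02):
    t = np.arange(n) * dt
    pos = np.outer(t, [v, 0.0, 0.0])
    return Track("straight", t, pos)


class TestSmoothing:
    def test_short_track_rejected(self):
        t = np.arange(int(2.9 * 50)) * 0.02  # 2.9 s < 3 s minimum
        tr = Track("short", t, np.outer(t, [2.0, 0, 0]))
        assert smooth_and_filter(tr) == []

    def test_straight_line_passes_through(self):
        """A noise-free straight line is in the spline's null space."""
        tr = _straight_track(400)
        (out,) = smooth_and_filter(tr)
        np.testing.assert_allclose(out.positions, tr.positions, atol=1e-6)

    def test_smoothed_track_close_to_ground_truth(self):
        """Smoothing a noisy synthetic track lands within the localisation
        noise of the noise-free path."""
        cfg = GeneratorConfig(duration=60.0, seed=21)
        tr = generate_swimmer_track(cfg)
        (out,) = smooth_and_filter(tr)
        rms = np.sqrt(
            np.mean((out.positions - tr.meta["true_positions"]) ** 2)
        )
        assert rms < 0.4

    def test_gap_interpolation_and_split(self):
        t = np.arange(500) * 0.02
        pos = np.outer(t, [2.0, 0, 0])
        keep = np.ones(500, bool)
        keep[100:103] = False  # 3-frame gap: interpolated
        tr = Track("gappy", t[keep], pos[keep])
        (out,) = smooth_and_filter(tr, max_gap=5)
        assert out.n_frames == 500
        assert out.is_uniform

        keep[300:320] = False  # 20-frame gap: split
        tr2 = Track("split", t[keep], pos[keep])
        pieces = smooth_and_filter(tr2, max_gap=5, min_duration=1.0)
        assert len(pieces) == 2

    def test_non_monotone_rejected(self):
        with pytest.raises(TrackFormatError):
            Track("bad", [0.0, 0.02, 0.01], np.zeros((3, 3)))


class TestClassification:
    def test_swimmer_is_swimming(self):
        cfg = GeneratorConfig(duration=30.0, seed=8)
        tr = generate_swimmer_track(cfg)
        (sm,) = smooth_and_filter(tr)
        assert classify_motile(sm) == "swimming"

    def test_diffuser_is_diffusing(self):
        cfg = GeneratorConfig(
            swim_speed=0.0, translational_diffusivity=0.5, duration=30.0, seed=9
        )
        tr = generate_swimmer_track(cfg)
        (sm,) = smooth_and_filter(tr)
        assert classify_motile(sm) == "diffusing"

    def test_straight_line_is_ballistic(self):
        assert classify_motile(_straight_track(400)) == "swimming"

    def test_too_short_indeterminate(self):
        assert classify_motile(_straight_track(60)) == "indeterminate"


class TestReversalStatistic:
    def test_constant_speed_straight_run_is_zero(self):
        series = reversal_statistic(_straight_track())
        np.testing.assert_allclose(series.xi, 0.0, atol=1e-9)

    def test_stationary_frame_value(self):
        """A frame with v_t -> 0 and collinear tangents at 50 Hz gives
        Xi -> 1/dt = 50 1/s (|a.a'| = 1, bracket -> 1)."""
        t = np.arange(6) * 0.02
        # one near-zero step amid uniform motion, all collinear
        x = np.array([0.0, 1.0, 2.0, 2.0 + 1e-12, 3.0, 4.0])
        tr = Track("pause", t, np.column_stack([x, np.zeros(6), np.zeros(6)]))
        series = reversal_statistic(tr)
        assert series.xi[2] == pytest.approx(50.0, rel=1e-6)

    def test_xi_bounded_by_inverse_dt(self):
        cfg = GeneratorConfig(duration=30.0, seed=10)
        tr = generate_swimmer_track(cfg)
        (sm,) = smooth_and_filter(tr)
        series = reversal_statistic(sm)
        assert np.nanmax(series.xi) <= 1 / sm.dt + 1e-9

    def test_invariant_under_rigid_motion(self):
        cfg = GeneratorConfig(duration=20.0, seed=11)
        tr = generate_swimmer_track(cfg)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = Track("moved", tr.times, tr.positions @ rot.T + [5.0, -3.0, 2.0])
        np.testing.assert_allclose(
            reversal_statistic(tr).xi, reversal_statistic(moved).xi, atol=1e-9
        )

    def test_degenerate_track_rejected(self):
        t = np.arange(5) * 0.02
        tr = Track("static", t, np.zeros((5, 3)))
        with pytest.raises(DegenerateTrackError):
            reversal_statistic(tr)

    def test_argmax_locates_programmed_reversal(self):
        """On a low-noise track the global argmax of Xi falls within a
        couple of frames of the programmed reversal; full localisation
        noise degrades this to ~0.25 s (see the statistical test below)."""
        cfg = GeneratorConfig(
            translational_diffusivity=0.0, noise_lateral=0.02,
            noise_axial=0.02, duration=60.0, seed=12,
        )
        tr = generate_swimmer_track(cfg, reversal_times=[30.0])
        (sm,) = smooth_and_filter(tr)
        series = reversal_statistic(sm)
        i = int(np.argmax(series.xi))
        t_ev = sm.times[i + 1]
        assert abs(t_ev - 30.0) <= 2 * sm.dt + 1e-9

    def test_argmax_location_with_full_noise(self):
        cfg = GeneratorConfig(duration=60.0, seed=13)
        tr = generate_swimmer_track(cfg, reversal_times=[30.0])
        (sm,) = smooth_and_filter(tr)
        series = reversal_statistic(sm)
        t_ev = sm.times[int(np.argmax(series.xi)) + 1]
        assert abs(t_ev - 30.0) < 0.5


class TestSegmentation:
    def test_no_events_single_censored_run(self):
        runs, series = segment_runs(_straight_track(400))
        assert len(runs) == 1
        assert runs[0].censored

    def test_recovers_programmed_reversals_low_noise(self):
        cfg = GeneratorConfig(
            translational_diffusivity=0.0, noise_lateral=0.02,
            noise_axial=0.02, duration=100.0, seed=14,
        )
        truth = [20.0, 45.0, 70.0]
        tr = generate_swimmer_track(cfg, reversal_times=truth)
        (sm,) = smooth_and_filter(tr)
        runs, series = segment_runs(sm)
        assert len(series.events) == 3
        np.testing.assert_allclose(series.event_times, truth, atol=0.1)
        interior = [r for r in runs if not r.censored]
        assert len(interior) == 2
        np.testing.assert_allclose(
            sorted(r.duration for r in interior), [25.0, 25.0], atol=0.2
        )

    def test_close_events_merged(self):
        """Two threshold crossings less than the minimum separation apart
        collapse into a single event."""
        cfg = GeneratorConfig(
            translational_diffusivity=0.0, noise_lateral=0.02,
            noise_axial=0.02, duration=60.0, seed=15,
        )
        tr = generate_swimmer_track(cfg, reversal_times=[30.0, 30.5])
        (sm,) = smooth_and_filter(tr)
        _, series = segment_runs(sm)
        assert len(series.events) <= 1 + 0  # merged (or one detected)

    def test_time_reversed_track_same_events(self):
        cfg = GeneratorConfig(
            translational_diffusivity=0.0, noise_lateral=0.02,
            noise_axial=0.02, duration=100.0, seed=16,
        )
        tr = generate_swimmer_track(cfg, reversal_times=[30.0, 60.0])
        (sm,) = smooth_and_filter(tr)
        _, fwd = segment_runs(sm)
        rev_tr = Track("rev", sm.times, sm.positions[::-1])
        _, bwd = segment_runs(rev_tr)
        t_end = sm.times[-1]
        fwd_t = np.sort(fwd.event_times)
        bwd_t = np.sort(t_end - bwd.event_times[::-1] - sm.dt * 0)
        assert len(fwd_t) == len(bwd_t)
        np.testing.assert_allclose(fwd_t, np.sort(bwd_t), atol=0.1)


class TestFits:
    def test_exponential_mle_is_sample_mean(self):
        fit = fit_run_durations([5.0, 5.0, 5.0])
        assert fit.mean == 5.0
        assert fit.stderr == pytest.approx(5.0 / np.sqrt(3))

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=50))
    def test_mle_equals_mean_property(self, durs):
        assert fit_run_durations(durs).mean == pytest.approx(np.mean(durs))

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            fit_run_durations([])

    def test_speed_fit_recovers_gaussian(self):
        rng = np.random.default_rng(0)
        sample = rng.normal(2.2, 0.8, size=10**5)
        fit = fit_speed_distribution(sample)
        assert fit.mean == pytest.approx(2.2, rel=0.01)
        assert fit.sd == pytest.approx(0.8, rel=0.01)

    def test_degenerate_speeds_rejected(self):
        with pytest.raises(DegenerateTrackError):
            fit_speed_distribution(np.full(100, 2.0))
        with pytest.raises(ParameterError):
            fit_speed_distribution([1.0, 2.0])  # too few


class TestEndToEnd:
    def test_tau_run_recovery_noisy_conditions(self):
        """Generate -> smooth -> segment -> fit recovers the generating
        mean run duration within 3 standard errors at study conditions."""
        cfg = GeneratorConfig(duration=120.0, seed=0)
        pop = generate_population(cfg, 25, seed=77)
        sm, _ = process_tracks(pop)
        durs = []
        for tr in sm:
            runs, _ = segment_runs(tr)
            durs += [r.duration for r in runs if not r.censored]
        fit = fit_run_durations(durs)
        assert abs(fit.mean - 14.7) < 3 * fit.stderr
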