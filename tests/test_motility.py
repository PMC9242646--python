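"""Kymograph construction, event tracing, classification and summaries."""

import numpy as np
import pytest

from adaptoquant.core import MicrotubulePath, MovieStack
from adaptoquant.motility import (
    ClassifyParams,
    DetectionParams,
    MotilityEvent,
    build_kymograph,
    classify_event,
    event_metrics,
    filter_events,
    summarize_fov,
    trace_events,
)
from adaptoquant.synthetic import SimulationConfig, simulate_tirf_movie, straight_paths

from conftest import make_moving_spot_movie


def _event(positions, start=0, intensity=100.0, path_id="p"):
    positions = np.asarray(positions, dtype=float)
    return MotilityEvent(
        path_id=path_id,
        start_frame=start,
        end_frame=start + len(positions) - 1,
        positions=positions,
        mean_spot_intensity=intensity,
    )


# ---------------------------------------------------------------------------
# build_kymograph
# ---------------------------------------------------------------------------


class TestBuildKymograph:
    def test_uniform_movie_gives_uniform_kymograph(self):
        frames = np.full((5, 32, 64), 7.0)
        movie = MovieStack(frames, pixel_size=0.16, frame_interval=0.3)
        path = MicrotubulePath("p", np.array([[5.0, 16.0], [58.0, 16.0]]))
        kymo = build_kymograph(movie, path, width=5)
        assert kymo.n_frames == 5
        assert kymo.n_bins == int(np.ceil(path.length_px))
        np.testing.assert_allclose(kymo.matrix, 7.0)

    def test_static_emitter_gives_single_bright_constant_column(self, single_spot_movie):
        movie, path = single_spot_movie
        kymo = build_kymograph(movie, path, width=5)
        expected_bin = int(3.2 / 0.16)  # floor(arclength / bin size)
        cols = kymo.matrix.argmax(axis=1)
        assert np.all(cols == expected_bin)
        # constant over rows
        assert np.ptp(kymo.matrix, axis=0).max() < 1e-10

    def test_moving_emitter_slope_recovers_speed(self):
        movie, path = make_moving_spot_movie(speed_um_s=0.5)
        kymo = build_kymograph(movie, path, width=5)
        rows = np.arange(kymo.n_frames)
        pos_um = kymo.matrix.argmax(axis=1) * kymo.bin_size
        slope = np.polyfit(rows * movie.frame_interval, pos_um, 1)[0]
        # one bin per frame of slack
        assert abs(slope - 0.5) <= kymo.bin_size / movie.frame_interval

    def test_even_width_rejected(self, single_spot_movie):
        movie, path = single_spot_movie
        with pytest.raises(ValueError, match="odd"):
            build_kymograph(movie, path, width=4)

    def test_path_outside_image_rejected(self):
        frames = np.zeros((3, 16, 16))
        movie = MovieStack(frames, pixel_size=0.16, frame_interval=0.3)
        path = MicrotubulePath("p", np.array([[2.0, 8.0], [40.0, 8.0]]))
        with pytest.raises(ValueError, match="exits"):
            build_kymograph(movie, path)


# ---------------------------------------------------------------------------
# trace_events
# ---------------------------------------------------------------------------


class TestTraceEvents:
    def test_blank_kymograph_yields_no_events(self):
        frames = np.random.default_rng(0).normal(100, 5, (20, 32, 64))
        movie = MovieStack(frames, pixel_size=0.16, frame_interval=0.3)
        path = MicrotubulePath("p", np.array([[5.0, 16.0], [58.0, 16.0]]))
        kymo = build_kymograph(movie, path)
        assert trace_events(kymo) == []

    def test_single_processive_particle_traced_within_one_bin(self):
        movie, path = make_moving_spot_movie(speed_um_s=0.5, n_frames=30)
        kymo = build_kymograph(movie, path)
        events = trace_events(kymo)
        assert len(events) == 1
        ev = events[0]
        t = np.arange(ev.start_frame, ev.end_frame + 1)
        truth = 1.0 + 0.5 * t * movie.frame_interval
        assert np.all(np.abs(ev.positions - truth) <= kymo.bin_size)

    def test_censoring_flagged_at_movie_edges(self):
        movie, path = make_moving_spot_movie(n_frames=10)
        kymo = build_kymograph(movie, path)
        (ev,) = trace_events(kymo)
        assert ev.censored  # spot present in frame 0 and the last frame

    def test_two_separated_concurrent_particles_not_merged(self):
        h, w = 32, 160
        n_frames = 30
        pixel_size, dt = 0.16, 0.3
        path = MicrotubulePath("p", np.array([[4.0, 16.0], [156.0, 16.0]]))
        yy, xx = np.mgrid[0:h, 0:w]
        frames = np.zeros((n_frames, h, w))
        for t in range(n_frames):
            for start_um in (2.0, 12.0):  # 10 µm apart, moving together
                x = 4.0 + (start_um + 0.4 * t * dt) / pixel_size
                frames[t] += 100 * np.exp(-((xx - x) ** 2 + (yy - 16) ** 2) / (2 * 0.8**2))
        movie = MovieStack(frames, pixel_size=pixel_size, frame_interval=dt)
        events = trace_events(build_kymograph(movie, path))
        assert len(events) == 2
        starts = sorted(ev.positions[0] for ev in events)
        assert abs(starts[1] - starts[0] - 10.0) < 0.5


# ---------------------------------------------------------------------------
# classify_event
# ---------------------------------------------------------------------------


class TestClassifyEvent:
    def test_monotone_long_trace_is_processive(self):
        ev = _event(np.linspace(0, 3.0, 20))
        assert classify_event(ev) == "processive"

    def test_constant_position_is_immotile(self):
        ev = _event(np.full(15, 2.0))
        assert classify_event(ev) == "immotile"

    def test_alternating_large_steps_are_diffusive(self):
        # net zero, excursion above the immobile radius, no directionality
        pos = np.array([0.0, 0.5, 0.0, 0.5, 0.0, 0.5, 0.0])
        assert classify_event(_event(pos)) == "diffusive"

    def test_single_frame_event_rejected(self):
        ev = _event([1.0])
        with pytest.raises(ValueError):
            classify_event(ev)


# ---------------------------------------------------------------------------
# filter_events
# ---------------------------------------------------------------------------


class TestFilterEvents:
    def test_four_frame_event_rejected_five_frame_kept(self):
        e4 = _event(np.linspace(0, 1, 4))
        e5 = _event(np.linspace(0, 1, 5))
        kept, rejected = filter_events([e4, e5], min_frames=4)
        assert kept == [e5]
        assert rejected == [(e4, "too_short")]

    def test_equal_intensities_give_no_aggregate_rejections(self):
        events = [_event(np.linspace(0, 1, 10), intensity=50.0) for _ in range(6)]
        kept, rejected = filter_events(events, min_frames=4, aggregate_multiplier=3.0)
        assert len(kept) == 6 and rejected == []

    def test_bright_event_rejected_as_aggregate(self):
        events = [_event(np.linspace(0, 1, 10), intensity=50.0) for _ in range(5)]
        bright = _event(np.linspace(0, 1, 10), intensity=500.0)  # 10x median
        kept, rejected = filter_events(events + [bright], aggregate_multiplier=3.0)
        assert (bright, "aggregate") in rejected
        assert bright.aggregate_flag
        assert len(kept) == 5

    def test_empty_input_returns_two_empty_lists(self):
        assert filter_events([]) == ([], [])

    def test_partition_conservation(self):
        rng = np.random.default_rng(42)
        events = [
            _event(rng.normal(0, 1, rng.integers(2, 12)), intensity=float(rng.uniform(10, 500)))
            for _ in range(30)
        ]
        kept, rejected = filter_events(events)
        assert len(kept) + len(rejected) == len(events)
        assert {id(e) for e in kept} | {id(e) for e, _ in rejected} == {id(e) for e in events}


# ---------------------------------------------------------------------------
# event_metrics
# ---------------------------------------------------------------------------


class TestEventMetrics:
    @pytest.mark.parametrize("a,b", [(2.0, 6.0), (6.0, 2.0)])
    def test_velocity_magnitude_convention(self, a, b):
        ev = _event(np.linspace(a, b, 21))  # 20 intervals x 0.5 s = 10 s
        ev.classification = "processive"
        m = event_metrics(ev, frame_interval=0.5)
        assert m.duration == pytest.approx(10.0)
        assert m.run_length == pytest.approx(4.0)
        assert m.velocity == pytest.approx(0.4)

    def test_non_processive_event_rejected(self):
        ev = _event(np.full(10, 1.0))
        ev.classification = "immotile"
        with pytest.raises(ValueError):
            event_metrics(ev, 0.3)

    def test_metrics_invariant_under_path_reversal(self):
        """Reversing vertex order flips arclength but not speed/run length."""
        movie, path = make_moving_spot_movie(speed_um_s=0.5, n_frames=30)
        out = {}
        for tag, p in (("fwd", path), ("rev", path.reversed())):
            (ev,) = trace_events(build_kymograph(movie, p))
            ev.classification = "processive"
            out[tag] = event_metrics(ev, movie.frame_interval)
        assert out["fwd"].velocity == pytest.approx(out["rev"].velocity, rel=1e-6)
        assert out["fwd"].run_length == pytest.approx(out["rev"].run_length, rel=1e-6)


# ---------------------------------------------------------------------------
# summarize_fov
# ---------------------------------------------------------------------------


class TestSummarizeFov:
    def _movie(self, n_frames=600, dt=0.3):
        return MovieStack(np.zeros((n_frames, 8, 8)), pixel_size=0.16, frame_interval=dt)

    def test_landing_rate_arithmetic(self):
        # 30 events, 150 µm of microtubule, 3 min, 1 pM
        movie = self._movie(n_frames=600, dt=0.3)  # 180 s
        path = MicrotubulePath("p", np.array([[0.0, 0.0], [150.0 / 0.16, 0.0]]))
        events = []
        for _ in range(30):
            e = _event(np.linspace(0, 1, 10))
            e.classification = "processive"
            events.append(e)
        s = summarize_fov(events, [path], movie, concentration=1.0)
        assert s.landing_rate == pytest.approx(30 / (150 * 3 * 1), rel=1e-6)
        assert s.landing_rate == pytest.approx(0.0667, abs=2e-4)

    def test_percent_processive(self):
        movie = self._movie()
        path = MicrotubulePath("p", np.array([[0.0, 0.0], [100.0, 0.0]]))
        events = []
        for cls, n in (("processive", 10), ("diffusive", 5), ("immotile", 5)):
            for _ in range(n):
                e = _event(np.linspace(0, 1, 5))
                e.classification = cls
                events.append(e)
        s = summarize_fov(events, [path], movie)
        assert s.percent_processive == pytest.approx(50.0)

    def test_landing_rate_recovered_from_simulation(self):
        """Pipeline landing rate matches the configured Poisson rate."""
        cfg = SimulationConfig(
            seed=11, frame_interval=0.5, movie_duration=180, field_size=(192, 256),
            landing_rate_true=0.08, state_fractions=(1.0, 0, 0),
            speed_distribution=("normal", 0.5, 0.05), run_length_mean=6.0,
        )
        paths = straight_paths(6, cfg.field_size)
        movie, truth = simulate_tirf_movie(cfg, paths)
        all_events = []
        for p in paths:
            all_events.extend(trace_events(build_kymograph(movie, p)))
        kept, _ = filter_events(all_events)
        for e in kept:
            e.classification = classify_event(e)
        s = summarize_fov(kept, paths, movie)
        n_expected = 0.08 * s.total_mt_length * s.movie_duration
        se = np.sqrt(n_expected) / (s.total_mt_length * s.movie_duration)
        assert abs(s.landing_rate - 0.08) <= 3 * se
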