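import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from logprf.stimulus import (
    DEFAULT_DIRECTIONS,
    FieldGrid,
    RunSpec,
    StimulusMovie,
    SweepSpec,
    WarpSpec,
    assemble_run,
    default_run,
    inverse_log_map,
    log_map,
    make_bar_frame,
    make_sweep,
    preprocess_movie,
    scale_constant,
    warp_movie,
)


class TestScaleConstant:
    def test_value_k5_rmax8(self):
        # closed form 8 / ln(41), evaluated independently
        assert scale_constant(5.0, 8.0) == pytest.approx(8.0 / np.log(41.0), abs=1e-12)
        assert scale_constant(5.0, 8.0) == pytest.approx(2.1542600645, abs=1e-9)

    def test_fixed_point(self, warp5):
        assert log_map(8.0, warp5) == pytest.approx(8.0, abs=1e-9)

    def test_k1_rmax_e_minus_1(self):
        rmax = np.e - 1.0
        assert scale_constant(1.0, rmax) == pytest.approx(rmax, abs=1e-12)

    @pytest.mark.parametrize("k,rmax", [(0.0, 8.0), (-1.0, 8.0), (5.0, 0.0), (5.0, -2.0)])
    def test_domain_errors(self, k, rmax):
        with pytest.raises(ValueError):
            scale_constant(k, rmax)


class TestLogMap:
    def test_zero(self, warp5):
        assert log_map(0.0, warp5) == 0.0

    def test_negative_raises(self, warp5):
        with pytest.raises(ValueError):
            log_map(-0.1, warp5)

    def test_identity_limit(self):
        spec = WarpSpec(k=1e-9, rmax=8.0)
        assert log_map(4.0, spec) == pytest.approx(4.0, abs=1e-6)

    @given(st.floats(min_value=0.0, max_value=8.0), st.floats(min_value=0.0, max_value=8.0))
    def test_monotone(self, a, b):
        spec = WarpSpec(k=5.0, rmax=8.0)
        lo, hi = sorted((a, b))
        assert log_map(lo, spec) <= log_map(hi, spec)

    @given(st.floats(min_value=0.0, max_value=8.0))
    @settings(max_examples=50)
    def test_roundtrip(self, r):
        spec = WarpSpec(k=5.0, rmax=8.0)
        assert inverse_log_map(log_map(r, spec), spec) == pytest.approx(r, abs=1e-9)


class TestInverseLogMap:
    def test_zero(self, warp5):
        assert inverse_log_map(0.0, warp5) == 0.0

    def test_fixed_point(self, warp5):
        assert inverse_log_map(8.0, warp5) == pytest.approx(8.0, abs=1e-9)

    def test_roundtrip_33(self, warp5):
        assert inverse_log_map(log_map(3.3, warp5), warp5) == pytest.approx(3.3, abs=1e-9)

    def test_negative_raises(self, warp5):
        with pytest.raises(ValueError):
            inverse_log_map(-1.0, warp5)


class TestBarFrame:
    def test_centered_strip(self, grid64):
        sweep = SweepSpec(direction=0.0)
        frame = make_bar_frame(0.0, sweep, grid64, rmax=8.0)
        x, y = grid64.coords()
        inside = (np.abs(x) <= 1.0) & (np.hypot(x, y) <= 8.0)
        assert np.array_equal(frame.astype(bool), inside)

    def test_fully_outside_is_blank(self, grid64):
        sweep = SweepSpec(direction=0.0)
        frame = make_bar_frame(8.0 + 1.0, sweep, grid64, rmax=8.0)
        assert frame.sum() == 0

    def test_area_matches_strip_disc_intersection(self):
        # independent oracle: quadrature of the strip-within-disc area
        grid = FieldGrid.square(540, fov_deg=16.0)
        sweep = SweepSpec(direction=0.0, bar_width=2.0)
        frame = make_bar_frame(0.0, sweep, grid, rmax=8.0)
        analytic, _ = integrate.quad(lambda x: 2 * np.sqrt(64.0 - x**2), -1.0, 1.0)
        measured = frame.sum() * grid.deg_per_px**2
        assert measured == pytest.approx(analytic, rel=0.02)

    def test_thin_bar_warns(self):
        grid = FieldGrid.square(16, fov_deg=16.0)  # 1 deg/px
        sweep = SweepSpec(direction=0.0, bar_width=0.5)
        with pytest.warns(UserWarning):
            make_bar_frame(0.0, sweep, grid, rmax=8.0)


class TestSweep:
    def test_frame_count(self, grid64):
        sweep = SweepSpec(direction=90.0)
        run = default_run(frame_rate_hz=10.0)
        frames = make_sweep(sweep, run, grid64, rmax=8.0)
        assert frames.shape == (64, 64, 450)

    def test_traverse_covers_aperture_plus_bar(self):
        sweep = SweepSpec(direction=0.0, bar_width=2.0, speed=0.4, duration=45.0)
        assert sweep.traverse_length() == pytest.approx(18.0)  # 16 + 2

    def test_first_frame_blank_or_edge(self, grid64):
        sweep = SweepSpec(direction=0.0)
        run = default_run(frame_rate_hz=1.0)
        frames = make_sweep(sweep, run, grid64, rmax=8.0)
        # bar center starts at -(rmax + width/2): nothing inside the aperture
        assert frames[:, :, 0].sum() == 0

    def test_bar_advances_monotonically(self, grid64):
        sweep = SweepSpec(direction=0.0)
        run = default_run(frame_rate_hz=1.0)
        frames = make_sweep(sweep, run, grid64, rmax=8.0)
        x, _ = grid64.coords()
        centers = [
            x[frames[:, :, t] > 0].mean()
            for t in range(10, 35)
        ]
        assert np.all(np.diff(centers) > 0)


class TestAssembleRun:
    def test_total_duration_366(self):
        run = default_run(frame_rate_hz=1.0)
        assert run.total_duration_s == pytest.approx(366.0)

    def test_frame_count_at_1fps(self, grid64):
        movie = assemble_run(default_run(frame_rate_hz=1.0), grid64, rmax=8.0)
        assert movie.n_frames == 366
        assert movie.duration_s == pytest.approx(366.0)

    @pytest.mark.parametrize("fps", [1.0, 2.0, 2.5])
    def test_frame_count_scales_with_rate(self, grid64, fps):
        movie = assemble_run(default_run(frame_rate_hz=fps), grid64, rmax=8.0)
        assert movie.n_frames == round(366 * fps)

    def test_determinism(self, grid64):
        a = assemble_run(default_run(rng_seed=42, frame_rate_hz=1.0), grid64, 8.0)
        b = assemble_run(default_run(rng_seed=42, frame_rate_hz=1.0), grid64, 8.0)
        assert np.array_equal(a.frames, b.frames)

    def test_seed_changes_sweep_order(self):
        a = default_run(rng_seed=0)
        b = default_run(rng_seed=1)
        assert [s.direction for s in a.sweeps] != [s.direction for s in b.sweeps]
        assert sorted(s.direction for s in a.sweeps) == sorted(DEFAULT_DIRECTIONS)

    def test_pre_blank_is_zero(self, grid64):
        movie = assemble_run(default_run(frame_rate_hz=1.0), grid64, rmax=8.0)
        assert movie.frames[:, :, :2].sum() == 0
        assert movie.frames[:, :, -4:].sum() == 0

    def test_binary(self, grid64):
        movie = assemble_run(default_run(frame_rate_hz=1.0), grid64, rmax=8.0)
        assert movie.is_binary()


def _single_sweep_movie(grid, direction=0.0, fps=1.0, seed=0):
    run = default_run(rng_seed=seed, frame_rate_hz=fps, directions=[direction])
    run = dataclasses.replace(run, sweeps=run.sweeps[:1])
    return assemble_run(run, grid, 8.0)


class TestWarpMovie:
    def test_zero_movie_stays_zero(self, grid64, warp5):
        movie = StimulusMovie(
            frames=np.zeros((64, 64, 5), dtype=np.uint8),
            grid=grid64, frame_duration_s=1.0,
        )
        warped = warp_movie(movie, warp5)
        assert warped.frames.sum() == 0
        assert warped.label == "log"

    def test_identity_limit(self, grid64):
        movie = _single_sweep_movie(grid64)
        warped = warp_movie(movie, WarpSpec(k=1e-8, rmax=8.0))
        assert np.array_equal(warped.frames, movie.frames)

    def test_aperture_edge_fixed_point(self, warp5):
        # a bar touching the aperture edge still touches it after warping
        grid = FieldGrid.square(216, fov_deg=16.0)
        sweep = SweepSpec(direction=0.0)
        frame = make_bar_frame(7.0, sweep, grid, rmax=8.0)
        movie = StimulusMovie(frames=frame[:, :, None], grid=grid,
                              frame_duration_s=1.0)
        warped = warp_movie(movie, warp5)
        x, y = grid.coords()
        r = np.hypot(x, y)
        src_max = r[movie.frames[:, :, 0] > 0].max()
        out_max = r[warped.frames[:, :, 0] > 0].max()
        assert out_max == pytest.approx(src_max, abs=2 * grid.deg_per_px)

    def test_polar_angle_preserved_on_spoke(self, warp5):
        # thin radial spoke at 30 degrees: warping must not rotate it
        grid = FieldGrid.square(216, fov_deg=16.0)
        x, y = grid.coords()
        theta = np.arctan2(y, x)
        r = np.hypot(x, y)
        ang = np.deg2rad(30.0)
        spoke = ((np.abs(np.mod(theta - ang + np.pi, 2 * np.pi) - np.pi) < 0.03)
                 & (r > 0.5) & (r < 8.0)).astype(np.uint8)
        movie = StimulusMovie(frames=spoke[:, :, None], grid=grid,
                              frame_duration_s=1.0)
        warped = warp_movie(movie, warp5)
        mask = warped.frames[:, :, 0] > 0
        assert mask.sum() > 0
        angles = theta[mask & (r > 0.5)]
        px_angle = grid.deg_per_px / 0.5  # one pixel at the innermost radius
        assert np.abs(angles - ang).max() < 0.03 + px_angle

    def test_content_compressed_toward_fovea(self, warp5):
        # a bar at [0.5, 2.5] in fixed space displays well inside 0.5 deg
        grid = FieldGrid.square(216, fov_deg=16.0)
        sweep = SweepSpec(direction=0.0)
        frame = make_bar_frame(1.5, sweep, grid, rmax=8.0)
        movie = StimulusMovie(frames=frame[:, :, None], grid=grid,
                              frame_duration_s=1.0)
        warped = warp_movie(movie, warp5)
        x, y = grid.coords()
        row = grid.height_px // 2
        on = warped.frames[row, :, 0] > 0
        assert on.sum() > 0
        xs = x[row, :][on]
        lo_expect = inverse_log_map(0.5, warp5)   # ~0.052
        hi_expect = inverse_log_map(2.5, warp5)   # ~0.438
        assert xs.min() == pytest.approx(lo_expect, abs=3 * grid.deg_per_px)
        assert xs.max() == pytest.approx(hi_expect, abs=3 * grid.deg_per_px)

    def test_peripheral_bar_wider_than_foveal(self, warp5):
        # radial extent of the displayed image: [6,8] source vs [0,2] source
        foveal = inverse_log_map(2.0, warp5) - inverse_log_map(0.0, warp5)
        peripheral = inverse_log_map(8.0, warp5) - inverse_log_map(6.0, warp5)
        assert peripheral > foveal
        # and the same holds for actual warped frames
        grid = FieldGrid.square(216, fov_deg=16.0)
        sweep = SweepSpec(direction=0.0)
        x, _ = grid.coords()
        row = grid.height_px // 2
        extents = {}
        for center in (1.0, 7.0):
            frame = make_bar_frame(center, sweep, grid, rmax=8.0)
            movie = StimulusMovie(frames=frame[:, :, None], grid=grid,
                                  frame_duration_s=1.0)
            warped = warp_movie(movie, warp5)
            on = warped.frames[row, :, 0] > 0
            extents[center] = x[row, :][on].max() - x[row, :][on].min()
        assert extents[7.0] > extents[1.0]


class TestPreprocess:
    def test_default_dimensions(self):
        grid = FieldGrid.square(540, fov_deg=16.0)
        movie = _single_sweep_movie(grid, fps=2.0)  # 45 s sweep + blanks
        out = preprocess_movie(movie, target_px=108, target_frames=51)
        assert out.frames.shape == (108, 108, 51)
        assert out.grid.deg_per_px == pytest.approx(16.0 / 108)

    def test_binary_output(self, grid64):
        movie = _single_sweep_movie(grid64, fps=2.0)
        out = preprocess_movie(movie, target_px=32, target_frames=51)
        assert out.is_binary()

    def test_fractional_option(self, grid64):
        movie = _single_sweep_movie(grid64, fps=2.0)
        out = preprocess_movie(movie, target_px=32, target_frames=51,
                               binarize=False)
        assert out.frames.min() >= 0 and out.frames.max() <= 1
        assert not np.array_equal(out.frames, out.frames.astype(bool))

    def test_upsampling_rejected(self, grid64):
        movie = _single_sweep_movie(grid64)
        with pytest.raises(ValueError):
            preprocess_movie(movie, target_px=128, target_frames=10)
        with pytest.raises(ValueError):
            preprocess_movie(movie, target_px=32, target_frames=10_000)

    def test_disc_preserved_within_one_pixel(self):
        # downsampling an all-ones disc then rebinarizing keeps its radius
        src = FieldGrid.square(540, fov_deg=16.0)
        x, y = src.coords()
        disc = (np.hypot(x, y) <= 6.0).astype(np.uint8)
        movie = StimulusMovie(frames=np.repeat(disc[:, :, None], 4, axis=2),
                              grid=src, frame_duration_s=1.0)
        out = preprocess_movie(movie, target_px=108, target_frames=4)
        tgt = out.grid
        xt, yt = tgt.coords()
        direct = (np.hypot(xt, yt) <= 6.0)
        mismatched = out.frames[:, :, 0].astype(bool) ^ direct
        # disagreement only within one pixel of the boundary
        assert np.all(np.abs(np.hypot(xt, yt)[mismatched] - 6.0) <= tgt.deg_per_px)
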