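"""Imaging-pipeline stages against synthetic ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from pvsflow.imaging import (
    TwoChannelMovie,
    _iterative_tile_displacement,
    binarize_locomotion,
    fit_hrf,
    gamma_kernel,
    piecewise_displacement,
    preprocess,
    radon_diameter,
    register_stack,
    remove_crosstalk,
    wavelet_denoise,
)
from pvsflow.synthetic import SyntheticSpec, render_line_field


@pytest.fixture(scope="module")
def texture():
    spec = SyntheticSpec(shape=(192, 192), n_lines=35, seed=7)
    return render_line_field(spec, np.random.default_rng(7))


class TestRegistration:
    def test_known_translations_recovered(self, texture):
        """Frames shifted by up to +-3 px are recovered within 0.1 px."""
        shifts_true = np.array([[0.0, 0.0], [1.5, -2.25], [-3.0, 0.5], [2.0, 3.0]])
        stack = np.stack([ndimage.shift(texture, -s, order=3) for s in shifts_true])
        shifts, errors = register_stack(stack, texture, upsample=50)
        assert np.allclose(shifts, shifts_true, atol=0.1)

    def test_static_movie_zero_shifts(self, texture):
        stack = np.stack([texture] * 6)
        movie = preprocess(TwoChannelMovie(red=stack, green=stack))
        assert np.allclose(movie.shifts, 0.0, atol=0.02)

    def test_flat_frame_flagged(self, texture):
        stack = np.stack([texture, np.zeros_like(texture)] * 3)
        shifts, errors = register_stack(stack, texture)
        assert np.isnan(shifts[1]).all() and errors[1] == 1.0

    def test_hot_pixel_removed_by_median(self, texture):
        stack = np.stack([texture] * 7)
        stack[3, 50, 50] = 1e4
        movie = preprocess(TwoChannelMovie(red=stack, green=stack))
        assert movie.red[3, 50, 50] < 2.0


class TestCrosstalk:
    def test_recovery_with_disjoint_signals(self, rng):
        """r_i = r_true + 0.3 g with spatially disjoint content: alpha is
        recovered within 0.02."""
        r_true = np.zeros((4, 64, 64))
        g = np.zeros((4, 64, 64))
        r_true[:, :, :30] = rng.random((4, 64, 30))
        g[:, :, 34:] = rng.random((4, 64, 30))
        ri = r_true + 0.3 * g
        _, alpha = remove_crosstalk(ri, g)
        assert alpha == pytest.approx(0.3, abs=0.02)

    def test_zero_green_returns_input_with_warning(self, rng):
        r = rng.random((3, 16, 16))
        with pytest.warns(UserWarning, match="alpha"):
            rf, alpha = remove_crosstalk(r, np.zeros_like(r))
        assert alpha == 0.0
        assert np.allclose(rf, r)

    def test_estimate_confined_to_search_interval(self, rng):
        g = rng.random((3, 32, 32))
        ri = 5.0 * g  # true bleed-through outside the interval
        _, alpha = remove_crosstalk(ri, g)
        assert 0.0 < alpha <= 1.5

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            remove_crosstalk(rng.random((2, 8, 8)), rng.random((2, 8, 9)))


class TestRadonDiameter:
    def test_disk_area_within_ten_percent(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disk = (((yy - 32) ** 2 + (xx - 32) ** 2) < 100).astype(float)
        trace = radon_diameter(disk[None])
        assert trace.area_px[0] == pytest.approx(100 * np.pi, rel=0.10)
        assert trace.diameter_px[0] == pytest.approx(20.0, rel=0.05)

    def test_all_zero_frame_invalid_and_filled(self):
        yy, xx = np.mgrid[0:48, 0:48]
        disk = (((yy - 24) ** 2 + (xx - 24) ** 2) < 64).astype(float)
        stack = np.stack([disk, np.zeros_like(disk), disk])
        trace = radon_diameter(stack)
        assert not trace.valid[1] and trace.valid[0]
        assert trace.area_px[1] == pytest.approx(trace.area_px[0])

    def test_diameter_tracks_a_15_percent_ramp(self):
        """A vessel whose radius grows 15% must show a 15% (+-2%) diameter
        increase in the Radon-space trace."""
        yy, xx = np.mgrid[0:96, 0:96]
        rr = np.hypot(yy - 48, xx - 48)
        frames = []
        radii = np.linspace(14.0, 14.0 * 1.15, 6)
        for R in radii:
            frames.append(1.0 / (1.0 + np.exp((rr - R) / 0.5)))
        trace = radon_diameter(np.stack(frames))
        ratio = trace.diameter_px[-1] / trace.diameter_px[0]
        assert ratio == pytest.approx(1.15, abs=0.02)


class TestHrf:
    def _make_traces(self, rng, noise=0.0):
        n, fr = 240, 3.0
        vel = np.zeros(n)
        for start in (30, 110, 180):
            vel[start:start + 15] = 2.0
        binary = binarize_locomotion(vel)
        t_k = np.arange(0, int(10 * fr)) / fr
        kern = gamma_kernel(t_k, 1.3, 1.8, 2.5)
        diam = 20.0 + np.convolve(binary, kern)[:n] + noise * rng.standard_normal(n)
        return vel, diam, fr

    def test_generative_recovery(self, rng):
        vel, diam, fr = self._make_traces(rng)
        params, r2, ok = fit_hrf(vel, diam, frame_rate=fr)
        assert ok and r2 > 0.99
        assert params["t_peak"] == pytest.approx(1.8, rel=0.05)
        assert params["amplitude"] == pytest.approx(1.3, rel=0.05)

    def test_uncorrelated_noise_rejected(self, rng):
        vel, _, fr = self._make_traces(rng)
        noise_diam = 20.0 + rng.standard_normal(240)
        params, r2, ok = fit_hrf(vel, noise_diam, frame_rate=fr)
        assert not ok and r2 < 0.6

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="locomotion"):
            fit_hrf(np.zeros(100), np.full(100, 20.0))


class TestPiecewiseDisplacement:
    def test_candidate_grid_on_512_frames(self):
        """(512 - 64)/16 + 1 = 29 tile positions per axis: 841 candidates."""
        ref = np.zeros((512, 512))
        ref[100:130, 200:230] = 1.0  # single bright patch keeps runtime low
        stack = np.stack([ref, ref])
        series = piecewise_displacement(stack, ref, percentile=99.9)
        assert series.candidates == 841

    def test_rigid_shift_recovered_per_tile(self, texture):
        shift = np.array([1.2, -0.8])
        moved = ndimage.shift(texture, shift, order=3)
        series = piecewise_displacement(np.stack([texture, moved]), texture,
                                        percentile=90.0)
        acc = series.accepted
        assert acc.any()
        # displacement OF the content equals the applied shift
        d = series.disp[acc][:, 1, :]
        assert np.allclose(d, shift, atol=0.15)

    def test_rotated_tile_rejected(self, texture):
        """A 45-degree rotation cannot be matched by a translation: the
        iterative registration must fail to converge."""
        tile = texture[40:104, 40:104]
        rot = ndimage.rotate(tile, 45.0, reshape=False, order=3)
        _, ok45, _ = _iterative_tile_displacement(tile, rot)
        _, ok2, _ = _iterative_tile_displacement(
            tile, ndimage.rotate(tile, 2.0, reshape=False, order=3))
        assert not ok45
        assert ok2

    def test_wavelet_denoise_reduces_noise_preserving_signal(self, rng):
        t = np.arange(0, 40, 1 / 3)
        clean = gamma_kernel(t, 3.0, 5.0, 2.0)
        noisy = clean + 0.4 * rng.standard_normal(len(t))
        den = wavelet_denoise(noisy)
        assert np.linalg.norm(den - clean) < 0.7 * np.linalg.norm(noisy - clean)
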