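"""Core engine: white field, reference synthesis, map/translation updates."""

import numpy as np
import pytest

from pxst import core
from pxst.core import (
    PixelMap,
    ReferenceImage,
    ScanData,
    WhiteField,
    bilinear_sample,
    build_reference,
    compute_error_map,
    estimate_white_field,
    initial_pixel_map,
    update_pixel_map,
    update_translations,
)
from pxst.geometry import ExperimentGeometry


def _geometry(n=64):
    z1 = 0.371e-3
    return ExperimentGeometry(16.7, z1, z1, 0.71 - z1, (n, n), 55e-6)


class TestScanData:
    def test_validation(self):
        g = _geometry(8)
        frames = np.ones((3, 8, 8))
        t = np.zeros((3, 2))
        mask = np.ones((8, 8), bool)
        ScanData(frames, t, mask, g)  # valid
        with pytest.raises(ValueError):
            ScanData(frames, np.zeros((2, 2)), mask, g)
        with pytest.raises(ValueError):
            ScanData(-frames, t, mask, g)
        with pytest.raises(ValueError):
            ScanData(frames, np.full((3, 2), np.nan), mask, g)


class TestWhiteField:
    def test_minority_occlusion_median_exact(self):
        """Median returns the unoccluded value when occlusion is < 50%."""
        g = _geometry(8)
        rng = np.random.default_rng(0)
        truth = 100 + 50 * rng.random((8, 8))
        n = 11
        frames = np.tile(truth, (n, 1, 1))
        # occlude each pixel in 5 of 11 frames (minority), halving its value
        for px in range(64):
            i, j = divmod(px, 8)
            occ = rng.choice(n, size=5, replace=False)
            frames[occ, i, j] *= 0.5
        scan = ScanData(frames, np.zeros((n, 2)), np.ones((8, 8), bool), g)
        w = estimate_white_field(scan)
        assert np.abs(w.data - truth).max() < 1e-12

    def test_few_frames_warns(self):
        g = _geometry(8)
        scan = ScanData(np.ones((2, 8, 8)), np.zeros((2, 2)), np.ones((8, 8), bool), g)
        with pytest.warns(UserWarning):
            estimate_white_field(scan)


class TestInitialPixelMap:
    def test_isotropic_scaling(self):
        g = _geometry()
        u = initial_pixel_map(g)
        y, x = g.detector_coords()
        m = g.magnification
        assert np.allclose(u.u[1], x / m, rtol=1e-12)
        assert np.allclose(u.u[0], y / m, rtol=1e-12)

    def test_high_mag_slope(self):
        z1 = 0.371e-3
        g = ExperimentGeometry(16.7, z1, z1, 0.70963, (32, 32), 55e-6)
        u = initial_pixel_map(g)
        y, x = g.detector_coords()
        slope = u.u[1][16, -1] / x[16, -1]
        assert slope == pytest.approx(1 / 1913.7, rel=1e-3)

    def test_astigmatic_slopes_differ(self):
        z1 = 0.371e-3
        g = ExperimentGeometry(16.7, z1, 1.2 * z1, 0.71, (32, 32), 55e-6)
        u = initial_pixel_map(g)
        y, x = g.detector_coords()
        sx = u.u[1][16, -1] / x[16, -1]
        sy = u.u[0][-1, 16] / y[-1, 16]
        assert sy > sx  # larger z1y -> weaker demagnification


class TestBuildReference:
    def test_single_frame_identity_map_resamples_input(self):
        """With u = x, W = 1 and one frame, the reference is the frame."""
        g = _geometry(32)
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter

        img = 1 + 0.3 * gaussian_filter(rng.standard_normal((32, 32)), 3)
        y, x = g.detector_coords()
        u = PixelMap(np.stack([y, x]), np.ones((32, 32), bool))
        scan = ScanData(img[None], np.zeros((1, 2)), np.ones((32, 32), bool), g)
        w = WhiteField(np.ones((32, 32)), np.ones((32, 32), bool))
        ref = build_reference(scan, w, u, pitch=g.pixel_size, cg_iters=20)
        ci = (u.u[0] - ref.origin[0]) / ref.pitch
        cj = (u.u[1] - ref.origin[1]) / ref.pitch
        back, valid = bilinear_sample(ref.data, ci, cj)
        assert np.abs(back[valid.reshape(32, 32)] - img[valid.reshape(32, 32)]).max() < 1e-6

    def test_reference_matches_ground_truth_hologram(self, sim_small):
        sim = sim_small
        w = estimate_white_field(sim.scan)
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true)
        # sample truth on the recovered grid and compare where covered
        ny, nx = ref.shape
        yy = ref.origin[0] + np.arange(ny)[:, None] * ref.pitch
        xx = ref.origin[1] + np.arange(nx)[None, :] * ref.pitch
        ti = (yy - sim.reference_true.origin[0]) / sim.reference_true.pitch
        tj = (xx - sim.reference_true.origin[1]) / sim.reference_true.pitch
        truth, tvalid = bilinear_sample(
            sim.reference_true.data, *np.broadcast_arrays(ti, tj)
        )
        good = np.isfinite(ref.data) & tvalid & (ref.weight > np.nanmedian(ref.weight))
        # compare within the bilinear-interpolation passband: the half-pixel
        # grid carries near-Nyquist hash the splat cannot represent
        from scipy.ndimage import gaussian_filter

        rd = gaussian_filter(np.where(np.isfinite(ref.data), ref.data, 1.0), 0.7)
        td = gaussian_filter(np.where(tvalid, truth, 1.0), 0.7)
        err = (rd - td)[good]
        assert np.sqrt((err**2).mean()) < 0.02 * truth[good].mean()

    def test_coverage_counts_contributing_samples(self):
        """Integer-aligned splats give integer coverage counts."""
        g = _geometry(16)
        y, x = g.detector_coords()
        u = PixelMap(np.stack([y, x]), np.ones((16, 16), bool))
        frames = np.ones((2, 16, 16))
        t = np.array([[0.0, 0.0], [0.0, 4 * g.pixel_size]])  # integer-pixel shift
        scan = ScanData(frames, t, np.ones((16, 16), bool), g)
        w = WhiteField(np.ones((16, 16)), np.ones((16, 16), bool))
        ref = build_reference(scan, w, u, pitch=g.pixel_size, margin=6, cg_iters=0)
        cov = ref.coverage
        assert np.allclose(cov, np.round(cov), atol=1e-9)
        assert int(np.round(cov.max())) == 2  # overlap region sees both frames

    def test_empty_coverage_raises(self):
        g = _geometry(8)
        u = PixelMap(np.zeros((2, 8, 8)), np.zeros((8, 8), bool))
        scan = ScanData(np.ones((1, 8, 8)), np.zeros((1, 2)), np.ones((8, 8), bool), g)
        w = WhiteField(np.ones((8, 8)), np.ones((8, 8), bool))
        with pytest.raises(ValueError):
            build_reference(scan, w, u)


class TestErrorMap:
    def test_perfect_model_zero_error(self, sim_small):
        sim = sim_small
        _, _, total = compute_error_map(
            sim.scan, sim.white_true, sim.reference_true, sim.pixel_map_true
        )
        signal = (sim.scan.frames**2).sum()
        assert total < 1e-16 * signal

    def test_decompositions_sum_to_total(self, sim_small_noisy):
        sim = sim_small_noisy
        w = estimate_white_field(sim.scan)
        ref = build_reference(sim.scan, w, sim.pixel_map_true, cg_iters=2)
        pix, per_frame, total = compute_error_map(sim.scan, w, ref, sim.pixel_map_true)
        assert per_frame.sum() == pytest.approx(total, rel=1e-12)
        assert pix.sum() == pytest.approx(total, rel=1e-9)

    def test_poisson_sse_matches_variance_identity(self):
        """For Poisson data against the exact model, SSE ~ sum of counts."""
        from pxst.phantoms import siemens_preset

        sim = siemens_preset(n_det=96, scan_shape=(4, 4), distortion_px=2.0,
                             flux=800.0, seed=21)
        noiseless = siemens_preset(n_det=96, scan_shape=(4, 4), distortion_px=2.0,
                                   flux=None, seed=21)
        expected = noiseless.scan.frames * 800.0  # expected counts
        sse = ((sim.scan.frames - expected) ** 2).sum()
        assert sse == pytest.approx(expected.sum(), rel=0.05)


class TestUpdatePixelMap:
    def test_fixed_point_on_consistent_data(self, sim_small):
        """Self-consistent data leave the map unchanged to < 0.05 ref px."""
        sim = sim_small
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true)
        u2, info = update_pixel_map(
            sim.scan, sim.white_true, ref, sim.pixel_map_true, search_radius=3
        )
        d = (u2.u - sim.pixel_map_true.u) / ref.pitch
        m = ~info["flagged"]
        assert np.sqrt(np.mean(d[:, m] ** 2)) < 0.05

    def test_recovers_known_shift_of_gaussian_blob(self):
        """Brute-force error surface plus parabola vertex tracks a 3.4-px shift.

        A single frame of a shifted Gaussian blob: the whole-frame error
        surface over integer shifts with sub-pixel quadratic refinement (the
        translation update) must locate the injected 3.40-px displacement.
        """
        g = _geometry(48)
        ny = nx = 48
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        blob = lambda cy, cx: 1 + 2.0 * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 4.0**2)
        )
        pitch = g.pixel_size
        ref = ReferenceImage(blob(24.0, 24.0), pitch, (0.0, 0.0))
        shift = 3.4  # reference pixels, along x
        frames = np.stack([blob(24.0, 24.0), blob(24.0, 24.0 - shift)])
        u = PixelMap(np.stack([yy * pitch, xx * pitch]), np.ones((ny, nx), bool))
        scan = ScanData(frames, np.zeros((2, 2)), np.ones((ny, nx), bool), g)
        w = WhiteField(np.ones((ny, nx)), np.ones((ny, nx), bool))
        t2, info = update_translations(scan, w, ref, u, search_radius=6)
        # a blob moved by -shift in the image means the sample translated by
        # +shift in the model I_ref(u - dx): dx_1 - dx_0 = -shift
        rec = (t2[1, 1] - t2[0, 1]) / pitch
        assert rec == pytest.approx(-shift, abs=0.1)

    def test_flat_error_surface_is_flagged(self):
        g = _geometry(16)
        ref = ReferenceImage(np.ones((64, 64)), g.pixel_size, (0.0, 0.0))
        yy, xx = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        u = PixelMap(
            np.stack([(yy + 20) * g.pixel_size, (xx + 20) * g.pixel_size]),
            np.ones((16, 16), bool),
        )
        scan = ScanData(np.ones((2, 16, 16)), np.zeros((2, 2)), np.ones((16, 16), bool), g)
        w = WhiteField(np.ones((16, 16)), np.ones((16, 16), bool))
        u2, info = update_pixel_map(scan, w, ref, u, search_radius=2)
        assert info["flagged"].all()
        assert np.array_equal(u2.u, u.u)  # previous values retained


class TestUpdateTranslations:
    def test_correct_positions_unchanged(self, sim_small):
        sim = sim_small
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true)
        t2, info = update_translations(
            sim.scan, sim.white_true, ref, sim.pixel_map_true, search_radius=3
        )
        corr = np.abs(t2 - sim.scan.translations) / ref.pitch
        assert corr.max() < 0.05

    def test_injected_offset_recovered(self, sim_small):
        sim = sim_small
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true)
        t_bad = sim.scan.translations.copy()
        inj = 2.0 * ref.pitch
        t_bad[7, 0] += inj  # one frame off by 2 ref px in y
        scan_bad = ScanData(sim.scan.frames, t_bad, sim.scan.mask, sim.scan.geometry)
        t2, info = update_translations(
            scan_bad, sim.white_true, ref, sim.pixel_map_true, search_radius=4
        )
        err = (t2 - sim.scan.translations) / ref.pitch
        err -= err.mean(axis=0)  # zero-mean gauge
        assert np.abs(err[7]).max() < 0.2 + 2.0 / 25  # gauge spreads 2px/25 frames
        assert np.abs(np.delete(err, 7, axis=0)).max() < 0.3

    def test_linear_drift_absorbed_to_gauge(self, sim_small):
        """A uniform drift is recovered up to the zero-mean constraint."""
        sim = sim_small
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true)
        drift = np.linspace(-1.5, 1.5, sim.scan.n_frames)[:, None] * np.array(
            [[0.0, 1.0]]
        ) * ref.pitch
        scan_bad = ScanData(
            sim.scan.frames, sim.scan.translations + drift, sim.scan.mask, sim.scan.geometry
        )
        t2, _ = update_translations(
            scan_bad, sim.white_true, ref, sim.pixel_map_true, search_radius=4
        )
        err = (t2 - sim.scan.translations) / ref.pitch
        err -= err.mean(axis=0)
        assert np.abs(err).max() < 0.2


class TestGaugeInvariance:
    def test_constant_translation_offset_is_gauge(self, sim_small):
        """Shifting all translations and u by the same constant changes nothing."""
        sim = sim_small
        const = np.array([3.7e-9, -2.2e-9])  # metres
        u_shift = PixelMap(
            sim.pixel_map_true.u + const[:, None, None], sim.pixel_map_true.mask
        )
        scan_shift = ScanData(
            sim.scan.frames,
            sim.scan.translations + const[None, :],
            sim.scan.mask,
            sim.scan.geometry,
        )
        ref = build_reference(sim.scan, sim.white_true, sim.pixel_map_true, cg_iters=0)
        ref2 = build_reference(scan_shift, sim.white_true, u_shift, cg_iters=0)
        _, _, sse1 = compute_error_map(sim.scan, sim.white_true, ref, sim.pixel_map_true)
        _, _, sse2 = compute_error_map(scan_shift, sim.white_true, ref2, u_shift)
        assert sse2 == pytest.approx(sse1, rel=1e-6, abs=1e-12)
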