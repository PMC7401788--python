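"""Synthetic-data generator: phantoms, pupils, propagation, scan simulation."""

import numpy as np
import pytest

from pxst.geometry import ExperimentGeometry
from pxst.phantoms import (
    hex_preset,
    make_hex_lattice_phantom,
    make_pupil_phase,
    make_siemens_star,
    propagate_angular_spectrum,
    siemens_preset,
    simulate_scan,
)
from pxst.wavefront import remove_low_orders


def _siemens_geometry(n=128, astig=0.0):
    z1 = 0.371e-3
    return ExperimentGeometry(
        photon_energy=16.7,
        focus_sample_x=z1,
        focus_sample_y=z1 * (1 + astig),
        sample_detector=0.71 - z1,
        detector_shape=(n, n),
        pixel_size=55e-6,
    )


class TestSiemensStar:
    def test_defaults_and_transmission_bound(self):
        star = make_siemens_star(shape=(512, 512), pitch=30e-9)
        assert star.thickness.max() <= 1.0e-6 + 1e-12
        t = star.transmission(7.424e-11)
        assert np.all(np.abs(t) <= 1.0 + 1e-12)
        # single-material consistency: T = exp(-(2pi/lam)(beta+i delta) dz)
        lam = 7.424e-11
        expect = np.exp(-(2 * np.pi / lam) * (star.beta + 1j * star.delta_r) * star.thickness)
        assert np.abs(t - expect).max() < 1e-12

    def test_empty_thickness_gives_unit_transmission(self):
        star = make_siemens_star(thickness_range=(0.0, 0.0), shape=(128, 128), pitch=60e-9)
        assert np.abs(star.transmission(7.4e-11) - 1.0).max() < 1e-12

    def test_angular_duty_cycle_is_half(self):
        star = make_siemens_star(shape=(1024, 1024), pitch=15e-9)
        yy, xx = star.coords()
        r = np.hypot(yy, xx)
        r_in = 100e-9 * 30 / np.pi
        r_out = 5e-6
        ann = (r > 1.2 * r_in) & (r < 0.86 * r_out)
        for frac in (0.45, 0.75):  # stay clear of the circular cuts
            ann &= np.abs(r - frac * r_out) > 0.2e-6
        opaque = star.thickness[ann] > 0.25e-6
        assert opaque.mean() == pytest.approx(0.5, abs=0.02)

    def test_coarse_grid_warns(self):
        with pytest.warns(UserWarning, match="coarser"):
            make_siemens_star(shape=(64, 64), pitch=150e-9)


class TestHexLattice:
    def test_reciprocal_peak_radius(self):
        a = 601e-9
        ph = make_hex_lattice_phantom(lattice_constant=a, extent=12e-6, pitch=30e-9)
        spec = np.abs(np.fft.fftshift(np.fft.fft2(ph.thickness - ph.thickness.mean()))) ** 2
        n = spec.shape[0]
        f = np.fft.fftshift(np.fft.fftfreq(n, d=30e-9))
        fy, fx = np.meshgrid(f, f, indexing="ij")
        fr = np.hypot(fy, fx)
        expected = 2.0 / (np.sqrt(3) * a)
        band = (fr > 0.5 * expected) & (fr < 1.5 * expected)
        peak_r = fr.ravel()[np.argmax(np.where(band, spec, 0.0))]
        assert peak_r == pytest.approx(expected, rel=0.02)

    def test_zero_motif_is_uniform(self):
        ph = make_hex_lattice_phantom(motif={"thickness": 0.0}, extent=6e-6, pitch=30e-9)
        assert np.ptp(ph.thickness) == 0.0

    def test_translation_by_lattice_vector_is_identity(self):
        a = 601e-9
        kw = dict(lattice_constant=a, extent=8e-6, pitch=30e-9)
        p0 = make_hex_lattice_phantom(**kw)
        p1 = make_hex_lattice_phantom(offset=(0.0, a), **kw)
        interior = np.s_[60:-60, 60:-60]
        scale = p0.thickness.max()
        assert np.abs(p1.thickness[interior] - p0.thickness[interior]).max() < 1e-10 * scale

    def test_too_coarse_grid_raises(self):
        with pytest.raises(ValueError):
            make_hex_lattice_phantom(lattice_constant=50e-9, pitch=30e-9)


class TestPupilPhase:
    def test_edge_ray_angle_equals_geometric(self):
        g = _siemens_geometry()
        pup = make_pupil_phase(g)
        theta_x = g.wavelength / (2 * np.pi) * pup.gradient[1]
        y, x = g.detector_coords()
        expect = x / (g.focus_sample_x + g.sample_detector)
        assert np.abs(theta_x - expect).max() < 1e-15

    def test_pure_quadratic_has_no_low_order_residual(self):
        g = _siemens_geometry()
        pup = make_pupil_phase(g)
        res, fit = remove_low_orders(pup.phase, g.pixel_size)
        assert res.std() < 1e-9 * pup.phase.std()
        assert fit.focus_distance_x(g.wavelength) == pytest.approx(0.71, rel=1e-9)

    def test_astigmatism_gives_distinct_curvatures(self):
        g = _siemens_geometry(astig=0.1)
        pup = make_pupil_phase(g)
        _, fit = remove_low_orders(pup.phase, g.pixel_size)
        rx = fit.focus_distance_x(g.wavelength)
        ry = fit.focus_distance_y(g.wavelength)
        assert ry > rx
        assert ry - rx == pytest.approx(0.1 * 0.371e-3, rel=1e-6)


class TestPropagation:
    def setup_method(self):
        self.n, self.pitch, self.lam = 512, 1e-6, 1e-9
        x = (np.arange(self.n) - self.n / 2) * self.pitch
        self.yy, self.xx = np.meshgrid(x, x, indexing="ij")

    def test_zero_distance_is_identity(self):
        g = np.exp(-(self.xx**2 + self.yy**2) / (12e-6) ** 2)
        out = propagate_angular_spectrum(g, self.pitch, 0.0, self.lam)
        assert np.array_equal(out, g)

    def test_gaussian_beam_width(self):
        w0 = 12e-6
        g = np.exp(-(self.xx**2 + self.yy**2) / w0**2)
        d = 0.15
        out = propagate_angular_spectrum(g, self.pitch, d, self.lam)
        inten = np.abs(out) ** 2
        r2 = (inten * (self.xx**2 + self.yy**2)).sum() / inten.sum()
        w_meas = np.sqrt(2 * r2)
        w_expect = w0 * np.sqrt(1 + (self.lam * d / (np.pi * w0**2)) ** 2)
        assert w_meas == pytest.approx(w_expect, rel=0.005)

    def test_energy_conservation(self):
        g = np.exp(-(self.xx**2 + self.yy**2) / (15e-6) ** 2) * np.exp(
            1j * 2 * np.pi * self.xx / 64e-6
        )
        out = propagate_angular_spectrum(g, self.pitch, 0.2, self.lam)
        e0 = (np.abs(g) ** 2).sum()
        e1 = (np.abs(out) ** 2).sum()
        assert abs(e1 / e0 - 1) < 1e-10

    def test_talbot_self_imaging(self):
        p = 16e-6
        g = (1 + 0.8 * np.cos(2 * np.pi * self.xx / p)) / 1.8 + 0j
        zt = 2 * p**2 / self.lam
        out = propagate_angular_spectrum(g, self.pitch, zt, self.lam)
        sl = slice(self.n // 4, -self.n // 4)
        i0 = (np.abs(g[sl, sl]) ** 2).ravel()
        i1 = (np.abs(out[sl, sl]) ** 2).ravel()
        assert np.corrcoef(i0, i1)[0, 1] > 0.99

    def test_aliasing_bound_raises_with_safe_distance(self):
        g = np.ones((128, 128), dtype=complex)
        with pytest.raises(ValueError, match="safe|<="):
            propagate_angular_spectrum(g, 1e-6, 10.0, 1e-9)


class TestSimulateScan:
    def test_empty_phantom_reproduces_white_field(self):
        g = _siemens_geometry(n=64)
        empty = make_siemens_star(
            thickness_range=(0.0, 0.0), shape=(512, 512), pitch=g.demagnified_pixel / 2
        )
        pup = make_pupil_phase(g)
        sim = simulate_scan(empty, pup, g, scan_shape=(2, 2), flux=None)
        for k in range(sim.scan.n_frames):
            assert np.abs(sim.scan.frames[k] - sim.white_true.data).max() < 1e-9

    def test_geometric_self_consistency(self, sim_small):
        """Frames equal W * I_ref(u_true - dx_n) by construction."""
        from pxst.core import bilinear_sample

        sim = sim_small
        ref = sim.reference_true
        k = 7
        ci = (sim.pixel_map_true.u[0] - sim.scan.translations[k, 0] - ref.origin[0]) / ref.pitch
        cj = (sim.pixel_map_true.u[1] - sim.scan.translations[k, 1] - ref.origin[1]) / ref.pitch
        pred, valid = bilinear_sample(ref.data, ci, cj)
        expect = sim.white_true.data * np.where(valid, pred, 1.0)
        assert np.abs(sim.scan.frames[k] - expect).max() < 1e-9

    def test_poisson_statistics(self):
        g = _siemens_geometry(n=48)
        empty = make_siemens_star(
            thickness_range=(0.0, 0.0), shape=(256, 256), pitch=g.demagnified_pixel
        )
        pup = make_pupil_phase(g)
        flux = 500.0
        sim = simulate_scan(empty, pup, g, scan_shape=(7, 7), flux=flux, seed=11)
        n = sim.scan.n_frames
        mean = sim.scan.frames.mean(axis=0)
        expect = sim.white_true.data
        rel = np.abs(mean - expect) / expect
        # Poisson: relative error of the mean ~ 1/sqrt(N*counts); allow 3x
        assert np.percentile(rel, 99) < 3.0 / np.sqrt(n * flux * 0.5)

    def test_seeded_simulation_is_bit_reproducible(self):
        a = siemens_preset(n_det=48, scan_shape=(2, 2), flux=300.0, seed=9)
        b = siemens_preset(n_det=48, scan_shape=(2, 2), flux=300.0, seed=9)
        assert np.array_equal(a.scan.frames, b.scan.frames)
        c = siemens_preset(n_det=48, scan_shape=(2, 2), flux=300.0, seed=10)
        assert not np.array_equal(a.scan.frames, c.scan.frames)

    def test_positions_outside_phantom_raise(self):
        g = _siemens_geometry(n=48)
        small = make_siemens_star(shape=(128, 128), pitch=g.demagnified_pixel)
        pup = make_pupil_phase(g)
        bad = np.array([[0.0, 1.0]])  # one metre off
        with pytest.raises(ValueError, match="extent"):
            simulate_scan(small, pup, g, positions=bad)

    def test_wave_and_geometric_modes_agree_for_mild_aberrations(self):
        """Model error of the pseudo-geometric forward model stays small."""
        simg = siemens_preset(n_det=128, scan_shape=(2, 2), distortion_px=1.0,
                              mode="geometric", seed=5)
        simw = siemens_preset(n_det=128, scan_shape=(2, 2), distortion_px=1.0,
                              mode="wave", seed=5)
        a = simg.scan.frames[0] / simg.white_true.data
        b = simw.scan.frames[0] / simw.white_true.data
        sl = slice(10, -10)
        corr = np.corrcoef(a[sl, sl].ravel(), b[sl, sl].ravel())[0, 1]
        assert corr > 0.98
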