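"""Phase gradients, least-squares integration, aberrations, focal propagation."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from pxst.core import PixelMap, initial_pixel_map
from pxst.geometry import ExperimentGeometry
from pxst.integration import gradient as discrete_gradient
from pxst.integration import integrate_gradient as integrate_raw
from pxst.integration import irrotational_projection as project_raw
from pxst.wavefront import (
    gradient_from_map,
    propagate_to_focus,
    ray_angles,
    remove_low_orders,
    remove_low_orders_gradient,
)


def _geometry(n=64, astig=0.0):
    z1 = 0.371e-3
    return ExperimentGeometry(16.7, z1, z1 * (1 + astig), 0.71 - z1, (n, n), 55e-6)


class TestGradientFromMap:
    def test_pure_magnification_gives_spherical_gradient(self):
        g = _geometry()
        u = initial_pixel_map(g)
        grad = gradient_from_map(u, g)
        y, x = g.detector_coords()
        lam = g.wavelength
        expect_x = 2 * np.pi * x / (lam * (g.focus_sample_x + g.sample_detector))
        assert np.allclose(grad[1], expect_x, rtol=1e-10)

    def test_identity_map_is_plane_wave(self):
        g = _geometry()
        y, x = g.detector_coords()
        u = PixelMap(np.stack([y, x]), np.ones(g.detector_shape, bool))
        grad = gradient_from_map(u, g)
        assert np.abs(grad).max() == 0.0

    def test_recovered_gradient_matches_pupil(self, sim_small, fitted_small):
        """Round trip: recovered ray angles match the simulated pupil's.

        The constant (tilt) component is a reconstruction gauge and is
        aligned before comparison.
        """
        res = fitted_small
        lam = res.geometry.wavelength
        theta_rec = res.wavefront.theta
        theta_true = ray_angles(sim_small.pupil.gradient, lam)
        m = res.pixel_map.mask & ~res.flagged
        interior = np.zeros_like(m)
        interior[6:-6, 6:-6] = True  # edge pixels have one-sided coverage
        d = (theta_rec - theta_true)[:, m & interior]
        d = d - d.mean(axis=1, keepdims=True)
        assert np.sqrt((d**2).mean()) < 10e-9  # 10 nrad, noiseless limit


class TestIntegration:
    def test_quadratic_potential_roundtrip(self):
        n = 64
        y, x = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
        phi = 0.01 * (x**2 + 0.5 * y**2 + 0.2 * x * y)
        gy, gx = np.gradient(phi)
        phi2 = integrate_raw(gy, gx, boundary="natural")
        assert np.abs(phi2 - (phi - phi.mean())).max() < 1e-8 * np.ptp(phi)

    def test_random_smooth_field_roundtrip(self, rng):
        phi = gaussian_filter(rng.standard_normal((96, 96)), 8) * 10
        gy, gx = np.gradient(phi)
        phi2 = integrate_raw(gy, gx, boundary="natural")
        g2y, g2x = discrete_gradient(phi2)
        num = np.sqrt(np.mean((g2y - gy) ** 2 + (g2x - gx) ** 2))
        den = np.sqrt(np.mean(gy**2 + gx**2))
        assert num < 1e-6 * den

    def test_linear_gradient_gives_planar_phase(self):
        gy = np.full((32, 32), 0.3)
        gx = np.full((32, 32), -0.7)
        phi = integrate_raw(gy, gx, boundary="natural")
        y, x = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        plane = 0.3 * y - 0.7 * x
        plane -= plane.mean()
        assert np.abs(phi - plane).max() < 1e-8

    def test_curl_free_input_unchanged_by_projection(self, rng):
        phi = gaussian_filter(rng.standard_normal((64, 64)), 6)
        gy, gx = np.gradient(phi)
        py, px = project_raw(gy, gx, boundary="natural")
        rms = np.sqrt(np.mean(gy**2 + gx**2))
        assert np.sqrt(np.mean((py - gy) ** 2 + (px - gx) ** 2)) < 1e-8 * rms

    def test_rotational_field_projects_to_zero_periodic(self):
        n = 128
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        f = np.outer(np.sin(2 * t), np.cos(3 * t)) + 0.5 * np.outer(
            np.cos(5 * t), np.sin(t)
        )
        fy, fx = discrete_gradient(f, boundary="periodic")
        rot_y, rot_x = fx, -fy
        py, px = project_raw(rot_y, rot_x, boundary="periodic")
        ratio = np.sqrt(np.mean(py**2 + px**2)) / np.sqrt(np.mean(rot_y**2 + rot_x**2))
        assert ratio < 1e-6

    def test_projection_idempotent(self, rng):
        gy = gaussian_filter(rng.standard_normal((64, 64)), 4)
        gx = gaussian_filter(rng.standard_normal((64, 64)), 4)
        p1 = project_raw(gy, gx, boundary="periodic")
        p2 = project_raw(*p1, boundary="periodic")
        assert np.abs(p2[0] - p1[0]).max() < 1e-10 * max(np.abs(p1[0]).max(), 1e-30)


class TestRemoveLowOrders:
    def _coords(self, n, pitch):
        c = (np.arange(n) - (n - 1) / 2) * pitch
        return np.meshgrid(c, c, indexing="ij")

    def test_pure_quadratic_removed(self):
        y, x = self._coords(64, 1e-5)
        phi = 5.0 + 3 * x + 2 * y + 4e8 * x**2 + 3e8 * y**2 + 1e8 * x * y
        res, fit = remove_low_orders(phi, 1e-5)
        assert res.std() < 1e-9 * phi.std()

    def test_cubic_survives(self):
        y, x = self._coords(64, 1e-5)
        cubic = 1e12 * x**3
        phi = 4e8 * x**2 + cubic
        res, _ = remove_low_orders(phi, 1e-5)
        # the residual equals the cubic up to its own low-order projection
        expect, _ = remove_low_orders(cubic, 1e-5)
        assert np.abs(res - expect).max() < 1e-6 * np.ptp(cubic)

    def test_spherical_curvature_returns_focus_distance(self):
        lam = 7.424e-11
        r_true = 0.71
        y, x = self._coords(64, 55e-6)
        phi = np.pi * (x**2 + y**2) / (lam * r_true)
        _, fit = remove_low_orders(phi, 55e-6)
        assert fit.focus_distance_x(lam) == pytest.approx(r_true, rel=1e-9)
        assert fit.focus_distance_y(lam) == pytest.approx(r_true, rel=1e-9)

    def test_gradient_low_order_fit_matches_phase_fit(self):
        lam = 7.424e-11
        y, x = self._coords(64, 55e-6)
        gx = 2 * np.pi * x / (lam * 0.7) + 3e3
        gy = 2 * np.pi * y / (lam * 0.75)
        res, fit = remove_low_orders_gradient(np.stack([gy, gx]), 55e-6)
        assert fit.focus_distance_x(lam) == pytest.approx(0.7, rel=1e-6)
        assert fit.focus_distance_y(lam) == pytest.approx(0.75, rel=1e-6)
        # residual is pure discretization noise
        assert np.abs(res).max() < 1e-6 * np.abs(gx).max()


class TestRayAngles:
    def test_flat_phase_zero_angles(self):
        assert np.abs(ray_angles(np.zeros((2, 8, 8)), 7e-11)).max() == 0.0

    def test_spherical_wave_edge_angle_is_na(self):
        g = _geometry()
        from pxst.phantoms import make_pupil_phase

        pup = make_pupil_phase(g)
        theta = ray_angles(pup.gradient, g.wavelength)
        y, x = g.detector_coords()
        r = g.focus_sample_x + g.sample_detector
        assert theta[1][32, -1] == pytest.approx(x[32, -1] / r, rel=1e-12)


class TestPropagateToFocus:
    def setup_method(self):
        n, pitch = 256, 10e-6
        self.n, self.pitch, self.lam = n, pitch, 1e-9
        x = (np.arange(n) - n / 2) * pitch
        yy, xx = np.meshgrid(x, x, indexing="ij")
        self.white = np.exp(-((xx / (0.4 * n * pitch)) ** 4 + (yy / (0.4 * n * pitch)) ** 4))
        self.zero = np.zeros((n, n))

    def test_zero_offset_returns_intensity(self):
        fs = propagate_to_focus(
            self.white, self.zero, self.lam, self.pitch, [0.0], curvature=(0.5, 0.5)
        )
        assert np.abs(fs.planes[0] - self.white).max() < 1e-12

    def test_lens_law_focus_location(self):
        r = 0.5
        offsets = -r + np.linspace(-0.008, 0.008, 33)
        fs = propagate_to_focus(
            self.white, self.zero, self.lam, self.pitch, offsets, curvature=(r, r)
        )
        peaks = [fs.proj_x[k].max() for k in range(len(offsets))]
        best = offsets[int(np.argmax(peaks))]
        spacing = offsets[1] - offsets[0]
        assert abs(best + r) <= spacing

    def test_astigmatic_line_foci_separation(self):
        ry, rx = 0.502, 0.5
        offsets = np.linspace(-0.506, -0.496, 21)
        fs = propagate_to_focus(
            self.white, self.zero, self.lam, self.pitch, offsets, curvature=(ry, rx)
        )
        ox = offsets[int(np.argmax([fs.proj_x[k].max() for k in range(21)]))]
        oy = offsets[int(np.argmax([fs.proj_y[k].max() for k in range(21)]))]
        spacing = offsets[1] - offsets[0]
        assert abs((ox - oy) - (ry - rx)) <= spacing

    def test_energy_conserved_per_plane(self):
        r = 0.5
        fs = propagate_to_focus(
            self.white, self.zero, self.lam, self.pitch, [-0.498], curvature=(r, r)
        )
        e_in = (self.white * self.pitch**2).sum()
        e_out = (fs.planes[0] * fs.pitches[0][0] * fs.pitches[0][1]).sum()
        assert abs(e_out / e_in - 1) < 1e-10

    def test_sampling_violation_raises(self):
        with pytest.raises(ValueError, match="chirp"):
            propagate_to_focus(
                self.white, self.zero, self.lam, self.pitch, [-0.3], curvature=(0.5, 0.5)
            )
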