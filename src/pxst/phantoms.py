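"""Synthetic-data generation: phantoms, aberrated pupils, propagation, scans.

The generator emulates a divergent-beam near-field scan: a single-material
sample phantom (Siemens star or quasi-periodic hexagonal lattice), an
astigmatic pupil phase with a polynomial aberration residual, and the two
forward models used throughout the test-suite —

* ``geometric``: the speckle-tracking forward model evaluated exactly,
  I_n(x) = W(x) * I_ref(u(x) - dx_n), with I_ref the wave-optically
  propagated hologram of the phantom; and
* ``wave``: full Fresnel propagation of the aberrated exit-surface wave to
  the detector via the scaled (magnified) propagation theorem.

Both share ground truth (white field, pixel map, reference), so algorithm
error and model error can be separated.  Poisson noise is applied to the
expected counts with a seeded generator; simulations are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.ndimage import gaussian_filter

from .core import PixelMap, ReferenceImage, ScanData, WhiteField, bilinear_sample
from .geometry import ExperimentGeometry, effective_defocus

__all__ = [
    "MATERIALS",
    "SamplePhantom",
    "PupilPhase",
    "SimulatedScan",
    "make_siemens_star",
    "make_hex_lattice_phantom",
    "make_diffuser",
    "make_pupil_phase",
    "propagate_angular_spectrum",
    "fresnel_propagate_tf",
    "fresnel_single_fft",
    "simulate_scan",
    "siemens_preset",
    "hex_preset",
]

#: Approximate (delta, beta) refractive-index components near 16.5 keV.
MATERIALS: Dict[str, Tuple[float, float]] = {
    "gold": (1.15e-5, 1.1e-6),
    "silica": (1.7e-6, 1.6e-9),
}


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass
class SamplePhantom:
    """Single-material sample on a regular sample-plane grid.

    ``thickness`` (m) is the projected thickness map; the complex
    transmission at wavelength lambda is
    T = exp(-(2*pi/lambda)*(beta + i*delta_r)*thickness).
    """

    thickness: np.ndarray
    pitch: float
    delta_r: float
    beta: float

    @property
    def shape(self):
        return self.thickness.shape

    @property
    def extent(self) -> float:
        return self.shape[0] * self.pitch

    def transmission(self, wavelength: float) -> np.ndarray:
        k = 2 * np.pi / wavelength
        return np.exp(-k * (self.beta + 1j * self.delta_r) * self.thickness)

    def coords(self):
        ny, nx = self.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pitch
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pitch
        return np.meshgrid(y, x, indexing="ij")


def make_siemens_star(
    diameter: float = 10e-6,
    n_spokes: int = 30,
    tip_width: float = 100e-9,
    thickness_range: Tuple[float, float] = (0.5e-6, 1.0e-6),
    cut_radii: Tuple[float, float] = (0.45, 0.75),
    cut_width: float = 200e-9,
    shape: Tuple[int, int] = (1024, 1024),
    pitch: float = 15e-9,
    material: str | Tuple[float, float] = "gold",
    supersample: int = 2,
) -> SamplePhantom:
    """Gold Siemens-star resolution phantom.

    30 radial spokes (even angular duty cycle) with two transparent circular
    cuts, spoke tips of 100 nm facing the centre, projected thickness ramping
    over ``thickness_range`` from tip to rim.  Rendered at ``supersample``-fold
    resolution and block-averaged, which keeps the opaque-area fraction of the
    spoke annulus at 1/2 up to grid quantization.
    """
    delta_r, beta = MATERIALS[material] if isinstance(material, str) else material
    if tip_width >= diameter:
        raise ValueError("tip_width must be smaller than the star diameter")
    if pitch > tip_width / 2:
        warnings.warn(
            "grid pitch coarser than half the spoke tip width; star rendered "
            "then low-pass filtered by one pixel"
        )
    s = max(int(supersample), 1)
    ny, nx = shape
    yy = (np.arange(ny * s) - (ny * s - 1) / 2.0) * (pitch / s)
    xx = (np.arange(nx * s) - (nx * s - 1) / 2.0) * (pitch / s)
    y, x = np.meshgrid(yy, xx, indexing="ij")
    r = np.hypot(y, x)
    theta = np.arctan2(y, x)
    r_out = diameter / 2.0
    # spoke arc width pi*r/n_spokes equals tip_width at the inner radius
    r_in = tip_width * n_spokes / np.pi
    spoke = np.mod(theta * n_spokes / (2 * np.pi), 1.0) < 0.5
    annulus = (r >= r_in) & (r <= r_out)
    opaque = spoke & annulus
    for frac in cut_radii:
        rc = frac * r_out
        opaque &= ~(np.abs(r - rc) < cut_width / 2.0)
    t0, t1 = thickness_range
    ramp = t0 + (t1 - t0) * np.clip((r - r_in) / max(r_out - r_in, 1e-30), 0, 1)
    thick = np.where(opaque, ramp, 0.0)
    if s > 1:
        thick = thick.reshape(ny, s, nx, s).mean(axis=(1, 3))
    if pitch > tip_width / 2:
        thick = gaussian_filter(thick, 1.0)
    return SamplePhantom(thickness=thick, pitch=pitch, delta_r=delta_r, beta=beta)


def make_hex_lattice_phantom(
    lattice_constant: float = 601e-9,
    motif: Optional[dict] = None,
    extent: float = 12e-6,
    pitch: float = 30e-9,
    material: str | Tuple[float, float] = "gold",
    envelope_sigma: Optional[float] = None,
    offset: Tuple[float, float] = (0.0, 0.0),
) -> SamplePhantom:
    """Quasi-periodic hexagonal dot lattice (mis-registration stress test).

    Gaussian dots of peak thickness ``motif['thickness']`` and width
    ``motif['sigma']`` sit on a hexagonal lattice of primitive constant ``a``;
    first-order reciprocal peaks lie at radius 2/(sqrt(3)*a).  An optional
    Gaussian aperiodic envelope and a lattice-frame ``offset`` (m) are
    provided for periodicity tests.
    """
    a = lattice_constant
    if a <= 2 * pitch:
        raise ValueError("lattice constant must exceed two grid pixels")
    motif = dict(motif or {})
    amp = motif.get("thickness", 0.3e-6)
    sig = motif.get("sigma", 0.18 * a)
    delta_r, beta = MATERIALS[material] if isinstance(material, str) else material
    n = int(round(extent / pitch))
    yy = (np.arange(n) - (n - 1) / 2.0) * pitch
    thick = np.zeros((n, n))
    if amp != 0.0:
        # lattice vectors (x, y): a1 = (a, 0), a2 = (a/2, sqrt(3)/2 a)
        a1 = np.array([0.0, a])
        a2 = np.array([a * np.sqrt(3) / 2.0, a / 2.0])
        half = extent / 2.0 + 4 * sig
        kmax = int(np.ceil(2 * half / a)) + 2
        win = int(np.ceil(4 * sig / pitch))
        for i in range(-kmax, kmax + 1):
            for j in range(-kmax, kmax + 1):
                cy = i * a2[0] + offset[0]
                cx = i * a2[1] + j * a1[1] + offset[1]
                if abs(cy) > half or abs(cx) > half:
                    continue
                iy = int(round((cy - yy[0]) / pitch))
                ix = int(round((cx - yy[0]) / pitch))
                lo_y, hi_y = max(iy - win, 0), min(iy + win + 1, n)
                lo_x, hi_x = max(ix - win, 0), min(ix + win + 1, n)
                if lo_y >= hi_y or lo_x >= hi_x:
                    continue
                ys = yy[lo_y:hi_y, None] - cy
                xs = yy[None, lo_x:hi_x] - cx
                thick[lo_y:hi_y, lo_x:hi_x] += amp * np.exp(
                    -(ys**2 + xs**2) / (2 * sig**2)
                )
        if envelope_sigma is not None:
            y, x = np.meshgrid(yy, yy, indexing="ij")
            thick *= np.exp(-(y**2 + x**2) / (2 * envelope_sigma**2))
    return SamplePhantom(thickness=thick, pitch=pitch, delta_r=delta_r, beta=beta)


def make_diffuser(
    extent: float,
    pitch: float,
    feature_size: float = 100e-9,
    thickness_max: float = 0.6e-6,
    material: str | Tuple[float, float] = "gold",
    seed: int = 0,
) -> SamplePhantom:
    """Random smooth phantom (diffuser-like dense speckle object).

    Gaussian-filtered white noise rescaled to [0, thickness_max]; its
    isotropic, detailed and non-repeating modulation makes it the ideal
    wavefront-sensing object (every pixel carries tracking contrast and the
    power spectrum has no angular structure).
    """
    delta_r, beta = MATERIALS[material] if isinstance(material, str) else material
    n = int(round(extent / pitch))
    rng = np.random.default_rng(seed)
    th = gaussian_filter(rng.standard_normal((n, n)), feature_size / pitch)
    th = (th - th.min()) / max(np.ptp(th), 1e-30) * thickness_max
    return SamplePhantom(thickness=th, pitch=pitch, delta_r=delta_r, beta=beta)


# ---------------------------------------------------------------------------
# pupil phase
# ---------------------------------------------------------------------------

@dataclass
class PupilPhase:
    """Ground-truth pupil phase on the detector grid.

    The phase splits into the astigmatic quadratic of the ideal lens,
    pi*(x^2/(lambda*(z1x+z)) + y^2/(lambda*(z1y+z))), plus a polynomial
    residual Sum c[i, j] * X^i * Y^j over normalized coordinates
    X = x/ax, Y = y/ay (half-extents of the detector).  The quadratic is
    stored analytically (its samples alias on the detector grid at hard
    X-ray wavelengths); ``phase_residual`` and the analytic gradient are the
    quantities consumed downstream.
    """

    geometry: ExperimentGeometry
    residual_coeffs: np.ndarray
    support: np.ndarray

    def _norm_coords(self):
        y, x = self.geometry.detector_coords()
        ay = 0.5 * self.geometry.detector_shape[0] * self.geometry.pixel_size
        ax = 0.5 * self.geometry.detector_shape[1] * self.geometry.pixel_size
        return y / ay, x / ax, ay, ax

    @property
    def phase_residual(self) -> np.ndarray:
        ynorm, xnorm, _, _ = self._norm_coords()
        return P.polyval2d(xnorm, ynorm, self.residual_coeffs)

    def residual_at(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Residual phase at arbitrary physical detector coordinates."""
        _, _, ay, ax = self._norm_coords()
        return P.polyval2d(x / ax, y / ay, self.residual_coeffs)

    @property
    def phase(self) -> np.ndarray:
        """Full phase samples (quadratic + residual); beware grid aliasing."""
        g = self.geometry
        y, x = g.detector_coords()
        lam = g.wavelength
        z = g.sample_detector
        quad = np.pi * (
            x**2 / (lam * (g.focus_sample_x + z)) + y**2 / (lam * (g.focus_sample_y + z))
        )
        return quad + self.phase_residual

    @property
    def gradient(self) -> np.ndarray:
        """Analytic (d/dy, d/dx) of the full phase, shape (2, R, C), rad/m."""
        g = self.geometry
        y, x = g.detector_coords()
        lam = g.wavelength
        z = g.sample_detector
        gy = 2 * np.pi * y / (lam * (g.focus_sample_y + z))
        gx = 2 * np.pi * x / (lam * (g.focus_sample_x + z))
        ynorm, xnorm, ay, ax = self._norm_coords()
        c = self.residual_coeffs
        if c.size > 1:
            gx = gx + P.polyval2d(xnorm, ynorm, P.polyder(c, axis=0)) / ax
            gy = gy + P.polyval2d(xnorm, ynorm, P.polyder(c, axis=1)) / ay
        return np.stack([gy, gx])

    def true_pixel_map(self) -> PixelMap:
        """u(x) = x - (lambda*z/(2*pi)) * grad(Phi), the ground-truth map."""
        g = self.geometry
        y, x = g.detector_coords()
        s = g.wavelength * g.sample_detector / (2 * np.pi)
        grad = self.gradient
        u = np.stack([y - s * grad[0], x - s * grad[1]])
        return PixelMap(u, self.support.copy())


def make_pupil_phase(
    geometry: ExperimentGeometry,
    residual_coeffs: Optional[np.ndarray] = None,
) -> PupilPhase:
    """Astigmatic quadratic pupil plus polynomial aberration residual."""
    if residual_coeffs is None:
        residual_coeffs = np.zeros((1, 1))
    residual_coeffs = np.atleast_2d(np.asarray(residual_coeffs, dtype=float))
    if not np.all(np.isfinite(residual_coeffs)):
        raise ValueError("residual coefficients must be finite")
    support = np.ones(geometry.detector_shape, dtype=bool)
    return PupilPhase(geometry=geometry, residual_coeffs=residual_coeffs, support=support)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def _check_tf_sampling(shape, pitch, wavelength, distance):
    nmin = min(shape)
    zmax = nmin * pitch**2 / wavelength
    if abs(distance) > zmax:
        raise ValueError(
            f"propagation distance {distance:.3e} m aliases the transfer "
            f"function at pitch {pitch:.3e} m; |z| must be <= {zmax:.3e} m "
            "(increase the grid or the pitch)"
        )


def propagate_angular_spectrum(
    fieldarr: np.ndarray, pitch: float, distance: float, wavelength: float
) -> np.ndarray:
    """Exact free-space angular-spectrum propagation on a fixed grid.

    Energy is conserved (unit-modulus transfer function; evanescent
    components are suppressed).  Raises when the requested distance violates
    the transfer-function sampling bound, naming the maximum safe distance.
    """
    if distance == 0:
        return fieldarr.copy()
    _check_tf_sampling(fieldarr.shape, pitch, wavelength, distance)
    ny, nx = fieldarr.shape
    fy = np.fft.fftfreq(ny, d=pitch)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch)[None, :]
    arg = 1.0 / wavelength**2 - fy**2 - fx**2
    kz = 2 * np.pi * np.sqrt(np.maximum(arg, 0.0))
    h = np.where(arg > 0, np.exp(1j * distance * kz), 0.0)
    return np.fft.ifft2(np.fft.fft2(fieldarr) * h)


def fresnel_propagate_tf(
    fieldarr: np.ndarray,
    pitch: float,
    wavelength: float,
    distance_y: float,
    distance_x: Optional[float] = None,
) -> np.ndarray:
    """Paraxial Fresnel propagation with independent per-axis distances.

    The separable transfer function exp(-i*pi*lambda*(zy*fy^2 + zx*fx^2))
    implements the effective-defocus propagation of an astigmatic system on a
    fixed grid.
    """
    if distance_x is None:
        distance_x = distance_y
    if distance_y == 0 and distance_x == 0:
        return fieldarr.copy()
    _check_tf_sampling(fieldarr.shape, pitch, wavelength, max(abs(distance_y), abs(distance_x)))
    ny, nx = fieldarr.shape
    fy = np.fft.fftfreq(ny, d=pitch)[:, None]
    fx = np.fft.fftfreq(nx, d=pitch)[None, :]
    h = np.exp(-1j * np.pi * wavelength * (distance_y * fy**2 + distance_x * fx**2))
    return np.fft.ifft2(np.fft.fft2(fieldarr) * h)


def fresnel_single_fft(
    fieldarr: np.ndarray,
    pitch: float,
    wavelength: float,
    distance_y: float,
    distance_x: Optional[float] = None,
):
    """Single-FFT (scaled-grid) Fresnel transform, per-axis distances.

    Returns (field_out, (pitch_y, pitch_x)): the output grid pitch is
    lambda*|d|/(N*pitch) per axis, so this form suits strongly diffracting
    (far/focal-region) propagation.  Negative distances use the inverse
    transform sign.  Energy Sum|U|^2*pitch^2 is conserved exactly.
    """
    if distance_x is None:
        distance_x = distance_y
    if distance_y == 0 or distance_x == 0:
        raise ValueError("single-FFT Fresnel transform requires nonzero distances")
    ny, nx = fieldarr.shape
    y = (np.arange(ny) - ny / 2.0)[:, None] * pitch
    x = (np.arange(nx) - nx / 2.0)[None, :] * pitch
    chirp = np.exp(
        1j * np.pi * (y**2 / (wavelength * distance_y) + x**2 / (wavelength * distance_x))
    )
    g = np.fft.ifftshift(fieldarr * chirp)
    g = np.fft.fft(g, axis=0) if distance_y > 0 else np.fft.ifft(g, axis=0) * ny
    g = np.fft.fft(g, axis=1) if distance_x > 0 else np.fft.ifft(g, axis=1) * nx
    g = np.fft.fftshift(g)
    py = wavelength * abs(distance_y) / (ny * pitch)
    px = wavelength * abs(distance_x) / (nx * pitch)
    yo = (np.arange(ny) - ny / 2.0)[:, None] * py
    xo = (np.arange(nx) - nx / 2.0)[None, :] * px
    out_chirp = np.exp(
        1j * np.pi * (yo**2 / (wavelength * distance_y) + xo**2 / (wavelength * distance_x))
    )
    # with unnormalized FFTs, Sum|F|^2 = ny*nx*Sum|f|^2 while
    # py*px = lambda^2*|dy*dx|/(ny*nx*pitch^2); this scale makes
    # Sum|out|^2*py*px == Sum|in|^2*pitch^2 exactly
    scale = pitch**2 / (wavelength * np.sqrt(abs(distance_y) * abs(distance_x)))
    return g * out_chirp * scale, (py, px)


# ---------------------------------------------------------------------------
# scan simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedScan:
    """A simulated scan together with its ground truth."""

    scan: ScanData
    white_true: WhiteField
    pixel_map_true: PixelMap
    reference_true: ReferenceImage
    pupil: PupilPhase
    phantom: SamplePhantom
    mode: str
    flux: Optional[float]
    seed: Optional[int]


def _white_envelope(geometry: ExperimentGeometry, kind: str) -> np.ndarray:
    ny, nx = geometry.detector_shape
    if kind == "uniform":
        return np.ones((ny, nx))
    yn = np.linspace(-1, 1, ny)[:, None]
    xn = np.linspace(-1, 1, nx)[None, :]
    # smooth low-order illumination structure (upstream-optics envelope)
    env = 1.0 + 0.10 * xn - 0.08 * yn - 0.18 * (xn**2 + yn**2) / 2.0 + 0.05 * xn * yn
    return env / env.max()


def _true_reference(phantom: SamplePhantom, geometry: ExperimentGeometry) -> ReferenceImage:
    lam = geometry.wavelength
    zby = effective_defocus(geometry.focus_sample_y, geometry.sample_detector)
    zbx = effective_defocus(geometry.focus_sample_x, geometry.sample_detector)
    t = phantom.transmission(lam)
    psi = fresnel_propagate_tf(t, phantom.pitch, lam, zby, zbx)
    data = np.abs(psi) ** 2
    ny, nx = data.shape
    origin = (-(ny - 1) / 2.0 * phantom.pitch, -(nx - 1) / 2.0 * phantom.pitch)
    return ReferenceImage(data=data, pitch=phantom.pitch, origin=origin)


def default_scan_positions(
    geometry: ExperimentGeometry,
    scan_shape: Tuple[int, int] = (9, 9),
    step: Optional[float] = None,
    jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Centred 2D raster of translations (y, x) in metres, optional jitter."""
    if step is None:
        step = 20.0 * geometry.demagnified_pixel
    sy, sx = scan_shape
    ys = (np.arange(sy) - (sy - 1) / 2.0) * step
    xs = (np.arange(sx) - (sx - 1) / 2.0) * step
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pos = np.stack([gy.ravel(), gx.ravel()], axis=1)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        pos = pos + rng.uniform(-jitter, jitter, size=pos.shape) * step
    return pos


def simulate_scan(
    phantom: SamplePhantom,
    pupil: PupilPhase,
    geometry: ExperimentGeometry,
    positions: Optional[np.ndarray] = None,
    scan_shape: Tuple[int, int] = (9, 9),
    step: Optional[float] = None,
    flux: Optional[float] = None,
    mode: str = "geometric",
    illumination: str = "smooth",
    jitter: float = 0.0,
    seed: Optional[int] = None,
) -> SimulatedScan:
    """Simulate a near-field scan of ``phantom`` under the aberrated pupil.

    ``flux`` is the peak expected count per pixel (None = noiseless, unit
    white field).  ``mode='geometric'`` evaluates the speckle-tracking
    forward model exactly (the oracle for the reconstruction engine);
    ``mode='wave'`` performs full Fresnel propagation of the shifted
    exit-surface wave via the scaled-propagation theorem.
    """
    rng = np.random.default_rng(seed)
    lam = geometry.wavelength
    z = geometry.sample_detector
    if positions is None:
        positions = default_scan_positions(geometry, scan_shape, step, jitter, rng)
    positions = np.asarray(positions, dtype=float)
    half = phantom.extent / 2.0
    if np.abs(positions).max() > half:
        raise ValueError("scan positions exceed the phantom extent")

    scale = 1.0 if flux is None else float(flux)
    w_data = scale * _white_envelope(geometry, illumination)
    white = WhiteField(data=w_data, mask=np.ones(geometry.detector_shape, dtype=bool))
    umap = pupil.true_pixel_map()
    ref = _true_reference(phantom, geometry)

    n = positions.shape[0]
    frames = np.empty((n,) + tuple(geometry.detector_shape))

    if mode == "geometric":
        for k in range(n):
            ci = (umap.u[0] - positions[k, 0] - ref.origin[0]) / ref.pitch
            cj = (umap.u[1] - positions[k, 1] - ref.origin[1]) / ref.pitch
            pred, valid = bilinear_sample(ref.data, ci, cj)
            frames[k] = w_data * np.where(valid, pred, 1.0)
    elif mode == "wave":
        frames = _simulate_wave_frames(phantom, pupil, geometry, positions, w_data, scale)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if flux is not None:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)

    scan = ScanData(
        frames=frames,
        translations=positions,
        mask=np.ones(geometry.detector_shape, dtype=bool),
        geometry=geometry,
    )
    return SimulatedScan(
        scan=scan,
        white_true=white,
        pixel_map_true=umap,
        reference_true=ref,
        pupil=pupil,
        phantom=phantom,
        mode=mode,
        flux=flux,
        seed=seed,
    )


def _simulate_wave_frames(phantom, pupil, geometry, positions, w_data, scale):
    """Full Fresnel frames via the scaled-propagation (magnifier) theorem.

    The exit wave a(xi)*exp(i*phi_res(M*xi))*T(xi - dx) is propagated by the
    per-axis effective defocus on the sample-plane grid; the detector image
    is the magnified intensity times nothing else (the white-field envelope
    is carried inside the amplitude a).
    """
    lam = geometry.wavelength
    z = geometry.sample_detector
    my = geometry.magnification_y
    mx = geometry.magnification_x
    zby = effective_defocus(geometry.focus_sample_y, z)
    zbx = effective_defocus(geometry.focus_sample_x, z)
    ys, xs = phantom.coords()
    # illumination amplitude and residual phase mapped to the sample plane
    env_det = w_data / w_data.max()
    ny, nx = geometry.detector_shape
    ci = (ys * my) / geometry.pixel_size + (ny - 1) / 2.0
    cj = (xs * mx) / geometry.pixel_size + (nx - 1) / 2.0
    env_s, valid = bilinear_sample(env_det, ci, cj)
    env_s = np.where(valid, env_s, 0.0)
    phi_res_s = pupil.residual_at(ys * my, xs * mx)
    illum = np.sqrt(np.clip(env_s, 0, None)) * np.exp(1j * phi_res_s)

    yd, xd = geometry.detector_coords()
    n = positions.shape[0]
    frames = np.empty((n, ny, nx))
    thick = phantom.thickness
    npx = thick.shape
    for k in range(n):
        # shift the phantom by interpolating its thickness map
        si = (ys - positions[k, 0] - ys[0, 0]) / phantom.pitch
        sj = (xs - positions[k, 1] - xs[0, 0]) / phantom.pitch
        tsh, valid = bilinear_sample(thick, si, sj)
        tsh = np.where(valid, tsh, 0.0)
        kw = 2 * np.pi / lam
        t = np.exp(-kw * (phantom.beta + 1j * phantom.delta_r) * tsh)
        psi = fresnel_propagate_tf(illum * t, phantom.pitch, lam, zby, zbx)
        inten = np.abs(psi) ** 2
        # sample the magnified intensity on the detector grid
        ci = (yd / my - ys[0, 0]) / phantom.pitch
        cj = (xd / mx - xs[0, 0]) / phantom.pitch
        vals, valid = bilinear_sample(inten, ci, cj)
        frames[k] = scale * np.where(valid, vals, 0.0)
    return frames


# ---------------------------------------------------------------------------
# presets (desk-scale study conditions)
# ---------------------------------------------------------------------------

def _scaled_residual_coeffs(
    geometry: ExperimentGeometry, base: np.ndarray, target_distortion_px: float
) -> np.ndarray:
    """Rescale a residual-aberration pattern to a target map distortion.

    The distortion is the displacement (lambda*z/(2*pi))*grad(phi_res)
    expressed in demagnified pixels; the base polynomial is scaled so its
    maximum over the detector equals ``target_distortion_px``.
    """
    if target_distortion_px == 0:
        return np.zeros((1, 1))
    probe = make_pupil_phase(geometry, base)
    quad_only = make_pupil_phase(geometry, None)
    disp = probe.true_pixel_map().u - quad_only.true_pixel_map().u
    dmax = np.abs(disp).max() / geometry.demagnified_pixel
    return base * (target_distortion_px / max(dmax, 1e-30))


_BASE_RESIDUAL = np.array(
    [
        # c[i, j] multiplies X^i * Y^j (X horizontal, Y vertical, normalized)
        [0.0, 0.0, 0.0, -0.7],
        [0.0, 0.6, -0.5, 0.0],
        [0.0, 0.45, 0.0, 0.0],
        [1.0, 0.0, 0.0, 0.0],
    ]
)


def siemens_preset(
    n_det: int = 256,
    scan_shape: Tuple[int, int] = (9, 9),
    astigmatism: float = 0.04,
    distortion_px: float = 4.0,
    flux: Optional[float] = None,
    mode: str = "geometric",
    seed: int = 0,
    step: Optional[float] = None,
    illumination: str = "smooth",
    phantom_pitch: Optional[float] = None,
) -> SimulatedScan:
    """Siemens-star study conditions at desk scale.

    Geometry follows the high-magnification configuration (16.7 keV, focus-
    sample 0.371 mm, sample-detector ~0.71 m, 55 um pixels) on an ``n_det``^2
    region of interest; the pupil carries a mild astigmatism and a polynomial
    residual scaled to ``distortion_px`` demagnified pixels of map distortion.
    """
    z1 = 0.371e-3
    geometry = ExperimentGeometry(
        photon_energy=16.7,
        focus_sample_x=z1,
        focus_sample_y=z1 * (1 + astigmatism),
        sample_detector=0.71 - z1,
        detector_shape=(n_det, n_det),
        pixel_size=55e-6,
    )
    if step is None:
        step = 20.0 * geometry.demagnified_pixel
    # phantom grid: half the demagnified pixel, covering FOV + scan + margin
    pitch = phantom_pitch or geometry.demagnified_pixel / 2.0
    sy, sx = scan_shape
    need = geometry.field_of_view + step * max(sy, sx) + 2e-6
    npix = int(2 ** np.ceil(np.log2(need / pitch)))
    star = make_siemens_star(shape=(npix, npix), pitch=pitch)
    coeffs = _scaled_residual_coeffs(geometry, _BASE_RESIDUAL, distortion_px)
    pupil = make_pupil_phase(geometry, coeffs)
    return simulate_scan(
        star, pupil, geometry,
        scan_shape=scan_shape, step=step, flux=flux, mode=mode,
        illumination=illumination, seed=seed,
    )


def hex_preset(
    n_det: int = 160,
    scan_shape: Tuple[int, int] = (5, 5),
    lattice_constant: float = 601e-9,
    distortion_px: float = 4.2,
    flux: Optional[float] = 1500.0,
    seed: int = 2,
    mode: str = "geometric",
) -> SimulatedScan:
    """Quasi-periodic hexagonal-lattice study conditions at desk scale.

    The geometry puts one lattice constant at ~9 demagnified pixels; the
    injected aberration distortion (4.2 px) approaches half a lattice
    constant and the Poisson noise (1500 peak counts) triggers scattered
    lattice-vector mis-registrations in unregularized per-pixel tracking —
    the failure mode that the 20 -> 0 px Gaussian annealing schedule is
    designed to suppress.  A Gaussian aperiodic envelope keeps the global
    registration anchored.
    """
    z1 = 1.56e-3
    geometry = ExperimentGeometry(
        photon_energy=16.3,
        focus_sample_x=z1,
        focus_sample_y=z1,
        sample_detector=1.32 - z1,
        detector_shape=(n_det, n_det),
        pixel_size=55e-6,
    )
    step = 12.0 * geometry.demagnified_pixel
    pitch = geometry.demagnified_pixel / 2.0
    sy, sx = scan_shape
    need = geometry.field_of_view + step * max(sy, sx) + 2e-6
    npix = int(2 ** np.ceil(np.log2(need / pitch)))
    phantom = make_hex_lattice_phantom(
        lattice_constant=lattice_constant,
        extent=npix * pitch,
        pitch=pitch,
        motif={"thickness": 0.35e-6, "sigma": 0.18 * lattice_constant},
        envelope_sigma=0.8 * geometry.field_of_view,
    )
    base = np.zeros((4, 4))
    base[3, 0] = 1.0
    base[0, 3] = -0.8
    coeffs = _scaled_residual_coeffs(geometry, base, distortion_px)
    pupil = make_pupil_phase(geometry, coeffs)
    return simulate_scan(
        phantom, pupil, geometry, scan_shape=scan_shape, step=step,
        flux=flux, mode=mode, seed=seed,
    )
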