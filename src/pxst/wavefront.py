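"""Wavefront analysis: phase gradients, integration, aberrations, focus.

The pixel map recovered by speckle tracking encodes the detector-plane
phase gradient through

    u(x) = x - (lambda*z/(2*pi)) * grad(Phi)(x),

so grad(Phi) = (2*pi/(lambda*z))*(x - u(x)).  The gradient splits into an
affine part — a tilt plus the astigmatic defocus quadratic, whose fitted
curvature returns refined focus distances — and a residual that is
integrated (least squares, zero-mean gauge) into the residual phase map of
the lens.  Ray angles are Theta = (lambda/(2*pi))*grad(Phi); the wavefield
sqrt(W)*exp(i*Phi) can be propagated to the focal region with scaled
single-FFT Fresnel transforms (the dominant quadratic is handled
analytically, since its direct samples alias on any real detector grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import PixelMap
from .geometry import ExperimentGeometry
from .integration import integrate_gradient as _integrate
from .integration import irrotational_projection as _project
from .phantoms import fresnel_single_fft

__all__ = [
    "WavefrontField",
    "LowOrderFit",
    "gradient_from_map",
    "integrate_gradient",
    "irrotational_projection",
    "remove_low_orders",
    "remove_low_orders_gradient",
    "ray_angles",
    "propagate_to_focus",
    "FocusStack",
]


def gradient_from_map(pixel_map: PixelMap, geometry: ExperimentGeometry) -> np.ndarray:
    """Phase gradient (d/dy, d/dx) in rad/m from the pixel map."""
    y, x = geometry.detector_coords()
    s = 2 * np.pi / (geometry.wavelength * geometry.sample_detector)
    return np.stack([s * (y - pixel_map.u[0]), s * (x - pixel_map.u[1])])


def integrate_gradient(
    grad: np.ndarray,
    pitch: float = 1.0,
    boundary: str = "natural",
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Least-squares 2D integral of (g_y, g_x), zero-mean gauge.

    ``grad`` has shape (2, R, C) in rad/m; the result is in rad when
    ``pitch`` is the grid pitch in metres.
    """
    return _integrate(grad[0] * pitch, grad[1] * pitch, spacing=1.0, boundary=boundary, mask=mask)


def irrotational_projection(
    grad: np.ndarray, boundary: str = "natural", mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Project a gradient field onto the curl-free (integrable) fields."""
    gy, gx = _project(grad[0], grad[1], boundary=boundary, mask=mask)
    return np.stack([gy, gx])


@dataclass
class LowOrderFit:
    """Constant + tilt + quadratic components of a phase map.

    ``coeffs`` are on normalized coordinates (X = x/ax, Y = y/ay in [-1, 1]);
    the physical curvatures c_xx = d^2 Phi / dx^2 / 2 etc. convert to focus
    distances through c = pi/(lambda*R) for a spherical wave
    pi*x^2/(lambda*R).
    """

    coeffs: dict
    curvature_x: float
    curvature_y: float
    half_extent: Tuple[float, float]

    def focus_distance_x(self, wavelength: float) -> float:
        """R_x = z1x + z implied by the fitted x^2 coefficient."""
        return np.pi / (wavelength * self.curvature_x)

    def focus_distance_y(self, wavelength: float) -> float:
        return np.pi / (wavelength * self.curvature_y)


def _norm_coords(shape, pitch):
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    ay = max(y.max(), pitch)
    ax = max(x.max(), pitch)
    yy, xx = np.meshgrid(y / ay, x / ax, indexing="ij")
    return yy, xx, ay, ax


def remove_low_orders(
    phi: np.ndarray, pitch: float = 1.0, mask: Optional[np.ndarray] = None
):
    """Subtract the fitted constant, tilt and quadratic from a phase map.

    Returns (phi_residual, LowOrderFit).  The quadratic coefficients yield
    refined effective focus distances (defocus aberrations); the residual is
    the deviation of the lens from an ideal astigmatic quadratic.
    """
    phi = np.asarray(phi, dtype=float)
    yy, xx, ay, ax = _norm_coords(phi.shape, pitch)
    if mask is None:
        mask = np.ones(phi.shape, dtype=bool)
    if mask.sum() < 6:
        raise ValueError("mask too small for a 6-parameter low-order fit")
    basis = np.stack(
        [np.ones_like(xx), xx, yy, xx**2, yy**2, xx * yy], axis=-1
    )[mask]
    sol, *_ = np.linalg.lstsq(basis, phi[mask], rcond=None)
    fitted = np.stack([np.ones_like(xx), xx, yy, xx**2, yy**2, xx * yy], axis=-1) @ sol
    names = ["c0", "cx", "cy", "cxx", "cyy", "cxy"]
    coeffs = dict(zip(names, sol))
    fit = LowOrderFit(
        coeffs=coeffs,
        curvature_x=coeffs["cxx"] / ax**2,
        curvature_y=coeffs["cyy"] / ay**2,
        half_extent=(ay, ax),
    )
    return phi - fitted, fit


def remove_low_orders_gradient(
    grad: np.ndarray, pitch: float, mask: Optional[np.ndarray] = None
):
    """Fit and subtract the gradient of a quadratic phase from (g_y, g_x).

    The model g_x = tx + 2*cxx*x + cxy*y, g_y = ty + cxy*x + 2*cyy*y (shared
    cross term, in physical units) is fitted jointly; removing it from the
    gradient before integration avoids integrating the numerically huge
    defocus term.  Returns (residual_grad, LowOrderFit).
    """
    ny, nx = grad.shape[1:]
    yy, xx, ay, ax = _norm_coords((ny, nx), pitch)
    y = yy * ay
    x = xx * ax
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    zeros = np.zeros(int(mask.sum()))
    ones = np.ones(int(mask.sum()))
    xm = x[mask]
    ym = y[mask]
    # unknowns: [tx, ty, cxx, cyy, cxy]
    ax_rows = np.stack([ones, zeros, 2 * xm, zeros, ym], axis=-1)
    ay_rows = np.stack([zeros, ones, zeros, 2 * ym, xm], axis=-1)
    a = np.concatenate([ax_rows, ay_rows])
    b = np.concatenate([grad[1][mask], grad[0][mask]])
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    tx, ty, cxx, cyy, cxy = sol
    fit_gx = tx + 2 * cxx * x + cxy * y
    fit_gy = ty + 2 * cyy * y + cxy * x
    residual = np.stack([grad[0] - fit_gy, grad[1] - fit_gx])
    coeffs = {
        "c0": 0.0,
        "cx": tx * ax,
        "cy": ty * ay,
        "cxx": cxx * ax**2,
        "cyy": cyy * ay**2,
        "cxy": cxy * ax * ay,
    }
    fit = LowOrderFit(
        coeffs=coeffs, curvature_x=cxx, curvature_y=cyy, half_extent=(ay, ax)
    )
    return residual, fit


def ray_angles(grad: np.ndarray, wavelength: float) -> np.ndarray:
    """Local ray angles Theta = (lambda/(2*pi))*grad(Phi), componentwise."""
    return wavelength / (2 * np.pi) * np.asarray(grad)


@dataclass
class WavefrontField:
    """Recovered wavefield on the detector grid.

    ``grad`` is the full (curl-free) phase gradient in rad/m; ``phi_res`` is
    the residual phase after removing constant, tilt and the astigmatic
    defocus quadratic (zero-mean gauge); ``low_order`` carries the fitted
    quadratic, whose curvatures give refined focus distances; ``theta`` are
    the ray angles.
    """

    white_field: np.ndarray
    grad: np.ndarray
    phi_res: np.ndarray
    theta: np.ndarray
    low_order: LowOrderFit
    pitch: float
    mask: np.ndarray
    geometry: ExperimentGeometry

    @classmethod
    def from_pixel_map(
        cls,
        pixel_map: PixelMap,
        white: np.ndarray,
        geometry: ExperimentGeometry,
        boundary: str = "natural",
        project: bool = True,
    ) -> "WavefrontField":
        grad = gradient_from_map(pixel_map, geometry)
        res_raw, fit = remove_low_orders_gradient(grad, geometry.pixel_size, pixel_map.mask)
        affine = grad - res_raw
        res = (
            irrotational_projection(res_raw, boundary=boundary, mask=pixel_map.mask)
            if project
            else res_raw
        )
        full = affine + res
        phi_res = integrate_gradient(res, pitch=geometry.pixel_size, boundary=boundary,
                                     mask=pixel_map.mask)
        return cls(
            white_field=np.asarray(white, dtype=float),
            grad=full,
            phi_res=phi_res,
            theta=ray_angles(full, geometry.wavelength),
            low_order=fit,
            pitch=geometry.pixel_size,
            mask=pixel_map.mask.copy(),
            geometry=geometry,
        )

    def refined_focus_sample_x(self) -> float:
        """z1x implied by the fitted defocus curvature (R_x - z)."""
        return self.low_order.focus_distance_x(self.geometry.wavelength) - \
            self.geometry.sample_detector

    def refined_focus_sample_y(self) -> float:
        return self.low_order.focus_distance_y(self.geometry.wavelength) - \
            self.geometry.sample_detector


@dataclass
class FocusStack:
    """Intensity planes near focus with axial projections.

    ``planes[k]`` is the intensity at propagation ``offsets[k]`` (m, negative
    = upstream of the detector) on a grid of pitch ``pitches[k]``;
    ``proj_x``/``proj_y`` are linear energy densities (per metre) resampled
    onto the common transverse grids ``axis_x``/``axis_y``.
    """

    offsets: np.ndarray
    planes: list
    pitches: list
    proj_x: np.ndarray
    proj_y: np.ndarray
    axis_x: np.ndarray
    axis_y: np.ndarray


def propagate_to_focus(
    white: np.ndarray,
    phi_res: np.ndarray,
    wavelength: float,
    pitch: float,
    offsets: Sequence[float],
    curvature: Optional[Tuple[float, float]] = None,
    mask: Optional[np.ndarray] = None,
) -> FocusStack:
    """Propagate sqrt(W)*exp(i*Phi) to planes near the focal region.

    ``curvature`` = (R_y, R_x) are the spherical-wave radii of the quadratic
    phase component (for a lens, R_a = z1a + z); it is combined analytically
    with the Fresnel chirp, so only the smooth residual ``phi_res`` is ever
    sampled.  When ``curvature`` is None the quadratic is fitted from
    ``phi_res`` and removed first.  Offsets are signed propagation distances
    from the detector (m); a zero offset returns the detector intensity
    itself.  Raises when an offset violates the chirp sampling bound, naming
    the safe range.
    """
    w = np.clip(np.asarray(white, dtype=float), 0, None)
    phi_res = np.asarray(phi_res, dtype=float)
    if mask is not None:
        w = np.where(mask, w, 0.0)
        phi_res = np.where(mask, phi_res, 0.0)
    if curvature is None:
        phi_res, fit = remove_low_orders(phi_res, pitch)
        ry = fit.focus_distance_y(wavelength)
        rx = fit.focus_distance_x(wavelength)
    else:
        ry, rx = curvature
    amp = np.sqrt(w) * np.exp(1j * phi_res)
    ny, nx = amp.shape
    y = (np.arange(ny) - ny / 2.0)[:, None] * pitch
    x = (np.arange(nx) - nx / 2.0)[None, :] * pitch
    ymax = max(abs(y).max(), pitch)
    xmax = max(abs(x).max(), pitch)

    planes, pitches = [], []
    for d in offsets:
        if d == 0:
            planes.append(w.copy())
            pitches.append((pitch, pitch))
            continue
        # combined chirp 1/R + 1/d must stay sampled: phase step < pi at edge
        ky = abs(1.0 / ry + 1.0 / d)
        kx = abs(1.0 / rx + 1.0 / d)
        ky_max = wavelength / (2 * ymax * pitch)
        kx_max = wavelength / (2 * xmax * pitch)
        if ky > ky_max or kx > kx_max:
            raise ValueError(
                f"offset {d:.4e} m aliases the residual chirp; |1/R + 1/d| must "
                f"stay below {min(ky_max, kx_max):.4e} 1/m (planes too far from "
                "the focal region for this grid)"
            )
        chirped = amp * np.exp(
            1j * np.pi / wavelength * (y**2 * (1.0 / ry) + x**2 * (1.0 / rx))
        )
        out, (py, px) = fresnel_single_fft(chirped, pitch, wavelength, d)
        planes.append(np.abs(out) ** 2)
        pitches.append((py, px))

    # common transverse grids from the smallest-pitch plane
    py_ref = min(p[0] for p in pitches)
    px_ref = min(p[1] for p in pitches)
    axis_y = (np.arange(ny) - ny / 2.0) * py_ref
    axis_x = (np.arange(nx) - nx / 2.0) * px_ref
    proj_x = np.zeros((len(planes), nx))
    proj_y = np.zeros((len(planes), ny))
    for k, (pl, (py, px)) in enumerate(zip(planes, pitches)):
        # linear energy densities (energy per metre along the kept axis)
        lx = pl.sum(axis=0) * py  # column energy per metre along x
        ly = pl.sum(axis=1) * px
        xsrc = (np.arange(nx) - nx / 2.0) * px
        ysrc = (np.arange(ny) - ny / 2.0) * py
        proj_x[k] = np.interp(axis_x, xsrc, lx, left=0, right=0)
        proj_y[k] = np.interp(axis_y, ysrc, ly, left=0, right=0)
    return FocusStack(
        offsets=np.asarray(list(offsets), dtype=float),
        planes=planes,
        pitches=pitches,
        proj_x=proj_x,
        proj_y=proj_y,
        axis_x=axis_x,
        axis_y=axis_y,
    )
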