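"""Sample analysis on the reference hologram: thickness retrieval, resolution.

The reference image is a plane-wave-equivalent in-line hologram recorded at
the effective defocus zbar.  For a single-material sample two standard
inversions recover the projected thickness:

* TIE (Paganin single-material form) — a low-pass filtered logarithm, exact
  in the large-Fresnel-number (edge projection) limit;
* CTF inversion — Fourier deconvolution of the weak-object contrast transfer
  function [delta_r*sin(chi) + beta*cos(chi)], chi = pi*lambda*zbar*f^2,
  Tikhonov-regularized at the transfer zeros, exact for weak objects.

Image resolution is quantified by the azimuthally averaged Fourier power
spectrum (FPS): the noise floor is the mean of the final 30 radial bins and
the cut-off is the highest frequency at which the FPS still exceeds twice
that floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phantoms import MATERIALS

__all__ = [
    "ThicknessMap",
    "ResolutionReport",
    "tie_thickness",
    "ctf_thickness",
    "ctf_forward_image",
    "fps_resolution",
    "DegenerateContrastError",
]


class DegenerateContrastError(ValueError):
    """The contrast transfer function vanishes identically (no inversion)."""


@dataclass
class ThicknessMap:
    """Projected thickness (m) on the reference grid."""

    thickness: np.ndarray
    pitch: float
    delta_r: float
    beta: float
    mu: float
    n_clipped: int = 0
    method: str = ""


@dataclass
class ResolutionReport:
    """Azimuthal FPS with noise floor and cut-off resolutions."""

    frequency: np.ndarray
    power: np.ndarray
    noise_floor: float
    cutoff_frequency: float
    full_period: float
    half_period: float
    floor_defined: bool = True


def _freq_grids(shape, pitch):
    fy = np.fft.fftfreq(shape[0], d=pitch)[:, None]
    fx = np.fft.fftfreq(shape[1], d=pitch)[None, :]
    return fy, fx


def _resolve_material(material, delta_r, beta):
    if material is not None:
        return MATERIALS[material]
    if delta_r is None or beta is None:
        raise ValueError("provide a material name or both delta_r and beta")
    return delta_r, beta


def tie_thickness(
    image: np.ndarray,
    wavelength: float,
    zbar: float,
    pitch: float,
    material: Optional[str] = None,
    delta_r: Optional[float] = None,
    beta: Optional[float] = None,
) -> ThicknessMap:
    """Single-material TIE (Paganin) thickness retrieval.

    t = -(1/mu) * ln( F^-1[ F[I/I0] / (1 + (zbar*delta_r/mu)*|k|^2) ] ),
    mu = 4*pi*beta/lambda, |k| = 2*pi*f.  Non-positive filtered intensities
    are clipped (counted in ``n_clipped``).  Best at large Fresnel numbers.
    """
    delta_r, beta = _resolve_material(material, delta_r, beta)
    if beta <= 0:
        raise ValueError("TIE single-material inversion needs beta > 0")
    mu = 4 * np.pi * beta / wavelength
    img = np.asarray(image, dtype=float)
    fy, fx = _freq_grids(img.shape, pitch)
    k2 = (2 * np.pi) ** 2 * (fy**2 + fx**2)
    filt = 1.0 / (1.0 + zbar * delta_r / mu * k2)
    sm = np.fft.ifft2(np.fft.fft2(img) * filt).real
    n_clipped = int((sm <= 0).sum())
    if n_clipped:
        warnings.warn(f"TIE: clipped {n_clipped} non-positive filtered pixels")
    sm = np.clip(sm, 1e-12, None)
    t = -np.log(sm) / mu
    return ThicknessMap(t, pitch, delta_r, beta, mu, n_clipped, method="tie")


def _ctf_kernel(shape, pitch, wavelength, zbar, delta_r, beta):
    fy, fx = _freq_grids(shape, pitch)
    chi = np.pi * wavelength * zbar * (fy**2 + fx**2)
    return (4 * np.pi / wavelength) * (delta_r * np.sin(chi) + beta * np.cos(chi))


def ctf_forward_image(
    thickness: np.ndarray,
    wavelength: float,
    zbar: float,
    pitch: float,
    delta_r: float,
    beta: float,
) -> np.ndarray:
    """Weak-object forward model: I/I0 = 1 - F^-1[K(f) * F[t]].

    The linearized hologram of a thin single-material object; the exact
    inverse of :func:`ctf_thickness` away from the transfer zeros (used as a
    self-consistency oracle and for generating weak test holograms).
    """
    k = _ctf_kernel(thickness.shape, pitch, wavelength, zbar, delta_r, beta)
    c = -np.fft.ifft2(k * np.fft.fft2(thickness)).real
    return 1.0 + c


def ctf_thickness(
    image: np.ndarray,
    wavelength: float,
    zbar: float,
    pitch: float,
    material: Optional[str] = None,
    delta_r: Optional[float] = None,
    beta: Optional[float] = None,
    reg: float = 1e-3,
) -> ThicknessMap:
    """Weak-object CTF inversion of a defocused hologram.

    Fourier division by K = (4*pi/lambda)*(delta_r*sin(chi) + beta*cos(chi))
    with Tikhonov regularization reg*max(K)^2 at the zero crossings.  Raises
    :class:`DegenerateContrastError` for a pure phase object at zero defocus
    (K vanishes identically).
    """
    delta_r, beta = _resolve_material(material, delta_r, beta)
    img = np.asarray(image, dtype=float)
    k = _ctf_kernel(img.shape, pitch, wavelength, zbar, delta_r, beta)
    kmax = np.abs(k).max()
    if kmax == 0:
        raise DegenerateContrastError(
            "contrast transfer vanishes (pure phase object at zero defocus)"
        )
    c = img - 1.0
    mu = 4 * np.pi * beta / wavelength
    t_hat = -np.fft.fft2(c) * k / (k**2 + reg * kmax**2)
    t = np.fft.ifft2(t_hat).real
    return ThicknessMap(t, pitch, delta_r, beta, mu, method="ctf")


def fps_resolution(
    image: np.ndarray,
    pitch: float,
    window_frac: float = 0.02,
    floor_bins: int = 30,
    threshold: float = 2.0,
    mask: Optional[np.ndarray] = None,
) -> ResolutionReport:
    """FPS cut-off resolution of an image.

    The image (mean removed, optionally coverage-masked) is apodized with a
    Gaussian window of std ``window_frac`` times the field size, the
    azimuthal average of |FT|^2 is formed in one-Fourier-pixel bins, the
    noise floor is the mean of the last ``floor_bins`` bins and the cut-off
    is the highest frequency at which the FPS >= ``threshold`` x floor.
    Invariant to intensity scaling.  A zero floor (strictly band-limited
    noiseless input) is flagged and the cut-off reported at the band edge.
    """
    img = np.asarray(image, dtype=float).copy()
    if mask is not None:
        img = np.where(mask, img, np.nan)
    finite = np.isfinite(img)
    img = np.where(finite, img, img[finite].mean())
    img = img - img.mean()
    ny, nx = img.shape
    # Gaussian edge taper: a border of 3 sigma is rolled off smoothly so the
    # periodic FT sees no sharp field edges
    sig = max(window_frac * min(ny, nx), 1.0)
    margin = int(np.ceil(3 * sig))
    box = np.zeros((ny, nx))
    box[margin:-margin or None, margin:-margin or None] = 1.0
    from scipy.ndimage import gaussian_filter

    img = img * gaussian_filter(box, sig)
    spec = np.fft.fftshift(np.abs(np.fft.fft2(img)) ** 2)
    iy = np.arange(ny) - ny // 2
    ix = np.arange(nx) - nx // 2
    r = np.hypot(iy[:, None], ix[None, :])
    nbins = min(ny, nx) // 2
    rbin = r.astype(int)
    selr = rbin < nbins
    prof = np.bincount(rbin[selr], weights=spec[selr], minlength=nbins)[:nbins]
    counts = np.bincount(rbin[selr], minlength=nbins)[:nbins]
    prof = prof / np.maximum(counts, 1)
    freq = np.arange(nbins) / (min(ny, nx) * pitch)
    floor = float(prof[-floor_bins:].mean()) if nbins > floor_bins else float(prof[-1])
    floor_defined = floor > 0
    if not floor_defined:
        cutoff = freq[-1]
    else:
        above = prof >= threshold * floor
        idx = np.where(above)[0]
        cutoff = freq[idx[-1]] if idx.size else freq[0]
    cutoff = float(max(cutoff, freq[1] if nbins > 1 else 0))
    return ResolutionReport(
        frequency=freq,
        power=prof,
        noise_floor=floor,
        cutoff_frequency=cutoff,
        full_period=1.0 / cutoff,
        half_period=0.5 / cutoff,
        floor_defined=floor_defined,
    )
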