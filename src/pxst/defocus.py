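"""Initial focus-to-sample distance estimates: Thon rings and SSE scan.

The Fresnel fringes of edge-rich samples imprint a ring system on the
cumulative power spectrum of the scan (Thon rings, familiar from defocused
electron micrographs).  For a magnified hologram the ring phase in
detector-plane spatial frequency f is

    chi(f) = pi*lambda*zbar_eff*q^2,   q = M*f,

and since zbar*M^2 = z*M this collapses to chi = pi*lambda*z*(Mx*fx^2 +
My*fy^2): the ring spacing encodes the per-axis magnification and hence the
per-axis focus distances (defocus + astigmatism).  The fit maximizes the
normalized correlation between a background-subtracted spectrum and the
sin^2(chi) ring model over a fitted frequency band — the strategy of the
cryo-EM defocus fitter CTFFIND, adapted to the divergent-beam geometry.

When only first-order fringes are visible the ring fit is hopeless; the
fallback scans candidate z1 values, runs one cheap reconstruction pass for
each (ideal map + reference synthesis) and picks the candidate minimizing
the model sum-squared error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .core import (
    ScanData,
    WhiteField,
    build_reference,
    compute_error_map,
    estimate_white_field,
    initial_pixel_map,
)
from .geometry import ExperimentGeometry, effective_defocus, magnification

__all__ = [
    "DefocusEstimate",
    "cumulative_power_spectrum",
    "fit_thon_rings",
    "scan_defocus_sse",
]


@dataclass
class DefocusEstimate:
    """Per-axis focus-sample distances with provenance.

    ``success`` is False when the method could not produce an estimate (the
    numeric fields are then NaN).
    """

    z1_x: float
    z1_y: float
    zbar_x: float
    zbar_y: float
    score: float
    method: str
    search_range: Tuple[float, float]
    success: bool = True
    curve: Optional[np.ndarray] = None

    @property
    def zbar(self) -> float:
        return 0.5 * (self.zbar_x + self.zbar_y)


def cumulative_power_spectrum(
    scan: ScanData, white: Optional[WhiteField] = None
) -> np.ndarray:
    """Sum over frames of |FT(I_n/W - 1)|^2, DC suppressed, fftshifted.

    Masked or zero-white pixels are filled with the zero contrast value
    (equivalent to the white-field-scaled mean).
    """
    if white is None:
        white = estimate_white_field(scan)
    good = scan.mask & white.mask & (white.data > 0)
    wsafe = np.where(good, white.data, 1.0)
    spec = np.zeros(scan.shape)
    for n in range(scan.n_frames):
        c = np.where(good, scan.frames[n] / wsafe - 1.0, 0.0)
        c = c - c.mean()
        spec += np.abs(np.fft.fft2(c)) ** 2
    spec = np.fft.fftshift(spec)
    cy, cx = spec.shape[0] // 2, spec.shape[1] // 2
    spec[cy, cx] = 0.0
    return spec


def fit_thon_rings(
    spectrum: np.ndarray,
    geometry: ExperimentGeometry,
    z1_range: Optional[Tuple[float, float]] = None,
    band: Tuple[float, float] = (0.1, 0.8),
    n_grid: int = 13,
    n_bins: int = 100,
    min_score: float = 0.1,
) -> DefocusEstimate:
    """Fit per-axis focus distances to the Thon-ring system of a spectrum.

    For each candidate (z1x, z1y) the spectrum is averaged over shells of
    constant chi — ellipses Mx*fx^2 + My*fy^2 = const, so both the rings and
    the anisotropically magnified sample spectrum become one-dimensional — a
    moving 30th-percentile background is subtracted along the shell profile,
    and the normalized correlation with the sin^2(chi) ring model is
    maximized (coarse log-spaced grid, then simplex refinement).

    ``spectrum`` is the fftshifted cumulative power spectrum; ``z1_range``
    brackets the candidates (default 0.5-2x the nominal value); ``band`` is
    the fitted frequency band in units of Nyquist.  At least two rings must
    fall inside the band to be meaningful; returns ``success=False`` when
    the best correlation stays below ``min_score`` — weak (first-order-only)
    fringing defeats ring analysis, use :func:`scan_defocus_sse` instead.
    """
    lam = geometry.wavelength
    z = geometry.sample_detector
    if z1_range is None:
        z1n = geometry.focus_sample
        z1_range = (0.5 * z1n, 2.0 * z1n)
    ny, nx = spectrum.shape
    fy = (np.arange(ny) - ny // 2) / (ny * geometry.pixel_size)
    fx = (np.arange(nx) - nx // 2) / (nx * geometry.pixel_size)
    fy2 = (fy**2)[:, None]
    fx2 = (fx**2)[None, :]
    fnyq = 1.0 / (2 * geometry.pixel_size)
    rr = np.sqrt(fy2 + fx2)
    sel = (rr >= band[0] * fnyq) & (rr <= band[1] * fnyq)
    sb = spectrum[sel]
    if not np.any(sb > 0):
        return DefocusEstimate(
            np.nan, np.nan, np.nan, np.nan, 0.0, "thon", z1_range, success=False
        )
    fy2s = fy2.repeat(nx, axis=1)[sel]
    fx2s = fx2.repeat(ny, axis=0)[sel]
    win = max(n_bins // 10, 5)

    def score(z1x, z1y):
        u = magnification(z1x, z) * fx2s + magnification(z1y, z) * fy2s
        edges = np.linspace(u.min(), u.max(), n_bins + 1)
        idx = np.clip(np.digitize(u, edges) - 1, 0, n_bins - 1)
        cnt = np.maximum(np.bincount(idx, minlength=n_bins), 1)
        prof = np.bincount(idx, weights=sb, minlength=n_bins) / cnt
        bg = np.array(
            [np.percentile(prof[max(i - win, 0): i + win + 1], 30) for i in range(n_bins)]
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        # pixel-level correlation: bin-level noise is correlated at the
        # background-window scale and would swamp the ring signal
        d = sb - np.interp(u, centers, bg)
        m = np.sin(np.pi * lam * z * u) ** 2
        d = d - d.mean()
        m = m - m.mean()
        denom = np.linalg.norm(d) * np.linalg.norm(m)
        if denom == 0:
            return 0.0
        return float(d @ m / denom)

    cands = np.geomspace(z1_range[0], z1_range[1], n_grid)
    best = (-np.inf, cands[0], cands[0])
    for zx in cands:
        for zy in cands:
            s = score(zx, zy)
            if s > best[0]:
                best = (s, zx, zy)
    res = minimize(
        lambda p: -score(np.exp(p[0]), np.exp(p[1])),
        x0=np.log([best[1], best[2]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
    )
    z1x, z1y = np.exp(res.x)
    s = -res.fun
    if s < min_score:
        return DefocusEstimate(
            np.nan, np.nan, np.nan, np.nan, float(s), "thon", z1_range, success=False
        )
    return DefocusEstimate(
        z1_x=float(z1x),
        z1_y=float(z1y),
        zbar_x=effective_defocus(z1x, z),
        zbar_y=effective_defocus(z1y, z),
        score=float(s),
        method="thon",
        search_range=z1_range,
    )


def scan_defocus_sse(
    scan: ScanData,
    z1_candidates: Sequence[float],
    white: Optional[WhiteField] = None,
) -> DefocusEstimate:
    """Brute-force defocus search by model-error minimization.

    For each candidate z1 (applied to both axes) one cheap reconstruction
    pass is run — ideal magnification map, reference synthesis, model SSE —
    and the candidate minimizing the SSE is returned together with the full
    error curve.  Warns when the minimum sits on the boundary of the scanned
    range (range too narrow).
    """
    z1_candidates = np.asarray(sorted(z1_candidates), dtype=float)
    if z1_candidates.size < 1:
        raise ValueError("need at least one candidate")
    if white is None:
        white = estimate_white_field(scan)
    geo = scan.geometry
    sse = np.empty(z1_candidates.size)
    for k, z1 in enumerate(z1_candidates):
        g = replace(geo, focus_sample_x=z1, focus_sample_y=z1)
        u = initial_pixel_map(g)
        # raw weighted-mean reference: keeps the SSE comparison across
        # candidates stable (the LS polish can overfit inconsistent maps)
        ref = build_reference(scan, white, u, cg_iters=0)
        _, _, total = compute_error_map(scan, white, ref, u)
        sse[k] = total
    k = int(np.argmin(sse))
    if z1_candidates.size > 2 and k in (0, z1_candidates.size - 1):
        warnings.warn("SSE minimum on the boundary of the scanned z1 range")
    z1 = float(z1_candidates[k])
    z = geo.sample_detector
    return DefocusEstimate(
        z1_x=z1,
        z1_y=z1,
        zbar_x=effective_defocus(z1, z),
        zbar_y=effective_defocus(z1, z),
        score=float(sse[k]),
        method="sse_scan",
        search_range=(float(z1_candidates[0]), float(z1_candidates[-1])),
        curve=np.stack([z1_candidates, sse]),
    )
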