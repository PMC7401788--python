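"""Core data containers and update operations of the speckle-tracking engine.

The forward model of divergent-beam near-field speckle tracking is

    I_n(x) = W(x) * I_ref(u(x) - dx_n),

where ``I_n`` are the recorded shadow images, ``W`` the white field (the
intensity with no sample in the beam), ``u`` the pixel map carrying the
magnification and the aberration-induced geometric distortions, and ``dx_n``
the sample translations.  The reference ``I_ref`` is the undistorted,
magnified, defocused hologram of the sample, expressed in white-field
normalized units on a grid at sample-plane scale.

This module provides the containers (:class:`ScanData`, :class:`PixelMap`,
:class:`ReferenceImage`) and the elementary updates: white-field estimation,
reference synthesis by weighted splatting, the per-pixel map update by
integer-grid search with sub-pixel quadratic refinement, the per-frame
translation update, and the sum-squared-error bookkeeping.  The iteration
orchestrator lives in :mod:`pxst.model`.

Coordinate conventions: array axis 0 is y (vertical, slow), axis 1 is x;
translations are (y, x) pairs in metres at sample-plane scale; the pixel map
``u`` holds sample-plane-scale coordinates in metres, so translations
subtract directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import ExperimentGeometry

__all__ = [
    "ScanData",
    "PixelMap",
    "ReferenceImage",
    "WhiteField",
    "estimate_white_field",
    "initial_pixel_map",
    "build_reference",
    "update_pixel_map",
    "update_translations",
    "compute_error_map",
    "bilinear_sample",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ScanData:
    """A scan of N shadow images with translations and a good-pixel mask.

    Attributes
    ----------
    frames : (N, R, C) float array
        Recorded images in photon counts.
    translations : (N, 2) float array
        Sample translations (y, x) in metres, sample-plane scale.
    mask : (R, C) bool array
        True for good pixels.
    geometry : ExperimentGeometry
    """

    frames: np.ndarray
    translations: np.ndarray
    mask: np.ndarray
    geometry: ExperimentGeometry

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (N, rows, cols)")
        n = self.frames.shape[0]
        if n < 1:
            raise ValueError("need at least one frame")
        if self.translations.shape != (n, 2):
            raise ValueError("translations must be (N, 2) (y, x) metres")
        if self.mask.shape != self.frames.shape[1:]:
            raise ValueError("mask shape must match frame shape")
        if not np.all(np.isfinite(self.translations)):
            raise ValueError("translations must be finite")
        if np.any(self.frames[:, self.mask] < 0):
            raise ValueError("photon counts must be >= 0 on good pixels")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class WhiteField:
    """Per-pixel white field with validity mask."""

    data: np.ndarray
    mask: np.ndarray
    n_all_masked: int = 0


@dataclass
class PixelMap:
    """Vector field u mapping detector pixels to reference-frame coordinates.

    ``u`` has shape (2, R, C): component 0 is the y coordinate, component 1
    the x coordinate, both in metres at sample-plane scale.
    """

    u: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.ndim != 3 or self.u.shape[0] != 2:
            raise ValueError("u must have shape (2, rows, cols)")
        if not np.all(np.isfinite(self.u[:, self.mask])):
            raise ValueError("pixel map must be finite on the mask")

    def copy(self) -> "PixelMap":
        return PixelMap(self.u.copy(), self.mask.copy())


@dataclass
class ReferenceImage:
    """The undistorted magnified hologram on its own regular grid.

    ``data`` is in white-field-normalized units (== 1 for empty beam);
    ``origin`` is the physical (y, x) coordinate of pixel (0, 0); ``coverage``
    counts contributing detector samples; ``weight`` is the accumulated
    W^2 splat weight used in the weighted mean.
    """

    data: np.ndarray
    pitch: float
    origin: Tuple[float, float]
    coverage: Optional[np.ndarray] = None
    weight: Optional[np.ndarray] = None

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    def pixel_coords(self, y: np.ndarray, x: np.ndarray):
        """Physical (y, x) metres -> fractional pixel indices (i, j)."""
        return (y - self.origin[0]) / self.pitch, (x - self.origin[1]) / self.pitch


# ---------------------------------------------------------------------------
# interpolation primitives
# ---------------------------------------------------------------------------

def bilinear_sample(data: np.ndarray, ci: np.ndarray, cj: np.ndarray):
    """Bilinear interpolation of ``data`` at fractional indices (ci, cj).

    Returns (values, valid); samples outside the grid or touching a
    non-finite cell are invalid (value 0).
    """
    h, w = data.shape
    ci = np.asarray(ci, dtype=float)
    cj = np.asarray(cj, dtype=float)
    inside = (ci >= 0) & (ci <= h - 1) & (cj >= 0) & (cj <= w - 1)
    i0 = np.clip(np.floor(ci).astype(np.int64), 0, h - 2)
    j0 = np.clip(np.floor(cj).astype(np.int64), 0, w - 2)
    fi = ci - i0
    fj = cj - j0
    flat = data.ravel()
    idx = i0 * w + j0
    v00 = flat[idx]
    v01 = flat[idx + 1]
    v10 = flat[idx + w]
    v11 = flat[idx + w + 1]
    vals = (
        (1 - fi) * (1 - fj) * v00
        + (1 - fi) * fj * v01
        + fi * (1 - fj) * v10
        + fi * fj * v11
    )
    valid = inside & np.isfinite(vals)
    return np.where(valid, vals, 0.0), valid


def _bilinear_splat(acc: np.ndarray, ci: np.ndarray, cj: np.ndarray, values: np.ndarray):
    """Deposit ``values`` at fractional indices into accumulator ``acc``."""
    h, w = acc.shape
    inside = (ci >= 0) & (ci <= h - 1) & (cj >= 0) & (cj <= w - 1)
    ci = ci[inside]
    cj = cj[inside]
    values = values[inside]
    i0 = np.clip(np.floor(ci).astype(np.int64), 0, h - 2)
    j0 = np.clip(np.floor(cj).astype(np.int64), 0, w - 2)
    fi = ci - i0
    fj = cj - j0
    idx = i0 * w + j0
    size = h * w
    buf = np.bincount(idx, weights=values * (1 - fi) * (1 - fj), minlength=size)
    buf += np.bincount(idx + 1, weights=values * (1 - fi) * fj, minlength=size)
    buf += np.bincount(idx + w, weights=values * fi * (1 - fj), minlength=size)
    buf += np.bincount(idx + w + 1, weights=values * fi * fj, minlength=size)
    acc += buf.reshape(h, w)


def _frame_coords(u: np.ndarray, translation: np.ndarray, origin, pitch: float):
    ci = (u[0] - translation[0] - origin[0]) / pitch
    cj = (u[1] - translation[1] - origin[1]) / pitch
    return ci, cj


# ---------------------------------------------------------------------------
# white field and initial map
# ---------------------------------------------------------------------------

def estimate_white_field(scan: ScanData) -> WhiteField:
    """Per-pixel median over frames; robust empty-beam estimate.

    With the sample occluding each pixel in a minority of frames, the median
    returns the unoccluded intensity without a dedicated empty-beam exposure.
    """
    if scan.n_frames < 3:
        warnings.warn("white-field median over fewer than 3 frames is fragile")
    w = np.median(scan.frames, axis=0)
    mask = scan.mask.copy()
    n_bad = int((~mask).sum())
    w = np.where(mask, w, 0.0)
    return WhiteField(data=w, mask=mask, n_all_masked=n_bad)


def initial_pixel_map(geometry: ExperimentGeometry, mask: Optional[np.ndarray] = None) -> PixelMap:
    """Pure per-axis magnification map u_a(x) = x_a * z1_a/(z1_a + z).

    This is the pixel map of an ideal astigmatic lens: the image is a
    demagnified copy of the detector coordinates with no distortions.
    """
    y, x = geometry.detector_coords()
    z = geometry.sample_detector
    sy = geometry.focus_sample_y / (geometry.focus_sample_y + z)
    sx = geometry.focus_sample_x / (geometry.focus_sample_x + z)
    u = np.stack([y * sy, x * sx])
    if mask is None:
        mask = np.ones(geometry.detector_shape, dtype=bool)
    return PixelMap(u, mask)


# ---------------------------------------------------------------------------
# reference synthesis
# ---------------------------------------------------------------------------

def build_reference(
    scan: ScanData,
    white: WhiteField,
    pixel_map: PixelMap,
    pitch: Optional[float] = None,
    frame_weights: Optional[np.ndarray] = None,
    margin: int = 2,
    cg_iters: int = 10,
) -> ReferenceImage:
    """Synthesize the reference hologram from all frames.

    Each white-field-normalized detector sample I_n(x)/W(x) is deposited at
    u(x) - dx_n with bilinear splatting and statistical weight W(x)^2 (inverse
    relative Poisson variance); the weighted mean is then polished by
    ``cg_iters`` conjugate-gradient steps on the underlying weighted
    least-squares problem min ||sqrt(w) (I_n - W * S_n r)||^2, with S_n the
    bilinear sampling operator and the splat its exact adjoint.  The polish
    removes the slight blur of the plain splat-mean, which otherwise biases
    the per-pixel map update (set ``cg_iters=0`` for the raw weighted mean).
    """
    if pitch is None:
        # half the demagnified pixel: keeps bilinear representation error of
        # the hologram sub-dominant in the per-pixel map update
        pitch = scan.geometry.demagnified_pixel / 2.0
    m = pixel_map.mask & white.mask & (white.data > 0) & scan.mask
    if not m.any():
        raise ValueError("no valid pixels to build a reference from")
    uy = pixel_map.u[0]
    ux = pixel_map.u[1]
    t = scan.translations
    ymin = uy[m].min() - t[:, 0].max()
    ymax = uy[m].max() - t[:, 0].min()
    xmin = ux[m].min() - t[:, 1].max()
    xmax = ux[m].max() - t[:, 1].min()
    origin = (ymin - margin * pitch, xmin - margin * pitch)
    shape = (
        int(np.ceil((ymax - origin[0]) / pitch)) + margin + 1,
        int(np.ceil((xmax - origin[1]) / pitch)) + margin + 1,
    )
    num = np.zeros(shape)
    den = np.zeros(shape)
    cov = np.zeros(shape)
    wgt2 = np.where(m, white.data**2, 0.0)
    val = np.where(m, white.data, 0.0)  # W^2 * (I/W) = W * I
    ones = m.astype(float)
    for n in range(scan.n_frames):
        fw = None if frame_weights is None else frame_weights[n]
        ci, cj = _frame_coords(pixel_map.u, t[n], origin, pitch)
        sel = m if fw is None else (m & fw)
        selr = sel.ravel()
        cir = ci.ravel()[selr]
        cjr = cj.ravel()[selr]
        _bilinear_splat(num, cir, cjr, (val * scan.frames[n]).ravel()[selr])
        _bilinear_splat(den, cir, cjr, wgt2.ravel()[selr])
        _bilinear_splat(cov, cir, cjr, ones.ravel()[selr])
    if not (den > 0).any():
        raise ValueError("empty reference coverage")
    good = den > 0
    r0 = np.zeros(shape)
    r0[good] = num[good] / den[good]
    if cg_iters > 0:
        r0 = _reference_cg_polish(
            scan, white, pixel_map, r0, good, origin, pitch, m, frame_weights, cg_iters
        )
    data = np.where(good, r0, np.nan)
    return ReferenceImage(data=data, pitch=pitch, origin=origin, coverage=cov, weight=den)


def _reference_cg_polish(
    scan, white, pixel_map, r0, good, origin, pitch, pixel_mask, frame_weights, n_iter
):
    """Conjugate-gradient solve of the weighted LS reference problem.

    Normal equations A r = b with A = Sum_n S_n^T W^2 S_n and
    b = Sum_n S_n^T (W I_n), restricted to covered reference pixels.
    """
    shape = r0.shape
    t = scan.translations
    coords = []
    for n in range(scan.n_frames):
        ci, cj = _frame_coords(pixel_map.u, t[n], origin, pitch)
        sel = pixel_mask if frame_weights is None else (pixel_mask & frame_weights[n])
        coords.append((ci.ravel()[sel.ravel()], cj.ravel()[sel.ravel()], sel))

    wf = white.data

    def apply_a(r):
        out = np.zeros(shape)
        for n in range(scan.n_frames):
            ci, cj, sel = coords[n]
            v, valid = bilinear_sample(r, ci, cj)
            w2 = (wf**2).ravel()[sel.ravel()]
            _bilinear_splat(out, ci[valid], cj[valid], (w2 * v)[valid])
        out[~good] = 0.0
        return out

    b = np.zeros(shape)
    for n in range(scan.n_frames):
        ci, cj, sel = coords[n]
        wi = (wf * scan.frames[n]).ravel()[sel.ravel()]
        _bilinear_splat(b, ci, cj, wi)
    b[~good] = 0.0

    r = r0.copy()
    resid = b - apply_a(r)
    p = resid.copy()
    rr = float((resid * resid).sum())
    rr0 = rr
    for _ in range(n_iter):
        if rr <= 1e-20 * max(rr0, 1e-300):
            break
        ap = apply_a(p)
        pap = float((p * ap).sum())
        if pap <= 0:
            break
        alpha = rr / pap
        r += alpha * p
        resid -= alpha * ap
        rr_new = float((resid * resid).sum())
        p = resid + (rr_new / rr) * p
        rr = rr_new
    return r


# ---------------------------------------------------------------------------
# error bookkeeping
# ---------------------------------------------------------------------------

def compute_error_map(
    scan: ScanData,
    white: WhiteField,
    reference: ReferenceImage,
    pixel_map: PixelMap,
    translations: Optional[np.ndarray] = None,
    frame_weights: Optional[np.ndarray] = None,
):
    """(per-pixel SSE, per-frame SSE, total SSE) of the forward model.

    The sum runs over masked pixels whose reference prediction is defined;
    the decompositions sum to the total exactly.
    """
    if translations is None:
        translations = scan.translations
    m = pixel_map.mask & white.mask & scan.mask
    pixel_sse = np.zeros(scan.shape)
    frame_sse = np.zeros(scan.n_frames)
    for n in range(scan.n_frames):
        ci, cj = _frame_coords(pixel_map.u, translations[n], reference.origin, reference.pitch)
        pred, valid = bilinear_sample(reference.data, ci, cj)
        sel = m & valid
        if frame_weights is not None:
            sel = sel & frame_weights[n]
        e = np.where(sel, scan.frames[n] - white.data * pred, 0.0)
        e2 = e * e
        pixel_sse += e2
        frame_sse[n] = e2.sum()
    return pixel_sse, frame_sse, float(frame_sse.sum())


# ---------------------------------------------------------------------------
# pixel-map update
# ---------------------------------------------------------------------------

def _quadratic_subpixel(err3: np.ndarray):
    """Sub-pixel vertex of a 2D quadratic fitted to a 3x3 error patch.

    ``err3`` has shape (3, 3, M).  Returns (di, dj, ok): offsets clamped to
    [-1, 1] and a flag for a usable (positive-definite) fit.
    """
    e = err3
    b = (e[2, 1] - e[0, 1]) / 2.0
    c = (e[1, 2] - e[1, 0]) / 2.0
    d = (e[2, 1] - 2 * e[1, 1] + e[0, 1]) / 2.0
    f = (e[1, 2] - 2 * e[1, 1] + e[1, 0]) / 2.0
    g = (e[2, 2] - e[2, 0] - e[0, 2] + e[0, 0]) / 4.0
    det = 4 * d * f - g * g
    ok = (d > 0) & (f > 0) & (det > 0)
    dets = np.where(ok, det, 1.0)
    di = np.where(ok, -(2 * f * b - g * c) / dets, 0.0)
    dj = np.where(ok, -(2 * d * c - g * b) / dets, 0.0)
    di = np.clip(di, -1, 1)
    dj = np.clip(dj, -1, 1)
    return di, dj, ok


def _shift_error_volume(
    scan: ScanData,
    white: WhiteField,
    reference: ReferenceImage,
    pixel_map: PixelMap,
    search_radius: int,
    frame_weights: Optional[np.ndarray],
    translations: Optional[np.ndarray] = None,
    per_pixel: bool = True,
):
    """Mean model error for every integer reference-pixel shift of the map.

    Returns (err, cnt, shifts): ``err`` has shape (S, S, R, C) when
    ``per_pixel`` else (S, S); ``cnt`` counts contributing samples.  Bilinear
    interpolation weights are shift-invariant for integer shifts, so the four
    reference gathers per (frame, shift) reuse precomputed corner indices.
    """
    if translations is None:
        translations = scan.translations
    h, w = reference.shape
    r = int(search_radius)
    side = 2 * r + 1
    m0 = pixel_map.mask & white.mask & scan.mask & (white.data > 0)
    flat = reference.data.ravel()
    shape = scan.shape
    if per_pixel:
        err = np.zeros((side, side) + shape)
        cnt = np.zeros((side, side) + shape, dtype=np.uint16)
    else:
        err = np.zeros((side, side))
        cnt = np.zeros((side, side), dtype=np.int64)
    wf = white.data
    for n in range(scan.n_frames):
        ci, cj = _frame_coords(pixel_map.u, translations[n], reference.origin, reference.pitch)
        i0 = np.floor(ci).astype(np.int64)
        j0 = np.floor(cj).astype(np.int64)
        fi = ci - i0
        fj = cj - j0
        w00 = (1 - fi) * (1 - fj)
        w01 = (1 - fi) * fj
        w10 = fi * (1 - fj)
        w11 = fi * fj
        m = m0 if frame_weights is None else (m0 & frame_weights[n])
        img = scan.frames[n]
        for a in range(-r, r + 1):
            ia = i0 + a
            vrow = (ia >= 0) & (ia <= h - 2)
            iac = np.clip(ia, 0, h - 2)
            for b in range(-r, r + 1):
                jb = j0 + b
                vcol = (jb >= 0) & (jb <= w - 2)
                jbc = np.clip(jb, 0, w - 2)
                idx = iac * w + jbc
                v = (
                    w00 * flat[idx]
                    + w01 * flat[idx + 1]
                    + w10 * flat[idx + w]
                    + w11 * flat[idx + w + 1]
                )
                valid = vrow & vcol & m & np.isfinite(v)
                e = img - wf * v
                e2 = np.where(valid, e * e, 0.0)
                if per_pixel:
                    err[a + r, b + r] += e2
                    cnt[a + r, b + r] += valid
                else:
                    err[a + r, b + r] += e2.sum()
                    cnt[a + r, b + r] += int(valid.sum())
    return err, cnt, np.arange(-r, r + 1)


def _fractional_error_surface(
    scan: ScanData,
    white: WhiteField,
    reference: ReferenceImage,
    pixel_map: PixelMap,
    base_shift_y: np.ndarray,
    base_shift_x: np.ndarray,
    offsets: np.ndarray,
    frame_weights: Optional[np.ndarray],
    translations: Optional[np.ndarray],
):
    """Mean model error at fractional shifts around a per-pixel base shift.

    Returns (err, cnt) with shape (len(offsets), len(offsets), R, C); the
    shift applied at pixel x is (base + offset) reference pixels.
    """
    if translations is None:
        translations = scan.translations
    shape = scan.shape
    m0 = pixel_map.mask & white.mask & scan.mask & (white.data > 0)
    k = len(offsets)
    err = np.zeros((k, k) + shape)
    cnt = np.zeros((k, k) + shape, dtype=np.uint16)
    wf = white.data
    for n in range(scan.n_frames):
        ci, cj = _frame_coords(pixel_map.u, translations[n], reference.origin, reference.pitch)
        ci = ci + base_shift_y
        cj = cj + base_shift_x
        m = m0 if frame_weights is None else (m0 & frame_weights[n])
        img = scan.frames[n]
        for a, da in enumerate(offsets):
            for b, db in enumerate(offsets):
                v, valid = bilinear_sample(reference.data, ci + da, cj + db)
                valid = valid & m
                e = img - wf * v
                err[a, b] += np.where(valid, e * e, 0.0)
                cnt[a, b] += valid
    return err, cnt


def update_pixel_map(
    scan: ScanData,
    white: WhiteField,
    reference: ReferenceImage,
    pixel_map: PixelMap,
    search_radius: int = 5,
    reg_sigma: float = 0.0,
    frame_weights: Optional[np.ndarray] = None,
    translations: Optional[np.ndarray] = None,
    flat_tol: float = 1e-12,
    refine_step: float = 0.25,
):
    """Refine the pixel map by per-pixel data-consistency minimization.

    For every detector pixel the model error summed over frames is evaluated
    on an integer grid of reference-pixel shifts of half-width
    ``search_radius``, followed by sub-pixel refinement from a 2D quadratic
    fit to the 3x3 neighbourhood of the minimum.  ``reg_sigma`` > 0 smooths
    the updated map with a Gaussian kernel of that width (detector pixels),
    the regularization used to suppress lattice mis-registration on
    quasi-periodic samples.

    Returns (PixelMap, info) with ``info['flagged']`` marking pixels whose
    error surface was degenerate (flat or non-convex); those retain their
    previous value.
    """
    err, cnt, shifts = _shift_error_volume(
        scan, white, reference, pixel_map, search_radius, frame_weights, translations
    )
    side = len(shifts)
    shape = scan.shape
    npix = shape[0] * shape[1]
    mean_err = np.where(cnt > 0, err / np.maximum(cnt, 1), np.inf).reshape(side * side, npix)
    best = np.argmin(mean_err, axis=0)
    emin = mean_err[best, np.arange(npix)]
    finite = np.isfinite(emin)
    emax = np.where(
        np.isfinite(mean_err), mean_err, -np.inf
    ).max(axis=0)
    flat = finite & (emax - emin <= flat_tol * np.maximum(emax, 1e-300))
    bi, bj = np.divmod(best, side)

    usable = finite & ~flat
    si = np.where(usable, shifts[0] + bi, 0.0).reshape(shape).astype(float)
    sj = np.where(usable, shifts[0] + bj, 0.0).reshape(shape).astype(float)
    flagged = (~usable).reshape(shape) | ~pixel_map.mask

    # sub-pixel stages: re-evaluate the error surface at shrinking fractional
    # spacings around the current optimum and move to the parabola vertex.
    # Fitting at integer spacing alone is biased when the surface is locally
    # non-quadratic (e.g. an exact zero-error minimum between asymmetric
    # neighbours); halving the spacing shrinks that model error ~ h^2.
    h = 0.5
    while refine_step and h >= refine_step - 1e-12:
        err3, cnt3 = _fractional_error_surface(
            scan, white, reference, pixel_map, si, sj,
            np.array([-h, 0.0, h]), frame_weights, translations,
        )
        me3 = np.where(cnt3 > 0, err3 / np.maximum(cnt3, 1), np.inf).reshape(3, 3, npix)
        good3 = np.isfinite(me3).all(axis=(0, 1))
        me3 = np.where(np.isfinite(me3), me3, 0.0)
        di, dj, ok = _quadratic_subpixel(me3)
        stage_ok = (good3 & ok).reshape(shape) & ~flagged
        si = si + np.where(stage_ok, di.reshape(shape) * h, 0.0)
        sj = sj + np.where(stage_ok, dj.reshape(shape) * h, 0.0)
        h /= 2.0

    u_new = pixel_map.u.copy()
    u_new[0] += np.where(flagged, 0.0, si * reference.pitch)
    u_new[1] += np.where(flagged, 0.0, sj * reference.pitch)

    if reg_sigma and reg_sigma > 0:
        u_new = _smooth_map_deviation(u_new, flagged, reg_sigma)

    info = {
        "flagged": flagged,
        "shift_y": si,
        "shift_x": sj,
        "n_flagged": int(flagged.sum()),
    }
    return PixelMap(u_new, pixel_map.mask.copy()), info


# ---------------------------------------------------------------------------
# translation update
# ---------------------------------------------------------------------------

def _smooth_map_deviation(u: np.ndarray, flagged: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-regularize the recovered pixel shifts.

    The map's affine part (magnification + tilt) is fitted and kept; the
    deviation field is smoothed with a normalized (flag-aware) Gaussian of
    std ``sigma`` detector pixels.  Smoothing the total deviation — not the
    per-iteration increment — is what suppresses sharp lattice-vector steps
    on quasi-periodic samples: accumulated jumps are wiped every iteration
    while the smoothing width stays large.
    """
    ny, nx = u.shape[1:]
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    basis = np.stack([np.ones_like(yy), yy, xx], axis=-1)
    good = ~flagged
    out = np.empty_like(u)
    w = good.astype(float)
    for k in range(2):
        sol, *_ = np.linalg.lstsq(basis[good], u[k][good], rcond=None)
        affine = basis @ sol
        dev = np.where(good, u[k] - affine, 0.0)
        sm = gaussian_filter(dev * w, sigma)
        norm = gaussian_filter(w, sigma)
        dev_s = np.where(norm > 1e-12, sm / np.maximum(norm, 1e-12), 0.0)
        out[k] = affine + dev_s
    return out


def update_translations(
    scan: ScanData,
    white: WhiteField,
    reference: ReferenceImage,
    pixel_map: PixelMap,
    search_radius: int = 3,
    frame_weights: Optional[np.ndarray] = None,
):
    """Refine per-frame translations by whole-frame error minimization.

    Each frame's global offset is searched on an integer grid of reference
    pixels with sub-pixel quadratic refinement.  The mean correction over all
    frames is removed (gauge fixing: a common offset of all translations is
    indistinguishable from a shift of the reference).

    Returns (translations, info); frames with no reference overlap are left
    unchanged and flagged.
    """
    r = int(search_radius)
    side = 2 * r + 1
    shifts = np.arange(-r, r + 1)
    n = scan.n_frames
    corrections = np.zeros((n, 2))
    no_overlap = np.zeros(n, dtype=bool)
    for k in range(n):
        sub = ScanData(
            scan.frames[k : k + 1],
            scan.translations[k : k + 1],
            scan.mask,
            scan.geometry,
        )
        fw = None if frame_weights is None else frame_weights[k : k + 1]
        e, c, _ = _shift_error_volume(sub, white, reference, pixel_map, r, fw, per_pixel=False)
        me = np.where(c > 0, e / np.maximum(c, 1), np.inf)
        if not np.isfinite(me).any():
            no_overlap[k] = True
            continue
        bi, bj = np.unravel_index(np.argmin(me), me.shape)
        di = dj = 0.0
        if 0 < bi < side - 1 and 0 < bj < side - 1:
            patch = me[bi - 1 : bi + 2, bj - 1 : bj + 2][:, :, None]
            if np.isfinite(patch).all():
                ddi, ddj, ok = _quadratic_subpixel(patch)
                if ok[0]:
                    di, dj = float(ddi[0]), float(ddj[0])
        si = shifts[bi] + di
        sj = shifts[bj] + dj
        # shifting sampling coords by s is equivalent to reducing dx_n by s*pitch
        corrections[k] = (-si * reference.pitch, -sj * reference.pitch)
    good = ~no_overlap
    if good.any():
        corrections[good] -= corrections[good].mean(axis=0)
    new_t = scan.translations + corrections
    info = {"corrections": corrections, "no_overlap": no_overlap}
    return new_t, info
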