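"""Least-squares 2D integration of gradient fields and curl-free projection.

A measured phase-gradient field g = (g_y, g_x) is in general not integrable
(curl-free).  ``integrate_gradient`` finds the scalar field phi minimizing
||G phi - g||^2 where G is the discrete gradient operator (central
differences in the interior, one-sided at the edges, i.e. the same stencil as
``numpy.gradient``), with the additive constant fixed by a zero-mean gauge.
``irrotational_projection`` returns G phi, the orthogonal projection of g
onto the range of G (the discrete curl-free fields); it is idempotent by
construction.

Two boundary treatments are provided:

* ``"natural"`` — one-sided differences at the edges; the normal equations
  are solved with a cached sparse LU factorization.  This is the treatment
  used inside the reconstruction loop (phase fields are not periodic).
* ``"periodic"`` — periodic central differences, diagonalized by the FFT;
  exact and fast, appropriate for synthetic periodic test fields.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["integrate_gradient", "irrotational_projection", "gradient"]

_factor_cache: Dict[Tuple[int, int], spla.SuperLU] = {}


def gradient(phi: np.ndarray, boundary: str = "natural"):
    """Discrete gradient (g_y, g_x) matching the operator inverted here."""
    if boundary == "periodic":
        gy = (np.roll(phi, -1, axis=0) - np.roll(phi, 1, axis=0)) / 2.0
        gx = (np.roll(phi, -1, axis=1) - np.roll(phi, 1, axis=1)) / 2.0
        return gy, gx
    gy, gx = np.gradient(phi)
    return gy, gx


def _axis_diff_matrix(n: int) -> sp.csr_matrix:
    """1D numpy.gradient stencil as a sparse matrix (unit spacing)."""
    d = sp.lil_matrix((n, n))
    for i in range(1, n - 1):
        d[i, i - 1] = -0.5
        d[i, i + 1] = 0.5
    d[0, 0], d[0, 1] = -1.0, 1.0
    d[n - 1, n - 2], d[n - 1, n - 1] = -1.0, 1.0
    return d.tocsr()


def _grad_ops(shape: Tuple[int, int]):
    ny, nx = shape
    dy = _axis_diff_matrix(ny)
    dx = _axis_diff_matrix(nx)
    iy = sp.identity(ny, format="csr")
    ix = sp.identity(nx, format="csr")
    Gy = sp.kron(dy, ix, format="csr")
    Gx = sp.kron(iy, dx, format="csr")
    return Gy, Gx


def _factorized_normal(shape: Tuple[int, int]) -> spla.SuperLU:
    key = tuple(shape)
    if key not in _factor_cache:
        Gy, Gx = _grad_ops(shape)
        A = (Gy.T @ Gy + Gx.T @ Gx).tocsc()
        # pin the constant nullspace with a tiny Tikhonov term; the resulting
        # constant offset is removed by the zero-mean gauge afterwards
        eps = 1e-12 * A.diagonal().max()
        A = A + eps * sp.identity(A.shape[0], format="csc")
        _factor_cache[key] = spla.splu(A)
    return _factor_cache[key]


def _integrate_natural(gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    shape = gy.shape
    Gy, Gx = _grad_ops(shape)
    rhs = Gy.T @ gy.ravel() + Gx.T @ gx.ravel()
    lu = _factorized_normal(shape)
    phi = lu.solve(rhs).reshape(shape)
    return phi - phi.mean()


def _integrate_periodic(gy: np.ndarray, gx: np.ndarray) -> np.ndarray:
    ny, nx = gy.shape
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    Dy = 1j * np.sin(2 * np.pi * ky)  # symbol of the periodic central difference
    Dx = 1j * np.sin(2 * np.pi * kx)
    denom = np.abs(Dy) ** 2 + np.abs(Dx) ** 2
    num = np.conj(Dy) * np.fft.fft2(gy) + np.conj(Dx) * np.fft.fft2(gx)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_hat = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    phi = np.fft.ifft2(phi_hat).real
    return phi - phi.mean()


def integrate_gradient(
    gy: np.ndarray,
    gx: np.ndarray,
    spacing: float = 1.0,
    boundary: str = "natural",
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares scalar potential of (g_y, g_x), zero-mean gauge.

    Parameters
    ----------
    gy, gx : 2D arrays
        Gradient components along axis 0 and axis 1 (units: value per metre
        if ``spacing`` is in metres).
    spacing : float
        Grid pitch; the returned potential has units value (gradient * m).
    boundary : {"natural", "periodic"}
    mask : 2D bool array, optional
        Invalid samples are replaced by the mean of the valid ones before
        integration (a smooth least-disruptive fill); the potential is still
        returned on the full grid.
    """
    gy = np.asarray(gy, dtype=float)
    gx = np.asarray(gx, dtype=float)
    if gy.shape != gx.shape or gy.ndim != 2:
        raise ValueError("gy and gx must be 2D arrays of identical shape")
    if mask is not None and not mask.all():
        gy = np.where(mask, gy, gy[mask].mean() if mask.any() else 0.0)
        gx = np.where(mask, gx, gx[mask].mean() if mask.any() else 0.0)
    if boundary == "periodic":
        phi = _integrate_periodic(gy, gx)
    elif boundary == "natural":
        phi = _integrate_natural(gy, gx)
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return phi * spacing


def irrotational_projection(
    gy: np.ndarray,
    gx: np.ndarray,
    boundary: str = "natural",
    mask: np.ndarray | None = None,
):
    """Project (g_y, g_x) onto the discretely curl-free fields.

    Returns the gradient of the least-squares potential, computed with the
    same discrete operator, so that projection o projection = projection.
    """
    phi = integrate_gradient(gy, gx, spacing=1.0, boundary=boundary, mask=mask)
    return gradient(phi, boundary=boundary)
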