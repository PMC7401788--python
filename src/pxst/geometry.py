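"""Imaging geometry for divergent-beam near-field speckle tracking.

All closed-form relations of the projection-imaging geometry live here: the
geometric magnification of the shadow image, the effective (plane-wave
equivalent) defocus, the demagnified pixel size, the validity limits on
sample thickness and scan-plane tilt, the ideal angular-sensitivity bound of
the ray-tracking procedure, and the effective Fresnel number of a sample
feature.

Conventions
-----------
* ``z1`` is the focus-to-sample distance, ``z`` the sample-to-detector
  distance, both in metres along the optical axis.
* An astigmatic lens system has distinct horizontal/vertical focal planes;
  every derived quantity therefore exists per axis (``z1x``, ``z1y``) and the
  scalar reported by :class:`DerivedGeometry` is the arithmetic mean of the
  two axes.
* Detector axis 0 is the slow (vertical, y) axis, axis 1 the fast
  (horizontal, x) axis; pixel centres sit on integer indices and physical
  coordinates are measured from the grid centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "HC_KEV_NM",
    "wavelength_from_energy",
    "energy_from_wavelength",
    "magnification",
    "effective_defocus",
    "demagnified_pixel",
    "thickness_limit",
    "tilt_limit",
    "validity_limits",
    "angular_sensitivity_bound",
    "effective_fresnel_number",
    "rayleigh_separation",
    "knife_edge_overlap_separation",
    "ExperimentGeometry",
    "DerivedGeometry",
    "InvalidGeometryError",
]

#: Conversion constant, lambda [nm] = HC_KEV_NM / E [keV].
HC_KEV_NM = 1.2398


class InvalidGeometryError(ValueError):
    """Raised when a geometric parameter is outside its physical domain."""


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in metres from energy in keV."""
    if energy_kev <= 0:
        raise InvalidGeometryError(f"photon energy must be > 0, got {energy_kev}")
    return HC_KEV_NM * 1e-9 / energy_kev


def energy_from_wavelength(wavelength_m: float) -> float:
    """Photon energy in keV from wavelength in metres (inverse of the above)."""
    if wavelength_m <= 0:
        raise InvalidGeometryError(f"wavelength must be > 0, got {wavelength_m}")
    return HC_KEV_NM * 1e-9 / wavelength_m


def magnification(z1: float, z: float) -> float:
    """Geometric magnification M = (z1 + z)/z1 of the shadow image."""
    if z1 <= 0:
        raise InvalidGeometryError(f"focus-sample distance z1 must be > 0, got {z1}")
    if z < 0:
        raise InvalidGeometryError(f"sample-detector distance z must be >= 0, got {z}")
    return (z1 + z) / z1


def effective_defocus(z1: float, z: float) -> float:
    """Effective defocus zbar = z*z1/(z1 + z).

    The shadow image is equivalent to a plane-wave in-line hologram recorded a
    distance ``zbar`` downstream of the sample, magnified by ``M``.
    """
    if z1 <= 0:
        raise InvalidGeometryError(f"focus-sample distance z1 must be > 0, got {z1}")
    if z < 0:
        raise InvalidGeometryError(f"sample-detector distance z must be >= 0, got {z}")
    return z * z1 / (z1 + z)


def demagnified_pixel(pixel_size: float, mag: float) -> float:
    """Sample-plane sampling pitch delta = sigma_det / M."""
    if mag < 1:
        raise InvalidGeometryError(f"magnification must be >= 1, got {mag}")
    if pixel_size <= 0:
        raise InvalidGeometryError(f"pixel size must be > 0, got {pixel_size}")
    return pixel_size / mag


def thickness_limit(delta: float, na: float) -> float:
    """Maximum tolerable projected thickness, delta/(2*NA).

    Features at top and bottom surfaces of a thicker sample would translate at
    measurably different camera lengths across the field of view, breaking the
    single-map registration model.
    """
    if delta <= 0 or na <= 0:
        raise InvalidGeometryError("demagnified pixel and NA must be > 0")
    return delta / (2.0 * na)


def tilt_limit(delta: float, fov: float) -> float:
    """Maximum tolerable scan-plane tilt, delta/FOV (radians)."""
    if delta <= 0 or fov <= 0:
        raise InvalidGeometryError("demagnified pixel and FOV must be > 0")
    return delta / fov


def validity_limits(delta: float, na: float, fov: float) -> Tuple[float, float]:
    """(thickness limit, tilt limit) of the speckle-tracking model."""
    return thickness_limit(delta, na), tilt_limit(delta, fov)


def angular_sensitivity_bound(
    pixel_size: float, delta_pix: float, z: float, mag: float
) -> float:
    """Ideal smallest resolvable ray deviation, dTheta = delta_pix*sigma/(z*M).

    ``delta_pix`` is the fractional effective pixel size achieved by sub-pixel
    interpolation (1 = no interpolation gain); ``pixel_size`` is the detector
    point-spread width (>= the physical pixel).
    """
    if pixel_size <= 0 or z <= 0 or mag <= 0:
        raise InvalidGeometryError("pixel size, z and M must be > 0")
    if delta_pix < 0:
        raise InvalidGeometryError(f"delta_pix must be >= 0, got {delta_pix}")
    return delta_pix * pixel_size / (z * mag)


def effective_fresnel_number(feature: float, wavelength: float, zbar: float) -> float:
    """Effective Fresnel number N_F = X^2/(lambda*zbar) of a full-period feature X.

    N_F >> 1 is the edge-projection regime; N_F ~< 1 features show several
    Fresnel fringes in the hologram.
    """
    if feature <= 0 or wavelength <= 0 or zbar <= 0:
        raise InvalidGeometryError("feature, wavelength and zbar must be > 0")
    return feature**2 / (wavelength * zbar)


def rayleigh_separation(wavelength: float, zbar: float, convention: str = "sqrt") -> float:
    """Direct-space two-point separation limit of the defocused hologram.

    The hologram blurs a point edge over the first Fresnel-fringe scale
    ``sqrt(lambda*zbar)``.  Two conventions are in circulation:

    * ``"sqrt"``:  sqrt(lambda*zbar)      (single fringe scale)
    * ``"edge-overlap"``: the numerically computed separation at which the
      first minimum of one knife-edge fringe pattern coincides with the
      zeroth-order maximum of the adjacent edge (~2.2*sqrt(lambda*zbar), see
      :func:`knife_edge_overlap_separation`).
    """
    if convention == "sqrt":
        return float(np.sqrt(wavelength * zbar))
    if convention == "edge-overlap":
        return knife_edge_overlap_separation(wavelength, zbar)
    raise ValueError(f"unknown convention {convention!r}")


def knife_edge_overlap_separation(
    wavelength: float, zbar: float, n: int = 8192, half_width_scale: float = 12.0
) -> float:
    """Numeric knife-edge oracle for the edge-overlap resolution convention.

    Computes the 1D Fresnel diffraction pattern of an opaque half-plane at
    propagation distance ``zbar`` and returns x_min + x_max: the distance from
    the geometric edge to the first intensity minimum of the fringe system
    plus the distance to the zeroth-order (first, brightest) maximum.  Two
    opposing edges separated by less than this overlap destructively.
    """
    s = np.sqrt(wavelength * zbar)
    # dimensionless Fresnel coordinate w = x*sqrt(2/(lambda*zbar))
    x = np.linspace(-half_width_scale, half_width_scale, n) * s
    w = x * np.sqrt(2.0 / (wavelength * zbar))
    from scipy.special import fresnel  # S(t), C(t)

    S, C = fresnel(w)
    inten = 0.5 * ((C + 0.5) ** 2 + (S + 0.5) ** 2)  # knife edge: opaque x<0
    bright = x > 0
    ib = inten[bright]
    xb = x[bright]
    # zeroth-order maximum: first local max; first minimum follows it
    d1 = np.diff(ib)
    turn = np.where((d1[:-1] > 0) & (d1[1:] <= 0))[0]
    x_max = xb[turn[0] + 1]
    turn_min = np.where((d1[:-1] < 0) & (d1[1:] >= 0))[0]
    turn_min = turn_min[turn_min > turn[0]]
    x_min = xb[turn_min[0] + 1]
    return float(x_min + x_max)


@dataclass(frozen=True)
class DerivedGeometry:
    """Closed-form quantities derived from an :class:`ExperimentGeometry`.

    Scalar fields are per-axis arithmetic means; the ``*_x``/``*_y`` fields
    carry the astigmatic per-axis values.
    """

    magnification_x: float
    magnification_y: float
    magnification: float
    effective_defocus_x: float
    effective_defocus_y: float
    effective_defocus: float
    demagnified_pixel_x: float
    demagnified_pixel_y: float
    demagnified_pixel: float
    numerical_aperture: float
    field_of_view: float
    thickness_limit: float
    tilt_limit: float
    sensitivity_bound: float

    def fresnel_number(self, feature: float, wavelength: float) -> float:
        return effective_fresnel_number(feature, wavelength, self.effective_defocus)


@dataclass(frozen=True)
class ExperimentGeometry:
    """Divergent-beam projection imaging geometry.

    Parameters
    ----------
    photon_energy : float
        Photon energy in keV.
    focus_sample_x, focus_sample_y : float
        Distances (m) from the horizontal / vertical focal planes to the
        sample plane.  Equal values describe a stigmatic system.
    sample_detector : float
        Sample-to-detector distance z (m).
    detector_shape : (int, int)
        (rows, cols) of the detector region of interest.
    pixel_size : float
        Square detector pixel side sigma_det (m).
    interpolation_factor : float
        delta_pix in (0, 1]: fractional effective pixel size achieved by
        sub-pixel interpolation.
    sample_tilt : float
        Tilt of the scan plane relative to the transverse plane (rad).
    na_override : float, optional
        User-supplied numerical aperture; when absent NA is computed from the
        detector half-extent divided by (z1 + z).
    """

    photon_energy: float
    focus_sample_x: float
    focus_sample_y: float
    sample_detector: float
    detector_shape: Tuple[int, int]
    pixel_size: float = 55e-6
    interpolation_factor: float = 1.0
    sample_tilt: float = 0.0
    na_override: Optional[float] = None

    def __post_init__(self):
        if self.photon_energy <= 0:
            raise InvalidGeometryError("photon_energy must be > 0")
        for name in ("focus_sample_x", "focus_sample_y", "sample_detector", "pixel_size"):
            if getattr(self, name) <= 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if len(self.detector_shape) != 2 or min(self.detector_shape) < 2:
            raise InvalidGeometryError("detector_shape must be (rows, cols) >= (2, 2)")
        if not (0 < self.interpolation_factor <= 1):
            raise InvalidGeometryError("interpolation_factor must be in (0, 1]")
        object.__setattr__(self, "detector_shape", tuple(int(s) for s in self.detector_shape))

    # -- basic properties -------------------------------------------------
    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.photon_energy)

    @property
    def focus_sample(self) -> float:
        """Mean focus-to-sample distance."""
        return 0.5 * (self.focus_sample_x + self.focus_sample_y)

    @property
    def magnification_x(self) -> float:
        return magnification(self.focus_sample_x, self.sample_detector)

    @property
    def magnification_y(self) -> float:
        return magnification(self.focus_sample_y, self.sample_detector)

    @property
    def magnification(self) -> float:
        return 0.5 * (self.magnification_x + self.magnification_y)

    @property
    def effective_defocus(self) -> float:
        return 0.5 * (
            effective_defocus(self.focus_sample_x, self.sample_detector)
            + effective_defocus(self.focus_sample_y, self.sample_detector)
        )

    @property
    def demagnified_pixel(self) -> float:
        return demagnified_pixel(self.pixel_size, self.magnification)

    @property
    def numerical_aperture(self) -> float:
        if self.na_override is not None:
            return self.na_override
        half_extent = 0.25 * (self.detector_shape[0] + self.detector_shape[1]) * self.pixel_size
        return half_extent / (self.focus_sample + self.sample_detector)

    @property
    def field_of_view(self) -> float:
        """Side length of the beam footprint at the sample (detector extent / M)."""
        extent = 0.5 * (self.detector_shape[0] + self.detector_shape[1]) * self.pixel_size
        return extent / self.magnification

    # -- grids ------------------------------------------------------------
    def detector_coords(self):
        """Physical (y, x) coordinate grids of pixel centres, origin at centre."""
        ny, nx = self.detector_shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_size
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size
        return np.meshgrid(y, x, indexing="ij")

    def derived(self) -> DerivedGeometry:
        mx, my = self.magnification_x, self.magnification_y
        zbx = effective_defocus(self.focus_sample_x, self.sample_detector)
        zby = effective_defocus(self.focus_sample_y, self.sample_detector)
        dx = demagnified_pixel(self.pixel_size, mx)
        dy = demagnified_pixel(self.pixel_size, my)
        d = 0.5 * (dx + dy)
        na = self.numerical_aperture
        fov = self.field_of_view
        return DerivedGeometry(
            magnification_x=mx,
            magnification_y=my,
            magnification=0.5 * (mx + my),
            effective_defocus_x=zbx,
            effective_defocus_y=zby,
            effective_defocus=0.5 * (zbx + zby),
            demagnified_pixel_x=dx,
            demagnified_pixel_y=dy,
            demagnified_pixel=d,
            numerical_aperture=na,
            field_of_view=fov,
            thickness_limit=thickness_limit(d, na),
            tilt_limit=tilt_limit(d, fov),
            sensitivity_bound=angular_sensitivity_bound(
                self.pixel_size, self.interpolation_factor, self.sample_detector, self.magnification
            ),
        )
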