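"""HDF5 scan container (CXI-style layout), configuration, exports.

Layout
------
::

    /entry_1/data_1/data                         (N, R, C) photon counts
    /entry_1/sample_1/geometry/translation       (N, 3) metres, columns (x, y, z)
    /entry_1/instrument_1/detector_1/distance    sample-detector z (m)
    /entry_1/instrument_1/detector_1/x_pixel_size, y_pixel_size  (m)
    /entry_1/instrument_1/detector_1/mask        (R, C), 1 = good
    /entry_1/instrument_1/source_1/energy        photon energy (eV)
    /speckle_tracking/focus_sample               (2,) = (z1x, z1y) (m)
    /speckle_tracking/*                          reconstruction results
    /truth/*                                     simulation ground truth

Coordinate convention (the one place it is defined): in-memory arrays use
axis 0 = slow/vertical with y increasing downward in file order; the
physical y axis points up, so the translation y component flips sign
between memory and file.  Translations are stored 3D per the CXI
convention; only (x, y) are used and z must be ~0 (the scan plane is
transverse).
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import h5py
import numpy as np
import yaml

from .core import PixelMap, ReferenceImage, ScanData, WhiteField
from .geometry import ExperimentGeometry

__all__ = ["write_scan", "read_scan", "write_results", "read_config", "export_tiff"]

_REQUIRED = [
    "/entry_1/data_1/data",
    "/entry_1/sample_1/geometry/translation",
    "/entry_1/instrument_1/detector_1/distance",
    "/entry_1/instrument_1/detector_1/x_pixel_size",
    "/entry_1/instrument_1/source_1/energy",
    "/speckle_tracking/focus_sample",
]


def _set(f, path, data, units=None):
    if path in f:
        del f[path]
    d = f.create_dataset(path, data=data)
    if units:
        d.attrs["units"] = units
    return d


def write_scan(path, scan: ScanData, truth: Optional[dict] = None) -> None:
    """Write a scan (and optional simulation ground truth) to HDF5."""
    g = scan.geometry
    with h5py.File(path, "w") as f:
        _set(f, "/entry_1/data_1/data", scan.frames, units="photons")
        t3 = np.zeros((scan.n_frames, 3))
        t3[:, 0] = scan.translations[:, 1]  # x
        t3[:, 1] = -scan.translations[:, 0]  # physical y -> file order
        _set(f, "/entry_1/sample_1/geometry/translation", t3, units="m")
        det = "/entry_1/instrument_1/detector_1"
        _set(f, det + "/distance", g.sample_detector, units="m")
        _set(f, det + "/x_pixel_size", g.pixel_size, units="m")
        _set(f, det + "/y_pixel_size", g.pixel_size, units="m")
        _set(f, det + "/mask", scan.mask.astype(np.uint8))
        _set(f, "/entry_1/instrument_1/source_1/energy", g.photon_energy * 1e3, units="eV")
        _set(f, "/speckle_tracking/focus_sample", [g.focus_sample_x, g.focus_sample_y], units="m")
        _set(f, "/speckle_tracking/interpolation_factor", g.interpolation_factor)
        _set(f, "/speckle_tracking/sample_tilt", g.sample_tilt, units="rad")
        if truth:
            for key, val in truth.items():
                if val is None:
                    continue
                if isinstance(val, PixelMap):
                    _set(f, f"/truth/{key}", val.u, units="m")
                elif isinstance(val, ReferenceImage):
                    d = _set(f, f"/truth/{key}", val.data)
                    d.attrs["pitch"] = val.pitch
                    d.attrs["origin"] = val.origin
                elif isinstance(val, WhiteField):
                    _set(f, f"/truth/{key}", val.data, units="photons")
                else:
                    _set(f, f"/truth/{key}", np.asarray(val))


def read_scan(path) -> Tuple[ScanData, ExperimentGeometry]:
    """Read a scan container; raises naming the first missing HDF5 path."""
    with h5py.File(path, "r") as f:
        for req in _REQUIRED:
            if req not in f:
                raise KeyError(f"scan container missing expected HDF5 path {req}")
        frames = f["/entry_1/data_1/data"][()].astype(float)
        t3 = f["/entry_1/sample_1/geometry/translation"]
        if "units" not in t3.attrs:
            warnings.warn("translation dataset has no units attribute; assuming metres")
        t3 = t3[()]
        if t3.ndim != 2 or t3.shape[1] != 3:
            raise ValueError("translation dataset must be (N, 3)")
        if np.abs(t3[:, 2]).max() > 1e-9:
            warnings.warn("translation z component is not ~0; ignoring it")
        translations = np.stack([-t3[:, 1], t3[:, 0]], axis=1)  # file -> (y, x) memory
        det = f["/entry_1/instrument_1/detector_1"]
        z = float(det["distance"][()])
        pix = float(det["x_pixel_size"][()])
        mask = (
            det["mask"][()].astype(bool)
            if "mask" in det
            else np.ones(frames.shape[1:], dtype=bool)
        )
        energy_ev = float(f["/entry_1/instrument_1/source_1/energy"][()])
        z1 = f["/speckle_tracking/focus_sample"][()]
        extra = {}
        if "/speckle_tracking/interpolation_factor" in f:
            extra["interpolation_factor"] = float(
                f["/speckle_tracking/interpolation_factor"][()]
            )
        if "/speckle_tracking/sample_tilt" in f:
            extra["sample_tilt"] = float(f["/speckle_tracking/sample_tilt"][()])
    geometry = ExperimentGeometry(
        photon_energy=energy_ev / 1e3,
        focus_sample_x=float(z1[0]),
        focus_sample_y=float(z1[1]),
        sample_detector=z,
        detector_shape=frames.shape[1:],
        pixel_size=pix,
        **extra,
    )
    scan = ScanData(frames=frames, translations=translations, mask=mask, geometry=geometry)
    return scan, geometry


def read_truth(path) -> dict:
    """Read the simulation ground-truth group, if present."""
    out = {}
    with h5py.File(path, "r") as f:
        if "/truth" not in f:
            return out
        for key, d in f["/truth"].items():
            arr = d[()]
            if "pitch" in d.attrs:
                out[key] = ReferenceImage(
                    data=arr, pitch=float(d.attrs["pitch"]), origin=tuple(d.attrs["origin"])
                )
            else:
                out[key] = arr
    return out


def write_results(path, results) -> None:
    """Write reconstruction results under /speckle_tracking."""
    with h5py.File(path, "a") as f:
        base = "/speckle_tracking"
        d = _set(f, base + "/reference_image", results.reference.data)
        d.attrs["pitch"] = results.reference.pitch
        d.attrs["origin"] = results.reference.origin
        _set(f, base + "/reference_coverage", results.reference.coverage)
        _set(f, base + "/pixel_map", results.pixel_map.u, units="m")
        t3 = np.zeros((results.translations.shape[0], 3))
        t3[:, 0] = results.translations[:, 1]
        t3[:, 1] = -results.translations[:, 0]
        _set(f, base + "/translations", t3, units="m")
        _set(f, base + "/sse_log", results.sse_log)
        _set(f, base + "/white_field", results.white_field.data, units="photons")
        _set(f, base + "/phase_residual", results.wavefront.phi_res, units="rad")
        _set(f, base + "/ray_angles", results.wavefront.theta, units="rad")
        _set(f, base + "/phase_gradient", results.wavefront.grad, units="rad/m")
        if results.flagged is not None:
            _set(f, base + "/flagged", results.flagged.astype(np.uint8))


def read_config(path) -> ExperimentGeometry:
    """Read a flat key-value text (YAML) geometry config.

    Keys: energy_kev, focus_sample_x_m, focus_sample_y_m, sample_detector_m,
    pixel_size_m, roi (rows, cols); optional interpolation_factor,
    sample_tilt_rad.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be flat key: value text")
    roi = cfg["roi"]
    return ExperimentGeometry(
        photon_energy=float(cfg["energy_kev"]),
        focus_sample_x=float(cfg["focus_sample_x_m"]),
        focus_sample_y=float(cfg["focus_sample_y_m"]),
        sample_detector=float(cfg["sample_detector_m"]),
        detector_shape=(int(roi[0]), int(roi[1])),
        pixel_size=float(cfg["pixel_size_m"]),
        interpolation_factor=float(cfg.get("interpolation_factor", 1.0)),
        sample_tilt=float(cfg.get("sample_tilt_rad", 0.0)),
    )


def export_tiff(path, array) -> None:
    """Export a 2D float map (reference, phase, ...) as TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
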