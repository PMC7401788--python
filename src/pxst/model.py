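"""Model/Results interface for the speckle-tracking reconstruction.

:class:`PXSTModel` wraps a scan and its geometry; :meth:`PXSTModel.fit`
runs the iterative update — white field, reference synthesis, per-pixel map
refinement with a scheduled Gaussian regularization, irrotational
projection of the implied phase gradient, translation refinement — and
returns a :class:`PXSTResults` carrying the recovered reference hologram,
pixel map, wavefront, refined translations, the per-iteration error log and
a text ``summary()``.  Downstream analyses (sensitivity, thickness,
resolution, focal propagation) hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import core, defocus, metrology, sample, wavefront
from .core import PixelMap, ReferenceImage, ScanData, WhiteField
from .geometry import ExperimentGeometry

__all__ = ["PXSTModel", "PXSTResults", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """The model error increased persistently across iterations."""

    def __init__(self, message, sse_log=None):
        super().__init__(message)
        self.sse_log = sse_log


class PXSTModel:
    """Speckle-tracking model of a near-field scan.

    Parameters
    ----------
    scan : ScanData
    geometry : ExperimentGeometry, optional
        Defaults to ``scan.geometry``; pass a replacement to refit with
        revised focus distances.
    """

    def __init__(self, scan: ScanData, geometry: Optional[ExperimentGeometry] = None):
        self.scan = scan
        self.geometry = geometry if geometry is not None else scan.geometry

    @classmethod
    def from_file(cls, path) -> "PXSTModel":
        from .io import read_scan

        scan, geometry = read_scan(path)
        return cls(scan, geometry)

    @classmethod
    def from_simulation(cls, sim) -> "PXSTModel":
        return cls(sim.scan)

    # -- initialization helpers ------------------------------------------
    def estimate_defocus(
        self, method: str = "thon", z1_candidates=None, **kwargs
    ) -> defocus.DefocusEstimate:
        """Initial per-axis focus-distance estimate (``thon`` or ``sse``)."""
        if method == "thon":
            spec = defocus.cumulative_power_spectrum(self.scan)
            return defocus.fit_thon_rings(spec, self.geometry, **kwargs)
        if method == "sse":
            if z1_candidates is None:
                z1 = self.geometry.focus_sample
                z1_candidates = np.linspace(0.8 * z1, 1.2 * z1, 11)
            return defocus.scan_defocus_sse(self.scan, z1_candidates)
        raise ValueError(f"unknown method {method!r}")

    def initial_pixel_map(self) -> PixelMap:
        return core.initial_pixel_map(self.geometry, self.scan.mask)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        n_iter: int = 3,
        search_radius: int = 5,
        reg_schedule: Optional[Sequence[float]] = None,
        refine_translations: bool = True,
        translation_radius: int = 3,
        initial_map: Optional[PixelMap] = None,
        white: Optional[WhiteField] = None,
        reference_pitch: Optional[float] = None,
        boundary: str = "natural",
        project: bool = True,
        divergence_tol: float = 0.01,
        verbose: bool = False,
    ) -> "PXSTResults":
        """Run the iterative speckle-tracking update.

        ``white`` overrides the median-estimated white field (e.g. a
        directly recorded empty-beam image, or when the scan span is too
        small for the per-pixel median to see past the sample).
        ``reg_schedule`` lists the Gaussian regularization width (detector
        pixels) per iteration — e.g. ``numpy.linspace(20, 0, n_iter)`` for
        the linear taper that suppresses lattice mis-registration on
        quasi-periodic samples; default is no regularization.  Aborts with
        :class:`ConvergenceError` when the total SSE increases by more than
        ``divergence_tol`` (relative) in two consecutive iterations.
        """
        if n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if reg_schedule is None:
            reg_schedule = [0.0] * n_iter
        reg_schedule = list(reg_schedule)
        if len(reg_schedule) != n_iter:
            raise ValueError("reg_schedule length must equal n_iter")

        scan = self.scan
        geometry = self.geometry
        if white is None:
            white = core.estimate_white_field(scan)
        umap = initial_map.copy() if initial_map is not None else self.initial_pixel_map()
        translations = scan.translations.copy()
        sse_log = []
        flags = None
        n_increase = 0
        reference = None
        for it in range(n_iter):
            current = ScanData(scan.frames, translations, scan.mask, geometry)
            reference = core.build_reference(current, white, umap, pitch=reference_pitch)
            umap, info = core.update_pixel_map(
                scan,
                white,
                reference,
                umap,
                search_radius=search_radius,
                reg_sigma=reg_schedule[it],
                translations=translations,
            )
            flags = info["flagged"]
            if project:
                umap = self._project_map(umap, geometry, boundary)
            if refine_translations:
                sub = ScanData(scan.frames, translations, scan.mask, geometry)
                translations, _ = core.update_translations(
                    sub, white, reference, umap, search_radius=translation_radius
                )
            _, _, total = core.compute_error_map(
                scan, white, reference, umap, translations=translations
            )
            sse_log.append(total)
            if verbose:
                print(f"iteration {it + 1}/{n_iter}: SSE = {total:.6e}")
            # the divergence guard only applies once annealing is over: a
            # nonzero smoothing width deliberately trades SSE for smoothness
            if it > 0 and reg_schedule[it] == 0 and total > sse_log[-2] * (1 + divergence_tol):
                n_increase += 1
                if n_increase >= 2:
                    raise ConvergenceError(
                        f"SSE increased for two consecutive iterations "
                        f"(log: {sse_log})",
                        sse_log=sse_log,
                    )
            else:
                n_increase = 0

        # final reference consistent with the last map and translations
        reference = core.build_reference(
            ScanData(scan.frames, translations, scan.mask, geometry),
            white, umap, pitch=reference_pitch,
        )
        wf = wavefront.WavefrontField.from_pixel_map(
            umap, white.data, geometry, boundary=boundary, project=project
        )
        return PXSTResults(
            model=self,
            white_field=white,
            reference=reference,
            pixel_map=umap,
            translations=translations,
            wavefront=wf,
            sse_log=np.asarray(sse_log),
            reg_schedule=np.asarray(reg_schedule, dtype=float),
            search_radius=search_radius,
            flagged=flags,
        )

    @staticmethod
    def _project_map(umap: PixelMap, geometry: ExperimentGeometry, boundary: str) -> PixelMap:
        """Enforce the irrotational constraint on the implied phase gradient.

        The affine (magnification + tilt) part is curl-free by construction;
        only the residual is projected, then the map is reassembled.
        """
        grad = wavefront.gradient_from_map(umap, geometry)
        res, _ = wavefront.remove_low_orders_gradient(grad, geometry.pixel_size, umap.mask)
        affine = grad - res
        res_p = wavefront.irrotational_projection(res, boundary=boundary, mask=umap.mask)
        full = affine + res_p
        y, x = geometry.detector_coords()
        s = geometry.wavelength * geometry.sample_detector / (2 * np.pi)
        u = np.stack([y - s * full[0], x - s * full[1]])
        return PixelMap(u, umap.mask.copy())


@dataclass
class PXSTResults:
    """Results of a speckle-tracking fit."""

    model: PXSTModel
    white_field: WhiteField
    reference: ReferenceImage
    pixel_map: PixelMap
    translations: np.ndarray
    wavefront: wavefront.WavefrontField
    sse_log: np.ndarray
    reg_schedule: np.ndarray
    search_radius: int
    flagged: Optional[np.ndarray] = None

    @property
    def geometry(self) -> ExperimentGeometry:
        return self.model.geometry

    # -- downstream analyses ----------------------------------------------
    def sensitivity(self, seed: int = 0, search_radius: int = 1) -> metrology.SensitivityReport:
        return metrology.split_half_sensitivity(
            self.model.scan,
            self.white_field,
            self.reference,
            self.pixel_map,
            geometry=self.geometry,
            translations=self.translations,
            seed=seed,
            search_radius=search_radius,
        )

    def thickness(self, method: str = "tie", **kwargs) -> sample.ThicknessMap:
        """Projected-thickness retrieval from the reference hologram."""
        data = np.where(np.isfinite(self.reference.data), self.reference.data, 1.0)
        zbar = self.geometry.derived().effective_defocus
        lam = self.geometry.wavelength
        fn = sample.tie_thickness if method == "tie" else sample.ctf_thickness
        return fn(data, lam, zbar, self.reference.pitch, **kwargs)

    def resolution(self, **kwargs) -> sample.ResolutionReport:
        data = self.reference.data
        mask = np.isfinite(data)
        return sample.fps_resolution(
            np.where(mask, data, 1.0), self.reference.pitch, mask=mask, **kwargs
        )

    def focus_stack(self, offsets) -> wavefront.FocusStack:
        g = self.geometry
        lam = g.wavelength
        ry = self.wavefront.low_order.focus_distance_y(lam)
        rx = self.wavefront.low_order.focus_distance_x(lam)
        return wavefront.propagate_to_focus(
            self.white_field.data,
            self.wavefront.phi_res,
            lam,
            g.pixel_size,
            offsets,
            curvature=(ry, rx),
            mask=self.pixel_map.mask,
        )

    # -- reporting ---------------------------------------------------------
    def map_distortion_rms(self) -> float:
        """RMS deviation (ref px) of the map from pure magnification."""
        ideal = core.initial_pixel_map(self.geometry, self.pixel_map.mask)
        d = (self.pixel_map.u - ideal.u) / self.reference.pitch
        m = self.pixel_map.mask & ~(self.flagged if self.flagged is not None else False)
        return float(np.sqrt(np.mean(d[:, m] ** 2)))

    def summary(self) -> str:
        g = self.geometry
        d = g.derived()
        lam = g.wavelength
        lines = [
            "Speckle-tracking reconstruction summary",
            "=" * 55,
            f"{'Photon energy':35s} {g.photon_energy:.4g} keV",
            f"{'Wavelength':35s} {lam * 1e10:.4f} A",
            f"{'Detector ROI':35s} {g.detector_shape[0]} x {g.detector_shape[1]} px",
            f"{'Pixel size':35s} {g.pixel_size * 1e6:.1f} um",
            f"{'Sample-detector distance':35s} {g.sample_detector:.5g} m",
            f"{'Focus-sample distance (x, y)':35s} "
            f"{g.focus_sample_x * 1e3:.4g}, {g.focus_sample_y * 1e3:.4g} mm",
            f"{'Average magnification':35s} {d.magnification:.1f}",
            f"{'Effective defocus':35s} {d.effective_defocus * 1e3:.3g} mm",
            f"{'Demagnified pixel':35s} {d.demagnified_pixel * 1e9:.1f} nm",
            f"{'Numerical aperture':35s} {d.numerical_aperture:.4f}",
            f"{'Field of view (sample)':35s} {d.field_of_view * 1e6:.2f} um",
            f"{'Thickness limit':35s} {d.thickness_limit * 1e6:.2f} um",
            f"{'Angular sensitivity bound':35s} {d.sensitivity_bound * 1e9:.1f} nrad",
            "-" * 55,
            f"{'Iterations':35s} {len(self.sse_log)}",
            f"{'Regularization schedule (px)':35s} "
            + ", ".join(f"{s:g}" for s in self.reg_schedule),
            f"{'SSE (first -> last)':35s} "
            f"{self.sse_log[0]:.4e} -> {self.sse_log[-1]:.4e}",
            f"{'Map distortion RMS':35s} {self.map_distortion_rms():.3f} ref px",
            f"{'Refined focus-sample x':35s} "
            f"{self.wavefront.refined_focus_sample_x() * 1e3:.4g} mm",
            f"{'Refined focus-sample y':35s} "
            f"{self.wavefront.refined_focus_sample_y() * 1e3:.4g} mm",
            f"{'Residual phase RMS':35s} "
            f"{float(np.std(self.wavefront.phi_res[self.pixel_map.mask])):.3f} rad",
            f"{'Flagged pixels':35s} "
            f"{int(self.flagged.sum()) if self.flagged is not None else 0}",
        ]
        return "\n".join(lines)

    def save(self, path):
        from .io import write_results

        write_results(path, self)

    # -- plotting -----------------------------------------------------------
    def plot_summary(self, path=None):
        """Reference image, residual phase and convergence log on one figure."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        axes[0].imshow(self.reference.data, cmap="gray")
        axes[0].set_title("reference hologram")
        im = axes[1].imshow(
            np.where(self.pixel_map.mask, self.wavefront.phi_res, np.nan), cmap="RdBu_r"
        )
        fig.colorbar(im, ax=axes[1], label="rad")
        axes[1].set_title("residual pupil phase")
        axes[2].semilogy(np.arange(1, len(self.sse_log) + 1), self.sse_log, "o-")
        axes[2].set_xlabel("iteration")
        axes[2].set_ylabel("total SSE")
        axes[2].set_title("convergence")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
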