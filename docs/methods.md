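# Methods

## The imaging model

A lens system (here: two crossed multilayer Laue lenses) focuses a hard
X-ray beam; a thin sample placed a distance `z1` downstream of the focus
casts a magnified near-field shadow image (in-line hologram) on a detector a
distance `z` further downstream.  For an ideal lens the image is a
defocused, magnified copy of the sample with magnification
`M = (z1 + z)/z1` and effective (plane-wave-equivalent) propagation distance
`zbar = z*z1/(z1 + z)`.  A real lens adds aberrations: the measured frame
`n` obeys the pseudo-geometric forward model

    I_n(x) = W(x) * I_ref(u(x) - dx_n),

where `W` is the white field (intensity without the sample), `dx_n` the
known sample translations, `I_ref` the undistorted magnified hologram
("reference"), and `u` the pixel map relating detector pixels to
reference-frame coordinates.  The map encodes the detector-plane phase
gradient of the illumination,

    u(x) = x - (lambda*z / 2*pi) * grad(Phi)(x),

so recovering `u` recovers the wavefront: ray angles
`Theta = (lambda/2pi) grad(Phi)`, and the phase by least-squares 2D
integration.  For an astigmatic system the horizontal and vertical focal
planes differ (`z1x != z1y`) and all derived quantities exist per axis; the
initial map is the per-axis magnification `u_a = x_a * z1a/(z1a + z)`.

Validity limits implemented in `pxst.geometry`: the projected sample
thickness must satisfy `dz < delta/(2 NA)` (features at top and bottom
surfaces would otherwise translate at measurably different camera lengths),
and the scan-plane tilt `phi < delta/FOV`, with `delta = sigma_det/M` the
demagnified pixel.  The ideal angular sensitivity is
`dTheta = delta_pix * sigma_det/(z*M)`.

## Reconstruction algorithm (`pxst.core`, `pxst.model`)

`PXSTModel.fit` alternates, per iteration:

1. **Reference synthesis.** Every white-field-normalized sample
   `I_n(x)/W(x)` is deposited at `u(x) - dx_n` by bilinear splatting with
   statistical weight `W^2`; the weighted mean is then polished by ~10
   conjugate-gradient steps on the underlying weighted least-squares
   problem (bilinear sampling operator and its exact adjoint).  The polish
   matters: the raw splat-mean is slightly blurred, which biases the
   per-pixel update by ~0.1 reference pixels.  The reference pitch defaults
   to half the demagnified pixel so bilinear representation error stays
   sub-dominant.
2. **Pixel-map update.** Per detector pixel, the model error summed over
   frames is evaluated on an integer grid of reference-pixel shifts
   (half-width `search_radius`), then refined by fitting a 2D quadratic to
   3x3 error patches re-evaluated at fractional spacings 0.5 and 0.25
   (fitting at integer spacing alone is biased wherever the surface is
   locally non-quadratic, e.g. at an exact-zero minimum).  Degenerate
   (flat or non-convex) pixels are flagged and keep their previous value.
   With `reg_sigma > 0` the map's deviation from its affine part is
   smoothed by a normalized Gaussian of that width — the regularization
   used on quasi-periodic samples (below).
3. **Irrotational projection.** The implied phase gradient must be
   curl-free.  The affine part (magnification + tilt) is curl-free by
   construction; the residual is projected onto the range of the discrete
   gradient operator by a cached sparse least-squares solve, and the map is
   reassembled.
4. **Translation refinement.** Per frame, a global offset minimizing the
   whole-frame error (integer grid + sub-pixel parabola); the mean
   correction is removed, since a common shift of all translations is
   indistinguishable from a shift of the reference (gauge).

The total SSE is logged per iteration; the fit aborts when it grows in two
consecutive un-regularized iterations (during annealing the smoothing
deliberately trades SSE for smoothness, so the guard is suspended).

Gauges worth knowing when comparing with ground truth: the recovered map is
defined up to a constant offset (absorbed by the reference origin), and its
affine part is attributed to the wavefront (defocus/tilt), not the sample.

## Wavefront analysis (`pxst.wavefront`)

The defocus quadratic of a hard X-ray lens is numerically huge
(10^8 rad across the detector) and its direct samples alias on any real
detector grid, so low orders are fitted and removed **in gradient space**
(a joint linear fit with shared cross term); only the smooth residual is
integrated (DCT-free sparse least-squares with zero-mean gauge, reflective
"natural" boundary; a periodic FFT variant exists for periodic test
fields).  The fitted curvatures return refined per-axis focus distances
through `c = pi/(lambda*R)`, which is how initial `z1` errors (up to
+-20%) are corrected after the fact.  Low-order basis is raw monomials on
normalized coordinates — the support is rectangular, not circular, so
Zernike polynomials offer no advantage.

Focal-region propagation factors the quadratic out analytically: the
single-FFT scaled Fresnel transform is applied to
`sqrt(W)*exp(i*phi_res)` with the known curvature folded into the chirp, so
only smooth fields are ever sampled.  Each requested plane reports its own
transverse pitch; axial projections are resampled onto a common grid as
linear energy densities.  A sampling guard rejects planes whose combined
chirp would alias, naming the safe offset range.

## Synthetic data (`pxst.phantoms`)

The generator defines the study conditions for every test:

* **Siemens star** — 10 um diameter, 30 spokes with even angular duty
  cycle, 100 nm tips, two transparent circular cuts, gold with thickness
  ramping 0.5 to 1 um (approximate tabulated gold optical constants near
  16.5 keV: delta = 1.15e-5, beta = 1.1e-6).  Rendered 2x supersampled.
* **Hexagonal lattice** — Gaussian dots on a lattice of constant 601 nm
  with an aperiodic Gaussian envelope; the quasi-periodic stress test.
* **Diffuser** — Gaussian-filtered noise thickness; the classic dense
  speckle object, used for defocus fitting and metrology (isotropic
  spectrum, contrast at every pixel).
* **Pupil** — astigmatic quadratic (from `z1x`, `z1y`) plus a polynomial
  residual over normalized detector coordinates, with analytic gradients;
  preset residuals are rescaled to a requested map distortion in
  demagnified pixels.

Two forward models share one ground truth.  `geometric` evaluates the
speckle-tracking model exactly (the reference is the Fresnel-propagated
hologram of the phantom at the per-axis effective defocus, then sampled
through the true map) — the oracle separating algorithm error from model
error.  `wave` propagates the aberrated, shifted exit wave by the scaled
(magnifier) Fresnel theorem — per-axis transfer-function propagation at
`zbar_a`, then anisotropic magnification onto the detector.  The two agree
to image correlation > 0.98 for mild aberrations; the residual difference
is genuine model error of the pseudo-geometric approximation.  Poisson
noise is applied to expected counts with a seeded generator;
simulations are bit-reproducible.  Default scan grids and steps follow the
reported scan shapes (9x9 down-scaled from 20x20; steps ~20 demagnified
pixels); the smooth low-order illumination envelope emulates non-uniform
upstream illumination (no parametric form is published; a quadratic-plus-
tilt surface is used).

What the generator does **not** emulate: partial coherence, detector PSF
beyond pixel integration, beam drift, and the MLL's internal diffraction.
Green tests therefore validate the algorithmic chain, not those physical
effects.

## Defocus initialization (`pxst.defocus`)

The cumulative power spectrum `sum_n |FT(I_n/W - 1)|^2` of an edge-rich
sample shows Thon rings.  For the magnified geometry the ring phase
collapses to `chi = pi*lambda*z*(Mx*fx^2 + My*fy^2)` (using
`zbar*M^2 = z*M`), so the fit averages the spectrum over shells of constant
`chi` — which also circularizes the anisotropically magnified sample
spectrum — subtracts a moving 30th-percentile background along the shell
coordinate, and maximizes the pixel-level normalized correlation with
`sin^2(chi)` over `(z1x, z1y)` (coarse log grid, simplex refinement, band
0.1–0.8 Nyquist).  Correlating at pixel rather than bin level matters: bin
noise is correlated at the background-window scale and produces spurious
scores on ring-free spectra.  A best score below 0.1 reports failure — the
regime with only first-order fringes, where the fallback applies: a
brute-force scan of `z1` candidates, each evaluated by one cheap pass
(ideal map, raw splat-mean reference, SSE), taking the arg-min.  The
absorption/phase ratio of real materials shifts ring zeros by
`atan(beta/delta)`, which biases the fitted defocus by a few percent
(within the 5% acceptance band); the sin^2 model is kept for parsimony.

## Quasi-periodic samples and regularization

On a (quasi-)periodic sample the per-pixel error surface is periodic in the
lattice vectors, and tracking can mis-register by exactly one lattice
constant.  Two regimes were mapped with the hex phantom (lattice
~9.2 demagnified pixels):

* search radius >= lattice constant: wholesale disorder (every pixel picks
  a random site) — avoid; keep `search_radius` below the lattice constant.
* search radius ~0.65 a with distortion near a/2 plus photon noise:
  scattered mis-registrations that self-reinforce through the reference,
  producing contiguous plateaus offset by exactly one lattice constant.

The cure is the annealed regularization: the recovered pixel-shift field is
smoothed each iteration with a Gaussian whose width tapers linearly from
20 px to 0 px, preventing sharp deviations from forming early; smoothing
the **total** deviation (not the per-iteration increment) is essential —
accumulated jumps are wiped while the width is large.  Under the preset hex
conditions the unregularized fit shows plateaus at 1.0 a while the annealed
fit keeps every adjacent-pixel jump below 0.08 a.

## Metrology (`pxst.metrology`)

Each (frame, pixel) is assigned i.i.d. (seeded 64-bit generator) to one of
two half data sets; the pixel-map update is re-run per half with the
reference, white field and translations frozen; the headline `dTheta` is
the std of the pooled raw difference `Theta_1 - Theta_2` (the implied
single-reconstruction uncertainty is that over sqrt(2)).  Two floors limit
the estimate besides photon noise: bilinear representation error of the
reference (per-frame systematic residuals that shift half-minima; it
shrinks with the number of frames per half, ~2.6 nrad at 7x7 frames on the
desk-scale geometry) and the interpolation floor (<0.4 nrad noiseless).
The sqrt(flux) scaling law is therefore verified at 7x7 frames where noise
dominates.  Phase uncertainty uses the documented propagation model
`dPhi = (2*pi/lambda)*dTheta*l` with the gradient-error correlation length
`l` an explicit parameter (of order two detector pixels for bilinear
tracking); the model is exposed, not asserted.

## Numerical choices and problem sizes

Reconstruction-scale tests run on 128^2–256^2 detector regions with 5x5 to
9x9 scans (the reported scans used 407x365 to 359x401 regions with 20x20 or
11x11 positions); these sizes keep every stage's behaviour in the same
regime (tens of rings, several fringes per feature, >5 frames overlap per
reference point) while the whole suite stays interactive.  Bilinear
interpolation is used for both sampling and splatting; sub-pixel optima by
quadratic fit at fractional spacings; masked pixels never contribute to SSE
or splatting; flat error surfaces are flagged with the previous value
retained.  Distances are SI metres throughout; translations are (y, x)
pairs at sample-plane scale so they subtract directly from the map.

## Known limitations

* The white-field median requires each pixel to see past the sample in a
  majority of frames; scans much smaller than the sample bias it (a
  measured empty-beam image can be passed to `fit(white=...)`).
* Per-pixel granularity makes featureless regions data-unconstrained;
  their map values are held by regularization and the irrotational
  projection only.
* The CTF/TIE thickness inversions assume a single material and (for CTF)
  weak objects; both are exact only in their asymptotic regimes.
* Sensitivity floors are reference-representation-limited at very high
  flux; absolute nrad figures from the beamline data sets additionally
  reflect their 400-frame redundancy and are not reproduced at desk scale.
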