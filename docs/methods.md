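# Methods

This note records the models the package implements, the assumptions they
rest on, the defaults that matter, and the choices made where the design
was genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and unit conventions

All positions are physical: micrometres for images and cubes, nanometres
for single-molecule work. Arrays are row-major with row = y, column = x;
pixel *i* covers `[i·p, (i+1)·p)` for pixel size *p*, so the centre of
pixel *i* sits at `(i + 0.5)·p` and `pixel = floor(position / p)`.
Interpolation and rendering use this centre convention consistently;
mixing nm and μm without the unit being named in the parameter
(`*_nm`, `*_um`) is considered a bug, not a convenience.

Randomness flows from a single integer seed. Stages derive child seeds by
BLAKE2 hashing of `"{seed}:{stage-name}"`, so adding or reordering stages
never shifts another stage's stream, and every derived seed stays below
2³¹.

## Synthetic phantoms

The generators exist so that every estimator can be validated by parameter
recovery; their defaults are chosen to be realistic for collagen-I /
spheroid imaging, and are free parameters, not measured constants.

**Fiber networks.** Fibers are straight segments with a Gaussian
cross-section of standard deviation σ_true. Collagen-I fibers formed under
typical gel conditions are ~50–100 nm wide, so σ_true defaults in the
30–130 nm range depending on the experiment being emulated (31.85 nm gives
a 75 nm FWHM, the width a localization-based reconstruction should
recover). `FiberNetworkPhantom.grid` builds an axis-aligned network in
which the *clear gap* between the edges of successive parallel fibers is
drawn i.i.d. from Exp(λ); the row/column gap law of the rendered network
is therefore exponential with characteristic pore size 1/λ by
construction, and the exact draws are retained as ground truth
(border-truncated gaps excluded, matching the gap counter). Real collagen
networks have curved, branching fibers with orientation correlations; the
grid geometry deliberately trades that realism for an exact, closed-form
gap law. A fiber's nominal on-structure width is its cross-section FWHM.

**Imaging model.** Each modality blurs with an isotropic Gaussian PSF;
the defaults (widefield 250 nm, confocal 210 nm, Airyscan 140 nm, SIM
120 nm FWHM, STORM rendering 0) reproduce the rank order of those
techniques' resolutions without claiming measured values. Rendering uses
the exact convolution identity for Gaussian cross-sections,
σ_apparent² = σ_true² + σ_PSF², conserving integrated intensity. Depth
degrades images with a multiplicative contrast loss `1/(1 + c·z)` and an
additive background `b₀(1 + s·z)`, one knob each; shot noise is Poisson.
A warning is raised when the pixel size exceeds half the narrowest
rendered FWHM (Nyquist violation).

**SMLM movies.** Blinking is a two-state telegraph: an off emitter turns
on with probability `on_rate` per frame; on-durations are geometric with
mean `mean_on_frames`; `initial_on` sets the frame-0 on-probability
(setting it to 1 with `on_rate = 0` yields a saturating, bleaching-like
movie while staying within the two-state model). Each on-frame emits a
fixed expected photon count rendered as an erf-integrated Gaussian PSF
(σ default 150 nm — the mid-range of the 50–250 nm width filter; the
camera-facing PSF width is not a measured value). The camera model is
`ADU = Poisson(signal + background)/g + baseline + N(0, σ_read/g)` with
the acquisition constants g = 0.46 e⁻/ADU, baseline 97 ADU, pixel 97 nm,
and read noise 1.6 e⁻ (a typical sCMOS figure; not a stated constant).
The noiseless expectation (`noise=False`) makes the model exactly
invertible, which the tests exploit for photon bookkeeping.

**Spheroid sections.** Cells are Gaussian spots: a dense core disk
(uniform in the disk) plus invasive cells at radius
`r_core + Exp(invasion_scale)`. Staining the intact 3D sample limits dye
penetration: a cell a distance *d* inside the core boundary keeps
`exp(−d/d_pen)` of its brightness (default d_pen 20 μm for dye channels,
∞ for beads); re-staining after sectioning is uniform. Imaging depth adds
background and removes contrast linearly, as above. No cell-shape realism
beyond disks/points is attempted.

**MSI cubes.** A section disk at the grid centre contains an inner core
and a surrounding invasive-front annulus. Species are Gaussian peaks in
m/z (σ 0.012 Da, a Q-ToF-like width) on a shared profile-mode axis
(default bin 0.01 Da), with spatial patterns core-only, uniform, or
front-enriched (the core retaining 30% of the front intensity). Noise is
Poisson on signal plus a small uniform baseline. The default 40 μm pixel
matches the DESI acquisition geometry.

What passing these phantom tests does *not* show: robustness to fiber
curvature and branching, to non-Gaussian/astigmatic PSFs, to sCMOS
per-pixel noise maps, to chromatic or stage-tilt artefacts, or to the
chemical-noise structure of real DESI spectra.

## SMLM reconstruction

Per frame the movie is converted to photons
(`max(0, ADU − baseline) × g`; counts below baseline clamp to zero because
read noise dips below the offset and negative photons are unphysical),
band-passed with a difference of Gaussians (σ 1.0 and 2.5 px), and
8-connected local maxima above `threshold × MAD-based noise σ` are fitted
with a symmetric 2D Gaussian in a 7×7 px window. The residuals are scaled
by the model's shot-noise standard deviation, making the fit an
approximate maximum-likelihood estimator; an unweighted fit is ~4/3 worse
than the information bound and would not match the precision formula.
The detection threshold defaults to 3.0: at lower factors a large
fraction of correlated smoothed-noise maxima in emitter-free frames pass
the cut, flooding the table with spurious candidates; genuinely dim
molecules are in any case removed by the downstream photon filter.
Coincident detection maxima tie-break to the lexicographically smallest
pixel index (row-major scan order).

Post-processing follows the standard chain with its published constants:
keep records with photons > 100 and 50 nm < σ < 250 nm (strict
inequalities; the photon/σ filter runs before the density filter),
remove DBSCAN noise points at ε = 50 nm, MinPts = 5 (MinPts counts the
point itself), then drift-correct with 5 temporal bins: each bin is
rendered as a 30 nm histogram, registered to the first bin by plain
(unnormalized) cross-correlation with subpixel refinement — phase
whitening amplifies shot noise on sparse histograms — and per-frame drift
is linearly interpolated between bin centres with constant extrapolation
at the ends. Bins with fewer than 10 localizations are interpolated from
their neighbours. Rendering splats each record as a unit-integral
Gaussian of σ = 10 nm on a 10 nm grid in float64, so the image mass
equals the record count.

Resolution combines two terms in quadrature,

    R = sqrt(precision² + R_Nyquist²),

with the per-record precision

    σ_loc² = (σ² + a²/12)/N + 8π σ⁴ b²/(a² N²)

(a = pixel size, N = photons, b² = background noise variance per pixel —
for Poisson background plus camera read noise, b² = background mean +
σ_read²), aggregated by the median (robust to the dim-emitter tail;
configurable), and the density-limited term R_Nyquist = 2/√ρ with ρ in
localizations per μm² (the 2D convention; the exponent is pluggable).

## Fiber morphometry

A transect perpendicular to the fiber axis is sampled by bilinear
interpolation at the pixel size and fitted with

    y = y0 + A·exp(−(x − x0)²/(2σ²))

by nonlinear least squares (initialization: y0 = min, A = max − min,
x0 = argmax, σ = span/6 — robust for unimodal profiles). The exponent is
squared: that is the only form for which the FWHM exists and the curve is
a Gaussian. Fits are accepted iff adjusted R² = 1 − (1−R²)(n−1)/(n−p−1)
with p = 4 is at least 0.95 (the boundary is closed) and the amplitude is
positive; the mean FWHM = 2√(2 ln 2)·σ of accepted fits is the apparent
fiber width. Bead fields are measured identically with two orthogonal
transects per bead (beads closer than 5 expected FWHMs to a neighbour are
excluded), giving each modality's PSF FWHM — its resolution and minimum
expected fiber width. `auto_transects` automates ROI placement: ridge
points are pixels whose smaller Hessian eigenvalue (scale 2 px) is
strongly negative, and the transect runs along the corresponding
eigenvector, i.e. across the ridge; given a seed the placement is
deterministic.

Transect length defaults to ~6 expected FWHMs: long enough to estimate
the baseline, short enough to avoid neighbouring fibers.

## Pore size

The uniform workflow (identical configuration for every image in a batch,
enforced by the API) is: difference-of-Gaussians band-pass (defaults 2
and 40 px), rolling-ball background subtraction (radius 50 px; for large
radii the ball runs on a downsampled copy, which is exact to
interpolation error because the background is smooth at the ball scale),
Phansalkar local threshold in a 15 px window (implemented in-package with
the standard parameters k = 0.25, R = 0.5, p = 2, q = 10 on the image
normalized to [0, 1]; Sauvola/Niblack/Otsu available), then row-by-row
and column-by-column gap counting: every maximal off-run strictly between
two on-pixels contributes its length × pixel size. Border-truncated runs
are censored observations and are excluded by default (including them
biases the rate estimate; a switch restores them). Row and column gaps
pool into one sample.

The pooled sample is fitted to f(x) = λ·e^(−λx). The default estimator is
the closed-form MLE λ̂ = 1/mean — the fitting method behind the published
workflow is not specified, and the MLE is the canonical choice — with a
histogram least-squares alternative for comparison and a one-sample
Kolmogorov–Smirnov statistic attached as a goodness-of-fit diagnostic.
The reported pore size is 1/λ̂, exactly. Gaps from several images of one
condition can be pooled before fitting (default) or fitted per image.

All filter scales and the threshold window are workflow defaults, not
measured constants. On grid phantoms the full pipeline carries a small
systematic (≲2%): binarization places fiber edges slightly off the
nominal half-maximum width, and pixel quantization works in the opposite
direction; the recovery tests budget for both.

## Spheroid quantification

Bisecting profiles run edge-to-edge through the spheroid centre at a
configurable angle (default 0°), sampled at the pixel size and normalized
to the line's own maximum (an all-zero line is flagged rather than
divided). Per-slice summaries aggregate normalized intensities for
box-whisker comparison. Signal-to-background is the ratio of the maximum
intensity over cell ROIs to the maximum over background ROIs.

The invasion metric: the core circle is centred on the centroid of the
t = 1 h core mask (Otsu threshold, largest connected component, holes
filled) with radius reaching its farthest mask pixel; the front circle,
with the same centre, is the smallest circle through an invading-cell
centroid enclosing at least 90% of the centroids segmented outside the
core at t = 48 h — the exact order statistic `sorted[ceil(0.9·n) − 1]`,
not an interpolated quantile, which for some n encloses slightly less
than 90%. Whether the front should be defined by centroids or cell
boundaries is ambiguous; centroids are deterministic and are used. The
invasive distance is the difference of circumferences,
2π(r_front − r_core); with no invasive cells it is zero and flagged.

Group comparison uses Welch's two-sided t-test by default (the underlying
measurements never name their test; Mann–Whitney is available) at
α = 0.05 with the star convention *, **, *** at p < 0.05, 0.01, 0.001 and
† otherwise, and no multiplicity correction unless requested (Holm).
Identical degenerate-variance groups short-circuit to p = 1.

## MSI quantification

Cubes store profile-mode spectra on one shared, strictly increasing m/z
axis. TIC normalization divides each pixel's spectrum by its summed
intensity; zero-TIC pixels are masked and counted, never divided. m/z
windows are closed intervals ([lo, hi] inclusive) so a full-axis window
conserves the normalized mass exactly. Window statistics average the
within-window sum over a section mask — user-supplied, or automatic as
pixels whose TIC exceeds 5% of the maximum (how section boundaries were
delineated for the reference measurements is not stated). Ion images
integrate the ppm window m/z·(1 ± ppm·10⁻⁶), default 5 ppm. Annotation
matches observed peaks against a user-supplied monoisotopic mass table at
5 ppm, reporting *all* matches within tolerance; ambiguity is surfaced,
never resolved, and no online database access or adduct arithmetic is
performed by default. Lock-mass recalibration is out of scope; cubes are
assumed mass-calibrated.

## Correlative registration

Rigid (optionally similarity) registration without fiducials: both images
are resampled to the coarser pixel size (with Gaussian anti-aliasing
before any downsampling), rotations are scanned on a ±20° grid in 1°
steps with FFT cross-correlation giving the best translation per
rotation, and the best candidate is refined by Nelder–Mead on the
normalized cross-correlation evaluated against the fixed image at its
native resolution (the moving image is warped straight onto the fixed
grid per evaluation, so coarse-grid search does not limit final
accuracy). A final NCC below threshold raises an error carrying the
score. Transforms are canonical similarity maps in physical units,
p' = s·R(θ)·p + t, with exact composition and inversion; the registered
image is the moving image resampled onto the fixed grid. Mutual
information is not implemented; for contrast-inverted cross-modality
pairs, invert one image first.

## Problem sizes used by tests and the acceptance script

The recovery studies run at desk scale, chosen as the smallest sizes at
which the estimators' sampling error is comfortably inside the asserted
tolerances: fiber-width phantoms of 2 fibers × 6 transects on a 4×4 μm,
10 nm/px field; the gap-law fit at 10,000 draws; the image-pipeline
recovery pooled over 10 phantom images of 250×250 μm at 0.1 μm/px
(~1,100 independent gaps, sampling SE ≈ 2.7%); localization Monte Carlo
over 1,000 frames; the frame-convergence study on a 600-frame saturating
movie of 20 emitters; MSI ordering over 100 seeded 12×12 cubes;
registration on 300×300 px section phantoms. The published acquisitions
are larger (e.g. 30,000-frame movies); the studies here are scaled
reproductions of the same procedures, not reproductions of the original
acquisitions.

## Known limitations

2D only (no astigmatic/biplane localization, no 3D pore metrics or
invasion in z); single-emitter fitting (overlapping activations within a
fit window merge and bias dense-scene statistics — the recovery tests use
sparse activity); the Phansalkar/rolling-ball defaults are reasonable for
fibrous networks at ~0.1 μm/px but are not auto-tuned; drift correction
assumes structure-rich fields (featureless bins interpolate); the
registration similarity metric assumes broadly matching contrast
polarity; MSI processing assumes continuous-mode, mass-calibrated
spectra.
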