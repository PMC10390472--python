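# disc3d

Quantitative image analysis for cryosectioned spheroid/hydrogel samples:
thin sections of multicellular tumour spheroids embedded in collagen-I /
gelatin dual hydrogels, imaged by optical microscopy (widefield through
STORM) and by DESI mass spectrometry imaging. The package implements the
full measurement chain those experiments need — and a synthetic-phantom
generator that makes every stage verifiable by parameter recovery, with
no external data.

**Who it is for.** Groups doing 3D culture / extracellular-matrix imaging
who need reproducible, scriptable versions of the quantification steps
usually done by hand in FIJI: fiber-width morphometry, pore-size
estimation, SMLM post-processing and resolution estimation, spheroid
staining and invasion metrics, MSI intensity statistics, and
cross-modality registration.

## What it computes

**Fiber width** (`disc3d.fibers`). Intensity profiles along transects
drawn across fibers are fitted with a Gaussian,

    y = y0 + A·exp(−(x − x0)² / (2σ²)),

fits with adjusted R² < 0.95 are discarded, and the mean
FWHM = 2√(2 ln 2)·σ of accepted fits is the apparent fiber width. Applied
to isolated beads, the same procedure yields each modality's PSF FWHM —
its resolution and minimum expected fiber width.

**Pore size** (`disc3d.pores`). Images are band-passed, background-
subtracted (rolling ball), and binarized with a local threshold; gaps
between "on" pixels are counted row by row and column by column and the
pooled gap sample is fitted to the exponential density f(x) = λe^(−λx).
The reported pore size is the characteristic length **1/λ**.

**SMLM reconstruction** (`disc3d.smlm`). Camera counts → photons
(gain 0.46 e⁻/ADU, baseline 97 ADU, 97 nm pixels), per-frame Gaussian
fitting, filtering (photons > 100, 50 nm < σ < 250 nm), DBSCAN outlier
removal (ε = 50 nm, MinPts = 5), 5-bin cross-correlation drift
correction, and normalized-Gaussian rendering at 10 nm. Resolution is

    R = √(precision² + Nyquist²),

with the Thompson-style precision σ_loc² = (σ² + a²/12)/N + 8πσ⁴b²/(a²N²)
and the density-limited Nyquist term R_N = 2/√ρ.

**Spheroid metrics** (`disc3d.spheroid`). Normalized bisecting-line
intensity profiles, per-slice summaries, max-over-ROI signal-to-background
ratios, and the invasive distance — the circumference of a circle
enclosing ≥ 90% of the invasive front at t = 48 h minus that of the circle
fully enclosing the core at t = 1 h, i.e. 2π(r_front − r_core).

**MSI statistics** (`disc3d.msi`). TIC normalization, mean intensity in
m/z windows over a section mask, ppm-tolerance ion images, pairwise
condition comparisons, and annotation of observed peaks against a
user-supplied monoisotopic mass table at 5 ppm.

**Registration** (`disc3d.registration`). Fiducial-free rigid/similarity
registration by rotation search + FFT translation + simplex refinement of
the normalized cross-correlation, robust to a 40 μm-vs-sub-μm pixel-size
gap (MSI onto confocal).

**Phantoms** (`disc3d.phantoms`). Ground-truth-annotated generators for
fiber networks with exponential gap statistics, blinking SMLM movies
under an explicit camera model, spheroid sections with limited dye
penetration vs. uniform re-staining, and MSI cubes with core/uniform/
front-enriched species. Identical spec + seed reproduces bit-identical
output.

## Worked example

Measure the apparent width of STORM-rendered collagen-like fibers whose
true Gaussian cross-section is σ = 31.85 nm (true FWHM 75 nm):

```python
import numpy as np
from disc3d import fibers
from disc3d.phantoms import FiberNetworkPhantom, FiberSegment, generate_fiber_image

phantom = FiberNetworkPhantom(
    fibers=[FiberSegment((1.0, 0.0), (1.0, 4.0), sigma_nm=31.85),
            FiberSegment((3.0, 0.0), (3.0, 4.0), sigma_nm=31.85)],
    field_size_um=(4.0, 4.0), pixel_size_um=0.01, seed=21,
)
image = generate_fiber_image(phantom, "storm_render", noise=False, background=0.0)
rois = [fibers.ProfileROI((x - 0.4, y), (x + 0.4, y))
        for x in (1.0, 3.0) for y in np.linspace(0.6, 3.4, 6)]
report = fibers.fiber_width_report(image, rois)
print(f"mean FWHM = {report['mean_fwhm']*1e3:.1f} nm "
      f"({report['n_accepted']} accepted, {report['n_rejected']} rejected)")
```

prints

```
mean FWHM = 75.9 nm (12 accepted, 0 rejected)
```

— the 75 nm true width recovered to ~1% (the small excess is bilinear-
interpolation broadening of the 10 nm grid). The same estimator on a
widefield rendering of the same phantom reports ≈ 261 nm
(√(75² + 250²)), the PSF-limited floor: only the localization-based
rendering reports the true fiber scale.

The pore-size estimator on its calibration conditions:

```python
import numpy as np
from disc3d import pores
gaps = np.random.default_rng(1).exponential(scale=4.0, size=10_000)
print(f"pore size = {pores.fit_exponential(gaps).pore_size_um:.3f} um")
```

```
pore size = 4.005 um
```

A `disc3d` command-line tool exposes the same operations
(`disc3d pores`, `disc3d fibers width`, `disc3d smlm reconstruct`,
`disc3d spheroid invasion`, `disc3d msi ion|annotate`, `disc3d register`,
`disc3d run`); see `disc3d --help`.

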