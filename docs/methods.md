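# Methods

## Scope and design

`mitomorph` reimplements, as one tested package, an analysis style common
in high-content mitochondrial toxicity screening: interactive
pixel-classification segmentation (Ilastik-like), CellProfiler-style
per-object shape features, an unsupervised two-class Gaussian mixture
over those features, and a set of intensity-based functional readouts,
compared across conditions with ANOVA + Dunnett. All stages run on
synthetic scenes with known ground truth, so every quantitative claim in
the test suite is a measured recovery against a planted value.

## Synthetic scenes

A scene is a pure function of its `SceneParams` (seed included); equal
parameters give bit-identical images.

* **Geometry.** Default 1024×1024 px at 0.1 µm/px with 5–30 cells,
  matching the acquisition the pipeline targets. Tests and benchmarks use
  a scaled-down field (256×256 px, 5 cells, 4–8 objects per cell) so the
  full suite runs in minutes; this changes the number of objects per
  image, not their sizes or contrasts.
* **Classes.** Fragmented objects are filled ellipses (area 20–120 px²,
  eccentricity ≤ 0.6); fused objects are dilated approximately
  self-avoiding random walks (tube length 30–90 px at full scale, width
  3–5 px, one optional branch). The quantitative ranges are generator
  assumptions chosen to yield two clearly separated populations — small
  round high-solidity puncta versus large elongated low-solidity
  networks, with a much wider size spread in the fused class; no
  published size table exists for either class.
* **Rendering.** Constant background (200) plus foreground amplitude
  (3000), Gaussian PSF (σ = 1 px), Poisson shot noise (`poisson_scale`
  0.04, i.e. intensity × 0.04 photons) then additive Gaussian read noise
  (sd 30), clipped to 16-bit. These defaults give a peak SNR near 10.
  Objects are placed with a minimum 8 px gap and never cross the border,
  so ground truth stays recoverable after blur; under crowding the
  generator resamples progressively smaller stamps before giving up with
  a `PackingError`.
* **Not modelled.** 3-D stacks, photobleaching, realistic optics,
  intensity variation within and between organelles, overlapping or
  touching organelles, out-of-focus light. Passing benchmarks therefore
  demonstrate correctness of the computational pipeline under its own
  stated noise model, not performance on real microscopy.

Time-lapse scenes render each cell's cytoplasm ring at a planted rho123
intensity per frame and set an exact planted fraction of nuclear pixels
PI-positive after a planted death onset; FRET pairs render 488-nm
emission as `base × ratio` against a constant 408-nm base inside a cell
mask.

## Segmentation

The filter bank defaults to Laplacian of Gaussian (σ = 3.5 px) and
Difference of Gaussians (σ = 3.5 px; narrow σ = 0.66·σ, the convention of
the interactive tools this emulates; sign `G(0.66σ)∗I − G(σ)∗I`). A raw
intensity plane can be added by flag but is off by default. The
classifier is a 100-tree random forest (no depth limit, fixed seed);
prediction is plain per-pixel argmax — no probability smoothing.

Synthetic "manual" annotations sample foreground from truth objects and
background half from a 1–3 px rim band around objects, half from far
background. The rim labels matter: the learned boundary sits where the
annotator says background begins, and rim-weighted annotation is what
careful interactive use looks like. With the defaults (2 training scenes,
400 px per class) the classifier reaches mean IoU ≈ 0.8 against ground
truth at default SNR.

Objects are 8-connected components of the mask (thin diagonal tubes stay
whole; 4-connectivity available). No minimum-size filter is applied by
default. Border-touching objects are kept. Nuclei: Gaussian smoothing
(σ = 3 px) → Otsu → hole filling → Euclidean distance transform →
h-maxima seeds (h = 0.3 × max distance) → watershed; fragments below
50 px are dropped and labels are renumbered contiguously without
re-merging watershed splits.

## Shape features

All four features are defined on the pixel grid (pixel units; physical
pixel size travels in metadata — the mixture is scale-sensitive, so units
must be fixed and pixels are the natural choice):

* **area** = pixel count;
* **perimeter** = count of object pixels with a 4-connected background
  neighbour, which automatically includes inner (hole) boundaries;
* **formfactor** defaults to the standard circularity 4πA/P² (≈1 for a
  disk; rasterisation bias keeps large disks within [0.8, 1.3]); the
  dimensionally inconsistent variant 4πA/P seen in some method write-ups
  is available as `formfactor_formula="literal"`;
* **solidity** = A divided by the number of pixels whose centres lie
  inside or on the convex hull of the object's pixel centres. Degenerate
  (collinear) objects fall back to counting integer points on the extreme
  segment. With this pixel-centre definition a 3-pixel L on a 2×2 grid is
  convex (solidity 1): hull membership is decided at pixel-centre
  resolution.

Features are exactly invariant under translation and 90° rotations and
are checked against exhaustive per-pixel oracles (the hull oracle decides
membership per pixel by linear-programming feasibility of the convex
combination).

## Mixture model

Two full-covariance 4-D Gaussians (full covariance because the class
clouds are tilted in feature space), fit by EM:

* per restart: means at two distinct random data rows, covariances at the
  pooled data covariance, uniform weights;
* covariance updates regularised by `1e-6 · (trace/d) · I`, which keeps
  degenerate directions (e.g. solidity pinned at 1.0 for convex puncta)
  positive definite;
* convergence at relative −logL change < 1e-6 or 500 iterations;
* 100 restarts by default, seeds drawn from a spawned `SeedSequence`
  stream so the best of *n* restarts is non-increasing in *n*;
* monotonicity of the EM log-likelihood holds per iteration up to
  floating-point roundoff of the log-sum-exp accumulations (checked at
  1e-8 relative).

No feature standardisation is applied before fitting (a z-scoring flag
exists for sensitivity analysis). Components are named afterwards —
smaller mean area → "fragmented" — and exactly equal mean areas raise an
error demanding manual assignment. Posterior ties in assignment break
toward the lower component index (a measure-zero event). "Object mass"
in the mass-weighted fraction means summed object area: objects are
binary at that stage, so area is the only available mass proxy.

The production pattern is one pooled fit across all conditions of a
dataset, then per-condition classification. Robustness of the fit to
data size is assessed by refitting on leave-one-compound-out subsets,
100 random halves of the images, or random object fractions (1/2, 1/10,
1/500); at desk scale the 1/2 and 1/10 refits move the component means
negligibly while 1/500 (≈40 objects) visibly inflates the spread of the
estimates.

## Functional readouts

* Cytoplasm ring: Euclidean distance ≤ 10 px from the nucleus, nuclei
  excluded, contested pixels to the nearest nucleus (ties to the lower
  label; implemented as an exact per-label distance-transform argmin).
* MMP: mean (or integrated, by option) rho123 intensity over the ring.
* Death: a cell is dead when ≥ 10% of its nuclear pixels are PI-positive;
  the threshold is exactly ≥ 0.10. Pixel-level PI positivity uses an
  Otsu threshold per image by default (no published pixel cutoff exists);
  an explicit threshold can be passed for full determinism.
* FRET: cell area by Otsu on the 408-nm image; ratio = mean 488 / mean
  408 over that area (orientation configurable and recorded). Empty cell
  area or a zero denominator raises instead of returning NaN.
* `normalize_to_vehicle` divides by the vehicle series at matched
  timepoints (vehicle maps to 1; zero vehicle values raise); replicate
  mean ± SE are computed after normalisation. OPA1 cleavage is L/(L+S)
  from already-integrated band intensities; densitometry is out of scope.

## Statistics

One-way fixed-effects ANOVA (`scipy.stats.f_oneway`; the all-constant
equal-means corner returns F = 0 rather than NaN) followed by Dunnett's
two-sided many-to-one test (`scipy.stats.dunnett`, classical pooled-error
form, seeded quasi-random evaluation of the multivariate-t). With one
treatment the adjusted p collapses to the ordinary pooled two-sample
t-test. Replicate unit: image-level fractions are aggregated per
biological replicate before testing. Simulated under the global null,
the ANOVA type-I error and the Dunnett familywise error both sit at
0.05 ± 0.01 (10,000 and 5,000 simulated experiments respectively).

## Pipeline and determinism

`run_pipeline` derives every stage seed from the master seed via
`SeedSequence`, writes CSV with a fixed float format and JSON with sorted
keys, and keeps wall-clock information out of the data outputs — a config
run twice produces byte-identical files. Stage failures re-raise tagged
with the stage name. The run log records package versions and seeds.

## Known limitations

* The segmentation benchmark measures the classifier on the generator's
  own noise model; real MitoTracker images have textured cytoplasmic
  background the generator does not emulate.
* Morphology is aggregated per image/condition, not per cell.
* The two-class mixture cannot distinguish swollen-but-round organelles
  from genuinely fragmented ones — an acknowledged failure mode of
  shape-only classification.
* No cell tracking across time-lapse frames; per-frame aggregation only.
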