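# mitomorph

Quantification and unsupervised classification of mitochondrial morphology
from high-content fluorescence microscopy, with the accompanying functional
readouts used in mitochondrial toxicity screening.

Chemical stress reshapes the mitochondrial network: fission produces many
small, roundish organelles ("fragmented"), fusion produces large,
irregular, interconnected ones ("fused"). `mitomorph` turns confocal
images of dye-stained mitochondria (e.g. MitoTracker Red, with a Hoechst
nuclei channel) into a per-condition *fraction of fragmented mitochondria*
and pairs it with membrane-potential, cell-death, and ATP readouts — the
kind of multi-parameter evidence used to tell OXPHOS complex V inhibitors
apart from complex I/III inhibitors.

The pipeline:

1. **Segmentation** — a filter bank (Laplacian of Gaussian and Difference
   of Gaussians, σ = 3.5 px) feeds a random-forest pixel classifier
   trained on sparse fore/background annotations; the per-pixel argmax
   gives a binary mask that is connected-component labelled into objects.
   Nuclei are segmented by Otsu thresholding plus a distance-transform
   seeded watershed.
2. **Features** — per object: area *A* (pixel count), perimeter *P*
   (boundary-pixel count, inner hole boundaries included), formfactor
   (circularity, 4π·A/P² by default), and solidity (A / convex-hull pixel
   area).
3. **Classification** — a two-component full-covariance Gaussian mixture
   over (A, P, formfactor, solidity), fit by multi-restart EM (100
   restarts, lowest −log-likelihood wins). The component with the smaller
   mean area is named *fragmented*. Each object goes to the class with the
   highest posterior probability. Fragmentation per condition is reported
   both as the fraction of objects and as the fraction of total object
   area ("mass").
4. **Functional readouts** — mean rhodamine-123 intensity in the
   cytoplasm ring (pixels within 10 px of each nucleus, nearest-nucleus
   tie-break), cell death when ≥ 10% of a nucleus's pixels are
   PI-positive, FRET ATP ratio (mean 488-nm / mean 408-nm emission over
   the thresholded cell area), normalisation to vehicle and to nuclear
   counts, and the OPA1 cleavage ratio L/(L+S).
5. **Statistics** — one-way ANOVA plus Dunnett's many-to-one test of every
   treatment against the vehicle control.

Because raw screening images are rarely shareable, the package ships a
seeded synthetic-scene generator (`mitomorph.synthetic`) that renders
nuclei + mitochondria fields with known per-object ground truth, planted
rho123/PI time courses and planted FRET ratios — every stage is testable
end to end without downloading anything.

## Worked example

```bash
mitomorph run --config config.yaml --out results/
```

with `config.yaml`:

```yaml
seed: 3
n_replicates: 3
n_images_per_replicate: 2
conditions:
  - {name: vehicle,    fragmented_fraction: 0.3}
  - {name: oligomycin, fragmented_fraction: 0.6}
```

simulates two conditions (a vehicle control and an oligomycin-like
condition with a planted fragmentation shift of +0.3), segments and
measures every scene, fits the mixture on the pooled objects, and prints:

```
wrote 6 outputs to results/
  oligomycin: fragmented fraction (count) 0.628 ± 0.056
  vehicle: fragmented fraction (count) 0.366 ± 0.002
```

`results/report.json` adds the statistics: for the count-based fraction
the ANOVA gives p ≈ 0.0094 and Dunnett's comparison of oligomycin against
vehicle an adjusted p ≈ 0.0098 — the planted shift is detected as a
significant increase in fragmentation. `features.csv` holds the
per-object measurements, `fractions.csv` the per-replicate fractions, and
`gmm_model.json` the fitted mixture (weights, means, covariances, class
map).

The same stages are available individually (`mitomorph simulate | train |
segment | features | fit-gmm | classify | fractions | fret`) and as
library functions.

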