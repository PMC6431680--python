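# famet — single-cell focal-adhesion metrology

`famet` quantifies how a cell's shape and its focal-adhesion (FA) pattern
reflect the geometry of the substrate it grows on. Fibroblasts on flat
glass spread into large elliptical sheets with elongated adhesions across
the whole body; cells suspended in woven microfiber scaffolds adopt
concave triangular shapes with large, round adhesions clustered around the
nucleus. The package turns 3-channel fluorescence images (red = actin,
green = vinculin, blue = nucleus) into a per-cell feature vector and
classifies the confinement state with a cross-validated linear SVM. It is
aimed at mechanobiology groups who want a reproducible, scriptable
alternative to interactive image-analysis software.

Because raw confocal data of this kind are rarely shareable, `famet`
ships a synthetic scene generator with full ground truth (masks, adhesion
centroids, areas, maturity labels) for four confinement-class archetypes
(A: spread elliptical; B: high-variance lamellar mixture; C: small poorly
spread; D: concave triangular with perinuclear adhesions), so every stage
of the pipeline is testable end to end.

## The metrology

**Segmentation** (per channel, after maximum-intensity projection of
z-stacks): CLAHE contrast equalization → non-local-means denoising → Otsu
thresholding → a single synchronous *conditional erosion* pass (a
foreground pixel is removed iff ≥ 5 of its 8 neighbors are background) →
hole filling. The vinculin channel gets an extra 1-px dilation before the
erosion, and its connected components are triaged by physical area:
background < 0.1 µm² ≤ nascent < 0.2 µm² ≤ mature. Only mature adhesions
enter the metrology.

**Seven features per cell (I–VII):**

| # | feature | definition |
|---|---------|------------|
| I | ellipticity | folded affine moment invariant `J = (m20·m02 − m11²)/m00⁴`, equal to 1 for any ellipse |
| II | rectangularity | area / axis-aligned bounding-box area |
| III | cell area | foreground pixels × (pixel size)², µm² |
| IV | FA size | mean mature-adhesion area, µm² |
| V | FA aspect ratio | mean major/minor axis of the moment-equivalent ellipse |
| VI | E-slope | zero-intercept LS slope of the E-function, `Σdᵢfᵢ/Σdᵢ²`, 1/µm |
| VII | G-function | mean nearest-neighbor distance between mature adhesions, µm |

The E-function is the empirical CDF of adhesion-to-nucleus centroid
distances; a steep slope means perinuclear clustering. Solidity, adhesion
count and coverage are computed as auxiliary metrics.

**Classification:** features are z-scored (sample sd), then a linear
soft-margin SVM (C = 1, one-vs-one) is assessed with stratified 5-fold
cross-validation; accuracy is the mean of per-fold accuracies, and
out-of-fold predictions pool into a confusion matrix. Tasks: all four
classes (`ABCD`), dropping the noisy class B (`ACD`), and the binary
contrast `ABCvD`. Univariate ANOVA-F scores rank features between two
classes, and the coefficient of variation (100·sd/|mean|) reports
within-class heterogeneity. Group differences use one-way ANOVA with
Tukey HSD.

## Worked example

```python
from famet import SceneConfig, assemble_features, generate_scene, segment_scene

scene = generate_scene("A", SceneConfig(), rng_seed=7)   # 0.15 µm/px
seg = segment_scene(scene.channels["red"], scene.channels["green"],
                    scene.channels["blue"], scene.pixel_size)
fv = assemble_features(seg, class_label=scene.class_label)
```

prints (via `python examples/02_segment_and_measure.py`):

```
detected: cell 37781 px, nucleus 5779 px, 35 mature + 0 nascent adhesions
I   ellipticity      1.000
II  rectangularity   0.783
III cell area        850.1 µm²
IV  FA size          1.042 µm² (mean of mature)
V   FA aspect ratio  1.84
VI  E-slope          0.0368 1/µm
VII G-function       3.02 µm
aux solidity 0.992, coverage 4.3%
```

An ellipticity of 1.000 and solidity 0.992 say the cell outline is a
convex ellipse; 850 µm² is a well-spread fibroblast; the low E-slope
(0.037 1/µm — adhesions far from the nucleus) and 3 µm mean
nearest-neighbor distance are the body-wide adhesion signature of an
unconfined cell. Running the same code on a class-D scene gives solidity
≈ 0.73, E-slope ≈ 0.14 and G ≈ 2.4 µm — the confined phenotype.

The other scripts in `examples/` cover scene simulation, spatial
statistics in isolation, population classification with feature ranking,
and the end-to-end pipeline. The same stages are scriptable from the
shell:

```sh
famet simulate --classes A,B,C,D --n-per-class 22 --seed 1 --outdir scenes/
famet features --scene-dir scenes/ --out features.csv
famet classify --features features.csv --task ABCvD --seed 1
famet rank-features --features features.csv --classes C,D
famet run --n-per-class 22 --seed 1 --outdir out/
```

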