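# Methods

## Synthetic phantom model

Each case is a 3D HU grid containing a vertical cylindrical bone peg — the
dens stand-in — built from voxel-center geometry: a cortical shell
(default 1200 HU, thickness 1.5 mm) around a trabecular core (300 HU),
embedded in soft tissue (mean 40 HU with its own texture SD, default
10 HU). A fracture is a planar cleft through the peg center whose voxels
drop to background intensity; the cleft plane's normal is tilted from the
transverse plane by a configurable angle (cohorts draw it uniformly within
±30°, matching the transverse-to-oblique appearance of dens fractures).
Displacement is a rigid integer-voxel lateral shift of the fragment above
the cleft; sub-voxel shifts are deliberately excluded so the generator
contains no resampling step of its own. Partial-volume behaviour of thick
slices is emulated by a Gaussian blur along z (sigma in mm), then i.i.d.
Gaussian acquisition noise is added. Default voxel spacing is
(0.6, 0.6, 1.5) mm, inside the clinical cervical-CT ranges (in-plane
0.17–0.98 mm, slice 1–2 mm).

The dens mask is the full cylinder including cleft voxels (a radiologist
outlines the anatomical peg, fractured or not), so the fracture mask is a
subset of the dens mask, the label is exactly "fracture mask non-empty",
and the undisplaced mask is one connected component. All randomness flows
from a per-case seed derived via `SeedSequence((cohort_seed, index))`, so
a case's content does not depend on cohort size or generation order;
cohort label assignment (exactly `round(n·prevalence)` fractures, default
prevalence 79/366) is a cohort-seeded shuffle. Per-case jitter: dens
radius ±10%, cleft width ±0.5 mm, noise ±20%, displacement 0 mm for half
of fracture cases, else 1–3 mm.

Two presets matter. `study_base_spec` is the realistic condition
(anisotropic voxels, 15 HU noise, 1–2 mm clefts). `easy_base_spec` is the
separable condition used by the pipeline sanity checks: near-isotropic
voxels, 2 HU noise, ~3 mm clefts, a 4 mm-radius × 12 mm peg on a 32³ grid.
The peg is sized so the desk-scale 16³ network crop can satisfy the ≥90%
dens-retention constraint even after 1.2× scaling augmentation.

What the generator does **not** emulate: beam hardening and metal
artifacts, anatomical neighbours (C1 arch, skull base), cortical thickness
variation, realistic trabecular texture, scanner-specific reconstruction
kernels, or fracture-type morphology (no Anderson–D'Alonzo breakdown —
the geometry is a modeling choice, not a reproduction). Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
two-stage design recovers a planted, well-separated fracture signal; they
say nothing about sensitivity on clinical data, where class overlap,
anatomy and artifacts dominate.

## Volumes, resampling, cropping

Grids are axis-aligned RAS with 0-based voxel indices and
`world = origin + index · spacing`. Resampling to isotropic spacing uses
`scipy.ndimage.zoom` (linear for intensities, nearest-neighbour for masks,
which provably preserves {0, 1}); an independent resampler is used as a
cross-check in the tests. Z-scoring rejects constant volumes. `pad_crop`
produces an exact target shape, padding with 0 and clamping crop windows
to bounds; even-sized targets round the requested center down (tie toward
the lower index).

## Windowing

All five methods are monotone pointwise maps onto [0, 1] (CLAHE is
locally, per-tile, monotone). Percentiles interpolate linearly between
order statistics — the same rule as the sort-based test oracle. The ROI
method's "immediate surroundings" is a Euclidean dilation of the mask with
default radius 3 mm (configurable), computed on physical distances so
anisotropic voxels dilate correctly; the resulting bounds are applied to
the whole image. CLAHE runs per axial slice (8×8 tiles, clip limit 0.01,
after min-max scaling); 3D CLAHE is out of scope. In the two-stage
pipeline, windowing is applied after isotropic resampling; neural inputs
are additionally z-scored, while radiomics reads the windowed [0, 1]
volume rescaled ×1000 (so fixed-width discretization would remain
meaningful across methods). A `feature_intensity="raw"` switch extracts
from raw HU instead.

## Radiomics conventions

- Discretization: fixed bin count (default 32) over the ROI min–max;
  fixed bin width available. A constant ROI maps to a single level.
- First-order moments are population (biased): variance `m2`, skewness
  `m3/m2^1.5`, Pearson kurtosis `m4/m2²`, both defined as 0 when `m2 = 0`.
  Entropy is base-2 on the discretized histogram; energy is the raw sum of
  squares.
- Shape: surface area counts exposed voxel faces (exactly enumerable;
  systematically larger than a meshed surface). Sphericity
  `π^(1/3)(6V)^(2/3)/A`. Elongation is `sqrt(λ₂/λ₁)` of the physical
  voxel-coordinate covariance (λ₁ the largest eigenvalue), 1.0 for a
  single voxel.
- GLCM: symmetric, distance 1, the 13 unique 3D offsets, normalized per
  offset; features are averaged over offsets that contain at least one
  in-mask pair. Correlation of a zero-variance matrix is defined as 1.
  An ROI with no co-occurring pair at any offset is an error in
  `glcm_features`; `extract_all` substitutes the homogeneous-texture
  sentinel (contrast 0, correlation 1, ASM 1, IDM 1, entropy 0) and flags
  the vector. The 23-feature schema is fixed and ordered.

Every feature is tested for equality (1e-9 relative) with a brute-force
enumeration oracle on 50 seeded random ROIs up to 6³.

## Dice-targeted perturbation

For a mask A, deleting k interior voxels and adding m exterior voxels
yields `DSC = 2(|A|−k)/(2|A|−k+m)` regardless of which voxels are chosen.
The integer pair nearest the target is found by a ±2 local search around
the closed-form solution (mixed mode uses k = m; delete-only
`k = 2a(1−d)/(2−d)`; add-only `m = 2a(1−d)/d`), so the achieved DSC is
deterministic before any randomness, and a target whose best integer
solution misses the tolerance (default ±0.005) raises a feasibility error
reporting what is achievable. Voxels are then drawn (seeded) from
successive erosion layers and at most two dilation shells — boundary-local
edits that mimic plausible segmentation error rather than scattered
salt-and-pepper flips, which would be adversarial for texture features.
The perturbed mask is therefore guaranteed to lie within a 2-layer
dilation of the original. Both-empty Dice is defined as 1 so empty-empty
comparisons are not penalized.

## Neural components

Both networks run on a small reverse-mode autodiff engine written for this
package (float64 numpy; 3D convolution as 27 shifted einsum contractions).
Every operation's analytic gradient is verified against central finite
differences in the test suite.

- **M1 (direct classifier):** DoubleConv blocks (two 3×3×3 convolutions,
  each with batch normalization and ReLU) with max-pooling, then a
  five-layer FNN with dropout 0.1 and a softmax 2-class output. Desk-scale
  defaults: channels (4, 8), hidden widths (64, 32, 16, 8), 16³ input.
- **Segmenter:** encoder–decoder with skip connections
  (nearest-neighbour upsampling + concatenation + DoubleConv, 1×1×1
  output head), depth 2, base 8 channels at desk scale. Loss is
  0.5·(1 − soft Dice) + 0.5·weighted cross-entropy (the mix weights are a
  declared default; only "combined" is prescribed).
- **Training:** Adam (lr 0.001 for M1, 0.01 for the segmenter; weight
  decay 1e-6), ReduceLROnPlateau (patience 10, cooldown 10, factor 0.1),
  batch size 4, best-validation checkpoint returned. Oversampling repeats
  each fracture case exactly 10× and each non-fracture case 3× per epoch.
  Augmentation: scaling 0.8–1.2, per-axis mirror flips (p = 0.5), and a
  random crop that must retain ≥90% of the dens voxels; crop origins are
  proposed from windows overlapping the dens bounding box (+2 voxels), and
  the retention test rejects the rest — uniform whole-grid proposals make
  valid crops a ~2% event at desk scale.
- **Class weights:** inverse prevalence `w_c = N/(K·N_c)`. M1's default
  applies this formula to the *effective* oversampled epoch counts
  (`N_c · repeats_c`), because oversampling already rebalances the epoch
  and weighting the raw prevalence on top corrects the imbalance twice;
  explicit weights override.

The clinical-scale shapes (256³ standardization, 120³ crops, 50
epochs) remain available through the same configs; the shipped defaults
and tests use 16³ inputs, 2-level 8-channel networks, ≤150-step smoke runs
and 10–12-epoch pipeline runs, sized for a single CPU. The architecture is
unchanged in kind, only in width and input size.

## Experiments layer

- **Split rule:** `|train| = floor(0.70·n)`, `|val| = round(0.10·n)`
  (half-up), `|test| = remainder` — for n = 366 exactly (256, 37, 73).
  Assignment is a seeded permutation; stratified mode applies the rule per
  class (used by the desk-scale pipeline runs so that a 13/60 prevalence
  cannot leave a split single-class).
- **M2:** stage-1 masks come from the trained segmenter, the oracle, or
  the perturbation engine (exactly controlled DSC); perturbing oracle
  masks is the default for the stability grid so the DSC axis is exact.
  Classifiers fit on the training split only; the validation split is
  reserved for neural checkpoint selection. Cases with empty predicted
  masks are excluded and counted.
- **Evaluation crop / centering:** phantoms are generated dens-centered,
  so M1's standardized evaluation crop is taken at the volume center; the
  mask centroid helper supports explicit centering when needed.
- **Stability grid:** one M2 run per (DSC level, windowing, classifier,
  seed) cell, defaults spanning DSC 0.82–0.94 in steps of 0.02; long-form
  CSV plus a two-panel heatmap (accuracy, balanced accuracy; darker =
  higher).
- **Leakage audit:** a marker column equal to the label (×1000) is planted
  in test rows only and the pipeline re-fit with a decision tree. A tree
  can only split on features that vary in the training rows, where the
  marker is constant zero, so with correct isolation the fitted model and
  its test predictions are bit-identical; any accuracy change would prove
  test information reached fitting. A distance-based classifier is not
  used here because the marker changes test-point geometry even without
  leakage.

## Numerical and degenerate-input choices

Soft Dice uses eps = 1e-7 in numerator and denominator. Constant volumes
are errors for z-scoring, min-max scaling and percentile windows
(degenerate window). Ties in max-pooling split the gradient evenly.
KNN defaults to k = 5 on z-scored features (training statistics only);
tree ensembles use 100 seeded estimators. Gradient-boosting and naive
Bayes receive class weighting through per-sample weights since they take
no class-weight parameter. Empty masks raise for all ROI operations.

## Known limitations

The phantom's fracture signal is strong by construction in the separable
preset; accuracies from those runs characterize the machinery, not
clinical difficulty. The numpy networks are CPU-sized: they demonstrate
the training recipe (losses, oversampling, augmentation, checkpointing)
rather than state-of-the-art segmentation capacity. Surface area is the
voxelized (face-count) definition and should not be compared directly to
mesh-based values. GLCM features are not IBSI-certified; wavelet/LoG
filtered features and GLRLM/GLSZM/NGTDM families are out of scope.
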