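# Methods

## Problem and approach

Incidental anomalies of the maxillary sinus (MS) — retention cysts and
polyps — are common findings on head-and-neck MRI. Classifying each sinus as
normal or anomalous requires first localizing the relevant sub-volume inside
a large scan. This package implements a non-learned localization strategy
combined with a learned classifier:

1. **Centroid model.** After rigid registration of every scan to a common
   reference (173×319×319 voxels, 0.53×0.75×0.75 mm — registration itself is
   out of scope; `apply_registration` only applies an externally estimated
   transform), the position of each sinus is modelled per side and per axis
   as a Gaussian N(μ, σ²) over voxel coordinates. The default parameters are
   left μ=(75, 231, 121), σ=(1.47, 1.56, 1.76) and right μ=(149, 232, 118),
   σ=(1.90, 1.66, 6.47), estimated upstream from 20 manually annotated
   scans. Although these values are nominally in mm, they only make sense as
   voxel indices in the reference grid (75 < 173, 231 < 319; dividing by the
   0.53/0.75 mm spacing would land far outside the head), so the package
   treats them as 0-based voxel coordinates. Axis 0 is the left–right axis
   (left μx=75 and right μx=149 straddle the 173-voxel extent), axis 1
   anterior–posterior, axis 2 inferior–superior.
2. **Instance sampling.** For each sinus, N centroids are drawn from the
   per-axis Gaussians (N ∈ {1, 5, 10, 15, 20}); a P³ patch (P ∈
   {25, 30, 35, 40, 45}) is cropped around each rounded centroid with
   zero-padding at the volume boundary; right-side patches are mirrored
   along the left–right axis so both sides share the left-sinus appearance;
   every patch is resampled to the 64³ network input. Sampling both enlarges
   the training set (2N instances per scan) and acts as implicit test-time
   augmentation.
3. **Deterministic variant.** "Equidistant" sampling places the N centroids
   evenly on the segment [μ−σ, μ+σ] per varying axis (coordinate i is
   μ − σ + 2σ(i−1)/(N−1); axes can instead be pinned at μ), used to probe
   which axes matter.
4. **Classifier.** A 3D CNN maps each 64³ instance to two-class softmax
   probabilities. Training: Adam, batch 16, lr 1e-4, up to 100 epochs,
   reduce-on-plateau (÷10 after 5 non-improving validation epochs),
   best-validation-loss checkpoint, unweighted cross-entropy. Instances are
   min–max normalized to [0, 1]; no further augmentation.
5. **Multiple Instance Ensembling (MIE).** At inference the per-sinus
   prediction is the arithmetic mean of the instance softmax vectors,
   ŷ = (1/N) Σᵢ softmax(f(xᵢ)). The single-instance baseline scores a sinus
   by its first sampled instance only.

Evaluation uses AUPRC (step-wise average precision, no interpolation) and F1
with the anomalous class positive (32% prevalence makes both preferable to
accuracy), reported per threefold-CV fold as mean ± sample (n−1) sd.
Percent-increase summaries across architecture families use the population
(n) sd, which is the convention that reproduces the published family-level
statistics from the published per-architecture values.

## Numerical and design choices

- **Patch centering and rounding:** continuous centroids are rounded half-up;
  the cube covers [c−⌊P/2⌋, c−⌊P/2⌋+P). Boundary handling is zero-padding
  (not clamping), preserving the geometry of off-center sinuses; a patch with
  no overlap raises `LocalizationError`.
- **Flip before resampling:** the mirror flip is exact on raw voxels;
  resampling afterwards avoids a second interpolation.
- **Resampling convention:** corner-aligned trilinear interpolation (output
  index i ↦ input coordinate i·(P−1)/63). This is the unique simple
  convention under which constants and linear ramps are exact fixed points
  and a 64³ input is returned unchanged; cell-extent alignment would clamp
  at the faces and bend ramps.
- **Equidistant centroids with N=1** degenerate to μ. Under Gaussian
  sampling, N=1 draws one random sample, matching the uniform description of
  the sampling scheme; extracting exactly at μ is available via the
  equidistant mode with all axes pinned.
- **Cross-validation:** three independent patient-level stratified splits
  with per-fold derived seeds. Patients are stratified by how many of their
  sinuses are anomalous, dealt to train/val/test by largest-remainder
  allocation (default proportions 327:37:41), then repaired by random
  patient swaps until each partition's sinus-level positive fraction is
  within ±3 points of the target (default: the cohort's realized fraction).
  Assignment is per patient — both sinuses and all N instances follow — so
  no patient leaks across partitions.
- **Decision threshold** for F1 is 0.5 on p(anomalous); exact ties classify
  positive.
- **Validation loss** is computed per instance (not per sinus); MIE is an
  inference-time rule only.

## Network architectures

No GPU framework is assumed: the layers (3D convolution via im2col, ReLU,
max/average pooling, global average pooling, fully connected, residual and
densely connected blocks, Adam, softmax cross-entropy) are implemented in
numpy with explicit backprop and are verified against numeric gradients in
the test suite. All families share a fixed stride-4 average-pooling stem
(64³ → 16³) so CPU training stays tractable:

- `tiny3d`: Conv(1→8)-ReLU-MaxPool — Conv(8→16)-ReLU-MaxPool — GAP — FC(16→2).
- `resnet3d` (depths 18/50/101/152/200 ↦ 2–6 residual blocks at width 8):
  scaled-down analogues of the published residual families.
- `densenet3d` (depths 121/169/201/264 ↦ 2–5 dense layers, growth 8):
  scaled-down densely connected analogues.

The depth labels select progressively deeper scaled-down variants; training
the literature-scale models is explicitly out of scope, and all desk-scale
experiments use `tiny3d`.

## Synthetic phantom cohort

Real cohort MRIs are not redistributable, so `phantom` generates a
statistical stand-in: a soft-tissue block (intensity 0.5) with two dark
ellipsoidal air cavities (0.05) whose centers are drawn from the
side-specific centroid Gaussians, cavity semi-axes uniform in 12–17 voxels
(roughly the size a P=35 patch should cover). Each sinus is independently
anomalous with probability 0.32; an anomalous cavity carries a bright mass
(0.9) attached to the cavity wall, drawn from two shape families chosen
uniformly — a smooth hemispherical "cyst-like" dome or a lobulated
"polyp-like" union of jittered spheres (radius 4–10 voxels) — emulating the
hyperintense appearance of fluid/mass lesions inside the hypointense sinus
on FLAIR. Additive Gaussian noise (sd 0.05 in tissue-intensity units) is
applied last; Rician noise, bias fields, motion artifacts, other paranasal
sinuses and any anatomical realism beyond the above are deliberately absent.

Consequently, passing the synthetic benchmark shows that localization,
extraction, flipping, resampling, training, ensembling, splitting and
scoring compose correctly and that MIE behaves as intended on a separable
task — it does not certify clinical performance: real anomalies are far more
variable and less separable than bright blobs in dark cavities, and the
published AUPRC/F1 on the clinical cohort cannot be reproduced without that
data.

Geometry, labels and lesion parameters can be drawn without rendering voxels
(`sample_cohort_truths`), which makes cohort-level statistical checks cheap
and lets generation stream one patient at a time. `PhantomSpec.downscaled`
shrinks the grid, the centroid model and all radii by a common factor; the
half-scale grid is 87×160×160.

## The desk-scale benchmark

`run_benchmark` is the canonical self-contained study: 120 half-scale
phantoms (240 sinuses, 32% anomalous), Gaussian sampling with N=5 at
P=18 (the half-scale equivalent of the optimal P=35), `tiny3d` trained for
20 epochs at lr 1e-3 (the small network converges well before the full
100-epoch/1e-4 protocol, which remains the default configuration), three
stratified folds. It reports per-fold MIE and single-instance AUPRC/F1 and
runs in a few minutes on one CPU core. Expected behavior: MIE AUPRC well
above the 0.32 chance level in every fold, and MIE at least as good as the
single-instance baseline in the majority of folds.

## Known limitations

- The phantom task is nearly separable by design; absolute metric values on
  it say nothing about clinical data.
- The published per-split counts (327/37/41 sinuses at N=1) sum to 405, not
  2×299 = 598; the exclusion rule behind that subset is not stated anywhere,
  so partition proportions are configuration (defaulting to 327:37:41) and
  no fixed 405-sinus subset is hard-coded.
- Scaled-down residual/dense families share the pooling stem and small
  widths; depth labels are an ordering, not an architectural reproduction.
- Stratification repair is randomized hill-climbing; for very small cohorts
  the ±3-point tolerance may be infeasible (it raises rather than silently
  degrading; tests on tiny cohorts pass a looser tolerance).
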