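# sinusmie

Classification of paranasal anomalies (polyps and cysts) in the maxillary
sinus (MS) from registered 3D head-and-neck MRI, for medical-image-analysis
researchers and engineers who need a localization-free screening pipeline.

The core idea is to replace learned localization with a statistical one and
to turn the resulting redundancy into an ensemble:

- **Gaussian centroid sampling.** In a rigidly registered reference frame
  (173×319×319 voxels, 0.53×0.75×0.75 mm), the position of each sinus is
  modelled per side and per axis as N(μ, σ²) over voxel coordinates
  (defaults: left μ = (75, 231, 121), σ = (1.47, 1.56, 1.76); right
  μ = (149, 232, 118), σ = (1.90, 1.66, 6.47)). For each sinus, N centroids
  are drawn, a P³ patch is cropped around each, right-side patches are
  mirrored along the left–right axis, and all patches are resampled to the
  64³ input of a 3D CNN f(·). A deterministic "equidistant" variant places
  centroids evenly on [μ−σ, μ+σ] instead.
- **Multiple Instance Ensembling (MIE).** The per-sinus prediction averages
  the instance softmax vectors:

      ŷ = (1/N) Σᵢ₌₁..N softmax(f(xᵢ)),   xᵢ ∈ ℝ^{P×P×P}

  with labels y ∈ {0 = normal, 1 = anomalous} and the anomalous class
  positive. Metrics are AUPRC and F1 under threefold patient-level
  cross-validation.

The package contains the full pipeline — synthetic phantom cohort
(`phantom`), centroid sampling and patch extraction (`sampling`), labeled
datasets and leak-free stratified splits (`dataset`), numpy 3D-CNN
classifiers with the reduce-on-plateau training protocol (`classifier`,
`layers`), and MIE evaluation plus report arithmetic (`evaluate`) — along
with a CLI (`sinus-mie generate|extract|train|evaluate|compare-sampling|benchmark`).
Since clinical cohorts cannot be redistributed, the phantom module generates
statistically matched stand-ins (two dark ellipsoidal cavities per head,
bright wall-attached masses in ~32% of sinuses, centroid jitter matching the
(μ, σ) above) so every experiment runs end to end from nothing. See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from sinusmie import (CentroidModel, SamplingScheme, sample_gaussian_centroids,
                      percentage_increase_report, relative_decrease)
from sinusmie.reference_results import ARCHITECTURE_AUPRC

cents = sample_gaussian_centroids(CentroidModel(), "left",
                                  SamplingScheme(mode="gaussian", n=5, seed=0))
print(cents.round(2))
print(percentage_increase_report(ARCHITECTURE_AUPRC).to_string(index=False))
print(round(relative_decrease(0.89, 0.88), 2))
```

prints

```
[[ 75.18 230.79 122.13]
 [ 75.15 230.16 121.64]
 [ 76.92 232.48 119.76]
 [ 73.14 230.03 121.07]
 [ 71.58 230.66 118.81]]
    family     variant  mean_increase_pct  sd_increase_pct  n_architectures
  resnet3d     sampled          21.883631        11.915408                5
  resnet3d sampled_mie          28.238342        12.811836                5
densenet3d     sampled           4.276896         5.047875                4
densenet3d sampled_mie           9.855558         4.025188                4
1.12
```

The five rows of `cents` are candidate left-MS centroids scattered around
μ = (75, 231, 121) with the configured per-axis spread. The report says that
across the residual-network family, sampling alone raised AUPRC by
21.88 ± 11.92 % over the single-sample baseline and sampling+MIE by
28.24 ± 12.81 % (mean ± population sd across the five depths); the dense
family gains 4.28 ± 5.05 % and 9.86 ± 4.03 %. The final value is the 1.12 %
AUPRC drop incurred by pinning the y-coordinate during equidistant sampling
relative to letting all axes vary (0.89 → 0.88).

The self-contained synthetic study (120 half-scale phantoms, N=5, tiny3d,
three folds) runs in a few minutes on one CPU:

```sh
sinus-mie benchmark --seed 1
```

```
fold 1: MIE AUPRC=1.000 F1=1.000 | single AUPRC=1.000 F1=1.000
fold 2: MIE AUPRC=1.000 F1=1.000 | single AUPRC=0.917 F1=0.933
fold 3: MIE AUPRC=1.000 F1=1.000 | single AUPRC=1.000 F1=1.000
MIE AUPRC 1.000 +/- 0.000; single-instance AUPRC 0.972 +/- 0.048; MIE >= single in 3/3 folds
```

On the (deliberately separable) phantom task the ensemble is never worse
than the single-instance baseline and is well above the 0.32 chance-level
AUPRC; see `docs/methods.md` for what this does and does not demonstrate.

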