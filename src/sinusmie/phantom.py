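"""Synthetic head-phantom cohort with two maxillary-sinus cavities.

Each phantom is a soft-tissue block (mid intensity) containing two dark
ellipsoidal air cavities whose centers are drawn from the side-specific
centroid Gaussians.  An anomalous sinus additionally carries a bright mass
attached to the cavity wall — either a smooth hemispherical "cyst-like" dome
or a lobulated "polyp-like" blob — emulating the FLAIR appearance of fluid
or mass lesions (hyperintense) inside the air-filled (hypointense) sinus.
Additive Gaussian intensity noise is applied last.

The generator is the stand-in for the study cohort: ~300 patients, two
sinuses each, ~32% of sinuses anomalous, centroid jitter matching the
published per-axis (mu, sigma).  It makes no attempt at anatomical realism
beyond what the downstream localization/classification pipeline exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .sampling import CentroidModel, Side, SIDES
from .volume import VolumeImage, REFERENCE_SHAPE, REFERENCE_VOXEL_SIZE_MM


class GeometryError(ValueError):
    """Raised when the requested cavity geometry cannot fit in the volume."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Radii are ellipsoid semi-axes in voxels of ``volume_shape``.  Intensities
    are arbitrary FLAIR-like units: tissue mid, air low, mass high.
    """

    n_patients: int
    anomaly_prevalence_sinus: float = 0.32
    volume_shape: tuple[int, int, int] = REFERENCE_SHAPE
    voxel_size_mm: tuple[float, float, float] = REFERENCE_VOXEL_SIZE_MM
    centroid_model: CentroidModel = field(default_factory=CentroidModel)
    cavity_radius_range: tuple[float, float] = (12.0, 17.0)
    anomaly_radius_range: tuple[float, float] = (4.0, 10.0)
    noise_sd: float = 0.05
    intensity_tissue: float = 0.5
    intensity_cavity: float = 0.05
    intensity_anomaly: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.anomaly_prevalence_sinus <= 1.0:
            raise ValueError("anomaly prevalence must be in [0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume shape must be strictly positive")
        for lo, hi in (self.cavity_radius_range, self.anomaly_radius_range):
            if not (0 < lo <= hi):
                raise ValueError("radius ranges must be positive and ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if 2 * self.cavity_radius_range[0] >= min(self.volume_shape):
            raise GeometryError("cavity cannot fit inside the volume")

    @classmethod
    def downscaled(cls, scale: float = 0.5, **kwargs) -> "PhantomSpec":
        """Spec on a grid shrunk by ``scale``, with the centroid model and
        radii rescaled to match.  The default half-scale grid (87x160x160)
        keeps tests and benchmarks desk-sized; full-size generation remains
        available via the plain constructor."""
        base_model = kwargs.pop("centroid_model", CentroidModel())
        shape = kwargs.pop("volume_shape", REFERENCE_SHAPE)
        kwargs.setdefault("volume_shape",
                          tuple(int(round(s * scale)) for s in shape))
        kwargs.setdefault("voxel_size_mm",
                          tuple(v / scale for v in REFERENCE_VOXEL_SIZE_MM))
        kwargs["centroid_model"] = base_model.scaled(scale)
        kwargs.setdefault("cavity_radius_range",
                          tuple(r * scale for r in cls.cavity_radius_range))
        kwargs.setdefault("anomaly_radius_range",
                          tuple(r * scale for r in cls.anomaly_radius_range))
        return cls(**kwargs)


@dataclass
class SinusTruth:
    """Ground truth for one sinus of one phantom."""

    centroid: tuple[float, float, float]
    label: int                                   # 0 normal, 1 anomalous
    cavity_semi_axes: tuple[float, float, float]
    anomaly_center: tuple[float, float, float] | None = None
    anomaly_radius: float | None = None
    anomaly_shape: str | None = None             # 'cyst' or 'polyp'


@dataclass
class PhantomTruth:
    patient_id: str
    sides: dict[Side, SinusTruth]


def _draw_sinus_truth(spec: PhantomSpec, side: Side,
                      rng: np.random.Generator) -> SinusTruth:
    shape = np.array(spec.volume_shape, dtype=float)
    mu = spec.centroid_model.mu(side)
    sigma = spec.centroid_model.sigma(side)
    lo, hi = spec.cavity_radius_range
    for _ in range(100):
        centroid = mu + sigma * rng.standard_normal(3)
        semi = rng.uniform(lo, hi, size=3)
        if np.all(centroid - semi >= 0) and np.all(centroid + semi <= shape - 1):
            break
    else:
        raise GeometryError(
            f"could not place a cavity for side {side}: centroid Gaussian "
            f"mu={tuple(mu)} with semi-axes up to {hi} does not fit in "
            f"volume {spec.volume_shape}")
    label = int(rng.random() < spec.anomaly_prevalence_sinus)
    anomaly_center = anomaly_radius = anomaly_shape = None
    if label:
        a_lo, a_hi = spec.anomaly_radius_range
        r = rng.uniform(a_lo, max(a_lo, min(a_hi, 0.8 * semi.min())))
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        # mass center pulled inward from the wall point so it stays attached
        # to (and mostly inside) the cavity
        wall = centroid + semi * u
        inward = min(1.0, r / float(semi.min()))
        anomaly_center = tuple(float(x) for x in
                               centroid + (1.0 - 0.8 * inward) * (wall - centroid))
        anomaly_radius = float(r)
        anomaly_shape = "cyst" if rng.random() < 0.5 else "polyp"
    return SinusTruth(centroid=tuple(float(x) for x in centroid), label=label,
                      cavity_semi_axes=tuple(float(x) for x in semi),
                      anomaly_center=anomaly_center, anomaly_radius=anomaly_radius,
                      anomaly_shape=anomaly_shape)


def sample_cohort_truths(spec: PhantomSpec) -> list[PhantomTruth]:
    """Draw labels, centroids and lesion geometry for the whole cohort
    without rendering any voxel data (cheap; used for statistical checks
    and as the first stage of generation)."""
    truths = []
    for pid_idx, child in enumerate(
            np.random.SeedSequence(spec.seed).spawn(spec.n_patients)):
        truth_rng = np.random.default_rng(child.spawn(2)[0])
        sides = {side: _draw_sinus_truth(spec, side, truth_rng)
                 for side in SIDES}
        truths.append(PhantomTruth(patient_id=f"phantom{pid_idx:04d}", sides=sides))
    return truths


def _ellipsoid_mask(box_shape, origin, center, semi) -> np.ndarray:
    coords = [np.arange(box_shape[a]) + origin[a] for a in range(3)]
    dist2 = sum(((coords[a].reshape([-1 if i == a else 1 for i in range(3)])
                  - center[a]) / semi[a]) ** 2 for a in range(3))
    return dist2 <= 1.0


def _sphere_mask(box_shape, origin, center, radius) -> np.ndarray:
    return _ellipsoid_mask(box_shape, origin, center, (radius,) * 3)


def render_phantom(spec: PhantomSpec, truth: PhantomTruth,
                   rng: np.random.Generator) -> VolumeImage:
    """Render the voxel data of one phantom from its ground truth.

    ``rng`` drives lesion lobulation and intensity noise only; geometry and
    labels come from ``truth``.
    """
    data = np.full(spec.volume_shape, spec.intensity_tissue, dtype=np.float32)
    for side in SIDES:
        st = truth.sides[side]
        center = np.array(st.centroid)
        semi = np.array(st.cavity_semi_axes)
        lo = np.maximum(np.floor(center - semi - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center + semi + 2).astype(int),
                        np.array(spec.volume_shape))
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        box_shape = tuple(b - a for a, b in zip(lo, hi))
        cavity = _ellipsoid_mask(box_shape, lo, center, semi)
        region = data[box]
        region[cavity] = spec.intensity_cavity
        if st.label:
            acent = np.array(st.anomaly_center)
            r = st.anomaly_radius
            if st.anomaly_shape == "cyst":
                blob = _sphere_mask(box_shape, lo, acent, r)
            else:  # lobulated: union of a few jittered spheres
                blob = np.zeros(box_shape, dtype=bool)
                n_lobes = rng.integers(2, 5)
                for _ in range(n_lobes):
                    c = acent + rng.uniform(-0.5, 0.5, size=3) * r
                    rr = r * rng.uniform(0.5, 1.0)
                    blob |= _sphere_mask(box_shape, lo, c, rr)
            region[blob & cavity] = spec.intensity_anomaly
        data[box] = region
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd,
                           size=spec.volume_shape).astype(np.float32)
    return VolumeImage(data=data, voxel_size_mm=spec.voxel_size_mm,
                       patient_id=truth.patient_id)


def iter_phantoms(spec: PhantomSpec
                  ) -> Iterator[tuple[VolumeImage, PhantomTruth]]:
    """Generate (volume, truth) pairs one patient at a time.

    Memory-friendly form of :func:`generate_phantom_cohort`; identical
    output for an identical spec (including seed).
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    for pid_idx, child in enumerate(children):
        truth_ss, render_ss = child.spawn(2)
        truth_rng = np.random.default_rng(truth_ss)
        sides = {side: _draw_sinus_truth(spec, side, truth_rng)
                 for side in SIDES}
        truth = PhantomTruth(patient_id=f"phantom{pid_idx:04d}", sides=sides)
        yield render_phantom(spec, truth, np.random.default_rng(render_ss)), truth


def generate_phantom_cohort(spec: PhantomSpec
                            ) -> tuple[list[VolumeImage], list[PhantomTruth]]:
    """Generate the full cohort as in-memory lists (see iter_phantoms)."""
    volumes, truths = [], []
    for vol, truth in iter_phantoms(spec):
        volumes.append(vol)
        truths.append(truth)
    return volumes, truths


def empirical_centroid_stats(truths: list[PhantomTruth], side: Side
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis sample mean and sample (n-1) sd of the true centroids."""
    if len(truths) == 0:
        raise ValueError("no truths given")
    if len(truths) < 2:
        raise ValueError("need at least 2 truths for a sample sd")
    cents = np.array([t.sides[side].centroid for t in truths], dtype=float)
    return cents.mean(axis=0), cents.std(axis=0, ddof=1)


def cavity_mean_intensities(volume: VolumeImage, truth: PhantomTruth
                            ) -> dict[Side, float]:
    """Mean intensity inside each cavity ellipsoid (ground-truth mask).

    Used to verify the separability floor: anomalous cavities must be
    brighter on average than normal ones by a positive margin.
    """
    out = {}
    for side in SIDES:
        st = truth.sides[side]
        center = np.array(st.centroid)
        semi = np.array(st.cavity_semi_axes)
        lo = np.maximum(np.floor(center - semi - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center + semi + 2).astype(int),
                        np.array(volume.data.shape))
        box_shape = tuple(b - a for a, b in zip(lo, hi))
        mask = _ellipsoid_mask(box_shape, lo, center, semi)
        region = volume.data[tuple(slice(a, b) for a, b in zip(lo, hi))]
        out[side] = float(region[mask].mean())
    return out


# -- truth table I/O ---------------------------------------------------------

TRUTH_COLUMNS = ["patient_id", "side", "label", "cx", "cy", "cz"]


def truths_to_table(truths: Iterable[PhantomTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        for side in SIDES:
            st = t.sides[side]
            rows.append({"patient_id": t.patient_id, "side": side,
                         "label": st.label, "cx": st.centroid[0],
                         "cy": st.centroid[1], "cz": st.centroid[2]})
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth_table(truths: Iterable[PhantomTruth], path) -> None:
    truths_to_table(truths).to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return df
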