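"""Maxillary-sinus localization and instance extraction.

Localization is non-learned: per side and per axis, a Gaussian N(mu, sigma^2)
over voxel coordinates of the sinus centroid in the registered reference
frame.  N centroids are sampled per sinus, a P^3 patch is cropped around each
(zero-padded at the volume boundary), right-side patches are mirrored along
the left-right axis so both sides share the left-sinus appearance, and every
patch is resampled to the 64^3 classifier input by trilinear interpolation.

A deterministic "equidistant" variant places the N centroids evenly along the
segment [mu - sigma, mu + sigma] on each varying axis, with non-varying axes
pinned at mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml
from scipy.ndimage import map_coordinates

from .volume import VolumeImage

Side = Literal["left", "right"]
SIDES: tuple[Side, Side] = ("left", "right")

MODEL_INPUT_SIZE = 64

#: Default centroid model, estimated in the source study from 20 manually
#: annotated patients in the registered 173x319x319 reference frame.
#: Values are 0-based voxel coordinates (left mu_x=75 vs right mu_x=149
#: straddle the 173-voxel left-right axis).
DEFAULT_LEFT_MU = (75.0, 231.0, 121.0)
DEFAULT_LEFT_SIGMA = (1.47, 1.56, 1.76)
DEFAULT_RIGHT_MU = (149.0, 232.0, 118.0)
DEFAULT_RIGHT_SIGMA = (1.90, 1.66, 6.47)


class LocalizationError(RuntimeError):
    """Raised when a sampled centroid places the patch fully outside the
    volume, i.e. localization has failed for this scan."""


def _triple(v: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 values, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class CentroidModel:
    """Six (mu, sigma) pairs: two sides x three axes, in voxel units."""

    left_mu: tuple[float, float, float] = DEFAULT_LEFT_MU
    left_sigma: tuple[float, float, float] = DEFAULT_LEFT_SIGMA
    right_mu: tuple[float, float, float] = DEFAULT_RIGHT_MU
    right_sigma: tuple[float, float, float] = DEFAULT_RIGHT_SIGMA

    def __post_init__(self) -> None:
        for name in ("left_mu", "left_sigma", "right_mu", "right_sigma"):
            object.__setattr__(self, name, _triple(getattr(self, name)))
        for s in (self.left_sigma, self.right_sigma):
            if any(x <= 0 for x in s):
                raise ValueError("all sigma must be > 0")

    def mu(self, side: Side) -> np.ndarray:
        self._check_side(side)
        return np.array(self.left_mu if side == "left" else self.right_mu)

    def sigma(self, side: Side) -> np.ndarray:
        self._check_side(side)
        return np.array(self.left_sigma if side == "left" else self.right_sigma)

    @staticmethod
    def _check_side(side: str) -> None:
        if side not in SIDES:
            raise ValueError(f"unknown side {side!r}; expected 'left' or 'right'")

    def scaled(self, factor: float) -> "CentroidModel":
        """Rescale the model to a downscaled voxel grid (mu and sigma both
        scale linearly with the grid)."""
        f = float(factor)
        return CentroidModel(
            left_mu=tuple(m * f for m in self.left_mu),
            left_sigma=tuple(s * f for s in self.left_sigma),
            right_mu=tuple(m * f for m in self.right_mu),
            right_sigma=tuple(s * f for s in self.right_sigma),
        )

    def mirrored(self, x_extent: int) -> "CentroidModel":
        """Model for a volume mirrored along the left-right axis
        (left and right swap; x-coordinates map to extent-1-x)."""
        flip = lambda mu: (x_extent - 1 - mu[0], mu[1], mu[2])
        return CentroidModel(
            left_mu=flip(self.right_mu), left_sigma=self.right_sigma,
            right_mu=flip(self.left_mu), right_sigma=self.left_sigma,
        )

    def to_dict(self) -> dict:
        return {
            "left": {"mu": list(self.left_mu), "sigma": list(self.left_sigma)},
            "right": {"mu": list(self.right_mu), "sigma": list(self.right_sigma)},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(left_mu=d["left"]["mu"], left_sigma=d["left"]["sigma"],
                   right_mu=d["right"]["mu"], right_sigma=d["right"]["sigma"])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "CentroidModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class SamplingScheme:
    """How the N centroids of one sinus are chosen.

    mode='gaussian' draws N iid samples from the per-axis Gaussians (the
    per-axis ``vary`` flags are ignored); mode='equidistant' places them
    deterministically on the segment [mu-sigma, mu+sigma] for each axis
    flagged True in ``vary``, pinning the other axes at mu.
    """

    mode: Literal["gaussian", "equidistant"] = "gaussian"
    n: int = 15
    seed: int = 0
    vary: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian", "equidistant"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("sample size N must be a positive integer")
        object.__setattr__(self, "vary", tuple(bool(v) for v in self.vary))

    def label(self) -> str:
        if self.mode == "gaussian":
            return "gaussian"
        tags = [a if v else f"{a}=mu" for a, v in zip("xyz", self.vary)]
        return "equidistant(" + ",".join(tags) + ")"


@dataclass
class SinusInstance:
    """One extracted sinus patch: cropped at a sampled centroid, mirrored if
    right-sided, and resampled to the 64^3 classifier input."""

    patient_id: str
    side: Side
    instance_index: int          # 1-based sampling order within the sinus
    centroid: tuple[float, float, float]
    patch_size: int
    data: np.ndarray             # exactly 64^3, finite, post-flip for right

    def __post_init__(self) -> None:
        shape = tuple(self.data.shape)
        if shape != (MODEL_INPUT_SIZE,) * 3:
            raise ValueError(f"instance data must be {MODEL_INPUT_SIZE}^3, got {shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("instance data contains non-finite values")


def sample_gaussian_centroids(model: CentroidModel, side: Side,
                              scheme: SamplingScheme,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw scheme.n centroids, each axis independently N(mu, sigma^2).

    Returns continuous (n, 3) coordinates; rounding to the voxel grid is
    deferred to patch extraction.
    """
    if scheme.mode != "gaussian":
        raise ValueError("scheme.mode must be 'gaussian'")
    mu, sigma = model.mu(side), model.sigma(side)
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    return mu + sigma * rng.standard_normal((scheme.n, 3))


def equidistant_centroids(model: CentroidModel, side: Side,
                          scheme: SamplingScheme) -> np.ndarray:
    """Place scheme.n centroids evenly on the segment [mu-sigma, mu+sigma].

    Varying axis i of centroid k takes mu - sigma + 2*sigma*(k-1)/(n-1)
    (mu when n == 1); fixed axes take mu.  The k-th centroid combines the
    k-th value of every varying axis, i.e. the points lie on a 3D line.
    """
    if scheme.mode != "equidistant":
        raise ValueError("scheme.mode must be 'equidistant'")
    mu, sigma = model.mu(side), model.sigma(side)
    n = scheme.n
    out = np.tile(mu, (n, 1)).astype(float)
    if n > 1:
        frac = np.arange(n) / (n - 1)          # 0 .. 1
        for ax in range(3):
            if scheme.vary[ax]:
                out[:, ax] = mu[ax] - sigma[ax] + 2.0 * sigma[ax] * frac
    return out


def extract_patch(volume: VolumeImage | np.ndarray,
                  centroid: Sequence[float], patch_size: int) -> np.ndarray:
    """Crop an axis-aligned P^3 cube centered at round(centroid).

    The continuous centroid is rounded half-up to a voxel index c and the
    cube covers [c - P//2, c - P//2 + P) on each axis.  Voxels outside the
    volume are zero-padded; a patch with no overlap at all raises
    LocalizationError.
    """
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    P = int(patch_size)
    if P < 1:
        raise ValueError("patch size must be >= 1")
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape != (3,) or not np.all(np.isfinite(centroid)):
        raise ValueError("centroid must be a finite coordinate triple")
    c = np.floor(centroid + 0.5).astype(int)    # round half up
    start = c - P // 2
    stop = start + P
    if np.any(start >= np.array(data.shape)) or np.any(stop <= 0):
        raise LocalizationError(
            f"patch at centroid {tuple(centroid)} (P={P}) lies fully outside "
            f"volume of shape {data.shape}")
    out = np.zeros((P, P, P), dtype=data.dtype)
    src = tuple(slice(max(s, 0), min(e, d))
                for s, e, d in zip(start, stop, data.shape))
    dst = tuple(slice(src_s.start - s, src_s.stop - s)
                for src_s, s in zip(src, start))
    out[dst] = data[src]
    return out


def flip_right_sinus(cube: np.ndarray) -> np.ndarray:
    """Mirror a patch along the left-right (x) axis, giving right-sinus
    patches the appearance of left ones."""
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("expected a 3D cube")
    return cube[::-1, :, :].copy()


def resample_to_input(cube: np.ndarray, size: int = MODEL_INPUT_SIZE) -> np.ndarray:
    """Trilinearly resample a P^3 cube onto a size^3 grid.

    Corner-aligned: output index i maps to input coordinate i*(P-1)/(size-1),
    so the resampled grid spans the full extent of the patch, constants and
    linear ramps are reproduced exactly, and a P == size input is returned
    unchanged (up to interpolation round-off).
    """
    cube = np.asarray(cube, dtype=np.float32)
    if cube.ndim != 3 or len(set(cube.shape)) != 1:
        raise ValueError("expected a cubic 3D array")
    P = cube.shape[0]
    if P < 2:
        raise ValueError("patch side must be >= 2 for trilinear resampling")
    coords_1d = np.linspace(0.0, P - 1.0, size)
    grid = np.meshgrid(coords_1d, coords_1d, coords_1d, indexing="ij")
    out = map_coordinates(cube, np.stack(grid), order=1, mode="nearest")
    return out.astype(np.float32)


def _side_rngs(scheme: SamplingScheme, patient_key: int = 0
               ) -> dict[Side, np.random.Generator]:
    ss = np.random.SeedSequence([int(scheme.seed) & 0x7FFFFFFF, int(patient_key)])
    left, right = ss.spawn(2)
    return {"left": np.random.default_rng(left), "right": np.random.default_rng(right)}


def extract_instances(volume: VolumeImage, model: CentroidModel,
                      scheme: SamplingScheme, patch_size: int,
                      patient_key: int = 0) -> list[SinusInstance]:
    """Extract the 2N sinus instances of one scan (N left + N right).

    Right-side patches are flipped before resampling so the flip acts on raw
    voxels.  ``patient_key`` decorrelates the Gaussian draws of different
    scans processed under the same scheme seed; results are reproducible
    from (scheme.seed, patient_key).
    """
    rngs = _side_rngs(scheme, patient_key)
    instances: list[SinusInstance] = []
    for side in SIDES:
        if scheme.mode == "gaussian":
            cents = sample_gaussian_centroids(model, side, scheme, rng=rngs[side])
        else:
            cents = equidistant_centroids(model, side, scheme)
        for i, cent in enumerate(cents, start=1):
            patch = extract_patch(volume, cent, patch_size)
            if side == "right":
                patch = flip_right_sinus(patch)
            cube = resample_to_input(patch)
            instances.append(SinusInstance(
                patient_id=volume.patient_id, side=side, instance_index=i,
                centroid=tuple(float(x) for x in cent),
                patch_size=int(patch_size), data=cube))
    return instances


def extract_cohort(volumes: Iterable[VolumeImage], model: CentroidModel,
                   scheme: SamplingScheme, patch_size: int
                   ) -> dict[tuple[str, Side], list[SinusInstance]]:
    """Extract instances for a whole cohort, keyed by (patient_id, side).

    Each scan gets an independent sampling substream derived from
    (scheme.seed, enumeration index), so cohorts are reproducible while
    different patients see different centroid draws.
    """
    out: dict[tuple[str, Side], list[SinusInstance]] = {}
    for key, vol in enumerate(volumes):
        for inst in extract_instances(vol, model, scheme, patch_size,
                                      patient_key=key):
            out.setdefault((inst.patient_id, inst.side), []).append(inst)
    return out
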