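"""Volumetric image container and NIfTI I/O.

The reference geometry of the cohort is a registered 173x319x319 voxel grid
with 0.53 x 0.75 x 0.75 mm spacing.  Array axis 0 is the left-right (x)
axis, axis 1 anterior-posterior (y), axis 2 inferior-superior (z); the two
maxillary sinuses straddle the x axis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

REFERENCE_SHAPE: tuple[int, int, int] = (173, 319, 319)
REFERENCE_VOXEL_SIZE_MM: tuple[float, float, float] = (0.53, 0.75, 0.75)


@dataclass
class VolumeImage:
    """A 3D scalar grid with voxel spacing and patient provenance."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = REFERENCE_VOXEL_SIZE_MM
    patient_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff


def load_nifti(path: str | os.PathLike, patient_id: str = "") -> VolumeImage:
    """Load a NIfTI volume; voxel size is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not patient_id:
        base = os.path.basename(str(path))
        patient_id = base.split(".nii")[0]
    return VolumeImage(data=data, voxel_size_mm=zooms, patient_id=patient_id,
                       affine=np.asarray(img.affine))


def save_nifti(volume: VolumeImage, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          volume.default_affine())
    img.header.set_zooms(volume.voxel_size_mm)
    nib.save(img, str(path))


def apply_registration(volume: VolumeImage, affine_transform: np.ndarray,
                       reference_shape: tuple[int, int, int] = REFERENCE_SHAPE,
                       order: int = 1) -> VolumeImage:
    """Resample ``volume`` into the reference frame given a 4x4 voxel-space
    affine produced by an external rigid-registration tool.

    Registration itself is out of scope for this package: upstream tools
    estimate the transform, and this hook only applies it so that one
    centroid model can be used for every patient.
    """
    from scipy.ndimage import affine_transform as nd_affine

    T = np.asarray(affine_transform, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("expected a 4x4 voxel-space affine")
    out = nd_affine(volume.data, T[:3, :3], offset=T[:3, 3],
                    output_shape=reference_shape, order=order, mode="constant")
    return VolumeImage(data=out.astype(np.float32),
                       voxel_size_mm=volume.voxel_size_mm,
                       patient_id=volume.patient_id)
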