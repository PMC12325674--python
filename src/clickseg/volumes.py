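"""Core volumetric data types, intensity normalization, binarization and NIfTI I/O.

Conventions used throughout the package:

* volumes are 3D arrays indexed ``(i, j, k)`` over ``(H, W, D)``, 0-based;
* voxel spacing is isotropic by default (1 mm), so voxel distances equal
  millimeters;
* CT intensities are Hounsfield units before normalization and lie in
  ``[-1, 1]`` after windowed normalization;
* PET intensities are uptake-scale before normalization and are z-scored
  per scan;
* probability volumes are voxelwise foreground probabilities in ``[0, 1]``
  and are binarized with a strict ``p > 0.5`` threshold before any metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "ImageVolume",
    "VolumePair",
    "BinaryMask",
    "ProbabilityVolume",
    "window_normalize_ct",
    "zscore_normalize_pet",
    "binarize",
    "read_nifti",
    "write_nifti",
]

#: Hounsfield-unit window applied to CT scans before rescaling to [-1, 1].
CT_WINDOW_HU = (-200.0, 200.0)

MIN_EXTENT = 8


class Modality(str, Enum):
    CT = "CT"
    PET = "PET"
    OTHER = "OTHER"


def _check_grid(data: np.ndarray, name: str) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got shape {data.shape}")
    if min(data.shape) < MIN_EXTENT:
        raise ValueError(
            f"{name} axis extents must all be >= {MIN_EXTENT}, got {data.shape}"
        )
    return data


@dataclass
class ImageVolume:
    """A single-modality 3D scalar image on an isotropic voxel grid."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        self.data = _check_grid(self.data, "ImageVolume.data").astype(
            np.float32, copy=False
        )
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 positive scalars, got {self.spacing_mm}")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VolumePair:
    """Co-registered, normalized CT + PET channels — the model input."""

    ct: ImageVolume
    pet: ImageVolume

    def __post_init__(self) -> None:
        if self.ct.shape != self.pet.shape:
            raise ValueError(
                f"CT/PET shapes differ: {self.ct.shape} vs {self.pet.shape}"
            )
        if self.ct.spacing_mm != self.pet.spacing_mm:
            raise ValueError("CT/PET voxel spacings differ")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        return self.ct.spacing_mm


@dataclass
class BinaryMask:
    """A 3D mask over {0, 1}; holds ground-truth and thresholded segmentations."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = _check_grid(self.data, "BinaryMask.data")
        vals = np.unique(data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0/1, found {vals[:10]}")
        self.data = data.astype(np.uint8, copy=False)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def sum(self) -> int:
        return int(self.data.sum())


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground probability in [0, 1].

    This is the sigmoid output of a segmentation network and, fed back as an
    input channel, the memory mechanism carried across interaction events.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = _check_grid(self.data, "ProbabilityVolume.data").astype(
            np.float32, copy=False
        )
        if not np.isfinite(data).all():
            raise ValueError("probability volume contains non-finite values")
        if data.min() < 0.0 or data.max() > 1.0:
            raise ValueError(
                f"probabilities must lie in [0, 1], range is "
                f"[{data.min():.4g}, {data.max():.4g}]"
            )
        self.data = data
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def window_normalize_ct(raw: ImageVolume) -> ImageVolume:
    """Window a CT volume to [-200, 200] HU and rescale linearly onto [-1, 1].

    Monotone non-decreasing; values outside the window saturate at +-1.
    """
    if raw.modality is not Modality.CT:
        raise ValueError(f"expected a CT volume, got modality {raw.modality.value}")
    n_bad = int((~np.isfinite(raw.data)).sum())
    if n_bad:
        raise ValueError(f"CT volume has {n_bad} non-finite voxels")
    lo, hi = CT_WINDOW_HU
    clipped = np.clip(raw.data.astype(np.float64), lo, hi)
    scaled = (clipped - lo) / (hi - lo) * 2.0 - 1.0
    return ImageVolume(scaled.astype(np.float32), raw.spacing_mm, Modality.CT)


def zscore_normalize_pet(raw: ImageVolume) -> ImageVolume:
    """Standardize a PET volume to zero mean, unit SD over all voxels.

    The statistics are computed per scan over the whole volume (no body
    masking).  A constant volume has zero SD and indicates broken input, so
    it raises instead of being silently zeroed.
    """
    if raw.modality is not Modality.PET:
        raise ValueError(f"expected a PET volume, got modality {raw.modality.value}")
    n_bad = int((~np.isfinite(raw.data)).sum())
    if n_bad:
        raise ValueError(f"PET volume has {n_bad} non-finite voxels")
    x = raw.data.astype(np.float64)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("PET volume is constant (zero SD); cannot z-score")
    z = (x - x.mean()) / sd
    return ImageVolume(z.astype(np.float32), raw.spacing_mm, Modality.PET)


def binarize(p: ProbabilityVolume) -> BinaryMask:
    """Threshold a probability volume at 0.5 (strict: p > 0.5 is foreground).

    A voxel at exactly 0.5 is background.  Applied identically before every
    evaluation metric.
    """
    return BinaryMask((p.data > 0.5).astype(np.uint8), p.spacing_mm)


def _spacing_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_nifti(path: str | Path, kind: str = "image") -> ImageVolume | BinaryMask:
    """Read a NIfTI volume as an ``ImageVolume`` (``kind='image'``) or
    ``BinaryMask`` (``kind='mask'``).

    Pass ``kind='ct'`` or ``kind='pet'`` to tag the modality.  Anisotropic
    spacing emits a warning (resampling is the caller's job); a mask file
    with values outside {0, 1} raises.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = _spacing_from_affine(img)
    if len(set(spacing)) > 1:
        warnings.warn(
            f"{path}: anisotropic voxel spacing {spacing}; distances assume "
            "isotropic voxels — resample before evaluation",
            stacklevel=2,
        )
    if kind == "mask":
        return BinaryMask(np.asarray(data), spacing)
    modality = {"ct": Modality.CT, "pet": Modality.PET, "image": Modality.OTHER}[kind]
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, modality)


def write_nifti(
    volume: ImageVolume | BinaryMask | ProbabilityVolume, path: str | Path
) -> None:
    """Write a volume to NIfTI; masks are stored as unsigned 8-bit, images as
    float32.  Spacing goes into the affine diagonal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, BinaryMask):
        data = volume.data.astype(np.uint8)
    else:
        data = volume.data.astype(np.float32)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
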