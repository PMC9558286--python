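"""Core volumetric data types and NIfTI-1 I/O.

A :class:`Volume` is the single image currency of the package: a 3D scalar
grid with its voxel-to-world affine and an optional binary brain mask.
Volumes are reoriented to the closest-to-RAS axis order on load so that all
voxel-space operations share one axis convention.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np

MODALITIES = frozenset({"FLAIR", "T1", "T1S"})

MASK_SUFFIX = "_mask"


@dataclasses.dataclass
class Volume:
    """A 3D scalar image with world geometry and an optional brain mask.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units, or [0, 1] after
        normalization).
    affine
        4x4 voxel-to-world (mm) homogeneous map.
    mask
        Optional boolean array on the same grid marking brain voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size (mm) along each axis, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray, mask: Optional[np.ndarray] = "keep") -> "Volume":
        """Return a new Volume sharing geometry, with replaced data."""
        if isinstance(mask, str) and mask == "keep":
            mask = None if self.mask is None else self.mask.copy()
        return Volume(np.asarray(data), self.affine.copy(), mask)

    def copy(self) -> "Volume":
        return Volume(
            self.data.copy(),
            self.affine.copy(),
            None if self.mask is None else self.mask.copy(),
        )

    def get_mask(self) -> np.ndarray:
        """The brain mask, or a full-grid mask when none is attached."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask


@dataclasses.dataclass
class LongitudinalCase:
    """Baseline + follow-up volumes per modality, with optional ground truth.

    ``new_lesion_mask`` marks voxels of lesions present only at follow-up;
    it lives on the follow-up grid.
    """

    case_id: str
    baseline: Dict[str, Volume]
    followup: Dict[str, Volume]
    new_lesion_mask: Optional[Volume] = None

    def __post_init__(self) -> None:
        for name in list(self.baseline) + list(self.followup):
            if name not in MODALITIES:
                raise ValueError(f"unknown modality {name!r}; expected one of {sorted(MODALITIES)}")
        if self.new_lesion_mask is not None and "FLAIR" in self.followup:
            if self.new_lesion_mask.shape != self.followup["FLAIR"].shape:
                raise ValueError("new_lesion_mask must share the follow-up grid")


def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 volume, reoriented to the closest-to-RAS axis order.

    Raises an OSError for a missing file and ValueError for non-3D images.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable header
        raise OSError(f"could not read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    return Volume(data, np.asarray(img.affine, dtype=float), None)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as NIfTI-1. The mask, if any, is *not* serialized here;
    write it separately (convention: same stem + ``_mask``)."""
    path = Path(path)
    if not path.parent.exists():
        raise OSError(f"parent directory does not exist: {path.parent}")
    data = np.asarray(vol.data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype not in (np.uint8, np.int16, np.int32):
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def mask_path_for(path) -> Path:
    """The companion mask filename for an intensity file."""
    path = Path(path)
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + MASK_SUFFIX + ext)
    raise ValueError(f"not a NIfTI filename: {path}")


def read_volume_with_mask(path) -> Volume:
    """Read a volume and attach its ``_mask`` companion file when present."""
    vol = read_volume(path)
    mpath = mask_path_for(path)
    if mpath.exists():
        m = read_volume(mpath)
        vol.mask = m.data > 0.5
    return vol


def write_volume_with_mask(vol: Volume, path) -> None:
    write_volume(vol, path)
    if vol.mask is not None:
        write_volume(Volume(vol.mask.astype(np.uint8), vol.affine), mask_path_for(path))
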