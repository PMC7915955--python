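"""Core voxel-grid containers shared by every stage of the pipeline.

Coordinate convention (used everywhere in this package): 0-based voxel
indices, axis order (x, y, z), and physical position of a voxel center
``origin_mm + index * spacing_mm``.  NIfTI I/O writes this convention into
the affine as a diagonal matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterator, Tuple

import nibabel as nib
import numpy as np

Vec3 = Tuple[float, float, float]


@dataclass
class ImageVolume:
    """A 3D scalar grid (HU or normalized intensity) with geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, axis order (x, y, z).
    spacing_mm : tuple of 3 floats
        Voxel pitch along each axis, strictly positive.
    origin_mm : tuple of 3 floats
        Physical position of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing_mm: Vec3 = (1.0, 1.0, 1.0)
    origin_mm: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def index_to_physical(self, index) -> np.ndarray:
        """Physical mm position of a (possibly fractional) voxel index."""
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(self.spacing_mm)

    def copy(self) -> "ImageVolume":
        return replace(self, data=self.data.copy())


@dataclass
class StructureSet:
    """Named binary masks sharing one grid (one subject's contours)."""

    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    spacing_mm: Vec3 = (1.0, 1.0, 1.0)
    origin_mm: Vec3 = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks on inconsistent grids: {shapes}")
        for name, mask in self.masks.items():
            self.masks[name] = np.asarray(mask).astype(bool)

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.masks)

    @property
    def shape(self) -> Tuple[int, int, int]:
        if not self.masks:
            raise ValueError("empty structure set has no grid shape")
        return next(iter(self.masks.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def volume_voxels(self, name: str) -> int:
        return int(self.masks[name].sum())

    def label_map(self, order=None) -> np.ndarray:
        """Integer label map: 0 = background, i+1 = structure ``order[i]``.

        Later structures overwrite earlier ones where masks overlap (they
        should not, for phantom data).
        """
        order = list(order) if order is not None else list(self.masks)
        out = np.zeros(self.shape, dtype=np.int32)
        for i, name in enumerate(order):
            out[self.masks[name]] = i + 1
        return out

    def copy(self) -> "StructureSet":
        return StructureSet(
            masks={k: v.copy() for k, v in self.masks.items()},
            spacing_mm=self.spacing_mm,
            origin_mm=self.origin_mm,
        )


def _affine(spacing_mm: Vec3, origin_mm: Vec3) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    aff[:3, 3] = origin_mm
    return aff


def save_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI, spacing/origin encoded in the affine."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing_mm, vol.origin_mm))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, spacing_mm: Vec3, origin_mm: Vec3, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm, origin_mm))
    nib.save(img, str(path))


def load_volume(path) -> ImageVolume:
    """Read a NIfTI volume; the affine must be axis-aligned (diagonal)."""
    img = nib.load(str(path))
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if not np.allclose(off_diag, 0):
        raise ValueError(f"{path}: only axis-aligned affines are supported")
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5


def load_structure_set(mask_dir, names=None) -> StructureSet:
    """Read every ``<name>.nii.gz`` in a directory into a StructureSet."""
    mask_dir = Path(mask_dir)
    paths = sorted(mask_dir.glob("*.nii.gz"))
    if names is not None:
        paths = [mask_dir / f"{n}.nii.gz" for n in names]
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks found in {mask_dir}")
    first = load_volume(paths[0])
    masks = {}
    for p in paths:
        name = p.name[: -len(".nii.gz")]
        masks[name] = load_mask(p)
    return StructureSet(masks=masks, spacing_mm=first.spacing_mm, origin_mm=first.origin_mm)
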