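"""Two-step segmentation: coarse localization, ROI extraction, ROI
segmentation, and reassembly.

Step 1 runs a multilabel/multiclass network on the downsampled field of
view and yields one coarse mask per structure.  For each structure the
*middle point* (rounded voxel centroid of the predicted coarse voxels,
mapped back to full-resolution index space) anchors a fixed-size ROI box
taken from a per-structure size table; boxes that would overhang the grid
are shifted inside rather than shrunk, so each per-structure network
always sees its preset input size.  Step 2 segments each ROI at full
resolution with a single-label network, and the box masks are pasted back
into the full grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .grids import ImageVolume, StructureSet
from .preprocess import PreprocessConfig, downsample_localization, preprocess_image

IntVec3 = Tuple[int, int, int]


class RoiSizeTable(dict):
    """structure name -> preset ROI size (x, y, z) voxels at full resolution."""

    @classmethod
    def from_labels(cls, label_sets: Sequence[StructureSet], pad_fraction: float = 0.25,
                    divisible_by: IntVec3 = (1, 1, 1),
                    max_size: Optional[IntVec3] = None) -> "RoiSizeTable":
        """Per-structure bounding-box maxima over training labels, padded by
        ``pad_fraction`` and rounded up to ``divisible_by`` per axis."""
        extents: Dict[str, np.ndarray] = {}
        for ss in label_sets:
            for name in ss.names:
                m = ss[name]
                if not m.any():
                    continue
                idx = np.nonzero(m)
                ext = np.array([a.max() - a.min() + 1 for a in idx])
                extents[name] = np.maximum(extents.get(name, 0), ext)
        table = cls()
        for name, ext in extents.items():
            size = np.ceil(ext * (1.0 + pad_fraction)).astype(int)
            div = np.asarray(divisible_by)
            size = (np.ceil(size / div) * div).astype(int)
            if max_size is not None:
                size = np.minimum(size, max_size)
            table[name] = tuple(int(v) for v in size)
        return table

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) for k, v in self.items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "RoiSizeTable":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls({k: tuple(v) for k, v in d.items()})


@dataclass(frozen=True)
class RoiBox:
    """A fixed-size ROI anchored at a structure's predicted middle point."""

    name: str
    start: IntVec3
    size: IntVec3

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(s, s + n) for s, n in zip(self.start, self.size))

    def contains_index(self, index) -> bool:
        return all(s <= i < s + n for i, s, n in zip(index, self.start, self.size))


class MissingStructure(RuntimeError):
    pass


def localize(step1_network, down_volume: ImageVolume, structure_names: Sequence[str],
             factors: IntVec3):
    """Run the coarse localization network and upmap results.

    Returns ``(indices, missing, anchors)``: for each structure an (N, 3)
    integer array of predicted voxel indices in *full-resolution* index
    space (coarse indices scaled by the downsample factors); the set of
    structures with no predicted voxels (flagged, not fatal); and, when
    the network exposes probabilities, a probability-weighted anchor per
    structure (full-grid index) that is robust to sparse or ragged
    thresholded predictions.
    """
    probs, labels = step1_network.predict(down_volume.data)
    factors = np.asarray(factors, dtype=int)
    indices: Dict[str, np.ndarray] = {}
    missing: Set[str] = set()
    anchors: Dict[str, Tuple[int, int, int]] = {}
    for i, name in enumerate(structure_names):
        if labels.ndim == 4:  # multilabel head: one channel per structure
            coarse = labels[i].astype(bool)
            chan = i
        else:
            coarse = labels == i + 1
            chan = i + 1
        idx = np.argwhere(coarse)
        if idx.size == 0:
            missing.add(name)
        else:
            indices[name] = idx * factors
        if probs is not None:
            # probability-weighted anchor: much more stable than the
            # centroid of a handful of argmax voxels.  Restricted to the
            # dominant probability mass so a faint response at a mirrored
            # structure cannot drag the anchor toward the midline.
            w = np.asarray(probs[chan], dtype=float)
            keep = w >= 0.5 * w.max()
            if keep.any() and w[keep].sum() > 0:
                pts = np.argwhere(keep)
                weights = w[keep]
                c = (pts * weights[:, None]).sum(axis=0) / weights.sum()
                anchors[name] = tuple(int(np.floor(ci * f + 0.5))
                                      for ci, f in zip(c, factors))
    return indices, missing, anchors


def compute_roi(coarse, roi_size, grid_size, name: str = "",
                middle: str = "centroid") -> RoiBox:
    """ROI box around the middle point of a predicted coarse volume.

    ``coarse`` is either a boolean mask or an (N, 3) index array in
    full-resolution index space.  The middle point is the rounded voxel
    centroid (``middle="bbox_center"`` switches to the bounding-box
    center); the box is ``middle - size//2`` and is shifted — never shrunk
    — to lie inside the grid, unless the preset size itself exceeds the
    grid, in which case it is clipped to the grid.
    """
    coarse = np.asarray(coarse)
    idx = np.argwhere(coarse) if coarse.dtype == bool else coarse
    if idx.size == 0:
        raise MissingStructure(
            f"empty coarse mask for {name or 'structure'}: use a fallback box "
            "(e.g. the cohort-mean centroid) or skip the structure")
    if middle == "centroid":
        mid = np.floor(idx.mean(axis=0) + 0.5).astype(int)
    elif middle == "bbox_center":
        mid = ((idx.min(axis=0) + idx.max(axis=0)) // 2).astype(int)
    else:
        raise ValueError(f"unknown middle-point rule {middle!r}")
    grid = np.asarray(grid_size, dtype=int)
    size = np.minimum(np.asarray(roi_size, dtype=int), grid)
    if np.any(size < 1):
        raise ValueError(f"roi size must be >= 1, got {tuple(roi_size)}")
    start = mid - size // 2
    start = np.clip(start, 0, grid - size)
    return RoiBox(name=name, start=tuple(int(v) for v in start),
                  size=tuple(int(v) for v in size))


def segment_roi(step2_network, volume: ImageVolume, box: RoiBox) -> np.ndarray:
    """Full-resolution single-label segmentation inside one ROI box.

    Returns a boolean mask of the box's size.  Networks exposing
    ``predict_roi(volume, box)`` (oracle stubs) are called directly;
    ordinary networks receive the cropped volume.
    """
    grid = volume.shape
    if any(s < 0 or s + n > g for s, n, g in zip(box.start, box.size, grid)):
        raise ValueError(f"box {box} not inside grid {grid}")
    if hasattr(step2_network, "predict_roi"):
        mask = step2_network.predict_roi(volume, box)
    else:
        crop = volume.data[box.slices]
        _, labels = step2_network.predict(crop)
        mask = labels == 1 if labels.ndim == 3 else labels[0].astype(bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != box.size:
        raise ValueError(f"network output {mask.shape} != box size {box.size}")
    return mask


def assemble(box_masks: Mapping[str, Tuple[RoiBox, np.ndarray]], grid_size: IntVec3,
             spacing_mm=(1.0, 1.0, 1.0), origin_mm=(0.0, 0.0, 0.0),
             missing: Iterable[str] = ()) -> Tuple[StructureSet, List[str]]:
    """Paste per-box masks into zeroed full-grid masks.

    Structures listed in ``missing`` get empty masks and a warning record.
    """
    masks: Dict[str, np.ndarray] = {}
    warnings: List[str] = []
    for name, (box, mask) in box_masks.items():
        if name in masks:
            raise ValueError(f"structure {name!r} pasted twice")
        full = np.zeros(grid_size, dtype=bool)
        full[box.slices] = mask
        masks[name] = full
    for name in missing:
        if name in masks:
            raise ValueError(f"structure {name!r} both segmented and missing")
        masks[name] = np.zeros(grid_size, dtype=bool)
        warnings.append(f"structure {name!r} missing from localization; empty mask emitted")
    return StructureSet(masks=masks, spacing_mm=spacing_mm, origin_mm=origin_mm), warnings


def _model_checksum(network) -> str:
    h = hashlib.sha256()
    state = getattr(network, "state_dict", None)
    if state is None:
        return "oracle-stub"
    for k in sorted(state()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(state()[k]).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(volume: ImageVolume, step1_network, step2_networks: Mapping[str, object],
                 preprocess_config: PreprocessConfig, roi_table: RoiSizeTable,
                 structure_names: Optional[Sequence[str]] = None,
                 crop_center: Optional[IntVec3] = None,
                 fallback_centers: Optional[Mapping[str, Sequence[int]]] = None,
                 keep_largest_component: bool = False):
    """Preprocess -> localize -> ROI -> segment -> assemble.

    Returns ``(structures, provenance)`` where ``structures`` is a
    StructureSet on the preprocessed full-resolution grid and
    ``provenance`` records boxes, missing structures and model checksums.
    ``fallback_centers`` optionally maps a structure to a full-grid voxel
    index used as the box anchor when localization finds nothing.
    """
    names = list(structure_names) if structure_names is not None else list(step2_networks)
    pre = preprocess_image(volume, preprocess_config, center=crop_center)
    down = downsample_localization(pre, preprocess_config.localization_downsample)
    factors = preprocess_config.localization_downsample

    indices, missing, soft_anchors = localize(step1_network, down, names, factors)
    box_masks: Dict[str, Tuple[RoiBox, np.ndarray]] = {}
    unresolved: Set[str] = set()
    boxes_record = {}
    for name in names:
        if name in soft_anchors:
            box = compute_roi(np.asarray([soft_anchors[name]]), roi_table[name],
                              pre.shape, name=name)
        elif name in indices:
            box = compute_roi(indices[name], roi_table[name], pre.shape, name=name)
        elif fallback_centers is not None and name in fallback_centers:
            anchor = np.asarray([fallback_centers[name]])
            box = compute_roi(anchor, roi_table[name], pre.shape, name=name)
        else:
            unresolved.add(name)
            continue
        mask = segment_roi(step2_networks[name], pre, box)
        if keep_largest_component and mask.any():
            from scipy import ndimage
            lab, n = ndimage.label(mask)
            if n > 1:
                counts = np.bincount(lab.ravel())[1:]
                mask = lab == (1 + int(counts.argmax()))
        box_masks[name] = (box, mask)
        boxes_record[name] = {"start": list(box.start), "size": list(box.size)}

    structures, warnings = assemble(box_masks, pre.shape, pre.spacing_mm, pre.origin_mm,
                                    missing=unresolved)
    provenance = {
        "boxes": boxes_record,
        "missing": sorted(unresolved),
        "missing_localization": sorted(missing),
        "warnings": warnings,
        "step1_checksum": _model_checksum(step1_network),
        "step2_checksums": {n: _model_checksum(m) for n, m in step2_networks.items()},
        "preprocess": {
            "target_spacing_mm": list(preprocess_config.target_spacing_mm),
            "fov_size_voxels": list(preprocess_config.fov_size_voxels),
            "hu_window": list(preprocess_config.hu_window),
            "localization_downsample": list(preprocess_config.localization_downsample),
        },
    }
    return structures, provenance
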