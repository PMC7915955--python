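"""Ground-truth lookup stubs with the network `predict` interface.

These stand-ins replace trained networks in pipeline plumbing tests: with
both steps replaced by oracles the two-step pipeline must reproduce the
ground-truth labels exactly, which isolates preprocessing, ROI and
assembly errors from model error.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .grids import ImageVolume, StructureSet
from .preprocess import PreprocessConfig, downsample_localization, preprocess_labels


class OracleStep1:
    """Localization stub: returns a fixed coarse label map, ignores input."""

    def __init__(self, label_map: np.ndarray):
        self.label_map = np.asarray(label_map)

    def predict(self, x):
        if self.label_map.shape != np.asarray(x).shape[-3:]:
            raise ValueError(
                f"oracle label map {self.label_map.shape} does not match "
                f"input grid {np.asarray(x).shape[-3:]}")
        return None, self.label_map

    @classmethod
    def from_labels(cls, labels: StructureSet, config: PreprocessConfig,
                    order: Sequence[str]) -> "OracleStep1":
        """Majority-vote downsample the true masks onto the coarse grid."""
        coarse = {}
        for name in order:
            vol = ImageVolume(labels[name].astype(float), labels.spacing_mm, labels.origin_mm)
            coarse[name] = downsample_localization(
                vol, config.localization_downsample, kind="mask").data
        ss = StructureSet(masks=coarse)
        return cls(ss.label_map(order=order))


class OracleStep2:
    """ROI stub: returns the true full-resolution mask cropped at the box."""

    def __init__(self, full_mask: np.ndarray):
        self.full_mask = np.asarray(full_mask).astype(bool)

    def predict_roi(self, volume, box):
        return self.full_mask[box.slices]


def oracle_networks(raw_labels: StructureSet, config: PreprocessConfig,
                    order: Sequence[str], crop_center=None):
    """Build (step1, step2 dict) oracles from *raw* ground-truth labels.

    Labels are run through the same preprocessing chain the image takes, so
    the oracles live on the pipeline's grids.
    """
    pre = preprocess_labels(raw_labels, config, center=crop_center)
    step1 = OracleStep1.from_labels(pre, config, order)
    step2 = {name: OracleStep2(pre[name]) for name in order}
    return step1, step2, pre
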