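"""Contour agreement metrics: overlap (DSC, FPD, FND) and surface distance
(HD95, MSD) between a computer contour C and a manual/reference contour M.

Definitions, with |.| counting voxels:

    DSC = 2|C ∩ M| / (|C| + |M|)
    FPD = 2|C \\ M| / (|C| + |M|)      (false-positive Dice)
    FND = 2|M \\ C| / (|C| + |M|)      (false-negative Dice)

so that 2·DSC + FPD + FND = 2 identically for any non-empty pair.
Distances are Euclidean in physical millimeters between surface voxels
(foreground voxels with a face-adjacent background or out-of-grid
neighbor); HD95 is the 95th percentile of the pooled bidirectional
distance vector and MSD the average of the two directed means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import StructureSet

METRIC_COLUMNS = ["DSC", "FPD", "FND", "HD95_mm", "MSD_mm"]


@dataclass
class MaskPair:
    """Computer contour ``C`` vs reference contour ``M`` on one grid."""

    C: np.ndarray
    M: np.ndarray
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C).astype(bool)
        self.M = np.asarray(self.M).astype(bool)
        if self.C.shape != self.M.shape:
            raise ValueError(f"grid mismatch: C {self.C.shape} vs M {self.M.shape}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")


def _counts(pair: MaskPair) -> Tuple[int, int, int]:
    inter = int(np.count_nonzero(pair.C & pair.M))
    nc = int(np.count_nonzero(pair.C))
    nm = int(np.count_nonzero(pair.M))
    return inter, nc, nm


def dsc(pair: MaskPair) -> float:
    """Volumetric Dice similarity coefficient."""
    inter, nc, nm = _counts(pair)
    if nc + nm == 0:
        raise ValueError("DSC undefined: both masks empty")
    return 2.0 * inter / (nc + nm)


def fpd_fnd(pair: MaskPair) -> Tuple[float, float]:
    """False-positive and false-negative Dice (over-/under-segmentation)."""
    inter, nc, nm = _counts(pair)
    if nc + nm == 0:
        raise ValueError("FPD/FND undefined: both masks empty")
    fpd = 2.0 * (nc - inter) / (nc + nm)
    fnd = 2.0 * (nm - inter) / (nc + nm)
    return fpd, fnd


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Surface voxels: foreground with a 6-connected background neighbor.

    The grid edge counts as background, so a mask touching the border has
    surface there.
    """
    mask = np.asarray(mask).astype(bool)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def surface_distances(pair: MaskPair) -> Tuple[np.ndarray, np.ndarray]:
    """Directed surface-distance vectors (C→M, M→C) in millimeters.

    One distance per surface voxel, in C-order of the voxel grid
    (order-stable).  Computed with an exact Euclidean distance transform of
    the opposing surface, so each value is the distance to the *nearest
    surface voxel* of the other mask.
    """
    for name, m in (("C", pair.C), ("M", pair.M)):
        if not m.any():
            raise ValueError(f"surface distances undefined: mask {name} is empty")
    surf_c = surface_mask(pair.C)
    surf_m = surface_mask(pair.M)
    dt_to_m = ndimage.distance_transform_edt(~surf_m, sampling=pair.spacing_mm)
    dt_to_c = ndimage.distance_transform_edt(~surf_c, sampling=pair.spacing_mm)
    return dt_to_m[surf_c], dt_to_c[surf_m]


def hd95(pair: MaskPair, percentile: float = 95.0, method: str = "linear") -> float:
    """Robust Hausdorff distance: percentile of the pooled distance vector.

    ``method="linear"`` interpolates between order statistics (numpy's
    default convention, R type 7); ``method="weibull"`` uses the R type 6
    convention some medical-imaging toolkits prefer; ``method="nearest"``
    uses nearest-rank.
    """
    d_cm, d_mc = surface_distances(pair)
    pooled = np.concatenate([d_cm, d_mc])
    interp = {"linear": "linear", "weibull": "weibull", "nearest": "nearest"}[method]
    return float(np.percentile(pooled, percentile, method=interp))


def msd(pair: MaskPair) -> float:
    """Mean surface distance: half the sum of the two directed means."""
    d_cm, d_mc = surface_distances(pair)
    return float(0.5 * (d_cm.mean() + d_mc.mean()))


def all_metrics(pair: MaskPair) -> Dict[str, float]:
    """DSC/FPD/FND always; distance metrics NaN when either mask is empty
    (one-sided empties give DSC 0 by convention)."""
    inter, nc, nm = _counts(pair)
    if nc + nm == 0:
        raise ValueError("metrics undefined: both masks empty")
    out = {"DSC": 2.0 * inter / (nc + nm)}
    out["FPD"], out["FND"] = fpd_fnd(pair)
    if nc > 0 and nm > 0:
        d_cm, d_mc = surface_distances(pair)
        pooled = np.concatenate([d_cm, d_mc])
        out["HD95_mm"] = float(np.percentile(pooled, 95.0))
        out["MSD_mm"] = float(0.5 * (d_cm.mean() + d_mc.mean()))
    else:
        out["HD95_mm"] = np.nan
        out["MSD_mm"] = np.nan
    return out


def evaluate(predicted: StructureSet, reference: StructureSet,
             method: str = "method", subject: str = "subject",
             groups: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Per-structure metric rows for one subject.

    Structures present in the reference but missing (empty) in the
    prediction get ``status='missing'`` with NaN distance metrics; they are
    excluded from summaries by :func:`summarize`.
    """
    rows = []
    for name in reference.names:
        ref = reference[name]
        pred = predicted.masks.get(name, np.zeros_like(ref))
        row = {"subject": subject, "structure": name,
               "group": (groups or {}).get(name, ""), "method": method}
        if not ref.any() and not pred.any():
            row.update({c: np.nan for c in METRIC_COLUMNS})
            row["status"] = "both_empty"
        else:
            row.update(all_metrics(MaskPair(pred, ref, reference.spacing_mm)))
            row["status"] = "ok" if pred.any() else "missing"
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame, by=("method", "group")) -> pd.DataFrame:
    """Mean ± SD summary rows over valid ('ok') rows."""
    ok = report[report["status"] == "ok"]
    agg = ok.groupby(list(by))[METRIC_COLUMNS].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()
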