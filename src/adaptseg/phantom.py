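"""Synthetic paired planning/adaptive head-phantom generator.

Real adaptive-radiotherapy cohorts pair an initial planning CT (pCT) with a
mid-course adaptive CT (aCT) of the same patient.  The dominant anatomy
change over that interval is glandular: parotid and submandibular analogs
lose about 10% of their volume while central, bony and optic structures
keep their volume and move only slightly.  This module generates cohorts of
such pairs from parametric primitives (ellipsoids, tubes, boxes) with
group-level HU statistics, so the whole segmentation/evaluation stack is
testable without patient data.

Anatomical realism is limited to group-level size, HU contrast, placement
variability and the volume-change model; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .grids import ImageVolume, StructureSet, save_mask, save_volume

GROUPS = ("central", "bony", "glandular", "optic")
SHAPES = ("ellipsoid", "tube", "box")


@dataclass
class StructureSpec:
    """One organ analog: shape family, size/placement ranges, HU statistics.

    ``semiaxes_mm`` are (low, high) sampling ranges per axis: ellipsoid
    semi-axes, tube (radius_x, radius_y, half-length_z), or box half-widths.
    ``center_frac`` are (low, high) ranges for the center as a fraction of
    the physical grid extent per axis.
    """

    name: str
    shape: str
    group: str
    mean_hu: float
    hu_sd: float
    semiaxes_mm: Tuple[Tuple[float, float], ...]
    center_frac: Tuple[Tuple[float, float], ...]
    # two-compartment option: a clearly visible core occupying a per-subject
    # random fraction of the structure, with the outer rim at the (faint)
    # structure HU.  Models glands whose parenchyma is visible on CT while
    # the true contoured boundary extends into near-isodense tissue.
    core_frac_range: Optional[Tuple[float, float]] = None
    core_delta_hu: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"{self.name}: unknown shape {self.shape!r}")
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")


@dataclass
class AnatomyConfig:
    """Phantom geometry, contrast and noise configuration."""

    structure_specs: List[StructureSpec]
    image_size: Tuple[int, int, int] = (64, 64, 16)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 3.0)
    noise_sd: float = 15.0
    background_hu: float = -50.0
    min_gap_mm: float = 4.0
    max_retries: int = 200
    max_layout_attempts: int = 20

    def __post_init__(self) -> None:
        names = [s.name for s in self.structure_specs]
        if len(names) != len(set(names)):
            raise ValueError("structure names must be unique")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        extent = self.extent_mm
        for spec in self.structure_specs:
            max_semi = [hi for (_, hi) in spec.semiaxes_mm]
            if any(2 * (a + self.min_gap_mm) > e for a, e in zip(max_semi, extent)):
                raise ValueError(
                    f"structure {spec.name!r} cannot fit inside the image "
                    f"extent {extent} mm with gap {self.min_gap_mm} mm"
                )

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.image_size, self.spacing_mm))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnatomyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["structure_specs"] = [
            StructureSpec(
                **{**s,
                   "semiaxes_mm": tuple(tuple(r) for r in s["semiaxes_mm"]),
                   "center_frac": tuple(tuple(r) for r in s["center_frac"]),
                   "core_frac_range": (tuple(s["core_frac_range"])
                                       if s.get("core_frac_range") else None)}
            )
            for s in d["structure_specs"]
        ]
        for key in ("image_size", "spacing_mm"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class StructureTruth:
    """Analytic ground truth for one placed structure."""

    name: str
    shape: str
    group: str
    center_mm: np.ndarray
    semiaxes_mm: np.ndarray
    hu: float
    shrink_fraction: float = 0.0
    core_frac: float = 0.0  # 0 -> single-compartment structure
    core_delta_hu: float = 0.0


@dataclass
class SubjectPhantom:
    """One synthetic subject: paired planning/adaptive volume + labels."""

    subject_id: str
    config: AnatomyConfig
    planning_volume: ImageVolume
    planning_labels: StructureSet
    planning_truth: Dict[str, StructureTruth]
    adaptive_volume: Optional[ImageVolume] = None
    adaptive_labels: Optional[StructureSet] = None
    adaptive_truth: Optional[Dict[str, StructureTruth]] = None

    @property
    def has_adaptive(self) -> bool:
        return self.adaptive_volume is not None


# ---------------------------------------------------------------------------
# default anatomy catalog

_CATALOG = [
    # name, shape, group, mean_hu, hu_sd, semiaxes ranges mm, center fracs
    ("cord", "tube", "central", 40.0, 5.0,
     ((3.0, 4.0), (3.0, 4.0), (14.0, 18.0)),
     ((0.46, 0.54), (0.62, 0.72), (0.45, 0.55))),
    ("mandible", "box", "bony", 700.0, 60.0,
     ((9.0, 12.0), (4.0, 6.0), (4.0, 6.0)),
     ((0.42, 0.58), (0.20, 0.32), (0.62, 0.78))),
    # glandular analogs: the most variable placement/size and a partly
    # invisible boundary.  The parenchymal core is clearly visible but the
    # true contour extends into a faint rim (near-isodense with
    # background) whose per-subject thickness cannot be read off the
    # image — mirroring gland boundaries on CT, where contouring relies on
    # patient-specific anatomy.  This is what makes subject-specific
    # (continual) training pay off for the glandular group.
    ("parotid_l", "ellipsoid", "glandular", -38.0, 4.0,
     ((5.0, 8.0), (6.0, 9.0), (7.0, 11.0)),
     ((0.14, 0.32), (0.35, 0.62), (0.30, 0.62)),
     (0.45, 0.75), 50.0),
    ("parotid_r", "ellipsoid", "glandular", -38.0, 4.0,
     ((5.0, 8.0), (6.0, 9.0), (7.0, 11.0)),
     ((0.68, 0.86), (0.35, 0.62), (0.30, 0.62)),
     (0.45, 0.75), 50.0),
    ("brainstem", "ellipsoid", "central", 38.0, 4.0,
     ((4.0, 6.0), (4.0, 6.0), (6.0, 9.0)),
     ((0.44, 0.56), (0.42, 0.52), (0.26, 0.40))),
    ("eye_l", "ellipsoid", "optic", 30.0, 5.0,
     ((4.0, 5.0), (4.0, 5.0), (4.0, 5.5)),
     ((0.22, 0.34), (0.12, 0.22), (0.22, 0.36))),
    ("eye_r", "ellipsoid", "optic", 30.0, 5.0,
     ((4.0, 5.0), (4.0, 5.0), (4.0, 5.5)),
     ((0.66, 0.78), (0.12, 0.22), (0.22, 0.36))),
    ("smg_l", "ellipsoid", "glandular", -35.0, 4.0,
     ((4.0, 6.0), (4.0, 6.0), (5.0, 8.0)),
     ((0.28, 0.42), (0.70, 0.84), (0.66, 0.84)),
     (0.45, 0.75), 45.0),
    ("smg_r", "ellipsoid", "glandular", -35.0, 4.0,
     ((4.0, 6.0), (4.0, 6.0), (5.0, 8.0)),
     ((0.58, 0.72), (0.70, 0.84), (0.66, 0.84)),
     (0.45, 0.75), 45.0),
    ("thyroid", "ellipsoid", "glandular", 70.0, 10.0,
     ((5.0, 7.0), (4.0, 5.5), (5.0, 7.0)),
     ((0.42, 0.58), (0.80, 0.90), (0.78, 0.90))),
]


def default_anatomy(n_structures: int = 6, image_size=(64, 64, 16),
                    spacing_mm=(1.0, 1.0, 3.0), noise_sd: float = 15.0,
                    **kwargs) -> AnatomyConfig:
    """Head-analog anatomy with ``n_structures`` organ analogs (4..10).

    The first six analogs cover all four organ groups (central, bony,
    glandular, optic); glandular analogs have the largest inter-subject
    placement and size variability, mirroring parotid/submandibular
    variability in real cohorts.
    """
    if not 2 <= n_structures <= len(_CATALOG):
        raise ValueError(f"n_structures must be in [2, {len(_CATALOG)}]")
    specs = [StructureSpec(*entry) for entry in _CATALOG[:n_structures]]
    return AnatomyConfig(structure_specs=specs, image_size=tuple(image_size),
                         spacing_mm=tuple(spacing_mm), noise_sd=noise_sd, **kwargs)


def anatomy_by_names(names, image_size=(64, 64, 16), spacing_mm=(1.0, 1.0, 3.0),
                     noise_sd: float = 15.0, **kwargs) -> AnatomyConfig:
    """Anatomy with a specific subset of catalog analogs, by name."""
    catalog = {c[0]: c for c in _CATALOG}
    unknown = [n for n in names if n not in catalog]
    if unknown:
        raise ValueError(f"unknown structure analogs {unknown}; available: {sorted(catalog)}")
    specs = [StructureSpec(*catalog[n]) for n in names]
    return AnatomyConfig(structure_specs=specs, image_size=tuple(image_size),
                         spacing_mm=tuple(spacing_mm), noise_sd=noise_sd, **kwargs)


# ---------------------------------------------------------------------------
# rasterization

def _voxel_centers(config: AnatomyConfig):
    grids = [np.arange(n) * s for n, s in zip(config.image_size, config.spacing_mm)]
    return np.meshgrid(*grids, indexing="ij", sparse=True)


def rasterize(shape: str, center_mm, semiaxes_mm, config: AnatomyConfig) -> np.ndarray:
    """Binary mask of voxel centers inside the analytic shape."""
    X, Y, Z = _voxel_centers(config)
    cx, cy, cz = center_mm
    ax, ay, az = semiaxes_mm
    if shape == "ellipsoid":
        return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0
    if shape == "tube":
        radial = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 <= 1.0
        return radial & (np.abs(Z - cz) <= az)
    if shape == "box":
        return (np.abs(X - cx) <= ax) & (np.abs(Y - cy) <= ay) & (np.abs(Z - cz) <= az)
    raise ValueError(f"unknown shape {shape!r}")


def _render_image(config: AnatomyConfig, truths: Dict[str, StructureTruth],
                  masks: Dict[str, np.ndarray], rng: np.random.Generator) -> np.ndarray:
    img = np.full(config.image_size, config.background_hu, dtype=float)
    for name, t in truths.items():
        img[masks[name]] = t.hu
        if t.core_frac > 0:
            core = rasterize(t.shape, t.center_mm, t.semiaxes_mm * t.core_frac, config)
            img[core] = t.hu + t.core_delta_hu
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=config.image_size)
    return img


# ---------------------------------------------------------------------------
# generation

class PlacementError(RuntimeError):
    pass


def generate_subject(config: AnatomyConfig, seed: int,
                     subject_id: Optional[str] = None) -> SubjectPhantom:
    """Generate the planning half of a subject phantom, deterministically.

    Structures are placed in spec order; a candidate that would overlap a
    previously placed structure (with a safety gap of ``min_gap_mm``) or
    stick out of the grid is re-sampled, up to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(config.extent_mm)

    def try_layout():
        masks: Dict[str, np.ndarray] = {}
        truths: Dict[str, StructureTruth] = {}
        occupied = np.zeros(config.image_size, dtype=bool)
        for spec in config.structure_specs:
            placed = False
            for _ in range(config.max_retries):
                semi = np.array([rng.uniform(lo, hi) for lo, hi in spec.semiaxes_mm])
                center = np.array([rng.uniform(lo, hi) for lo, hi in spec.center_frac]) * extent
                margin = semi + config.min_gap_mm
                if np.any(center - margin < 0) or np.any(center + margin > extent):
                    continue
                # occupancy test inflates the candidate by the gap so
                # structures stay min_gap_mm apart and adaptive
                # displacements (bounded well below the gap) cannot overlap
                guard = rasterize(spec.shape, center, semi + config.min_gap_mm, config)
                if (guard & occupied).any():
                    continue
                mask = rasterize(spec.shape, center, semi, config)
                if not mask.any():
                    continue
                masks[spec.name] = mask
                occupied |= mask
                hu = spec.mean_hu + (rng.normal(0.0, spec.hu_sd) if spec.hu_sd > 0 else 0.0)
                core_frac = 0.0
                if spec.core_frac_range is not None:
                    core_frac = float(rng.uniform(*spec.core_frac_range))
                truths[spec.name] = StructureTruth(
                    name=spec.name, shape=spec.shape, group=spec.group,
                    center_mm=center, semiaxes_mm=semi, hu=float(hu),
                    core_frac=core_frac, core_delta_hu=spec.core_delta_hu)
                placed = True
                break
            if not placed:
                return None, spec.name
        return (masks, truths), None

    failed = ""
    for _ in range(config.max_layout_attempts):
        layout, failed = try_layout()
        if layout is not None:
            break
    else:
        raise PlacementError(
            f"could not place structure {failed!r} after "
            f"{config.max_layout_attempts} layout attempts of "
            f"{config.max_retries} retries each (grid too crowded)")
    masks, truths = layout

    img = _render_image(config, truths, masks, rng)
    sid = subject_id or f"subj{seed:08d}"
    return SubjectPhantom(
        subject_id=sid, config=config,
        planning_volume=ImageVolume(img, config.spacing_mm),
        planning_labels=StructureSet(masks=masks, spacing_mm=config.spacing_mm),
        planning_truth=truths,
    )


def derive_adaptive(subject: SubjectPhantom,
                    shrink_fraction=None,
                    deform_amplitude_mm: float = 2.0,
                    seed: int = 0) -> SubjectPhantom:
    """Populate the adaptive half: glandular shrink + small displacement.

    ``shrink_fraction`` maps group tag -> fractional volume loss (default
    ``{"glandular": 0.10}``, all other groups 0).  Shrink is an isotropic
    radial rescale of the analytic shape about its center (factor
    ``(1-s)^(1/3)`` on every semi-axis), then re-rasterization.  Structures
    in non-shrinking groups are displaced by a smooth random field — a
    shared rigid shift plus a low-frequency sinusoidal warp evaluated at
    the structure center — with total amplitude clamped to
    ``deform_amplitude_mm`` and then snapped to whole voxels (so the
    rasterized mask translates rigidly and its voxel volume is preserved
    exactly; the snap may round a component up to the nearest voxel
    pitch).  A fresh noise realization is drawn for the adaptive image.
    """
    if shrink_fraction is None:
        shrink_fraction = {"glandular": 0.10}
    if isinstance(shrink_fraction, (int, float)):
        shrink_fraction = {"glandular": float(shrink_fraction)}
    for g, s in shrink_fraction.items():
        if not 0.0 <= s < 1.0:
            raise ValueError(f"shrink fraction for group {g!r} must be in [0, 1), got {s}")

    config = subject.config
    rng = np.random.default_rng(seed)
    extent = np.asarray(config.extent_mm)

    # shared smooth displacement field: rigid + one sinusoidal mode
    amp = float(deform_amplitude_mm)
    rigid = rng.uniform(-amp / 2, amp / 2, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    wavelength = np.maximum(extent, 1.0)

    spacing = np.asarray(config.spacing_mm)

    def displacement(center_mm: np.ndarray) -> np.ndarray:
        if amp == 0:
            return np.zeros(3)
        wave = (amp / 2) * np.sin(2 * np.pi * center_mm / wavelength + phase)
        d = rigid + wave
        norm = np.linalg.norm(d)
        if norm > amp:
            d = d * (amp / norm)
        # snap to whole voxels: the rasterization pattern then translates
        # rigidly, so displaced structures keep their voxel volume exactly
        # (sub-voxel inter-scan motion is not resolvable on the grid anyway)
        return np.round(d / spacing) * spacing

    masks: Dict[str, np.ndarray] = {}
    truths: Dict[str, StructureTruth] = {}
    for name, t in subject.planning_truth.items():
        s = float(shrink_fraction.get(t.group, 0.0))
        semi = t.semiaxes_mm * (1.0 - s) ** (1.0 / 3.0)
        center = t.center_mm.copy()
        if s == 0.0:
            center = np.clip(center + displacement(t.center_mm),
                             semi, extent - semi)
        mask = rasterize(t.shape, center, semi, config)
        if not mask.any():
            raise ValueError(
                f"structure {name!r} vanished after shrink fraction {s} "
                "(shape smaller than one voxel)")
        masks[name] = mask
        truths[name] = StructureTruth(name=name, shape=t.shape, group=t.group,
                                      center_mm=center, semiaxes_mm=semi,
                                      hu=t.hu, shrink_fraction=s,
                                      core_frac=t.core_frac,
                                      core_delta_hu=t.core_delta_hu)

    # disjointness audit (placement gap should guarantee this)
    union = np.zeros(config.image_size, dtype=bool)
    for name, m in masks.items():
        if (m & union).any():
            raise RuntimeError(f"adaptive displacement made {name!r} overlap a neighbor")
        union |= m

    img = _render_image(config, truths, masks, rng)
    return dataclasses.replace(
        subject,
        adaptive_volume=ImageVolume(img, config.spacing_mm),
        adaptive_labels=StructureSet(masks=masks, spacing_mm=config.spacing_mm),
        adaptive_truth=truths,
    )


def generate_cohort(n_subjects: int, config: AnatomyConfig, seed: int,
                    shrink_fraction=None, deform_amplitude_mm: float = 2.0,
                    out_dir=None, overwrite: bool = False):
    """Generate ``n_subjects`` paired phantoms; optionally write to disk.

    Returns ``(subjects, manifest)`` where the manifest is a DataFrame with
    one row per scan (subject_id, role in {planning, adaptive}, image_path,
    mask_dir; paths empty when not written).  Subject seeds derive
    deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=2 * n_subjects)

    subjects = []
    for i in range(n_subjects):
        subj = generate_subject(config, int(subject_seeds[2 * i]), subject_id=f"subj{i:03d}")
        subj = derive_adaptive(subj, shrink_fraction=shrink_fraction,
                               deform_amplitude_mm=deform_amplitude_mm,
                               seed=int(subject_seeds[2 * i + 1]))
        subjects.append(subj)

    rows = []
    base = Path(out_dir) if out_dir is not None else None
    if base is not None:
        if base.exists() and any(base.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {base} exists; pass overwrite=True")
        base.mkdir(parents=True, exist_ok=True)
        config.to_yaml(base / "anatomy.yaml")

    for subj in subjects:
        for role in ("planning", "adaptive"):
            vol = subj.planning_volume if role == "planning" else subj.adaptive_volume
            labels = subj.planning_labels if role == "planning" else subj.adaptive_labels
            image_path, mask_dir = "", ""
            if base is not None:
                sdir = base / subj.subject_id / role
                (sdir / "masks").mkdir(parents=True, exist_ok=True)
                image_path = str(sdir / "image.nii.gz")
                mask_dir = str(sdir / "masks")
                save_volume(vol, image_path)
                for name, m in labels.masks.items():
                    save_mask(m, vol.spacing_mm, vol.origin_mm, Path(mask_dir) / f"{name}.nii.gz")
            rows.append({"subject_id": subj.subject_id, "role": role,
                         "image_path": image_path, "mask_dir": mask_dir})
    manifest = pd.DataFrame(rows)
    if base is not None:
        manifest.to_csv(base / "manifest.csv", index=False)
    return subjects, manifest
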