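"""Matched (continual) vs unmatched (conventional) training protocols.

The matched protocol trains on the planning scans of the shared training
subjects *plus the test subjects' own planning scans* — deliberate
patient-specific overfitting, which is legitimate in adaptive radiotherapy
because each test subject's prior planning scan exists before their
adaptive scan needs contouring.  The unmatched protocol replaces the test
subjects' planning scans with planning scans of extra, disjoint subjects,
so both training sets always have the same size.  Test evaluation is
always on the *adaptive* scans of the test subjects, which never appear in
any training set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grids import ImageVolume, StructureSet
from .metrics import evaluate
from .nn.densenet import FCDenseNet3D, NetworkConfig, build_network
from .nn.train import TrainConfig, train
from .preprocess import (PreprocessConfig, downsample_localization,
                         preprocess_image, preprocess_labels)
from .two_step import RoiSizeTable, compute_roi, run_pipeline


@dataclass
class SplitPlan:
    """Assignment of cohort subjects to test / shared-train / extra-train."""

    test_subjects: Tuple[str, ...]
    shared_train_subjects: Tuple[str, ...]
    extra_train_subjects: Tuple[str, ...]
    mode: str  # "matched" | "unmatched"

    def __post_init__(self) -> None:
        self.test_subjects = tuple(self.test_subjects)
        self.shared_train_subjects = tuple(self.shared_train_subjects)
        self.extra_train_subjects = tuple(self.extra_train_subjects)
        if self.mode not in ("matched", "unmatched"):
            raise ValueError(f"mode must be matched|unmatched, got {self.mode!r}")
        t, s, e = map(set, (self.test_subjects, self.shared_train_subjects,
                            self.extra_train_subjects))
        if (t & s) or (t & e) or (s & e):
            raise ValueError("test/shared/extra subject sets must be disjoint")
        if self.mode == "unmatched" and len(self.extra_train_subjects) != len(self.test_subjects):
            raise ValueError(
                "unmatched mode needs as many extra subjects as test subjects "
                "so training-set sizes match")

    @property
    def train_subjects(self) -> Tuple[str, ...]:
        if self.mode == "matched":
            return self.shared_train_subjects + self.test_subjects
        return self.shared_train_subjects + self.extra_train_subjects

    def to_json(self, path=None) -> str:
        s = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            return cls(**json.load(fh))


def allocate_splits(manifest: pd.DataFrame, n_test: int, n_shared: int, n_extra: int,
                    seed: int) -> Tuple[SplitPlan, SplitPlan]:
    """Random disjoint test/shared/extra assignment; returns the matched and
    unmatched plans, which share identical test and shared sets.

    Every subject must have both a planning and an adaptive scan.
    """
    if n_extra != n_test:
        raise ValueError(
            f"n_extra ({n_extra}) must equal n_test ({n_test}) for "
            "size-matched training sets")
    counts = manifest.groupby("subject_id")["role"].agg(lambda r: set(r))
    incomplete = [s for s, roles in counts.items() if {"planning", "adaptive"} - roles]
    if incomplete:
        raise ValueError(f"subjects missing a scan role: {incomplete}")
    ids = sorted(counts.index)
    need = n_test + n_shared + n_extra
    if len(ids) < need:
        raise ValueError(f"cohort has {len(ids)} subjects; need {need} "
                         f"({n_test} test + {n_shared} shared + {n_extra} extra)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    test = tuple(perm[:n_test])
    shared = tuple(perm[n_test:n_test + n_shared])
    extra = tuple(perm[n_test + n_shared:need])
    return (SplitPlan(test, shared, extra, "matched"),
            SplitPlan(test, shared, extra, "unmatched"))


def audit_no_leakage(plan: SplitPlan, manifest: pd.DataFrame) -> None:
    """Assert that no test adaptive scan appears in the training manifest."""
    train_df = training_manifest(plan, manifest)
    test_adaptive = manifest[(manifest["subject_id"].isin(plan.test_subjects))
                             & (manifest["role"] == "adaptive")]
    leaked = set(train_df["image_path"]) & set(test_adaptive["image_path"])
    leaked |= {(s, r) for s, r in zip(train_df["subject_id"], train_df["role"])
               if r == "adaptive"}
    if leaked:
        raise AssertionError(f"test/adaptive scans leaked into training: {leaked}")


def training_manifest(plan: SplitPlan, manifest: pd.DataFrame) -> pd.DataFrame:
    """Planning-scan rows of the plan's training subjects."""
    return manifest[(manifest["subject_id"].isin(plan.train_subjects))
                    & (manifest["role"] == "planning")].reset_index(drop=True)


# ---------------------------------------------------------------------------
# protocol execution

@dataclass
class ProtocolConfig:
    """Everything a protocol run needs besides the data and the plan."""

    preprocess: PreprocessConfig
    step1_network: NetworkConfig
    step2_network: NetworkConfig
    train: TrainConfig
    roi_pad_fraction: float = 0.25
    seed: int = 0


def _structure_order(labels: StructureSet) -> List[str]:
    return list(labels.names)


def step1_sample(image: ImageVolume, labels: StructureSet, cfg: PreprocessConfig,
                 order: Sequence[str], crop_center=None):
    """(downsampled input, coarse label map) for localization training."""
    pre = preprocess_image(image, cfg, center=crop_center)
    down = downsample_localization(pre, cfg.localization_downsample)
    pre_labels = preprocess_labels(labels, cfg, center=crop_center)
    coarse = {
        name: downsample_localization(
            ImageVolume(pre_labels[name].astype(float), pre_labels.spacing_mm),
            cfg.localization_downsample, kind="mask").data
        for name in order
    }
    label_map = StructureSet(masks=coarse).label_map(order=order)
    return down.data.astype(np.float32), label_map


def step2_samples(image: ImageVolume, labels: StructureSet, cfg: PreprocessConfig,
                  roi_table: RoiSizeTable, order: Sequence[str], crop_center=None):
    """Per-structure (ROI crop, binary target) pairs at full resolution,
    boxed around the true structure centroid (training-time anchoring)."""
    pre = preprocess_image(image, cfg, center=crop_center)
    pre_labels = preprocess_labels(labels, cfg, center=crop_center)
    out = {}
    for name in order:
        mask = pre_labels[name]
        if not mask.any():
            continue
        box = compute_roi(mask, roi_table[name], pre.shape, name=name)
        out[name] = (pre.data[box.slices].astype(np.float32),
                     mask[box.slices].astype(np.int64))
    return out


def run_protocol(plan: SplitPlan, subjects: Mapping[str, object],
                 config: ProtocolConfig, oracle: bool = False):
    """Train step-1 and step-2 models per the plan, evaluate on the test
    subjects' adaptive scans.

    ``subjects`` maps subject id to an object with ``planning_volume``,
    ``planning_labels``, ``adaptive_volume``, ``adaptive_labels`` (e.g. a
    :class:`~adaptseg.phantom.SubjectPhantom`).  Returns
    ``(models, report)`` where ``models`` holds the trained step-1 network,
    per-structure step-2 networks and the ROI size table, and ``report``
    is the per-(subject, structure) MetricsReport DataFrame.

    With ``oracle=True`` training is skipped and ground-truth stub
    networks stand in for both steps (a plumbing check: the report must
    then show DSC 1.0 everywhere).
    """
    missing = [s for s in plan.train_subjects + plan.test_subjects if s not in subjects]
    if missing:
        raise FileNotFoundError(f"subjects missing from cohort: {missing}")
    for sid in plan.test_subjects:
        if getattr(subjects[sid], "adaptive_volume", None) is None:
            raise FileNotFoundError(f"test subject {sid} has no adaptive scan")

    pcfg = config.preprocess
    first = subjects[plan.train_subjects[0]]
    order = _structure_order(first.planning_labels)
    groups = {}
    truth = getattr(first, "planning_truth", None)
    if truth:
        groups = {name: t.group for name, t in truth.items()}

    if oracle:
        from .oracles import oracle_networks
        train_labels = [preprocess_labels(subjects[sid].planning_labels, pcfg)
                        for sid in plan.train_subjects]
        roi_table = RoiSizeTable.from_labels(train_labels,
                                             pad_fraction=config.roi_pad_fraction,
                                             max_size=pcfg.fov_size_voxels)
        reports = []
        for sid in plan.test_subjects:
            subj = subjects[sid]
            step1, step2, ref = oracle_networks(subj.adaptive_labels, pcfg, order)
            pred, _ = run_pipeline(subj.adaptive_volume, step1, step2, pcfg,
                                   roi_table, structure_names=order)
            reports.append(evaluate(pred, ref, method=plan.mode, subject=sid,
                                    groups=groups))
        models = {"step1": None, "step2": None, "roi_table": roi_table,
                  "order": order, "histories": {}}
        return models, pd.concat(reports, ignore_index=True)

    # ---- step 1: coarse localization, multiclass over structures+background
    s1_samples = [
        step1_sample(subjects[sid].planning_volume, subjects[sid].planning_labels,
                     pcfg, order)
        for sid in plan.train_subjects
    ]
    net1_cfg = dataclasses.replace(config.step1_network, in_channels=1,
                                   out_channels=len(order) + 1, mode="single_label")
    rng = np.random.default_rng(config.seed)
    net1 = build_network(net1_cfg, seed=int(rng.integers(2**31 - 1)))
    tcfg = dataclasses.replace(config.train, seed=int(rng.integers(2**31 - 1)))
    net1, hist1 = train(net1, s1_samples, tcfg, epochs=config.train.epochs_step1)

    # ---- ROI size table from training labels (bbox maxima + padding)
    train_labels = [preprocess_labels(subjects[sid].planning_labels, pcfg)
                    for sid in plan.train_subjects]
    roi_table = RoiSizeTable.from_labels(
        train_labels, pad_fraction=config.roi_pad_fraction,
        divisible_by=config.step2_network.total_downsampling,
        max_size=pcfg.fov_size_voxels)

    # cohort-mean centroid fallback for structures the localizer misses
    fallback = {}
    for name in order:
        cents = [np.argwhere(ls[name]).mean(axis=0) for ls in train_labels if ls[name].any()]
        if cents:
            fallback[name] = tuple(int(v) for v in np.floor(np.mean(cents, axis=0) + 0.5))

    # ---- step 2: one single-label network per structure
    per_struct: Dict[str, List] = {name: [] for name in order}
    for sid in plan.train_subjects:
        crops = step2_samples(subjects[sid].planning_volume, subjects[sid].planning_labels,
                              pcfg, roi_table, order)
        for name, sample in crops.items():
            per_struct[name].append(sample)
    net2_cfg = dataclasses.replace(config.step2_network, in_channels=1,
                                   out_channels=2, mode="single_label")
    step2_nets: Dict[str, FCDenseNet3D] = {}
    histories = {"step1": hist1}
    for name in order:
        net = build_network(net2_cfg, seed=int(rng.integers(2**31 - 1)))
        t2 = dataclasses.replace(config.train, seed=int(rng.integers(2**31 - 1)))
        net, hist = train(net, per_struct[name], t2, epochs=config.train.epochs_step2)
        step2_nets[name] = net
        histories[f"step2:{name}"] = hist

    # ---- evaluation on the test subjects' adaptive scans
    reports = []
    for sid in plan.test_subjects:
        subj = subjects[sid]
        pred, _prov = run_pipeline(subj.adaptive_volume, net1, step2_nets, pcfg,
                                   roi_table, structure_names=order,
                                   fallback_centers=fallback)
        ref = preprocess_labels(subj.adaptive_labels, pcfg)
        reports.append(evaluate(pred, ref, method=plan.mode, subject=sid, groups=groups))
    report = pd.concat(reports, ignore_index=True)
    models = {"step1": net1, "step2": step2_nets, "roi_table": roi_table,
              "fallback_centers": fallback, "order": order, "histories": histories}
    return models, report


def continual_finetune(base_model: FCDenseNet3D, samples, config: TrainConfig,
                       epochs: int):
    """Further optimize a *copy* of ``base_model`` on one subject's samples.

    The cheaper operational variant of matched-set retraining: start from
    the conventionally trained model and fine-tune on the test subject's
    own planning scan.  ``epochs=0`` returns an identical copy; the base
    model is never modified.
    """
    tuned = base_model.copy()
    if epochs == 0:
        return tuned, []
    tuned, history = train(tuned, samples, config, epochs=epochs)
    return tuned, history
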