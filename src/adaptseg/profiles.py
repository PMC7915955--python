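"""Desk-scale study profiles: the fixed configurations under which the
package's benchmark experiments run on a single CPU.

Two profiles are defined once, here, and reused by the test suite, the
acceptance script and the examples:

* ``smoke``  — two-step training sanity check: 8 six-structure phantoms of
  64 x 64 x 16 voxels at 1 x 1 x 3 mm; tiny network (2 transitions,
  growth rate 4); 30 localization epochs, 40 ROI epochs.
* ``desk``   — continual-vs-conventional comparison: 10-subject cohorts of
  four-structure phantoms (spinal-cord, mandible and paired parotid
  analogs) of 48 x 48 x 12 voxels at 1.5 x 1.5 x 4 mm; 3 test / 4 shared /
  3 extra subjects; 10% glandular shrink; 45 epochs per step.

Problem sizes were chosen so a full matched/unmatched replicate trains in
about two minutes; the network/optimizer knobs (coordinate channels on the
localizer only, plain cross entropy, learning rate 3e-3) are the
configuration that trains these tiny networks reliably and are documented
in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .metrics import evaluate
from .nn import NetworkConfig, TrainConfig
from .oracles import oracle_networks
from .phantom import AnatomyConfig, anatomy_by_names, default_anatomy, generate_cohort
from .preprocess import PreprocessConfig, preprocess_labels
from .protocols import ProtocolConfig, SplitPlan, allocate_splits, run_protocol
from .two_step import RoiSizeTable, run_pipeline

GLANDULAR_SHRINK = 0.10  # fractional glandular volume loss between scans
DEFORM_AMPLITUDE_MM = 2.0

DESK_STRUCTURES = ["cord", "mandible", "parotid_l", "parotid_r"]


def _tiny_network(append_coords: bool) -> NetworkConfig:
    return NetworkConfig(layers_per_block=(2, 2, 2), growth_rate=4, n_transitions=2,
                         pool_factors=((2, 2, 2), (2, 2, 1)), first_channels=8,
                         append_coords=append_coords)


def smoke_anatomy() -> AnatomyConfig:
    return default_anatomy(6, image_size=(64, 64, 16), spacing_mm=(1.0, 1.0, 3.0))


def smoke_protocol_config(seed: int = 0) -> ProtocolConfig:
    pre = PreprocessConfig(target_spacing_mm=(1.0, 1.0, 3.0), fov_size_voxels=(64, 64, 16),
                           localization_downsample=(2, 2, 1))
    train = TrainConfig(learning_rate=3e-3, epochs_step1=45, epochs_step2=60,
                        fp_weight=0.0, seed=seed)
    return ProtocolConfig(preprocess=pre, step1_network=_tiny_network(True),
                          step2_network=_tiny_network(False), train=train, seed=seed)


def desk_anatomy() -> AnatomyConfig:
    return anatomy_by_names(DESK_STRUCTURES, image_size=(48, 48, 12),
                            spacing_mm=(1.5, 1.5, 4.0))


def desk_protocol_config(seed: int = 0) -> ProtocolConfig:
    pre = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0), fov_size_voxels=(48, 48, 12),
                           localization_downsample=(2, 2, 1))
    train = TrainConfig(learning_rate=3e-3, epochs_step1=45, epochs_step2=45,
                        fp_weight=0.0, seed=seed)
    return ProtocolConfig(preprocess=pre, step1_network=_tiny_network(True),
                          step2_network=_tiny_network(False), train=train, seed=seed)


def run_oracle_identity(seed: int, n_phantoms: int = 5) -> pd.DataFrame:
    """Two-step pipeline with ground-truth stub networks on fresh phantoms.

    Any DSC below 1.0 indicates a voxel-level error introduced by
    preprocessing, ROI extraction or assembly.
    """
    anat = smoke_anatomy()
    subjects, _ = generate_cohort(n_phantoms, anat, seed=seed,
                                  shrink_fraction={"glandular": GLANDULAR_SHRINK},
                                  deform_amplitude_mm=DEFORM_AMPLITUDE_MM)
    pcfg = smoke_protocol_config().preprocess
    table = RoiSizeTable.from_labels(
        [preprocess_labels(s.planning_labels, pcfg) for s in subjects], pad_fraction=0.25)
    reports = []
    for s in subjects:
        order = list(s.planning_labels.names)
        step1, step2, pre_lab = oracle_networks(s.planning_labels, pcfg, order)
        pred, _ = run_pipeline(s.planning_volume, step1, step2, pcfg, table,
                               structure_names=order)
        reports.append(evaluate(pred, pre_lab, subject=s.subject_id, method="oracle"))
    return pd.concat(reports, ignore_index=True)


def run_smoke_training(seed: int) -> Dict:
    """Train the tiny two-step model on 8 phantoms; evaluate on a phantom
    seen during training (deliberate memorization check) and on the held
    test subject's adaptive scan.

    Returns loss histories and per-structure Dice for both evaluations.
    """
    anat = smoke_anatomy()
    subjects, _ = generate_cohort(8, anat, seed=seed,
                                  shrink_fraction={"glandular": GLANDULAR_SHRINK},
                                  deform_amplitude_mm=DEFORM_AMPLITUDE_MM)
    cfg = smoke_protocol_config(seed=seed)
    subj = {s.subject_id: s for s in subjects}
    ids = [s.subject_id for s in subjects]
    plan = SplitPlan(test_subjects=(ids[0],), shared_train_subjects=tuple(ids[1:]),
                     extra_train_subjects=(), mode="matched")
    models, test_report = run_protocol(plan, subj, cfg)

    seen = subj[ids[1]]  # a training subject: seen-phantom evaluation
    pred, _ = run_pipeline(seen.planning_volume, models["step1"], models["step2"],
                           cfg.preprocess, models["roi_table"],
                           structure_names=models["order"],
                           fallback_centers=models["fallback_centers"])
    ref = preprocess_labels(seen.planning_labels, cfg.preprocess)
    seen_report = evaluate(pred, ref, subject=ids[1], method="seen")

    histories = models["histories"]
    all_hist = [h for h in histories.values() if h]
    return {
        "histories": histories,
        "mean_epoch_delta": float(np.mean([np.mean(np.diff(h)) for h in all_hist
                                           if len(h) > 1])),
        "final_below_initial": all(h[-1] < h[0] for h in all_hist),
        "seen_report": seen_report,
        "test_report": test_report,
    }


def run_protocol_comparison(seed: int, n_seeds: int = 5) -> Dict:
    """Matched vs unmatched training on ``n_seeds`` independent 10-subject
    cohorts (10% glandular shrink); the continual-training benchmark.

    Returns per-replicate mean test Dice for both protocols and the
    per-structure mean Dice gap (matched minus unmatched).
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rows = []
    gaps = []
    for i, rs in enumerate(rep_seeds):
        anat = desk_anatomy()
        subjects, manifest = generate_cohort(
            10, anat, seed=int(rs),
            shrink_fraction={"glandular": GLANDULAR_SHRINK},
            deform_amplitude_mm=DEFORM_AMPLITUDE_MM)
        cfg = desk_protocol_config(seed=int(rs) % (2**31 - 1))
        subj = {s.subject_id: s for s in subjects}
        matched, unmatched = allocate_splits(manifest, n_test=3, n_shared=4, n_extra=3,
                                             seed=int(rs))
        _, m_rep = run_protocol(matched, subj, cfg)
        _, u_rep = run_protocol(unmatched, subj, cfg)
        gap = (m_rep.groupby("structure").DSC.mean()
               - u_rep.groupby("structure").DSC.mean())
        gaps.append(gap)
        rows.append({"replicate": i, "matched_mean_dsc": float(m_rep.DSC.mean()),
                     "unmatched_mean_dsc": float(u_rep.DSC.mean())})
    table = pd.DataFrame(rows)
    table["matched_wins"] = table.matched_mean_dsc >= table.unmatched_mean_dsc
    mean_gap = pd.concat(gaps, axis=1).mean(axis=1)
    groups = {s.name: s.group for s in desk_anatomy().structure_specs}
    return {
        "per_replicate": table,
        "wins": int(table.matched_wins.sum()),
        "n_seeds": n_seeds,
        "structure_gap": mean_gap,
        "largest_gap_structure": str(mean_gap.idxmax()),
        "largest_gap_group": groups[str(mean_gap.idxmax())],
    }


def run_shrink_fidelity(seed: int, n_seeds: int = 10) -> Dict:
    """Measure realized glandular shrink and non-glandular volume change
    over ``n_seeds`` paired phantoms."""
    rng = np.random.default_rng(seed)
    shr, nong = [], []
    for rs in rng.integers(0, 2**31 - 1, size=n_seeds):
        anat = desk_anatomy()
        subjects, _ = generate_cohort(1, anat, seed=int(rs),
                                      shrink_fraction={"glandular": GLANDULAR_SHRINK},
                                      deform_amplitude_mm=DEFORM_AMPLITUDE_MM)
        s = subjects[0]
        for name, t in s.planning_truth.items():
            v0 = s.planning_labels.volume_voxels(name)
            v1 = s.adaptive_labels.volume_voxels(name)
            rel = 1.0 - v1 / v0
            (shr if t.group == "glandular" else nong).append(rel)
    return {
        "mean_glandular_shrink": float(np.mean(shr)),
        "max_abs_nonglandular_change": float(np.max(np.abs(nong))),
        "mean_abs_nonglandular_change": float(np.mean(np.abs(nong))),
    }
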