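"""Two-step pipeline plumbing: ROI geometry, localization mapping, assembly."""

import numpy as np
import pytest

from adaptseg.grids import ImageVolume, StructureSet
from adaptseg.metrics import evaluate
from adaptseg.oracles import OracleStep1, OracleStep2, oracle_networks
from adaptseg.preprocess import PreprocessConfig, preprocess_labels
from adaptseg.profiles import desk_anatomy
from adaptseg.phantom import generate_subject
from adaptseg.two_step import (MissingStructure, RoiBox, RoiSizeTable, assemble,
                               compute_roi, localize, run_pipeline, segment_roi)


class TestComputeRoi:
    def test_single_voxel_centroid_box(self):
        coarse = np.array([[50, 50, 10]])
        box = compute_roi(coarse, (16, 16, 8), (100, 100, 40), name="t")
        assert box.start == (42, 42, 6)
        assert box.size == (16, 16, 8)

    def test_boundary_box_shifts_inside_without_shrinking(self):
        box = compute_roi(np.array([[2, 2, 2]]), (16, 16, 8), (100, 100, 40))
        assert box.start == (0, 0, 0)
        assert box.size == (16, 16, 8)
        assert box.contains_index((2, 2, 2))

    def test_symmetric_mask_middle_point_is_geometric_center(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask[4:10, 6:12, 2:6] = True  # center (6.5, 8.5, 3.5) -> rounds to (7, 9, 4)
        box = compute_roi(mask, (8, 8, 4), (20, 20, 10))
        assert box.start == (3, 5, 2)

    def test_bbox_center_option(self):
        mask = np.zeros((20, 20, 10), dtype=bool)
        mask[2, 2, 2] = mask[10, 2, 2] = mask[3, 2, 2] = True
        centroid_box = compute_roi(mask, (4, 4, 4), (20, 20, 10))
        bbox_box = compute_roi(mask, (4, 4, 4), (20, 20, 10), middle="bbox_center")
        assert centroid_box.start[0] == 3  # centroid x = 5 -> start 3
        assert bbox_box.start[0] == 4      # bbox center x = 6 -> start 4

    def test_roi_larger_than_grid_is_clipped(self):
        box = compute_roi(np.array([[5, 5, 5]]), (64, 64, 64), (20, 20, 10))
        assert box.size == (20, 20, 10)
        assert box.start == (0, 0, 0)

    def test_empty_mask_raises_instructive_error(self):
        with pytest.raises(MissingStructure, match="fallback"):
            compute_roi(np.zeros((4, 4, 4), dtype=bool), (2, 2, 2), (4, 4, 4))


class TestLocalize:
    def test_coarse_to_full_index_scaling(self):
        label_map = np.zeros((16, 16, 8), dtype=np.int64)
        label_map[10, 20 % 16, 5] = 0  # keep grid small: use (10, 12, 5)
        label_map[10, 12, 5] = 1
        stub = OracleStep1(label_map)
        vol = ImageVolume(np.zeros((16, 16, 8)))
        indices, missing, anchors = localize(stub, vol, ["a"], (2, 2, 1))
        assert indices["a"].tolist() == [[20, 24, 5]]
        assert missing == set()

    def test_empty_prediction_flagged_missing(self):
        stub = OracleStep1(np.zeros((8, 8, 4), dtype=np.int64))
        vol = ImageVolume(np.zeros((8, 8, 4)))
        indices, missing, anchors = localize(stub, vol, ["a", "b"], (2, 2, 1))
        assert missing == {"a", "b"}
        assert indices == {}

    def test_oracle_coarse_masks_overlap_truth(self, desk_subject):
        cfg = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0),
                               fov_size_voxels=(48, 48, 12),
                               localization_downsample=(2, 2, 1))
        order = list(desk_subject.planning_labels.names)
        step1, _, pre_lab = oracle_networks(desk_subject.planning_labels, cfg, order)
        vol = ImageVolume(np.zeros((24, 24, 12)))
        indices, missing, _ = localize(step1, vol, order, (2, 2, 1))
        assert not missing
        for name in order:
            true_vox = {tuple(i) for i in np.argwhere(pre_lab[name])}
            # scaled coarse indices must land inside/near the true mask
            hits = sum(tuple(i) in true_vox for i in indices[name])
            assert hits > 0


class TestSegmentAndAssemble:
    def test_oracle_stub_returns_truth_inside_box(self, desk_subject):
        cfg = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0),
                               fov_size_voxels=(48, 48, 12),
                               localization_downsample=(2, 2, 1))
        pre_lab = preprocess_labels(desk_subject.planning_labels, cfg)
        name = pre_lab.names[0]
        stub = OracleStep2(pre_lab[name])
        box = compute_roi(pre_lab[name], (16, 16, 8), pre_lab.shape, name=name)
        vol = ImageVolume(np.zeros(pre_lab.shape))
        mask = segment_roi(stub, vol, box)
        assert np.array_equal(mask, pre_lab[name][box.slices])

    def test_all_background_crop_allows_empty_mask(self):
        stub = OracleStep2(np.zeros((20, 20, 10), dtype=bool))
        vol = ImageVolume(np.zeros((20, 20, 10)))
        box = RoiBox("x", (0, 0, 0), (8, 8, 4))
        assert segment_roi(stub, vol, box).sum() == 0

    def test_box_outside_grid_rejected(self):
        stub = OracleStep2(np.zeros((10, 10, 10), dtype=bool))
        vol = ImageVolume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError, match="inside grid"):
            segment_roi(stub, vol, RoiBox("x", (5, 5, 5), (8, 8, 8)))

    def test_paste_then_recrop_round_trip(self, rng):
        mask = rng.random((6, 6, 4)) < 0.4
        box = RoiBox("a", (3, 5, 2), (6, 6, 4))
        ss, warnings = assemble({"a": (box, mask)}, (20, 20, 10))
        assert np.array_equal(ss["a"][box.slices], mask)
        assert ss["a"].sum() == mask.sum()
        assert warnings == []

    def test_missing_structures_get_empty_masks_and_warnings(self):
        ss, warnings = assemble({}, (8, 8, 4), missing=["cord"])
        assert ss["cord"].sum() == 0
        assert len(warnings) == 1

    def test_foreground_confined_to_boxes(self, rng):
        boxes = {
            "a": (RoiBox("a", (0, 0, 0), (4, 4, 2)), rng.random((4, 4, 2)) < 0.5),
            "b": (RoiBox("b", (10, 10, 4), (4, 4, 2)), rng.random((4, 4, 2)) < 0.5),
        }
        ss, _ = assemble(boxes, (16, 16, 8))
        allowed = np.zeros((16, 16, 8), dtype=bool)
        for box, _m in boxes.values():
            allowed[box.slices] = True
        for name in ss.names:
            assert not (ss[name] & ~allowed).any()

    def test_duplicate_paste_rejected(self):
        box = RoiBox("a", (0, 0, 0), (2, 2, 2))
        with pytest.raises(ValueError):
            assemble({"a": (box, np.ones((2, 2, 2), bool))}, (4, 4, 4),
                     missing=["a"])


class TestRoiSizeTable:
    def test_from_labels_pads_and_rounds_to_divisibility(self, desk_subject):
        labels = desk_subject.planning_labels
        table = RoiSizeTable.from_labels([labels], pad_fraction=0.25,
                                         divisible_by=(4, 4, 2))
        for name in labels.names:
            idx = np.argwhere(labels[name])
            extent = idx.max(axis=0) - idx.min(axis=0) + 1
            for k in range(3):
                assert table[name][k] >= extent[k]
                assert table[name][k] % (4, 4, 2)[k] == 0

    def test_yaml_round_trip(self, tmp_path):
        table = RoiSizeTable({"thyroid": (144, 176, 48)})
        table.to_yaml(tmp_path / "roi.yaml")
        assert RoiSizeTable.from_yaml(tmp_path / "roi.yaml") == table


class TestPipeline:
    def test_oracle_end_to_end_is_identity_on_labels(self, desk_subject):
        cfg = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0),
                               fov_size_voxels=(48, 48, 12),
                               localization_downsample=(2, 2, 1))
        order = list(desk_subject.planning_labels.names)
        step1, step2, pre_lab = oracle_networks(desk_subject.planning_labels, cfg, order)
        table = RoiSizeTable.from_labels([pre_lab], pad_fraction=0.3)
        pred, prov = run_pipeline(desk_subject.planning_volume, step1, step2, cfg,
                                  table, structure_names=order)
        rep = evaluate(pred, pre_lab, subject="s")
        assert (rep.DSC == 1.0).all()
        assert prov["missing"] == []
        assert set(prov["boxes"]) == set(order)

    def test_pipeline_deterministic_and_provenance_complete(self, desk_subject):
        cfg = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0),
                               fov_size_voxels=(48, 48, 12),
                               localization_downsample=(2, 2, 1))
        order = list(desk_subject.planning_labels.names)
        step1, step2, pre_lab = oracle_networks(desk_subject.planning_labels, cfg, order)
        table = RoiSizeTable.from_labels([pre_lab], pad_fraction=0.3)
        a, prov_a = run_pipeline(desk_subject.planning_volume, step1, step2, cfg,
                                 table, structure_names=order)
        b, _ = run_pipeline(desk_subject.planning_volume, step1, step2, cfg,
                            table, structure_names=order)
        for name in order:
            assert np.array_equal(a[name], b[name])
        for key in ("boxes", "missing", "step1_checksum", "step2_checksums",
                    "preprocess"):
            assert key in prov_a

    def test_roi_containment_on_phantoms(self):
        """Boxes sized >= structure extent capture >=95% of true voxels."""
        cfg = PreprocessConfig(target_spacing_mm=(1.5, 1.5, 4.0),
                               fov_size_voxels=(48, 48, 12),
                               localization_downsample=(2, 2, 1))
        for seed in (11, 12):
            subj = generate_subject(desk_anatomy(), seed=seed)
            order = list(subj.planning_labels.names)
            step1, _, pre_lab = oracle_networks(subj.planning_labels, cfg, order)
            table = RoiSizeTable.from_labels([pre_lab], pad_fraction=0.4)
            vol = ImageVolume(np.zeros((24, 24, 12)))
            indices, missing, _ = localize(step1, vol, order, (2, 2, 1))
            for name in order:
                box = compute_roi(indices[name], table[name], pre_lab.shape, name=name)
                inside = pre_lab[name][box.slices].sum()
                assert inside >= 0.95 * pre_lab[name].sum()
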