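"""Nuclei-seeded split/merge proofreading of cell segmentations."""

from collections import deque

import numpy as np
import pytest

from nuctools import (
    LabelVolume,
    ProbabilityVolume,
    ProofreadConfig,
    apply_merge,
    apply_split,
    corrupt_segmentation,
    find_correction_candidates,
    make_tissue,
    mean_average_precision,
    overlap_table,
    proofread,
)

from conftest import ISO


def bfs_distances(mask, seed_idx):
    """6-connected graph distance from one seed voxel within a mask."""
    dist = np.full(mask.shape, -1, dtype=np.int32)
    dist[seed_idx] = 0
    q = deque([seed_idx])
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= c < s for c, s in zip(n, mask.shape)) and mask[n] and dist[n] < 0:
                dist[n] = dist[z, y, x] + 1
                q.append(n)
    return dist


class TestCandidates:
    def test_two_interior_nuclei_trigger_split(self):
        cells = np.ones((3, 3, 8), dtype=np.int32)
        nuclei = np.zeros_like(cells)
        nuclei[1, 1, 1] = 4
        nuclei[1, 1, 6] = 9
        cand = find_correction_candidates(overlap_table(cells, nuclei))
        assert set(cand.splits) == {1}
        assert set(cand.splits[1]) == {4, 9}
        assert cand.splits[1][4] == 1.0
        assert cand.merges == {}

    def test_straddling_nucleus_triggers_merge(self):
        cells = np.zeros((2, 2, 8), dtype=np.int32)
        cells[..., :4] = 1
        cells[..., 4:] = 2
        nuclei = np.zeros_like(cells)
        nuclei[1, 1, 3:5] = 7  # 50/50 split, both > t_merge = 0.33
        cand = find_correction_candidates(overlap_table(cells, nuclei))
        assert set(cand.merges) == {7}
        assert set(cand.merges[7]) == {1, 2}
        assert cand.splits == {}

    def test_clean_mononucleate_cells_are_silent(self, small_tissue):
        t = small_tissue
        cand = find_correction_candidates(overlap_table(t.cells, t.nuclei))
        assert cand.splits == {} and cand.merges == {}

    def test_cell_volume_denominator_variant(self):
        # two nuclei each 1 voxel in a 72-voxel cell: nucleus-denominator
        # fires (1.0 > 0.66), literal cell-denominator cannot (1/72)
        cells = np.ones((3, 3, 8), dtype=np.int32)
        nuclei = np.zeros_like(cells)
        nuclei[1, 1, 1] = 4
        nuclei[1, 1, 6] = 9
        ov = overlap_table(cells, nuclei)
        literal = find_correction_candidates(
            ov, ProofreadConfig(split_frac_of_cell=True)
        )
        assert literal.splits == {}

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ProofreadConfig(t_split=0.0)
        with pytest.raises(ValueError):
            ProofreadConfig(t_merge=1.5)


class TestApplySplit:
    def test_sharp_wall_separates_two_nuclei(self):
        """A merged pair with a bright pmap wall splits at the wall."""
        cells = np.zeros((5, 5, 10), dtype=np.int32)
        cells[1:4, 1:4, 1:9] = 1
        nuclei = np.zeros_like(cells)
        nuclei[2, 2, 2:4] = 11
        nuclei[2, 2, 6:8] = 12
        pmap = np.zeros(cells.shape, dtype=np.float32)
        pmap[:, :, 5] = 1.0
        out, edit = apply_split(
            LabelVolume(cells, ISO), ProbabilityVolume(pmap, ISO),
            LabelVolume(nuclei, ISO), 1, {11, 12},
        )
        assert edit is not None
        assert len(edit.cells_after) == 2
        a, b = edit.cells_after
        assert not (out.voxels == 1).any()
        # the fragment boundary follows the pmap ridge at x = 5
        assert np.all(out.voxels[1:4, 1:4, 1:5] == a)
        assert np.all(out.voxels[1:4, 1:4, 6:9] == b)

    def test_flat_pmap_equals_geodesic_partition(self):
        """On a flat landscape, fragments equal the nearest-seed geodesic
        partition (ties may go either way)."""
        cells = np.zeros((9, 9, 9), dtype=np.int32)
        cells[1:8, 1:8, 1:8] = 1
        nuclei = np.zeros_like(cells)
        s1, s2 = (2, 2, 2), (6, 6, 6)
        nuclei[s1] = 5
        nuclei[s2] = 6
        pmap = np.zeros(cells.shape, dtype=np.float32)
        out, edit = apply_split(
            LabelVolume(cells, ISO), ProbabilityVolume(pmap, ISO),
            LabelVolume(nuclei, ISO), 1, {5, 6},
        )
        id1, id2 = edit.cells_after  # ordered by seed nucleus ID
        mask = cells == 1
        d1 = bfs_distances(mask, s1)
        d2 = bfs_distances(mask, s2)
        strictly_1 = mask & (d1 < d2)
        strictly_2 = mask & (d2 < d1)
        assert np.all(out.voxels[strictly_1] == id1)
        assert np.all(out.voxels[strictly_2] == id2)

    def test_single_effective_seed_is_noop_with_warning(self):
        cells = np.ones((3, 3, 3), dtype=np.int32)
        nuclei = np.zeros_like(cells)
        nuclei[1, 1, 1] = 2
        pmap = ProbabilityVolume(np.zeros(cells.shape, np.float32), ISO)
        with pytest.warns(UserWarning, match="fewer than 2"):
            out, edit = apply_split(
                LabelVolume(cells, ISO), pmap, LabelVolume(nuclei, ISO), 1, {2, 99},
            )
        assert edit is None
        assert np.array_equal(out.voxels, cells)

    def test_voxels_outside_cell_untouched(self, small_tissue):
        t = small_tissue
        corrupted, record = corrupt_segmentation(t, n_merges=1, seed=3)
        merged_id = record.merged_ids[0]
        nuclei_in = [
            tr.nucleus_id for tr in t.truth if tr.cell_id in record.merges[0]["cells"]
        ]
        out, edit = apply_split(
            corrupted, t.pmap, t.nuclei, merged_id, set(nuclei_in),
        )
        other = corrupted.voxels != merged_id
        assert np.array_equal(out.voxels[other], corrupted.voxels[other])
        assert not (out.voxels == merged_id).any()


class TestApplyMerge:
    def test_merge_relabels_to_smallest_id(self):
        cells = np.zeros((2, 2, 4), dtype=np.int32)
        cells[..., :2] = 5
        cells[..., 2:] = 9
        out, edit = apply_merge(LabelVolume(cells, ISO), {5, 9})
        assert np.all(out.voxels == 5)
        assert edit.cells_before == [5, 9]
        assert edit.cells_after == [5]

    def test_single_id_set_is_noop(self):
        cells = np.full((2, 2, 2), 5, dtype=np.int32)
        out, edit = apply_merge(LabelVolume(cells, ISO), {5})
        assert edit is None
        assert np.array_equal(out.voxels, cells)

    def test_missing_ids_raise(self):
        cells = np.full((2, 2, 2), 5, dtype=np.int32)
        with pytest.raises(KeyError):
            apply_merge(LabelVolume(cells, ISO), {5, 77})

    def test_merge_reverses_injected_split(self, small_tissue):
        t = small_tissue
        corrupted, record = corrupt_segmentation(t, n_splits=1, seed=4)
        split = record.splits[0]
        out, _ = apply_merge(corrupted, set(split["new_ids"]))
        assert np.array_equal(out.voxels, t.cells.voxels)


class TestProofread:
    def test_error_free_tissue_is_untouched(self, small_tissue):
        t = small_tissue
        out, log = proofread(t.cells, t.nuclei, t.pmap)
        assert len(log) == 0
        assert np.array_equal(out.voxels, t.cells.voxels)

    def test_edit_counts_match_injected_corruption(self, small_tissue):
        t = small_tissue
        corrupted, record = corrupt_segmentation(t, n_merges=2, n_splits=1, seed=5)
        out, log = proofread(corrupted, t.nuclei, t.pmap)
        # injected merges require split edits and vice versa
        assert log.n_splits == len(record.merges) == 2
        assert log.n_merges == len(record.splits) == 1

    def test_correction_improves_map50(self, small_tissue):
        t = small_tissue
        corrupted, _ = corrupt_segmentation(t, n_merges=2, n_splits=1, seed=5)
        out, log = proofread(corrupted, t.nuclei, t.pmap)
        before = mean_average_precision([(t.cells, corrupted)], "mAP50").mean
        after = mean_average_precision([(t.cells, out)], "mAP50").mean
        assert len(log) > 0
        assert after > before

    def test_idempotence(self, small_tissue):
        t = small_tissue
        corrupted, _ = corrupt_segmentation(t, n_merges=2, n_splits=1, seed=5)
        once, log1 = proofread(corrupted, t.nuclei, t.pmap)
        twice, log2 = proofread(once, t.nuclei, t.pmap)
        assert len(log2) == 0
        assert np.array_equal(twice.voxels, once.voxels)

    def test_locality_and_conservation(self, small_tissue):
        t = small_tissue
        corrupted, _ = corrupt_segmentation(t, n_merges=2, n_splits=1, seed=5)
        out, log = proofread(corrupted, t.nuclei, t.pmap)
        outside = np.ones(out.voxels.shape, bool)
        for e in log.edits:
            (z0, z1), (y0, y1), (x0, x1) = e.bbox
            outside[z0:z1, y0:y1, x0:x1] = False
        assert np.array_equal(out.voxels[outside], corrupted.voxels[outside])
        # relabeling only: the foreground voxel set is invariant
        assert np.array_equal(out.voxels > 0, corrupted.voxels > 0)

    def test_replay_reproduces_output(self, small_tissue):
        t = small_tissue
        corrupted, _ = corrupt_segmentation(t, n_merges=2, n_splits=1, seed=5)
        out, log = proofread(corrupted, t.nuclei, t.pmap)
        replayed = log.replay(corrupted, t.nuclei, t.pmap)
        assert np.array_equal(replayed.voxels, out.voxels)

    def test_editlog_json_roundtrip(self, tmp_path, small_tissue):
        t = small_tissue
        corrupted, _ = corrupt_segmentation(t, n_merges=1, n_splits=1, seed=6)
        out, log = proofread(corrupted, t.nuclei, t.pmap)
        path = tmp_path / "edits.json"
        log.save(path)
        from nuctools import EditLog

        back = EditLog.load(path)
        assert [e.to_json() for e in back.edits] == [e.to_json() for e in log.edits]
        replayed = back.replay(corrupted, t.nuclei, t.pmap)
        assert np.array_equal(replayed.voxels, out.voxels)

    def test_nuclear_errors_propagate_to_cells(self, small_tissue):
        """Designed failure: merging two nuclei induces a wrong cell merge."""
        t = small_tissue
        # find two adjacent nucleate cells and merge their nuclei
        from nuctools.synthesize import corrupt_segmentation as _c

        corrupted, record = _c(t, n_merges=1, seed=7)
        cell_a, cell_b = record.merges[0]["cells"]
        nuc = {tr.cell_id: tr.nucleus_id for tr in t.truth if tr.nucleus_id}
        na, nb = nuc[cell_a], nuc[cell_b]
        bad_nuclei = t.nuclei.copy()
        bad_nuclei.voxels[bad_nuclei.voxels == nb] = na
        out, log = proofread(t.cells, bad_nuclei, t.pmap)  # cells were correct!
        assert log.n_merges == 1
        assert sorted(log.edits[0].cells_before) == sorted([cell_a, cell_b])
        assert not np.array_equal(out.voxels, t.cells.voxels)

    def test_shape_mismatch_rejected(self, small_tissue):
        t = small_tissue
        bad = LabelVolume(np.zeros((4, 4, 4), int), ISO)
        with pytest.raises(ValueError, match="shape"):
            proofread(bad, t.nuclei, t.pmap)
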