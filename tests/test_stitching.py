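"""Pairwise stitching, the orthogonal rejection vote, and whole-volume passes."""

import itertools

import numpy as np
import pytest

from cellstitch.stitching import (
    StitchConfig,
    jaccard_cost,
    rejection_fraction,
    remove_isolated_cells,
    stitch_pair,
    stitch_volume,
)
from cellstitch.synthetic import slice_masks
from cellstitch.volumes import LabelVolume, OrthogonalMasks, reslice


def gt_ortho(gt: LabelVolume, seed_a=101, seed_b=102) -> OrthogonalMasks:
    """Consistent orthogonal masks: per-plane relabelings of the GT sections."""
    return OrthogonalMasks(yz=slice_masks(gt, "x", seed=seed_a),
                           xz=slice_masks(gt, "y", seed=seed_b))


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same grouping of voxels into cells, labels ignored."""
    if not np.array_equal(a > 0, b > 0):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    return (len({p for p, _ in pairs}) == len(pairs)
            and len({q for _, q in pairs}) == len(pairs))


class TestRejectionFraction:
    def test_consistent_planes_never_reject(self, stacked_cells_scene):
        ortho = OrthogonalMasks(yz=reslice(stacked_cells_scene, "x"),
                                xz=reslice(stacked_cells_scene, "y"))
        pix = np.argwhere(stacked_cells_scene.data[1] == 1)
        assert rejection_fraction(pix, 0, ortho) == 0.0

    def test_total_relabel_rejects_unanimously(self, stacked_cells_scene):
        ortho = OrthogonalMasks(yz=reslice(stacked_cells_scene, "x"),
                                xz=reslice(stacked_cells_scene, "y"))
        pix = np.argwhere(stacked_cells_scene.data[2] == 2)
        # layers 1 -> 2 cross the cell boundary: both votes reject everywhere
        assert rejection_fraction(pix, 1, ortho) == 1.0

    def test_partial_disagreement_counts_votes(self):
        # 10 pixels; YZ disagrees at 4 of them, XZ at none -> 4/20
        z, h, w = 2, 1, 10
        yz = np.zeros((w, z, h), dtype=np.int32)          # (X, Z, Y)
        xz = np.zeros((h, z, w), dtype=np.int32)          # (Y, Z, X)
        yz[:4, 1, 0] = 5                                   # differs from layer 0
        ortho = OrthogonalMasks(yz=yz, xz=xz)
        pix = np.array([[0, c] for c in range(10)])
        assert rejection_fraction(pix, 0, ortho) == pytest.approx(0.2)

    def test_empty_pixel_set_errors(self, stacked_cells_scene):
        ortho = OrthogonalMasks(yz=reslice(stacked_cells_scene, "x"),
                                xz=reslice(stacked_cells_scene, "y"))
        with pytest.raises(ValueError):
            rejection_fraction(np.empty((0, 2), int), 0, ortho)


class TestStitchPair:
    def test_identical_layers_propagate_labels(self):
        layer = np.zeros((8, 8), dtype=np.int32)
        layer[1:4, 1:4] = 11
        layer[5:8, 5:8] = 22
        raw = np.zeros_like(layer)
        raw[1:4, 1:4] = 2
        raw[5:8, 5:8] = 1
        out, nxt, _ = stitch_pair(layer, raw, 0, None, StitchConfig(), 100)
        assert np.array_equal(out, layer)
        assert nxt == 100

    def test_disjoint_cell_starts_fresh(self):
        rel = np.zeros((8, 8), dtype=np.int32)
        rel[0:2, 0:2] = 7
        raw = np.zeros_like(rel)
        raw[6:8, 6:8] = 1
        out, nxt, recs = stitch_pair(rel, raw, 0, None, StitchConfig(), 50)
        assert out[6:8, 6:8].min() == 50 and nxt == 51
        assert recs[0].new_cell

    def test_oversegmented_source_relabels_via_least_cost(self):
        # two source fragments both trace to one target; the larger-overlap
        # (lower-cost) fragment wins, the other relabels nothing
        rel = np.zeros((6, 10), dtype=np.int32)
        rel[1:5, 1:6] = 3   # 20 px
        rel[1:5, 6:9] = 8   # 12 px
        raw = np.zeros_like(rel)
        raw[1:5, 1:9] = 1   # undivided cell spanning both fragments
        C = jaccard_cost(rel, raw)
        c3 = C.entries[C.row_index(3), C.col_index(1)]
        c8 = C.entries[C.row_index(8), C.col_index(1)]
        assert c3 < c8  # fragment 3 overlaps more
        out, nxt, _ = stitch_pair(rel, raw, 0, None, StitchConfig(), 99)
        assert set(np.unique(out[raw == 1])) == {3}
        assert nxt == 99

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            stitch_pair(np.zeros((3, 3), int), np.zeros((4, 3), int), 0, None,
                        StitchConfig(), 1)


class TestStitchVolume:
    def test_single_layer_is_a_relabeled_copy(self):
        layer = np.zeros((6, 6), dtype=np.int32)
        layer[1:3, 1:3] = 4
        vol = stitch_volume(LabelVolume(layer[None]),
                            config=StitchConfig(min_layers_per_cell=1))
        assert partitions_equal(vol.data[0], layer)

    def test_shuffled_cylinder_becomes_one_cell(self):
        disc = np.zeros((9, 9), dtype=np.int32)
        disc[2:7, 2:7] = 1
        layers = [disc * 5, disc * 2, disc * 9]  # per-layer arbitrary labels
        gt = LabelVolume(np.stack([disc, disc, disc]))
        vol = stitch_volume(LabelVolume.from_layers(layers), ortho=gt_ortho(gt))
        labs = vol.labels()
        assert labs.size == 1
        assert np.array_equal(vol.data > 0, gt.data > 0)

    def test_stacked_cells_split_by_vote_merged_without(self, stacked_cells_scene):
        z_masks = LabelVolume(slice_masks(stacked_cells_scene, "z", seed=5))
        with_vote = stitch_volume(z_masks, ortho=gt_ortho(stacked_cells_scene))
        without = stitch_volume(z_masks, ortho=None)
        assert with_vote.labels().size == 2
        assert without.labels().size == 1

    def test_raising_threshold_only_merges(self):
        # one cell footprint across two layers; YZ planes disagree across z
        # for the left half of the footprint only -> rejection fraction 0.25
        gt = np.zeros((2, 12, 12), dtype=np.int32)
        gt[:, 3:9, 3:9] = 1
        vol = LabelVolume(gt)
        yz = reslice(vol, "x")
        yz[3:6, 1] += 40  # X columns 3..5 relabeled in layer 1
        ortho = OrthogonalMasks(yz=yz, xz=reslice(vol, "y"))
        frac = rejection_fraction(np.argwhere(gt[1] == 1), 0, ortho)
        assert frac == pytest.approx(0.25)
        below = stitch_volume(vol, ortho=ortho,
                              config=StitchConfig(rejection_threshold=0.2,
                                                  min_layers_per_cell=1))
        above = stitch_volume(vol, ortho=ortho,
                              config=StitchConfig(rejection_threshold=0.3,
                                                  min_layers_per_cell=1))
        assert below.labels().size == 2  # vote splits under the low threshold
        assert above.labels().size == 1  # raising the threshold merges the pair

    def test_ortho_dimension_mismatch_errors(self, stacked_cells_scene):
        bad = OrthogonalMasks(yz=np.zeros((3, 4, 12), dtype=np.int32),
                              xz=np.zeros((12, 4, 12), dtype=np.int32))
        with pytest.raises(ValueError):
            stitch_volume(stacked_cells_scene, ortho=bad)

    def test_permutation_equivariance(self, rng):
        # unambiguous two-cell ladder; permuting per-layer labels must leave
        # the voxel partition unchanged
        base = np.zeros((3, 10, 10), dtype=np.int64)
        base[:, 1:5, 1:5] = 1
        base[:, 6:9, 6:9] = 2
        ref = stitch_volume(LabelVolume(base))
        for _ in range(5):
            shuffled = np.zeros_like(base)
            for z in range(3):
                perm = rng.permutation([7, 13]).tolist()
                shuffled[z][base[z] == 1] = perm[0]
                shuffled[z][base[z] == 2] = perm[1]
            out = stitch_volume(LabelVolume(shuffled))
            assert partitions_equal(out.data, ref.data)


class TestRemoveIsolatedCells:
    def _volume(self):
        data = np.zeros((3, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 1            # single layer
        data[:2, 2, 2] = 2           # two layers
        data[:, 3, 3] = 3            # all layers
        return LabelVolume(data)

    def test_single_layer_cell_removed(self):
        out = remove_isolated_cells(self._volume(), min_layers=2)
        assert 1 not in out.labels()

    def test_spanning_cells_kept_untouched(self):
        out = remove_isolated_cells(self._volume(), min_layers=2)
        assert out.labels().tolist() == [2, 3]
        assert np.array_equal(out.data == 2, self._volume().data == 2)

    def test_census_removes_exactly_the_short_spans(self):
        out = remove_isolated_cells(self._volume(), min_layers=3)
        assert out.labels().tolist() == [3]


def brute_force_matching(layer_a, layer_b):
    """Minimum-total-cost injective matching between overlapping cells,
    by exhaustive enumeration (equal cell counts, <= 4 cells/side)."""
    C = jaccard_cost(layer_a, layer_b)
    rows = [l for l in C.row_labels.tolist() if l]
    cols = [l for l in C.col_labels.tolist() if l]
    best, best_cost = None, np.inf
    for perm in itertools.permutations(cols):
        cost = sum(C.entries[C.row_index(x), C.col_index(y)]
                   for x, y in zip(rows, perm))
        if cost < best_cost - 1e-12:
            best, best_cost = dict(zip(rows, perm)), cost
    return best


def unambiguous_instance(rng, k):
    """k disjoint squares; the second layer jitters each square by <= 2 px so
    every cell overlaps exactly its own counterpart."""
    a = np.zeros((26, 26), dtype=np.int64)
    b = np.zeros((26, 26), dtype=np.int64)
    anchors = [(2, 2), (2, 14), (14, 2), (14, 14)][:k]
    perm = rng.permutation(k) + 1
    for i, (r, c) in enumerate(anchors):
        a[r:r + 6, c:c + 6] = i + 1
        dr, dc = rng.integers(-2, 3, size=2)
        b[r + dr:r + dr + 6, c + dc:c + dc + 6] = perm[i]
    return a, b


def test_stitching_matches_brute_force_on_unambiguous_instances(rng):
    for trial in range(10):
        k = int(rng.integers(1, 5))
        a, b = unambiguous_instance(rng, k)
        oracle = brute_force_matching(a, b)
        out, _, _ = stitch_pair(a, b, 0, None, StitchConfig(), 1000)
        stitched = {}
        for y in np.unique(b[b > 0]):
            got = np.unique(out[b == y])
            assert got.size == 1
            stitched[int(got[0])] = int(y)
        assert stitched == {x: y for x, y in oracle.items()}
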