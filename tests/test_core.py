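"""The iterative segmentation loop: clearing, local splitting, termination."""

import numpy as np
import pytest

from acsat import (
    AcsatConfig,
    CollapsedImage,
    FibatConfig,
    ROI,
    ShapeCriteria,
    auto_epsilon,
    clear_rois,
    count_valid_rois,
    binarize_and_refine,
    fibat,
    local_split,
    run_acsat,
)
from conftest import disc_image, gaussian_blob

LOCAL = ShapeCriteria(a_min=20, a_max=np.inf)


def roi_from_mask(mask, iteration=0):
    return ROI(pixels=np.column_stack(np.nonzero(mask)), iteration=iteration)


class TestClearRois:
    def test_empty_list_returns_image_unchanged(self):
        img = CollapsedImage(pixels=np.arange(16.0).reshape(4, 4))
        out = clear_rois(img, [], radius=2)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_whole_image_roi_zeroes_everything(self):
        img = CollapsedImage(pixels=np.ones((6, 6)))
        roi = roi_from_mask(np.ones((6, 6), dtype=bool))
        assert np.all(clear_rois(img, [roi], radius=1).pixels == 0)

    def test_dilated_clearing_matches_naive_disc_oracle(self):
        rng = np.random.default_rng(0)
        px = rng.uniform(1, 2, size=(30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 12:22] = True
        radius = 2
        out = clear_rois(CollapsedImage(pixels=px), [roi_from_mask(mask)], radius).pixels
        # oracle: a pixel is cleared iff within Euclidean distance `radius`
        # of any mask pixel
        mr, mc = np.nonzero(mask)
        for y in range(30):
            for x in range(30):
                d2 = ((mr - y) ** 2 + (mc - x) ** 2).min()
                if d2 <= radius * radius:
                    assert out[y, x] == 0
                else:
                    assert out[y, x] == px[y, x]


class TestLocalSplit:
    def test_single_blob_returns_one_roi(self):
        img = np.zeros((48, 48))
        gaussian_blob(img, 24, 24, 1.0, 3.5)
        image = CollapsedImage(pixels=img)
        parent = roi_from_mask(img > 0.05)
        out = local_split(parent, image, LOCAL, FibatConfig(epsilon=1e-4))
        assert len(out) == 1

    def test_dumbbell_splits_into_two(self):
        # two equal blobs joined by a lower-intensity bridge; at the parent's
        # threshold they are one component
        img = np.zeros((40, 64))
        gaussian_blob(img, 20, 20, 1.0, 2.8)
        gaussian_blob(img, 20, 44, 1.0, 2.8)
        img[18:23, 20:44] += 0.35  # bridge
        image = CollapsedImage(pixels=img)
        parent_mask = img > 0.2
        assert count_valid_rois(parent_mask, ShapeCriteria(a_min=20, a_max=1e6)) == 1
        # oracle: an exhaustive threshold sweep on the patch peaks at 2
        best = max(
            count_valid_rois(binarize_and_refine(image, t), LOCAL)
            for t in np.linspace(0.01, 0.99, 197)
        )
        assert best == 2
        out = local_split(roi_from_mask(parent_mask), image, LOCAL, FibatConfig(epsilon=1e-4))
        assert len(out) == 2

    def test_five_cell_cluster_splits_into_five(self, five_cell_cluster):
        image = five_cell_cluster
        res = fibat(image, ShapeCriteria(a_min=50, a_max=300))
        cluster = [
            r
            for r in res.rois
            if ((r.pixels[:, 0] == 40) & (r.pixels[:, 1] == 40)).any()
        ]
        assert len(cluster) == 1  # global thresholding merges the five cells
        eps = auto_epsilon(image.pixels)
        pieces = local_split(cluster[0], image, LOCAL, FibatConfig(epsilon=eps))
        assert len(pieces) == 5

    def test_split_rois_carry_disjoint_cores_within_parent(self, five_cell_cluster):
        image = five_cell_cluster
        res = fibat(image, ShapeCriteria(a_min=50, a_max=300))
        cluster = max(res.rois, key=lambda r: r.area)
        pieces = local_split(
            cluster, image, LOCAL, FibatConfig(epsilon=auto_epsilon(image.pixels))
        )
        seen = set()
        for p in pieces:
            core = set(map(tuple, p.core_pixels.tolist()))
            assert not (core & seen)
            seen |= core


class TestRunAcsat:
    def test_five_equal_discs_found_first_iteration(self):
        img = disc_image((96, 96), [(16, 16), (16, 80), (48, 48), (80, 16), (80, 80)], 5)
        seg = run_acsat(CollapsedImage(pixels=img))
        assert len(seg.rois) == 5
        assert all(r.iteration == 1 for r in seg.rois)
        assert seg.n_iterations <= 2  # terminates promptly

    def test_all_zero_image_gives_empty_segmentation(self):
        seg = run_acsat(CollapsedImage(pixels=np.zeros((64, 64))))
        assert seg.rois == [] and seg.n_iterations == 0

    def test_two_intensity_tiers_need_two_iterations(self):
        # bright cells appear as four close pairs whose bridges keep them
        # merged (and oversize) at low thresholds, so the count-maximizing
        # first threshold sits high, above the dim cells entirely
        img = np.zeros((128, 128))
        pair_centers = [(24, 24), (24, 88), (88, 24), (88, 88)]
        for cy, cx in pair_centers:
            gaussian_blob(img, cy, cx - 5.5, 1.0, 3.5)
            gaussian_blob(img, cy, cx + 5.5, 1.0, 3.5)
        dim_centers = [(56, 24), (56, 88), (24, 56)]
        for cy, cx in dim_centers:
            gaussian_blob(img, cy, cx, 0.15, 3.5)
        seg = run_acsat(CollapsedImage(pixels=img))
        by_iter = {}
        for r in seg.rois:
            by_iter.setdefault(r.iteration, []).append(r)
        assert seg.n_iterations >= 2
        taus = seg.tau_trace
        assert taus[1] < taus[0]
        # every dim cell is recovered in an iteration after the first
        later = [r for r in seg.rois if r.iteration >= 2]
        for cy, cx in dim_centers:
            assert any(
                ((r.pixels[:, 0] == cy) & (r.pixels[:, 1] == cx)).any() for r in later
            )
        # no first-iteration ROI touches a dim cell center
        for cy, cx in dim_centers:
            assert not any(
                ((r.pixels[:, 0] == cy) & (r.pixels[:, 1] == cx)).any()
                for r in by_iter.get(1, [])
            )

    def test_rerun_is_bit_identical(self, five_cell_cluster):
        a = run_acsat(five_cell_cluster)
        b = run_acsat(five_cell_cluster)
        assert len(a.rois) == len(b.rois)
        for ra, rb in zip(a.rois, b.rois):
            assert np.array_equal(ra.pixels, rb.pixels)
            assert ra.iteration == rb.iteration
        assert a.tau_trace == b.tau_trace

    def test_output_cores_are_pairwise_disjoint(self, five_cell_cluster):
        seg = run_acsat(five_cell_cluster)
        claimed = np.zeros(seg.image_shape, dtype=bool)
        for roi in seg.rois:
            px = roi.core_pixels
            assert not claimed[px[:, 0], px[:, 1]].any()
            claimed[px[:, 0], px[:, 1]] = True

    def test_cumulative_count_non_decreasing(self, five_cell_cluster):
        seg = run_acsat(five_cell_cluster)
        counts = [rec.cumulative_rois for rec in seg.history]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AcsatConfig(delta=0.0)
        with pytest.raises(ValueError):
            AcsatConfig(max_iterations=0)
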