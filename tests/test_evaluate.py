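"""SNR definitions, mutual overlap, and ROI-set matching."""

import itertools

import numpy as np
import pytest

from acsat import (
    ImageStack,
    MatchConfig,
    ROI,
    match_roi_sets,
    mutual_overlap,
    normalize_trace,
    snr_image,
    snr_trace,
)


def block_roi(top, left, h, w, iteration=0):
    rr, cc = np.mgrid[top : top + h, left : left + w]
    return ROI(pixels=np.column_stack([rr.ravel(), cc.ravel()]), iteration=iteration)


class TestMutualOverlap:
    def test_identical_masks_give_one(self):
        a = block_roi(0, 0, 10, 10)
        assert mutual_overlap(a, a) == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self):
        assert mutual_overlap(block_roi(0, 0, 5, 5), block_roi(20, 20, 5, 5)) == 0.0

    def test_printed_definition_arithmetic(self):
        # |a| = 100, |b| = 50, |a & b| = 50 -> (0.5 + 1.0) / 2 = 0.75
        a = block_roi(0, 0, 10, 10)
        b = block_roi(0, 0, 5, 10)
        assert mutual_overlap(a, b) == pytest.approx(0.75)

    @pytest.mark.parametrize("shift", [(0, 0), (2, 1), (7, 3), (9, 9)])
    def test_symmetry(self, shift):
        a = block_roi(0, 0, 8, 12)
        b = block_roi(shift[0], shift[1], 10, 6)
        assert mutual_overlap(a, b) == pytest.approx(mutual_overlap(b, a))


def brute_force_best_matching(pred, truth, cfg):
    """Oracle: exhaustive one-to-one assignment maximizing matched-pair count
    (ties broken by total overlap) over candidate pairs."""
    cand = {}
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            d = np.hypot(p.centroid[0] - t.centroid[0], p.centroid[1] - t.centroid[1])
            ov = mutual_overlap(p, t)
            if d < cfg.max_centroid_dist and ov > cfg.min_mutual_overlap:
                cand[(i, j)] = ov
    best = (0, 0.0)
    n = min(len(pred), len(truth))
    for k in range(n, 0, -1):
        for pred_subset in itertools.combinations(range(len(pred)), k):
            for truth_perm in itertools.permutations(range(len(truth)), k):
                pairs = list(zip(pred_subset, truth_perm))
                if all(p in cand for p in pairs):
                    score = (k, sum(cand[p] for p in pairs))
                    best = max(best, score)
        if best[0] == k:
            break
    return best[0]


class TestMatching:
    def test_perfect_prediction_matches_everything(self):
        truth = [block_roi(0, 0, 8, 8), block_roi(20, 20, 8, 8)]
        m = match_roi_sets(truth, truth)
        assert m.n_match == 2 and m.recall == 1.0 and m.precision == 1.0
        assert m.fdr == 0.0 and m.fnr == 0.0
        assert all(ov == pytest.approx(1.0) for _, _, ov in m.pairs)

    def test_empty_prediction_reports_degenerate_precision(self):
        truth = [block_roi(5 * k, 0, 4, 4) for k in range(10)]
        m = match_roi_sets([], truth)
        assert m.recall == 0.0 and m.n_truth_only == 10
        assert m.precision == 0.0 and m.degenerate_precision

    def test_one_to_one_and_result_is_order_invariant(self):
        rng = np.random.default_rng(11)
        truth = [block_roi(12 * k, 12 * j, 8, 8) for k in range(3) for j in range(3)]
        pred = [
            block_roi(12 * k + rng.integers(-2, 3), 12 * j + rng.integers(-2, 3), 8, 8)
            for k in range(3)
            for j in range(3)
        ]
        m1 = match_roi_sets(pred, truth)
        order = rng.permutation(len(pred))
        m2 = match_roi_sets([pred[i] for i in order], truth)
        assert m1.n_match == m2.n_match
        mapped = {(int(order[i]), j) for i, j, _ in
                  [(list(order).index(i), j, ov) for i, j, ov in m1.pairs]}
        assert {(i, j) for i, j, _ in m2.pairs} == {
            (list(order).index(i), j) for i, j, _ in m1.pairs
        }

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_brute_force_assignment(self, seed):
        """On small realistic instances the greedy pairing attains the
        exhaustive max-cardinality one-to-one assignment."""
        rng = np.random.default_rng(seed)
        truth = [
            block_roi(int(r), int(c), 8, 8)
            for r, c in zip(rng.uniform(0, 40, 4), rng.uniform(0, 40, 4))
        ]
        pred = []
        for t in truth[: rng.integers(2, 5)]:
            dy, dx = rng.integers(-3, 4, 2)
            pred.append(block_roi(int(t.pixels[0, 0] + dy), int(t.pixels[0, 1] + dx), 8, 8))
        cfg = MatchConfig()
        m = match_roi_sets(pred, truth, cfg)
        assert m.n_match == brute_force_best_matching(pred, truth, cfg)

    def test_rates_satisfy_their_identities(self):
        truth = [block_roi(0, 0, 8, 8), block_roi(30, 30, 8, 8), block_roi(60, 0, 8, 8)]
        pred = [block_roi(1, 0, 8, 8), block_roi(90, 90, 8, 8)]
        m = match_roi_sets(pred, truth)
        assert m.recall == pytest.approx(m.n_match / (m.n_match + m.n_truth_only))
        assert m.precision == pytest.approx(m.n_match / (m.n_match + m.n_pred_only))
        assert m.fdr + m.precision == pytest.approx(1.0)
        assert 0 <= m.recall <= 1 and 0 <= m.precision <= 1


class TestSnr:
    def test_image_snr_decades(self):
        arr = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5] = True
        rng = np.random.default_rng(0)
        bg = rng.normal(0, 1.0, size=(5, 10))
        arr[5:] = bg
        arr[:5] = 10.0 * bg.std()
        assert snr_image(mask, arr) == pytest.approx(20.0)
        arr[:5] = bg.std()
        assert snr_image(mask, arr) == pytest.approx(0.0)

    def test_image_snr_error_paths(self):
        with pytest.raises(ValueError):
            snr_image(np.ones((4, 4), dtype=bool), np.ones((4, 4)))
        with pytest.raises(ValueError):
            snr_image(np.eye(4, dtype=bool), np.ones((4, 4)))  # zero bg variance

    def test_trace_snr_grows_with_flash_amplitude(self):
        def stack_with_flash(amp):
            rng = np.random.default_rng(1)
            frames = rng.normal(10, 0.5, size=(16, 16, 40))
            frames[4:8, 4:8, 20] += amp
            return ImageStack(frames=frames)

        roi = block_roi(4, 4, 4, 4)
        low = snr_trace(roi, stack_with_flash(5.0))
        high = snr_trace(roi, stack_with_flash(50.0))
        assert high > low

    def test_trace_snr_constant_background_errors(self):
        frames = np.ones((8, 8, 10))
        frames[2:4, 2:4, 5] = 3.0
        roi = block_roi(2, 2, 2, 2)
        with pytest.raises(ValueError):
            snr_trace(roi, ImageStack(frames=frames))

    def test_trace_display_normalization(self):
        trace = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(normalize_trace(trace), [-0.5, 0.0, 0.5])
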