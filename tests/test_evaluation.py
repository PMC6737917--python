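"""Boundary precision-recall: edgels, bipartite matching, PR curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldseg.evaluation import (
    CORRECT,
    FALSE,
    MISSED,
    EdgelSet,
    MatchConfig,
    error_map,
    extract_edgels,
    f_measure,
    match_edgels,
    pr_curve,
    precision_recall,
)


def brute_force_matching(det, ref, cfg):
    """Exhaustive enumeration over all partial matchings: returns
    (max cardinality, min cost among max-cardinality matchings)."""
    n, m = len(det), len(ref)
    adm = {}
    for i in range(n):
        for j in range(m):
            d = np.hypot(det.rows[i] - ref.rows[j], det.cols[i] - ref.cols[j])
            if d <= cfg.d_max:
                dth = abs(det.orientations[i] - ref.orientations[j]) % np.pi
                dth = min(dth, np.pi - dth)
                adm[(i, j)] = d / cfg.d_max + cfg.orientation_weight * dth / (np.pi / 2)
    best = (-1, 0.0)

    def rec(i, used, card, cost):
        nonlocal best
        if i == n:
            if card > best[0] or (card == best[0] and cost < best[1] - 1e-12):
                best = (card, cost)
            return
        rec(i + 1, used, card, cost)
        for j in range(m):
            if j not in used and (i, j) in adm:
                rec(i + 1, used | {j}, card + 1, cost + adm[(i, j)])

    rec(0, frozenset(), 0, 0.0)
    return best


class TestExtractEdgels:
    def test_empty(self):
        assert len(extract_edgels(np.zeros((10, 10), bool))) == 0

    def test_horizontal_line_orientations(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 3:17] = True
        es = extract_edgels(mask)
        assert len(es) == mask.sum()
        acute = np.minimum(es.orientations, np.pi - es.orientations)
        assert np.degrees(acute).max() < 10

    def test_count_equals_thinned_foreground(self, rng):
        mask = rng.random((40, 40)) < 0.3
        from skimage.morphology import thin as sk_thin

        assert len(extract_edgels(mask)) == sk_thin(mask).sum()


class TestMatching:
    CFG = MatchConfig(d_max=5.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 10_000))
    def test_equals_exhaustive_enumeration(self, n, m, seed):
        rng = np.random.default_rng(seed)
        det = EdgelSet(rng.uniform(0, 20, n), rng.uniform(0, 20, n), rng.uniform(0, np.pi, n))
        ref = EdgelSet(rng.uniform(0, 20, m), rng.uniform(0, 20, m), rng.uniform(0, np.pi, m))
        corr = match_edgels(det, ref, self.CFG)
        card, cost = brute_force_matching(det, ref, self.CFG)
        assert corr.n_matched == card
        assert corr.total_cost == pytest.approx(cost, abs=1e-9)

    def test_identical_sets_fully_matched(self, rng):
        e = EdgelSet(rng.uniform(0, 30, 15), rng.uniform(0, 30, 15), rng.uniform(0, np.pi, 15))
        corr = match_edgels(e, e, self.CFG)
        assert corr.n_matched == 15
        assert len(corr.unmatched_detected) == 0

    def test_shift_within_tolerance_all_matched(self):
        ref = EdgelSet(np.full(20, 10.0), np.arange(20.0), np.zeros(20))
        det = EdgelSet(np.full(20, 13.0), np.arange(20.0), np.zeros(20))
        assert match_edgels(det, ref, self.CFG).n_matched == 20

    def test_shift_beyond_tolerance_no_match(self):
        ref = EdgelSet(np.full(20, 10.0), np.arange(20.0), np.zeros(20))
        det = EdgelSet(np.full(20, 17.0), np.arange(20.0), np.zeros(20))
        assert match_edgels(det, ref, self.CFG).n_matched == 0

    def test_swap_symmetry(self, rng):
        det = EdgelSet(rng.uniform(0, 30, 12), rng.uniform(0, 30, 12), rng.uniform(0, np.pi, 12))
        ref = EdgelSet(rng.uniform(0, 30, 9), rng.uniform(0, 30, 9), rng.uniform(0, np.pi, 9))
        a = precision_recall(match_edgels(det, ref, self.CFG), 12, 9)
        b = precision_recall(match_edgels(ref, det, self.CFG), 9, 12)
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)
        assert a.f_measure == pytest.approx(b.f_measure)

    def test_matched_bounds(self, rng):
        det = EdgelSet(rng.uniform(0, 30, 25), rng.uniform(0, 30, 25), rng.uniform(0, np.pi, 25))
        ref = EdgelSet(rng.uniform(0, 30, 7), rng.uniform(0, 30, 7), rng.uniform(0, np.pi, 7))
        corr = match_edgels(det, ref, self.CFG)
        assert corr.n_matched <= 7


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "p,r,f",
        [
            (0.717, 0.617, 0.663),  # contour benchmark printed cells
            (0.757, 0.601, 0.670),
        ],
    )
    def test_harmonic_mean_of_printed_cells(self, p, r, f):
        assert f_measure(p, r) == pytest.approx(f, abs=5e-4)

    def test_equal_pr_gives_f_equal(self):
        assert f_measure(0.42, 0.42) == pytest.approx(0.42)

    def test_zero_division_conventions(self):
        empty = match_edgels(
            EdgelSet([], [], []), EdgelSet([], [], []), MatchConfig(d_max=5)
        )
        pr = precision_recall(empty, 0, 0)
        assert pr.precision == pr.recall == pr.f_measure == 0.0

    def test_f_bounds(self, rng):
        p, r = rng.uniform(0.01, 1, 2)
        f = f_measure(p, r)
        assert min(p, r) <= f <= (p + r) / 2 + 1e-12


class TestPRCurve:
    def test_perfect_strength_map_reaches_f1(self, small_scene):
        from fieldseg.reference import prepare_reference

        _, truth = small_scene
        ref = prepare_reference(truth.boundary_lines, truth.image.grid)
        strength = ref.mask.astype(float)
        res = pr_curve(strength, ref.mask, MatchConfig(d_max=5), n_thresholds=5)
        assert res["best_f"] == pytest.approx(1.0)

    def test_recall_non_increasing_in_threshold(self, rng):
        from scipy.ndimage import gaussian_filter

        strength = gaussian_filter(rng.random((64, 64)), 2)
        strength = (strength - strength.min()) / np.ptp(strength)
        ref = strength > 0.7
        res = pr_curve(strength, ref, MatchConfig(d_max=3), n_thresholds=9)
        recalls = [row[2] for row in res["curve"]]
        assert all(a >= b - 1e-9 for a, b in zip(recalls, recalls[1:]))

    def test_rejects_single_threshold(self):
        with pytest.raises(ValueError):
            pr_curve(np.zeros((8, 8)), np.zeros((8, 8), bool), MatchConfig(d_max=3), 1)


class TestToleranceConversion:
    @pytest.mark.parametrize("d_max,metres", [(10, 5.0), (5, 2.5)])
    def test_pixel_to_ground(self, d_max, metres):
        cfg = MatchConfig(d_max=d_max, resolution_m=0.5)
        assert cfg.tolerance_m == pytest.approx(metres)


class TestErrorMap:
    def test_identical_masks_all_correct(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 2:18] = True
        e = extract_edgels(mask)
        corr = match_edgels(e, e, MatchConfig(d_max=3))
        emap = error_map(corr, mask.shape)
        assert (emap[mask] == CORRECT).all()
        assert (emap != FALSE).all() and (emap != MISSED).all()

    def test_empty_detection_all_missed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 2:18] = True
        ref = extract_edgels(mask)
        corr = match_edgels(EdgelSet([], [], []), ref, MatchConfig(d_max=3))
        emap = error_map(corr, mask.shape)
        assert (emap[mask] == MISSED).all()
        assert (emap != FALSE).all()

    def test_class_counts_match_correspondence(self, rng):
        a = rng.random((40, 40)) < 0.1
        b = rng.random((40, 40)) < 0.1
        det, ref = extract_edgels(a), extract_edgels(b)
        corr = match_edgels(det, ref, MatchConfig(d_max=2))
        emap = error_map(corr, a.shape)
        # counts can collide on shared pixels only between classes; compare sets
        assert (emap == MISSED).sum() <= len(corr.unmatched_reference)
        assert (emap == FALSE).sum() <= len(corr.unmatched_detected)
        assert (emap == CORRECT).sum() <= corr.n_matched
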