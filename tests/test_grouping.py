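"""Combinatorial grouping: candidate enumeration, scoring, flat selection."""

import numpy as np
import pytest
from skimage.measure import label as cc_label

from fieldseg.grouping import (
    CandidateRegion,
    CombinatorialGrouping,
    enumerate_candidates,
    flat_segmentation,
    score_candidate,
)
from fieldseg.owt import build_ucm

from conftest import random_toy_hierarchy, strip_partition


def three_region_hierarchy():
    part = strip_partition([3, 3, 3])
    strengths = [0.2 if arc.pair == (1, 2) else 0.8 for arc in part.arcs]
    return build_ucm(part, strengths)


class TestEnumerate:
    def test_two_leaf_hierarchy_three_candidates(self):
        part = strip_partition([4, 4])
        h = build_ucm(part, [0.6])
        cands = enumerate_candidates(h)
        assert len(cands) == 3
        assert {frozenset(c.leaf_set) for c in cands} == {
            frozenset({1}),
            frozenset({2}),
            frozenset({1, 2}),
        }

    def test_max_combine_one_gives_hierarchy_nodes_only(self, rng):
        h = random_toy_hierarchy(rng, n_strips=6)
        cands = enumerate_candidates(h, max_combine=1, max_candidates=10_000)
        # nodes: n leaves + n-1 merges
        assert len(cands) == 6 + 5

    def test_candidates_connected_unions_of_finest(self, rng):
        h = random_toy_hierarchy(rng, n_strips=7)
        labels = h.finest.labels
        for cand in enumerate_candidates(h, max_candidates=10_000):
            mask = np.isin(labels, list(cand.leaf_set))
            assert cc_label(mask, connectivity=1).max() == 1

    def test_deduplicated(self, rng):
        h = random_toy_hierarchy(rng, n_strips=8)
        cands = enumerate_candidates(h, max_candidates=10_000)
        sets = [c.leaf_set for c in cands]
        assert len(sets) == len(set(sets))


class TestScore:
    def test_strong_outline_weak_interior(self):
        h = three_region_hierarchy()
        # region {1, 2}: outer boundary = frame (1.0) + the 0.8 arc;
        # interior = the 0.2 arc
        cand = CandidateRegion(leaf_set=frozenset({1, 2}), provenance="node")
        s = score_candidate(cand, h)
        # outer mean: frame sides of strips 1+2 and the (2,3) boundary
        assert s > score_candidate(
            CandidateRegion(leaf_set=frozenset({1}), provenance="node"), h
        ) or s > 0.5

    def test_splitting_true_field_scores_lower(self):
        """Half of a merged 'field' scores below the whole field."""
        h = three_region_hierarchy()
        whole = score_candidate(
            CandidateRegion(leaf_set=frozenset({1, 2}), provenance="node"), h
        )
        half = score_candidate(
            CandidateRegion(leaf_set=frozenset({1}), provenance="node"), h
        )
        # the half exposes the weak 0.2 boundary in its outline
        assert half < whole

    def test_root_score_from_frame(self, rng):
        h = random_toy_hierarchy(rng, n_strips=4)
        root = CandidateRegion(
            leaf_set=frozenset(range(1, 5)), provenance="node"
        )
        s = score_candidate(root, h)
        assert 0 <= s <= 1.0


class TestFlatSegmentation:
    def test_single_node_hierarchy_single_segment(self):
        from fieldseg.owt import FinestPartition, UCMHierarchy

        part = FinestPartition(labels=np.ones((8, 8), dtype=np.int32), arcs=[])
        h = UCMHierarchy(finest=part, merges=[], edge_values={})
        cands = enumerate_candidates(h)
        seg = flat_segmentation(cands, h)
        assert seg.n_regions == 1

    def test_empty_candidates_rejected(self):
        h = three_region_hierarchy()
        with pytest.raises(ValueError):
            flat_segmentation([], h)

    def test_output_is_partition(self, rng):
        for _ in range(5):
            h = random_toy_hierarchy(rng)
            seg = CombinatorialGrouping().transform(h)
            labels = seg.labels
            assert labels.min() >= 1  # cover
            for lab in np.unique(labels):
                assert cc_label(labels == lab, connectivity=1).max() >= 1

    def test_boundaries_subset_of_finest_arcs(self, rng):
        h = random_toy_hierarchy(rng, n_strips=8)
        seg = CombinatorialGrouping().transform(h)
        fine, flat = h.finest.labels, seg.labels
        # wherever the flat segmentation changes label, the finest does too
        assert (
            (flat[:, :-1] != flat[:, 1:]) & (fine[:, :-1] == fine[:, 1:])
        ).sum() == 0
        assert (
            (flat[:-1, :] != flat[1:, :]) & (fine[:-1, :] == fine[1:, :])
        ).sum() == 0

    def test_three_region_toy_groups_weak_pair(self):
        h = three_region_hierarchy()
        seg = CombinatorialGrouping().transform(h)
        labels = seg.labels
        # the 0.2 boundary disappears, the 0.8 boundary survives
        assert labels[0, 0] == labels[0, 4]
        assert labels[0, 0] != labels[0, 8]


def test_end_to_end_two_field_toy(two_field_scene):
    """Cues → OWT-UCM → grouping recovers the two fields of the easiest
    scene within a 5-px boundary tolerance."""
    from fieldseg.cues import CueConfig, mpb
    from fieldseg.evaluation import (
        MatchConfig,
        extract_edgels,
        match_edgels,
        precision_recall,
    )
    from fieldseg.owt import OWTUCM
    from fieldseg.reference import prepare_reference

    _, truth = two_field_scene
    sig = mpb(truth.image, CueConfig(use_texture=False, scales=(4, 8, 16)))
    hier = OWTUCM().transform(sig)
    seg = CombinatorialGrouping().transform(hier)
    assert seg.n_regions == 2
    b = seg.boundary_mask()
    ref = prepare_reference(truth.boundary_lines, truth.image.grid)
    det_e = extract_edgels(b)
    ref_e = extract_edgels(ref.mask)
    corr = match_edgels(det_e, ref_e, MatchConfig(d_max=5))
    pr = precision_recall(corr, len(det_e), len(ref_e))
    assert pr.f_measure > 0.8


def test_candidates_cover_true_fields_at_least_as_well_as_thresholds(two_field_scene):
    """For each true field, the best candidate Jaccard is at least the best
    Jaccard achievable by any single UCM threshold (candidates include every
    hierarchy node, and threshold regions are hierarchy nodes)."""
    from fieldseg.cues import CueConfig, mpb
    from fieldseg.owt import OWTUCM, threshold_ucm

    _, truth = two_field_scene
    sig = mpb(truth.image, CueConfig(use_texture=False, scales=(4, 8, 16)))
    hier = OWTUCM().transform(sig)
    cands = enumerate_candidates(hier, max_candidates=100_000)
    fine = hier.finest.labels

    def jaccard(mask_a, mask_b):
        inter = (mask_a & mask_b).sum()
        union = (mask_a | mask_b).sum()
        return inter / union if union else 0.0

    levels = sorted({m[3] for m in hier.merges})
    for fid in np.unique(truth.label_map):
        if fid == 0:
            continue
        true_mask = truth.label_map == fid
        best_cand = max(
            jaccard(np.isin(fine, list(c.leaf_set)), true_mask) for c in cands
        )
        best_thresh = 0.0
        for k in [0.0] + levels:
            part = threshold_ucm(hier, k).labels
            for lab in np.unique(part):
                best_thresh = max(best_thresh, jaccard(part == lab, true_mask))
        assert best_cand >= best_thresh - 1e-12
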