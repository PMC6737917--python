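"""Oriented watershed transform and ultrametric contour maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fieldseg.cues import OrientedContourSignal
from fieldseg.grids import RasterGrid
from fieldseg.owt import (
    FinestPartition,
    build_ucm,
    reweight_arcs,
    threshold_ucm,
    watershed_partition,
)

from conftest import random_toy_hierarchy, scalar_signal, strip_partition


def oriented(strength):
    return OrientedContourSignal(
        grid=RasterGrid(width=strength.shape[2], height=strength.shape[1]),
        strength=strength,
    )


class TestWatershed:
    def test_constant_signal_single_region(self):
        part = watershed_partition(scalar_signal(np.zeros((16, 16))))
        assert part.n_regions == 1 and len(part.arcs) == 0

    def test_closed_ring_two_regions(self):
        s = np.zeros((32, 32))
        rr, cc = np.mgrid[0:32, 0:32]
        s[np.abs(np.hypot(rr - 16, cc - 16) - 8) < 0.7] = 1.0
        part = watershed_partition(scalar_signal(s))
        assert part.n_regions == 2
        # flood-fill oracle: inside/outside labels differ
        labels = part.labels
        assert labels[16, 16] != labels[0, 0]
        # arcs cover the ring: every arc edge is near the circle
        for arc in part.arcs:
            for r, c, _ in arc.edges:
                assert abs(np.hypot(r - 16, c - 16) - 8) < 3

    def test_two_parallel_ridges_three_regions(self):
        s = np.zeros((32, 32))
        s[10, :] = 1.0
        s[20, :] = 1.0
        part = watershed_partition(scalar_signal(s))
        assert part.n_regions == 3

    def test_partition_validity(self, two_field_scene):
        from fieldseg.cues import CueConfig, mpb
        from skimage.measure import label as cc_label

        _, truth = two_field_scene
        sig = mpb(truth.image, CueConfig(use_texture=False, scales=(2, 4)))
        part = watershed_partition(sig)
        labels = part.labels
        assert labels.min() >= 1  # full cover
        for lab in np.unique(labels):
            assert cc_label(labels == lab, connectivity=1).max() == 1
        # every arc separates exactly two distinct regions
        for arc in part.arcs:
            a, b = arc.pair
            assert a != b
            for r, c, kind in arc.edges:
                p, q = (
                    (labels[r, c], labels[r, c + 1])
                    if kind == "v"
                    else (labels[r, c], labels[r + 1, c])
                )
                assert {p, q} == {a, b}


class TestReweight:
    def test_isotropic_signal_reduces_to_mean(self, rng):
        part = strip_partition([4, 4, 4])
        scalar = rng.random((6, 12))
        strengths, _ = reweight_arcs(part, scalar_signal(scalar))
        for arc, s in zip(part.arcs, strengths):
            vals = []
            for r, c, kind in arc.edges:
                if kind == "v":
                    vals.append(0.5 * (scalar[r, c] + scalar[r, c + 1]))
                else:
                    vals.append(0.5 * (scalar[r, c] + scalar[r + 1, c]))
            assert s == pytest.approx(np.mean(vals))

    def test_oriented_arc_selects_tangent_bin(self):
        # horizontal boundary between two horizontal strips
        labels = np.ones((10, 12), dtype=np.int32)
        labels[5:, :] = 2
        from fieldseg.owt import _boundary_edges, _trace_arcs

        part = FinestPartition(labels=labels, arcs=_trace_arcs(_boundary_edges(labels)))
        st_ = np.zeros((8, 10, 12))
        st_[0] = 1.0  # horizontal-tangent bin
        s_tan, _ = reweight_arcs(part, oriented(st_))
        assert s_tan[0] == pytest.approx(1.0)
        st_ = np.zeros((8, 10, 12))
        st_[4] = 1.0  # orthogonal bin
        s_orth, _ = reweight_arcs(part, oriented(st_))
        assert s_orth[0] == pytest.approx(0.0)


class TestUCM:
    def test_three_region_hand_simulated_merge(self):
        part = strip_partition([3, 3, 3])
        strengths = [0.2 if arc.pair == (1, 2) else 0.8 for arc in part.arcs]
        h = build_ucm(part, strengths)
        assert [m[3] for m in h.merges] == pytest.approx([0.2, 0.8])
        assert h.merges[0][:2] == (1, 2)
        assert sorted(set(round(v, 6) for v in h.edge_values.values())) == [0.2, 0.8]
        assert threshold_ucm(h, 0.5).n_regions == 2
        assert threshold_ucm(h, 0.0).n_regions == 3  # zero preserves all edges
        assert threshold_ucm(h, 1.0).n_regions == 1

    def test_merge_count(self, rng):
        h = random_toy_hierarchy(rng, n_strips=9)
        assert len(h.merges) == 8

    def test_merge_strengths_non_decreasing(self, rng):
        for _ in range(5):
            h = random_toy_hierarchy(rng)
            s = [m[3] for m in h.merges]
            assert all(a <= b + 1e-12 for a, b in zip(s, s[1:]))

    def test_threshold_nesting(self, rng):
        """Regions at a high threshold are unions of regions at a low one."""
        h = random_toy_hierarchy(rng, n_strips=8)
        fine = threshold_ucm(h, 0.3).labels
        coarse = threshold_ucm(h, 0.7).labels
        for lab in np.unique(fine):
            covered = coarse[fine == lab]
            assert len(np.unique(covered)) == 1

    def test_region_count_monotone_in_threshold(self, rng):
        h = random_toy_hierarchy(rng, n_strips=10)
        counts = [threshold_ucm(h, k).n_regions for k in np.linspace(0, 1, 11)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ultrametric_property(self, seed):
        """The threshold at which two leaves first share a region equals
        the max merge strength on the merge-tree path between them."""
        rng = np.random.default_rng(seed)
        h = random_toy_hierarchy(rng)
        n = h.finest.n_regions
        # brute-force co-occurrence threshold for each leaf pair
        for a in range(1, n + 1):
            for b in range(a + 1, n + 1):
                # walk the merge list; leaves join when their sets meet
                sets = {i: {i} for i in range(1, n + 1)}
                node_sets = dict(sets)
                joined_at = None
                for ia, ib, new, s in h.merges:
                    node_sets[new] = node_sets[ia] | node_sets[ib]
                    if joined_at is None and a in node_sets[new] and b in node_sets[new]:
                        joined_at = s
                # threshold sweep oracle
                for k in sorted({m[3] for m in h.merges}):
                    part = threshold_ucm(h, k)
                    la = part.labels[h.finest.labels == a][0]
                    lb = part.labels[h.finest.labels == b][0]
                    if la == lb:
                        assert k == pytest.approx(joined_at)
                        break

    def test_ucm_raster_thresholds_close_regions(self, rng):
        h = random_toy_hierarchy(rng, n_strips=6)
        raster = h.ucm_raster()
        assert raster.min() >= 0 and raster.max() <= 1
        # boundaries in the raster appear exactly where edges have value > k
        k = 0.5
        part = threshold_ucm(h, k)
        # interior columns of surviving boundaries carry raster > k
        boundary_cols = np.nonzero((part.labels[:, :-1] != part.labels[:, 1:]).any(axis=0))[0]
        for c in boundary_cols:
            assert raster[:, c].max() > k

    def test_inconsistent_strengths_rejected(self):
        part = strip_partition([3, 3])
        with pytest.raises(ValueError):
            build_ucm(part, [0.5, 0.5])
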