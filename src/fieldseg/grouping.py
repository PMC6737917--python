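"""Single-scale combinatorial grouping: from a UCM hierarchy to a flat
field segmentation.

Candidate regions are all nodes of the hierarchy (every region at every
level) plus connected combinations of up to ``max_combine`` adjacent
regions sampled from the partitions along the hierarchy, deduplicated by
their pixel set (every candidate is a union of finest regions).  Each
candidate is scored by its UCM persistence — the threshold interval between
the disappearance of its strongest interior boundary (birth) and of its
weakest outer boundary (death) — so complete fields (strong closed outline,
weak inside) outrank both fragments and over-merged regions.  The final
segmentation is a greedy non-overlapping selection in decreasing score;
pixels left uncovered join the adjacent accepted segment with the weakest
separating boundary.  The procedure needs no threshold parameter.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .owt import RegionPartition, UCMHierarchy

__all__ = [
    "CandidateRegion",
    "enumerate_candidates",
    "score_candidate",
    "flat_segmentation",
    "segment_polygons",
    "CombinatorialGrouping",
]

# strength assigned to image-frame pixel sides (the scene outline is always
# a boundary)
FRAME_STRENGTH = 1.0


@dataclass
class CandidateRegion:
    """A connected union of finest regions, with provenance and score."""

    leaf_set: frozenset  # finest-partition labels
    provenance: str  # "node" or "combo"
    score: float = 0.0
    area: int = 0


class _BoundaryTables:
    """Per-leaf-pair UCM sums/counts and per-leaf frame/area tables, so
    candidate scores are exact edge-level means computed in O(|adjacency|)."""

    def __init__(self, hierarchy: UCMHierarchy):
        labels = hierarchy.finest.labels
        self.leaf_area = dict(
            zip(*[a.tolist() for a in np.unique(labels, return_counts=True)])
        )
        self.pair_sum, self.pair_cnt = {}, {}
        for arc in hierarchy.finest.arcs:
            s = sum(hierarchy.edge_values[e] for e in arc.edges)
            self.pair_sum[arc.pair] = self.pair_sum.get(arc.pair, 0.0) + s
            self.pair_cnt[arc.pair] = self.pair_cnt.get(arc.pair, 0) + len(arc.edges)
        self.nbrs = {}
        for a, b in self.pair_cnt:
            self.nbrs.setdefault(a, set()).add(b)
            self.nbrs.setdefault(b, set()).add(a)
        # image-frame sides per leaf
        H, W = labels.shape
        self.frame_cnt = {}
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        ids, counts = np.unique(border, return_counts=True)
        for i, c in zip(ids.tolist(), counts.tolist()):
            self.frame_cnt[i] = c

    def area(self, leaf_set) -> int:
        return int(sum(self.leaf_area[l] for l in leaf_set))

    def score(self, leaf_set) -> float:
        """UCM persistence of the region: the threshold interval over which
        it exists as one piece.

        The region is born when its strongest interior boundary disappears
        and dies when its weakest outer boundary disappears, so the score is
        min over outer leaf-pair mean strengths (image-frame sides count as
        FRAME_STRENGTH) minus max over interior ones, clipped at 0.  Complete
        fields — strong closed outline, only weak structure inside — persist
        longest; fragments die at their weakest ridge and over-merged regions
        are born late."""
        outer = None
        inner = 0.0
        seen = set()
        has_frame = False
        for l in leaf_set:
            if self.frame_cnt.get(l, 0):
                has_frame = True
            for m in self.nbrs.get(l, ()):
                pair = (min(l, m), max(l, m))
                if pair in seen:
                    continue
                seen.add(pair)
                v = self.pair_sum[pair] / self.pair_cnt[pair]
                if m in leaf_set:
                    inner = max(inner, v)
                else:
                    outer = v if outer is None else min(outer, v)
        if outer is None:
            outer = FRAME_STRENGTH if has_frame else 0.0
        return max(0.0, outer - inner)


def _node_leaf_sets(hierarchy: UCMHierarchy):
    n = hierarchy.finest.n_regions
    node_leaves = {i: frozenset([i]) for i in range(1, n + 1)}
    for ia, ib, new, _ in hierarchy.merges:
        node_leaves[new] = node_leaves[ia] | node_leaves[ib]
    return node_leaves


def enumerate_candidates(
    hierarchy: UCMHierarchy,
    max_combine: int = 3,
    max_candidates: int = 2000,
    n_levels: int = 12,
) -> list:
    """All hierarchy node regions plus adjacent pair/triplet combinations
    sampled along the hierarchy, deduplicated and capped by score."""
    tables = _BoundaryTables(hierarchy)
    node_leaves = _node_leaf_sets(hierarchy)
    seen = set()
    out = []

    def add(leaf_set, provenance):
        if leaf_set in seen:
            return
        seen.add(leaf_set)
        out.append(
            CandidateRegion(
                leaf_set=leaf_set,
                provenance=provenance,
                score=tables.score(leaf_set),
                area=tables.area(leaf_set),
            )
        )

    for ls in node_leaves.values():
        add(ls, "node")

    if max_combine >= 2 and hierarchy.merges:
        n = hierarchy.finest.n_regions
        levels = sorted(
            {int(round(t)) for t in np.linspace(0, len(hierarchy.merges) - 1, n_levels)}
        )
        # walk the merge sequence, maintaining the current partition as
        # groups of leaves with adjacency from the leaf tables
        parent = {i: i for i in range(1, n + 1)}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        group_leaves = {i: frozenset([i]) for i in range(1, n + 1)}

        def sample_level():
            roots = {find(i) for i in group_leaves}
            regions = {r: group_leaves[r] for r in roots}
            adj = {r: set() for r in roots}
            for a, b in tables.pair_cnt:
                ra, rb = find(a), find(b)
                if ra != rb:
                    adj[ra].add(rb)
                    adj[rb].add(ra)
            for r in sorted(regions):
                for s in sorted(adj[r]):
                    if s > r:
                        add(regions[r] | regions[s], "combo")
                        if max_combine >= 3:
                            for t in sorted(adj[r] & adj[s]):
                                if t > s:
                                    add(
                                        regions[r] | regions[s] | regions[t],
                                        "combo",
                                    )

        step = 0
        for lvl in levels:
            while step <= lvl:
                ia, ib, new, _ = hierarchy.merges[step]
                # merge the two groups
                la = next(iter(_leaves_of(node_leaves, ia)))
                lb = next(iter(_leaves_of(node_leaves, ib)))
                ra, rb = find(la), find(lb)
                if ra != rb:
                    parent[rb] = ra
                    group_leaves[ra] = group_leaves[ra] | group_leaves.pop(rb)
                step += 1
            sample_level()

    out.sort(key=lambda c: (-c.score, c.area, sorted(c.leaf_set)))
    return out[:max_candidates]


def _leaves_of(node_leaves, node_id):
    return node_leaves[node_id]


def score_candidate(region: CandidateRegion, hierarchy: UCMHierarchy) -> float:
    """Boundary-contrast score (standalone recomputation)."""
    return _BoundaryTables(hierarchy).score(region.leaf_set)


def flat_segmentation(
    candidates: list,
    hierarchy: UCMHierarchy,
    overlap_tolerance: float = 0.05,
    min_area_frac: float = 0.004,
) -> RegionPartition:
    """Greedy non-overlapping selection in decreasing score; overlapping
    pixels stay with the earlier (higher-scored) segment; uncovered finest
    regions join the adjacent accepted segment across the weakest boundary.

    Candidates smaller than ``min_area_frac`` of the scene are not
    selectable (thin boundary-sliver watershed cells persist as long as
    their surrounding ridge, but are not fields); their pixels are absorbed
    by the residual rule instead."""
    if not candidates:
        raise ValueError("candidate list is empty")
    tables = _BoundaryTables(hierarchy)
    min_area = min_area_frac * hierarchy.finest.labels.size
    order = sorted(
        candidates, key=lambda c: (-c.score, c.area, sorted(c.leaf_set))
    )
    assigned = {}  # leaf -> segment id
    next_seg = 0
    for cand in order:
        if cand.area < min_area:
            continue
        taken = [l for l in cand.leaf_set if l in assigned]
        taken_area = sum(tables.leaf_area[l] for l in taken)
        if taken_area >= overlap_tolerance * max(tables.area(cand.leaf_set), 1):
            continue
        next_seg += 1
        for l in cand.leaf_set:
            if l not in assigned:
                assigned[l] = next_seg
    if next_seg == 0:  # every candidate under the area floor: take the best
        next_seg = 1
        for l in order[0].leaf_set:
            assigned[l] = 1
    # residual leaves: weakest separating boundary to an assigned neighbour
    all_leaves = set(tables.leaf_area)
    heap = []
    for l in sorted(all_leaves - set(assigned)):
        for m in tables.nbrs.get(l, ()):
            if m in assigned:
                pair = (min(l, m), max(l, m))
                w = tables.pair_sum[pair] / tables.pair_cnt[pair]
                heapq.heappush(heap, (w, l, m))
    while heap:
        w, l, m = heapq.heappop(heap)
        if l in assigned or m not in assigned:
            continue
        assigned[l] = assigned[m]
        for x in tables.nbrs.get(l, ()):
            if x not in assigned:
                pair = (min(l, x), max(l, x))
                wx = tables.pair_sum[pair] / tables.pair_cnt[pair]
                heapq.heappush(heap, (wx, x, l))
    if set(assigned) != all_leaves:
        # disconnected leftovers (no assigned neighbour anywhere): own segments
        for l in sorted(all_leaves - set(assigned)):
            next_seg += 1
            assigned[l] = next_seg
    labels = hierarchy.finest.labels
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for l, s in assigned.items():
        remap[l] = s
    return RegionPartition(labels=remap[labels])


def segment_polygons(partition: RegionPartition, grid) -> list:
    """Polygonal outline per segment in map coordinates: union of per-row
    pixel runs mapped through the grid's affine transform.  Returns
    (segment_id, shapely geometry) pairs."""
    from shapely.geometry import Polygon
    from shapely.ops import unary_union

    labels = partition.labels
    out = []
    for lab in np.unique(labels):
        rects = []
        for r in range(labels.shape[0]):
            row = labels[r] == lab
            if not row.any():
                continue
            d = np.diff(np.concatenate([[0], row.view(np.int8), [0]]))
            starts = np.nonzero(d == 1)[0]
            ends = np.nonzero(d == -1)[0]
            for c0, c1 in zip(starts, ends):
                xs, ys = zip(
                    *[
                        grid.pixel_to_world(rr, cc, center=False)
                        for rr, cc in [(r, c0), (r, c1), (r + 1, c1), (r + 1, c0)]
                    ]
                )
                rects.append(Polygon(zip(xs, ys)))
        out.append((int(lab), unary_union(rects)))
    return out


class CombinatorialGrouping(BaseEstimator):
    """Transformer-shaped surface: UCM hierarchy → flat segmentation."""

    def __init__(
        self,
        max_combine: int = 3,
        max_candidates: int = 2000,
        overlap_tolerance: float = 0.05,
        min_area_frac: float = 0.004,
        n_levels: int = 12,
    ):
        self.max_combine = max_combine
        self.max_candidates = max_candidates
        self.overlap_tolerance = overlap_tolerance
        self.min_area_frac = min_area_frac
        self.n_levels = n_levels

    def fit(self, X=None, y=None):
        return self

    def transform(self, hierarchy: UCMHierarchy) -> RegionPartition:
        cands = enumerate_candidates(
            hierarchy,
            max_combine=self.max_combine,
            max_candidates=self.max_candidates,
            n_levels=self.n_levels,
        )
        return flat_segmentation(
            cands, hierarchy, self.overlap_tolerance, self.min_area_frac
        )
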