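"""Oriented watershed transform and ultrametric contour maps.

From an oriented contour signal, the watershed of the max-over-orientations
strength surface (flooded from its regional minima) gives the finest
partition — an over-segmentation whose boundaries sit on the signal's
ridges.  Region boundaries are represented on the interpixel grid: an
*edge* separates two 4-adjacent pixels with different labels; maximal
same-region-pair chains of edges, split at junction corners, are *arcs*.

Arcs are re-weighted by the oriented signal: each arc is approximated by
short straight segments (≤ 5 edges) and every edge takes the signal value
at the orientation bin nearest its segment's direction (orientation bins
index the boundary tangent, matching the cue module's convention).

Greedy agglomeration then repeatedly merges the pair of adjacent regions
whose common boundary has the lowest average strength; recording each merge
at the running maximum of strengths enforces the ultrametric property.  The
resulting real-valued boundary map (the UCM) assigns each boundary its
"scale of disappearance": thresholding at any k yields closed, nested
partitions, with k = 0 preserving the full over-segmentation.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import h_minima, local_minima
from skimage.measure import label as cc_label
from skimage.segmentation import watershed as _sk_watershed
from sklearn.base import BaseEstimator

from .cues import OrientedContourSignal
from .grids import RasterGrid

__all__ = [
    "Arc",
    "FinestPartition",
    "UCMHierarchy",
    "RegionPartition",
    "partition_boundary",
    "watershed_partition",
    "reweight_arcs",
    "build_ucm",
    "threshold_ucm",
    "OWTUCM",
]

# An interpixel edge is (r, c, kind): kind "v" separates (r, c)|(r, c+1)
# (the boundary element is vertical), kind "h" separates (r, c)|(r+1, c).


@dataclass
class Arc:
    pair: tuple  # (label_a, label_b), a < b
    edges: list  # ordered chain of (r, c, kind)


@dataclass
class FinestPartition:
    labels: np.ndarray  # (H, W) int, 1..n_regions, 4-connected regions
    arcs: list

    @property
    def n_regions(self) -> int:
        return int(self.labels.max())

    def region_adjacency(self) -> dict:
        adj = {}
        for i, arc in enumerate(self.arcs):
            adj.setdefault(arc.pair, []).append(i)
        return adj


@dataclass
class RegionPartition:
    """Flat labeling of pixels into closed segments."""

    labels: np.ndarray

    @property
    def n_regions(self) -> int:
        return len(np.unique(self.labels))

    def boundary_mask(self, include_frame: bool = True) -> np.ndarray:
        """Binary boundary raster of the partition; the scene outline is a
        boundary of every partition and is included by default (reference
        boundary sets include it too)."""
        return partition_boundary(self.labels, include_frame)


def partition_boundary(labels: np.ndarray, include_frame: bool = True) -> np.ndarray:
    b = np.zeros(labels.shape, dtype=bool)
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    if include_frame:
        b[0, :] = b[-1, :] = True
        b[:, 0] = b[:, -1] = True
    return b


@dataclass
class UCMHierarchy:
    finest: FinestPartition
    merges: list  # (id_a, id_b, new_id, strength), strengths non-decreasing
    edge_values: dict  # (r, c, kind) -> ucm value ("scale of disappearance")

    def ucm_raster(self, frame_strength: float = 1.0) -> np.ndarray:
        """Pixel-raster export: each pixel takes the max UCM value of its
        incident interpixel edges (0 where no boundary touches it).  The
        scene outline is a boundary of the partition at every threshold and
        is written at ``frame_strength`` (0 to omit it)."""
        H, W = self.finest.labels.shape
        out = np.zeros((H, W), dtype=np.float32)
        for (r, c, kind), v in self.edge_values.items():
            if kind == "v":
                out[r, c] = max(out[r, c], v)
                out[r, c + 1] = max(out[r, c + 1], v)
            else:
                out[r, c] = max(out[r, c], v)
                out[r + 1, c] = max(out[r + 1, c], v)
        if frame_strength > 0:
            out[0, :] = np.maximum(out[0, :], frame_strength)
            out[-1, :] = np.maximum(out[-1, :], frame_strength)
            out[:, 0] = np.maximum(out[:, 0], frame_strength)
            out[:, -1] = np.maximum(out[:, -1], frame_strength)
        return out

    def merge_strength_of_pixel_pairs(self):  # pragma: no cover - debug aid
        return self.edge_values


# ---------------------------------------------------------------------------
# finest partition


def _boundary_edges(labels: np.ndarray):
    """All interpixel edges between 4-adjacent pixels of different labels,
    with their region pair."""
    edges = []
    H, W = labels.shape
    dv = labels[:, :-1] != labels[:, 1:]
    for r, c in zip(*np.nonzero(dv)):
        a, b = int(labels[r, c]), int(labels[r, c + 1])
        edges.append(((r, c, "v"), (min(a, b), max(a, b))))
    dh = labels[:-1, :] != labels[1:, :]
    for r, c in zip(*np.nonzero(dh)):
        a, b = int(labels[r, c]), int(labels[r + 1, c])
        edges.append(((r, c, "h"), (min(a, b), max(a, b))))
    return edges


def _edge_corners(edge):
    """The two lattice corners an edge connects (corner (i, j) = top-left
    corner of pixel (i, j))."""
    r, c, kind = edge
    if kind == "v":
        return (r, c + 1), (r + 1, c + 1)
    return (r + 1, c), (r + 1, c + 1)


def _trace_arcs(edges_with_pairs) -> list:
    """Group edges by region pair and split each group into ordered chains
    at junction corners (corners touched by ≥ 3 boundary edges)."""
    corner_degree = {}
    for edge, _ in edges_with_pairs:
        for corner in _edge_corners(edge):
            corner_degree[corner] = corner_degree.get(corner, 0) + 1
    junctions = {c for c, d in corner_degree.items() if d >= 3}

    by_pair = {}
    for edge, pair in edges_with_pairs:
        by_pair.setdefault(pair, []).append(edge)

    arcs = []
    for pair in sorted(by_pair):
        edges = by_pair[pair]
        # corner -> incident edges of this pair, junctions acting as walls
        incident = {}
        for e in edges:
            for corner in _edge_corners(e):
                if corner not in junctions:
                    incident.setdefault(corner, []).append(e)
        unused = set(edges)

        def walk(start_edge):
            chain = [start_edge]
            unused.discard(start_edge)
            for direction in (0, 1):
                corner = _edge_corners(start_edge)[direction]
                while corner in incident:
                    nxt = [e for e in incident[corner] if e in unused]
                    if not nxt:
                        break
                    e = nxt[0]
                    unused.discard(e)
                    if direction == 0:
                        chain.insert(0, e)
                    else:
                        chain.append(e)
                    c0, c1 = _edge_corners(e)
                    corner = c1 if c0 == corner else c0
            return chain

        # start walks from chain ends (corners of degree 1 within the pair)
        for e in sorted(edges):
            if e in unused:
                arcs.append(Arc(pair=pair, edges=walk(e)))
    return arcs


def watershed_partition(
    signal: OrientedContourSignal,
    presmooth_sigma: float = 0.5,
    min_depth: float = 0.02,
) -> FinestPartition:
    """Watershed of the max-over-orientations surface from its regional
    minima; ridge pixels become interpixel arcs split at junctions.

    The surface is lightly smoothed and regional minima shallower than
    ``min_depth`` are suppressed (h-minima) before flooding, so the finest
    partition reflects contour ridges rather than per-pixel noise; both
    steps can be disabled by passing 0."""
    s = signal.max_over_orientations().astype(np.float64)
    if s.max() - s.min() <= 0:
        return FinestPartition(labels=np.ones(s.shape, dtype=np.int32), arcs=[])
    if presmooth_sigma > 0:
        s = gaussian_filter(s, presmooth_sigma)
    if min_depth > 0:
        minima = h_minima(s, min_depth)
        if not minima.any():
            minima = local_minima(s, connectivity=1)
    else:
        minima = local_minima(s, connectivity=1)
    markers = cc_label(minima, connectivity=1)
    labels = _sk_watershed(s, markers=markers, connectivity=1)
    labels = labels.astype(np.int32)
    arcs = _trace_arcs(_boundary_edges(labels))
    return FinestPartition(labels=labels, arcs=arcs)


# ---------------------------------------------------------------------------
# oriented re-weighting


def _segment_bins(arc: Arc, n_orientations: int, max_seg: int = 5):
    """Orientation bin per edge: the arc is cut into chains of ≤ max_seg
    edges whose endpoint corners define the segment direction."""
    bins = np.empty(len(arc.edges), dtype=int)
    for s0 in range(0, len(arc.edges), max_seg):
        seg = arc.edges[s0 : s0 + max_seg]
        (r0, c0) = _edge_corners(seg[0])[0]
        (r1, c1) = _edge_corners(seg[-1])[1]
        dr, dc = r1 - r0, c1 - c0
        if dr == 0 and dc == 0:  # closed loop segment: use first edge
            (r0, c0), (r1, c1) = _edge_corners(seg[0])
            dr, dc = r1 - r0, c1 - c0
        theta = np.arctan2(dr, dc) % np.pi
        b = int(np.round(theta / (np.pi / n_orientations))) % n_orientations
        bins[s0 : s0 + len(seg)] = b
    return bins


def _edge_pixel_values(edge, band: np.ndarray) -> float:
    r, c, kind = edge
    if kind == "v":
        return 0.5 * (band[r, c] + band[r, c + 1])
    return 0.5 * (band[r, c] + band[r + 1, c])


def reweight_arcs(
    partition: FinestPartition, signal: OrientedContourSignal, max_seg: int = 5
):
    """Per-edge oriented weights and per-arc mean strength.

    Returns (arc_strengths, edge_weights): arc_strengths[i] is the mean of
    its edges' weights; edge_weights maps (r, c, kind) -> weight."""
    n_or = signal.n_orientations
    strengths = np.zeros(len(partition.arcs))
    edge_weights = {}
    for i, arc in enumerate(partition.arcs):
        bins = _segment_bins(arc, n_or, max_seg)
        vals = np.array(
            [
                _edge_pixel_values(e, signal.strength[b])
                for e, b in zip(arc.edges, bins)
            ]
        )
        for e, v in zip(arc.edges, vals):
            edge_weights[e] = float(v)
        strengths[i] = float(vals.mean()) if len(vals) else 0.0
    return strengths, edge_weights


# ---------------------------------------------------------------------------
# ultrametric contour map


def build_ucm(
    partition: FinestPartition, arc_strengths, edge_weights: dict = None
) -> UCMHierarchy:
    """Greedy agglomeration into an ultrametric hierarchy.

    Repeatedly removes the region pair whose common boundary has the lowest
    average strength, recording the merge at max(previous strength, average)
    so merge strengths are non-decreasing.  Averages are recomputed exactly
    after every merge.
    """
    arc_strengths = np.asarray(arc_strengths, dtype=float)
    n = partition.n_regions
    if len(arc_strengths) != len(partition.arcs):
        raise ValueError("one strength per arc required")
    if edge_weights is None:
        edge_weights = {
            e: float(s)
            for arc, s in zip(partition.arcs, arc_strengths)
            for e in arc.edges
        }
    # union-find over leaf labels; leaves are 1..n
    root = {i: i for i in range(1, n + 1)}
    node_of = {i: i for i in range(1, n + 1)}  # uf root -> hierarchy node id

    def find(i):
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return i

    # per root-pair common boundary: exact sum/count of edge weights + edges
    pair_edges, pair_sum, pair_cnt = {}, {}, {}
    nbrs = {}
    for arc in partition.arcs:
        p = arc.pair
        pair_edges.setdefault(p, []).extend(arc.edges)
    for p, edges in pair_edges.items():
        pair_sum[p] = float(sum(edge_weights[e] for e in edges))
        pair_cnt[p] = len(edges)
        a, b = p
        nbrs.setdefault(a, set()).add(b)
        nbrs.setdefault(b, set()).add(a)

    version = {p: 0 for p in pair_edges}
    heap = [
        (pair_sum[p] / pair_cnt[p], p, 0) for p in pair_edges
    ]
    heapq.heapify(heap)

    merges = []
    edge_values = {}
    next_id = n + 1
    level = 0.0
    n_merges = 0
    while heap and n_merges < n - 1:
        avg, best, ver = heapq.heappop(heap)
        if best not in version or version[best] != ver:
            continue
        a, b = best
        level = max(level, avg)
        for e in pair_edges[best]:
            edge_values[e] = level
        merges.append((node_of[a], node_of[b], next_id, level))
        n_merges += 1
        # merge b into a; re-key b's remaining boundaries onto a
        for d in (pair_edges, pair_sum, pair_cnt, version):
            del d[best]
        root[b] = a
        node_of[a] = next_id
        node_of.pop(b, None)
        next_id += 1
        nbrs[a].discard(b)
        nbrs[b].discard(a)
        for x in nbrs.pop(b):
            old = (min(b, x), max(b, x))
            new = (min(a, x), max(a, x))
            nbrs[x].discard(b)
            nbrs[x].add(a)
            nbrs[a].add(x)
            if new in pair_edges:
                pair_edges[new].extend(pair_edges.pop(old))
                pair_sum[new] += pair_sum.pop(old)
                pair_cnt[new] += pair_cnt.pop(old)
            else:
                pair_edges[new] = pair_edges.pop(old)
                pair_sum[new] = pair_sum.pop(old)
                pair_cnt[new] = pair_cnt.pop(old)
            version.pop(old, None)
            version[new] = version.get(new, -1) + 1
            heapq.heappush(
                heap, (pair_sum[new] / pair_cnt[new], new, version[new])
            )
    if n_merges != n - 1:
        raise ValueError("inconsistent adjacency: hierarchy did not reach one region")
    return UCMHierarchy(finest=partition, merges=merges, edge_values=edge_values)


def threshold_ucm(hierarchy: UCMHierarchy, k: float) -> RegionPartition:
    """Partition whose boundaries are exactly the UCM edges with value > k;
    thresholds are nested (larger k coarsens smaller k)."""
    n = hierarchy.finest.n_regions
    parent = list(range(n + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    leaf_sets = {i: [i] for i in range(1, n + 1)}
    node_leaves = dict(leaf_sets)
    for ia, ib, new, s in hierarchy.merges:
        la = node_leaves[ia]
        lb = node_leaves[ib]
        node_leaves[new] = la + lb
        if s <= k:
            parent[find(la[0])] = find(lb[0])
    remap = np.arange(n + 1)
    roots = {}
    out_id = 0
    for leaf in range(1, n + 1):
        r = find(leaf)
        if r not in roots:
            out_id += 1
            roots[r] = out_id
        remap[leaf] = roots[r]
    return RegionPartition(labels=remap[hierarchy.finest.labels])


class OWTUCM(BaseEstimator):
    """Transformer-shaped surface: oriented signal → UCM hierarchy."""

    def __init__(
        self,
        max_seg: int = 5,
        presmooth_sigma: float = 0.5,
        min_depth: float = 0.02,
    ):
        self.max_seg = max_seg
        self.presmooth_sigma = presmooth_sigma
        self.min_depth = min_depth

    def fit(self, X=None, y=None):
        return self

    def transform(self, signal: OrientedContourSignal) -> UCMHierarchy:
        part = watershed_partition(signal, self.presmooth_sigma, self.min_depth)
        if not part.arcs:
            return UCMHierarchy(finest=part, merges=[], edge_values={})
        strengths, edge_weights = reweight_arcs(part, signal, self.max_seg)
        return build_ucm(part, strengths, edge_weights)
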