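"""Vector boundary lines → uniform-thickness raster reference boundaries.

Three steps: (1) select candidate boundary pixels whose center lies within a
ground distance (default 1 m) of the lines, (2) morphological thinning to a
1-px skeleton, (3) dilation + closing with a 3x3 square, yielding a raster
boundary of uniform ~3 px thickness suitable as training/evaluation truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.ops import unary_union
from skimage.morphology import closing as _sk_closing, dilation as _sk_dilation, thin as _sk_thin

from .grids import RasterGrid
from .io import VectorBoundarySet

__all__ = [
    "BoundaryMask",
    "select_candidates",
    "thin",
    "dilate_close",
    "prepare_reference",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass
class BoundaryMask:
    """Binary per-pixel boundary raster on a grid."""

    grid: RasterGrid
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")


def select_candidates(
    lines: VectorBoundarySet, grid: RasterGrid, dist_m: float = 1.0
) -> BoundaryMask:
    """Pixels whose center is within ``dist_m`` (Euclidean, to the line
    segments themselves) of any boundary line."""
    if dist_m <= 0:
        raise ValueError("dist_m must be positive")
    if lines.crs != grid.crs:
        raise ValueError(f"CRS mismatch: lines {lines.crs} vs grid {grid.crs}")
    if len(lines) == 0:
        return BoundaryMask(grid=grid, mask=np.zeros(grid.shape, dtype=bool))
    union = unary_union(lines.geometries)
    xs, ys = grid.pixel_center_grid()
    pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    d = shapely.distance(pts, union).reshape(grid.shape)
    return BoundaryMask(grid=grid, mask=d <= dist_m)


def thin(mask: BoundaryMask) -> BoundaryMask:
    """Morphological thinning to a 1-px-wide 8-connected skeleton (homotopy
    preserving, so foreground connectivity is retained)."""
    return BoundaryMask(grid=mask.grid, mask=_sk_thin(mask.mask))


def dilate_close(mask: BoundaryMask, se: np.ndarray = _SQUARE3) -> BoundaryMask:
    """Dilation followed by closing with a square structuring element."""
    out = _sk_dilation(mask.mask, footprint=se)
    out = _sk_closing(out, footprint=se)
    # closing of a dilation is extensive w.r.t. the original mask
    return BoundaryMask(grid=mask.grid, mask=out | mask.mask)


def prepare_reference(
    lines: VectorBoundarySet, grid: RasterGrid, dist_m: float = 1.0
) -> BoundaryMask:
    """Full three-step preparation: candidates → thin → dilate+close."""
    return dilate_close(thin(select_candidates(lines, grid, dist_m)))
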