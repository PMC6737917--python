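"""Raster grid descriptor and pixel/world coordinate conventions.

Conventions used throughout the package: 0-based (row, col) indexing,
pixel-center sampling, and an affine map from *pixel* coordinates to world
coordinates.  The affine transform is the usual six-parameter GDAL-style
mapping applied to (col, row):

    x = a*col + b*row + c
    y = d*col + e*row + f

so that pixel (0, 0) maps its *corner* to (c, f) and its center to the image
of (0.5, 0.5).  North-up rasters have b = d = 0 and e < 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "MultibandRaster"]


@dataclass(frozen=True)
class RasterGrid:
    """Size + georeferencing of a raster; the common currency between stages."""

    width: int
    height: int
    transform: tuple = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs: str = "EPSG:32632"

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        if len(self.transform) != 6:
            raise ValueError("affine transform must have 6 coefficients")
        object.__setattr__(self, "transform", tuple(float(v) for v in self.transform))

    @property
    def shape(self) -> tuple:
        return (self.height, self.width)

    @property
    def resolution(self) -> float:
        """Ground size of a pixel (meters), from the affine scale."""
        a, b, _, d, e, _ = self.transform
        return float(np.sqrt(abs(a * e - b * d)))

    def pixel_to_world(self, rows, cols, center: bool = True):
        """Map row/col indices to world (x, y). ``center`` samples pixel centers."""
        a, b, c, d, e, f = self.transform
        off = 0.5 if center else 0.0
        cols = np.asarray(cols, dtype=float) + off
        rows = np.asarray(rows, dtype=float) + off
        return a * cols + b * rows + c, d * cols + e * rows + f

    def world_to_pixel(self, x, y):
        """Inverse map world (x, y) to fractional (row, col) pixel coordinates."""
        a, b, c, d, e, f = self.transform
        det = a * e - b * d
        if det == 0:
            raise ValueError("degenerate affine transform")
        x = np.asarray(x, dtype=float) - c
        y = np.asarray(y, dtype=float) - f
        col = (e * x - b * y) / det
        row = (-d * x + a * y) / det
        return row, col

    def pixel_center_grid(self):
        """World coordinates of every pixel center, as two (H, W) arrays."""
        rows, cols = np.mgrid[0 : self.height, 0 : self.width]
        return self.pixel_to_world(rows, cols)


@dataclass
class MultibandRaster:
    """A (bands, H, W) image with its grid. Bands are kept band-major."""

    data: np.ndarray
    grid: RasterGrid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, H, W)")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.grid.shape
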