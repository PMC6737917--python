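"""Standard-format I/O: GeoTIFF-style rasters and GeoJSON vectors.

Rasters are written as TIFF with the affine transform and CRS carried in a
JSON ImageDescription tag; reading refuses files without georeferencing so
that no silent coordinate assumptions are made.  Vectors are GeoJSON feature
collections; geometries round-trip through shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape

from .grids import MultibandRaster, RasterGrid

__all__ = [
    "VectorBoundarySet",
    "load_raster",
    "write_raster",
    "load_vector",
    "write_vector",
]


@dataclass
class VectorBoundarySet:
    """A set of shapely geometries with per-feature properties and a CRS."""

    geometries: list
    properties: list = None
    crs: str = "EPSG:32632"

    def __post_init__(self):
        if self.properties is None:
            self.properties = [{} for _ in self.geometries]
        if len(self.properties) != len(self.geometries):
            raise ValueError("one property dict per geometry required")

    def __len__(self):
        return len(self.geometries)


def write_raster(path, raster: MultibandRaster, dtype=None) -> None:
    data = raster.data if dtype is None else raster.data.astype(dtype)
    meta = {"transform": list(raster.grid.transform), "crs": raster.grid.crs}
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=json.dumps(meta),
    )


def load_raster(path) -> MultibandRaster:
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        transform = tuple(meta["transform"])
        crs = meta["crs"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path} carries no georeferencing metadata") from exc
    if data.ndim == 2:
        data = data[None]
    grid = RasterGrid(width=data.shape[2], height=data.shape[1], transform=transform, crs=crs)
    return MultibandRaster(data=data, grid=grid)


def write_vector(path, vectors: VectorBoundarySet) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(vectors.geometries, vectors.properties)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": vectors.crs}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def load_vector(path) -> VectorBoundarySet:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    try:
        crs = doc["crs"]["properties"]["name"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path} carries no CRS") from exc
    geoms, props = [], []
    for feat in doc["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return VectorBoundarySet(geometries=geoms, properties=props, crs=crs)
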