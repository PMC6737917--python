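import numpy as np
import pytest

from fieldseg.cues import OrientedContourSignal
from fieldseg.grids import RasterGrid
from fieldseg.owt import FinestPartition, _boundary_edges, _trace_arcs, build_ucm
from fieldseg.synthetic import SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A small scene with a handful of fields, no roads (fast to rasterize)."""
    params = SceneParams(
        width_px=128, height_px=128, n_fields=5, road_count=0,
        tree_density_per_ha=0.0, seed=11,
    )
    return params, generate_scene(params)


@pytest.fixture(scope="session")
def two_field_scene():
    """Two contrasting fields split by one boundary; the easiest toy."""
    params = SceneParams(
        width_px=64, height_px=64, n_fields=2, road_count=0,
        tree_density_per_ha=0.0, noise_sd=0.01, seed=5, lloyd_relax=False,
        merge_fraction=0.0,
    )
    return params, generate_scene(params)


def scalar_signal(s, n_orientations=8):
    """Lift a scalar strength map to an isotropic oriented signal."""
    s = np.asarray(s, dtype=float)
    return OrientedContourSignal(
        grid=RasterGrid(width=s.shape[1], height=s.shape[0]),
        strength=np.repeat(s[None], n_orientations, axis=0),
    )


def strip_partition(widths, height=6):
    """Vertical strips as a finest partition (labels 1..k left to right)."""
    labels = np.zeros((height, sum(widths)), dtype=np.int32)
    c = 0
    for i, w in enumerate(widths, start=1):
        labels[:, c : c + w] = i
        c += w
    arcs = _trace_arcs(_boundary_edges(labels))
    return FinestPartition(labels=labels, arcs=arcs)


def random_toy_hierarchy(rng, n_strips=None):
    """A random UCM hierarchy over vertical strips (≤ 12 regions)."""
    if n_strips is None:
        n_strips = int(rng.integers(2, 9))
    part = strip_partition([3] * n_strips)
    strengths = {}
    for arc in part.arcs:
        strengths.setdefault(arc.pair, rng.uniform(0.05, 1.0))
    arc_strengths = [strengths[a.pair] for a in part.arcs]
    return build_ucm(part, arc_strengths)
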