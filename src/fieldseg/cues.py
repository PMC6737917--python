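"""Oriented contour cues: multiscale half-disc gradients, spectral
globalization, and linear combination with the FCN boundary probability.

The local cue at a pixel, radius and orientation is the χ² distance between
value histograms of the two half-discs split by a diameter at that
orientation; summing over channels and scales gives the multiscale local
signal (mPb).  A spectral globalization step builds a sparse affinity graph
with the intervening-contour rule, takes the smallest generalized
eigenvectors of its Laplacian, and reads oriented contour information out
of their directional derivatives (sPb).  Their weighted sum is the
globalized boundary probability (gPb), which can be linearly combined with
the (orientation-lifted) FCN probability into one oriented contour signal.
An optional lightweight texton channel (small filter bank + seeded k-means)
adds a texture cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as _sig, sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import eigsh
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .fcn import BoundaryProbabilityMap
from .grids import MultibandRaster, RasterGrid

__all__ = [
    "OrientedContourSignal",
    "CueConfig",
    "half_disc_gradient",
    "mpb",
    "spectral_globalization",
    "gpb",
    "combine_with_fcn",
    "CueExtractor",
    "orientation_bins",
]


@dataclass
class OrientedContourSignal:
    """Per-pixel, per-orientation boundary strength in [0, 1].

    ``strength`` has shape (n_orientations, H, W); orientations cover
    [0, π) in equal steps (bin o ↔ angle o·π/n)."""

    grid: RasterGrid
    strength: np.ndarray

    def __post_init__(self):
        self.strength = np.asarray(self.strength, dtype=np.float32)
        if self.strength.ndim != 3:
            raise ValueError("strength must be (n_orientations, H, W)")
        if self.strength.shape[1:] != self.grid.shape:
            raise ValueError("strength shape does not match grid")
        if self.strength.min() < -1e-6:
            raise ValueError("oriented strength must be non-negative")

    @property
    def n_orientations(self) -> int:
        return self.strength.shape[0]

    @property
    def orientations(self) -> np.ndarray:
        return orientation_bins(self.n_orientations)

    def max_over_orientations(self) -> np.ndarray:
        return self.strength.max(axis=0)


def orientation_bins(n: int) -> np.ndarray:
    return np.arange(n) * np.pi / n


@dataclass(frozen=True)
class CueConfig:
    # disc radii at or above the crop-row stripe period, so within-field
    # row texture averages out while between-field transitions respond
    scales: tuple = (4, 8, 16)
    n_orientations: int = 8
    n_bins: int = 12
    channel_weights: tuple = None  # None → equal weights
    use_texture: bool = True
    n_textons: int = 32
    texture_scale: int = 10
    # normalization percentile (100 = global max); lower values clip rare
    # extreme responses such as sharp tree/shadow edges
    norm_percentile: float = 100.0
    n_eigenvectors: int = 16
    globalization_grid_factor: int = 4
    affinity_sigma: float = 0.1
    affinity_radius: int = 5
    spb_weight: float = 1.0
    alpha_fcn: float = 0.5
    lift_mode: str = "structure-tensor"  # or "replicate"
    seed: int = 0

    def __post_init__(self):
        if not self.scales:
            raise ValueError("at least one scale required")
        if self.channel_weights is not None and any(
            w < 0 for w in self.channel_weights
        ):
            raise ValueError("channel weights must be non-negative")
        if not 0 <= self.alpha_fcn <= 1:
            raise ValueError("alpha_fcn must be in [0, 1]")


def _normalize01(x: np.ndarray, percentile: float = 100.0) -> np.ndarray:
    """Scale to [0, 1]; with percentile < 100 the scale is the given upper
    percentile of the positive responses and the rest is clipped, so a few
    extreme outliers do not compress the whole signal."""
    if percentile >= 100.0:
        mx = x.max()
        return x / mx if mx > 0 else x
    pos = x[x > 0]
    if pos.size == 0:
        return x
    scale = np.percentile(pos, percentile)
    if scale <= 0:
        scale = x.max()
    return np.clip(x / scale, 0.0, 1.0)


def _half_disc_masks(radius: int, theta: float):
    d = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    disc = dr**2 + dc**2 <= radius**2
    side = dr * np.cos(theta) - dc * np.sin(theta)
    pos = disc & (side > 1e-9)
    neg = disc & (side < -1e-9)
    return pos.astype(float), neg.astype(float)


def _conv(img, kernel):
    return _sig.fftconvolve(img, kernel, mode="same")


def _chi2_from_indicators(indicators, radius, theta):
    """χ² half-disc distance given per-bin indicator images."""
    pos, neg = _half_disc_masks(radius, theta)
    shape = indicators[0].shape
    ones = np.ones(shape)
    area_p = _conv(ones, pos)
    area_n = _conv(ones, neg)
    # half-discs falling (almost) entirely outside the image carry no evidence
    valid = (area_p >= 1.0) & (area_n >= 1.0)
    area_p = np.maximum(area_p, 1.0)
    area_n = np.maximum(area_n, 1.0)
    chi2 = np.zeros(shape)
    for ind in indicators:
        g = np.clip(_conv(ind, pos), 0.0, None) / area_p
        h = np.clip(_conv(ind, neg), 0.0, None) / area_n
        chi2 += 0.5 * (g - h) ** 2 / (g + h + 1e-9)
    return np.clip(chi2, 0.0, None) * valid


def _bin_indicators(channel: np.ndarray, n_bins: int, discrete: bool = False):
    if discrete:
        ids = channel.astype(int)
        return [(ids == b).astype(float) for b in range(int(ids.max()) + 1)]
    lo, hi = float(channel.min()), float(channel.max())
    if hi <= lo:
        return [np.ones_like(channel, dtype=float)]
    q = np.clip(((channel - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    return [(q == b).astype(float) for b in range(n_bins)]


def half_disc_gradient(
    channel: np.ndarray,
    radius: int,
    theta: float,
    n_bins: int = 12,
    discrete: bool = False,
) -> np.ndarray:
    """χ² distance between value histograms of the two half-discs of the
    given radius split by a diameter at angle ``theta``."""
    channel = np.asarray(channel, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius > min(channel.shape) // 2:
        raise ValueError("radius exceeds image half-size")
    return _chi2_from_indicators(
        _bin_indicators(channel, n_bins, discrete), radius, theta
    )


# ---------------------------------------------------------------------------
# texture channel


def _filter_bank(sigma: float = 1.4):
    kernels = []
    n = int(3 * sigma + 0.5) * 2 + 1
    d = np.arange(n) - n // 2
    yy, xx = np.meshgrid(d, d, indexing="ij")
    g = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
    for theta in orientation_bins(4):
        u = xx * np.cos(theta) + yy * np.sin(theta)
        v = -xx * np.sin(theta) + yy * np.cos(theta)
        even = g * (u**2 / sigma**2 - 1)  # second derivative (bar)
        odd = g * u  # first derivative (edge)
        kernels += [even / np.abs(even).sum(), odd / np.abs(odd).sum()]
    log = g * ((xx**2 + yy**2) / sigma**2 - 2)
    kernels.append(log / np.abs(log).sum())
    kernels.append(g / g.sum())
    return kernels


def texton_map(channel: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each pixel to one of k texture archetypes (textons): filter
    bank responses clustered with seeded k-means."""
    responses = np.stack(
        [_conv(channel, kern) for kern in _filter_bank()], axis=-1
    )
    H, W, F = responses.shape
    flat = responses.reshape(-1, F)
    rng = np.random.default_rng(seed)
    n_sample = min(len(flat), 8000)
    sub = flat[rng.choice(len(flat), n_sample, replace=False)]
    km = KMeans(n_clusters=min(k, n_sample), n_init=1, random_state=seed).fit(sub)
    return km.predict(flat).reshape(H, W)


# ---------------------------------------------------------------------------


def _image_channels(image, cfg: CueConfig):
    data = image.data if isinstance(image, MultibandRaster) else np.asarray(image)
    if data.ndim == 2:
        data = data[None]
    channels = [(np.asarray(b, dtype=float), False) for b in data]
    if cfg.use_texture:
        # texton map computed on the mean of the bands
        channels.append((texton_map(data.mean(axis=0), cfg.n_textons, cfg.seed), True))
    return channels


def mpb(image, cfg: CueConfig = None) -> OrientedContourSignal:
    """Multiscale local boundary signal: weighted half-disc χ² over
    channels, scales and orientations, normalized to [0, 1]."""
    cfg = cfg or CueConfig()
    grid = (
        image.grid
        if isinstance(image, MultibandRaster)
        else RasterGrid(width=np.asarray(image).shape[-1], height=np.asarray(image).shape[-2])
    )
    channels = _image_channels(image, cfg)
    weights = cfg.channel_weights
    if weights is None:
        weights = [1.0] * len(channels)
    if len(weights) != len(channels):
        raise ValueError(
            f"{len(weights)} channel weights for {len(channels)} channels"
        )
    thetas = orientation_bins(cfg.n_orientations)
    out = np.zeros((cfg.n_orientations, *grid.shape))
    for (chan, discrete), w in zip(channels, weights):
        if w == 0:
            continue
        scales = [cfg.texture_scale] if discrete else cfg.scales
        indicators = _bin_indicators(chan, cfg.n_bins, discrete)
        for radius in scales:
            for o, theta in enumerate(thetas):
                out[o] += w * _chi2_from_indicators(indicators, radius, theta)
    return OrientedContourSignal(
        grid=grid, strength=_normalize01(out, cfg.norm_percentile)
    )


# ---------------------------------------------------------------------------
# spectral globalization


def _intervening_contour_affinity(s: np.ndarray, cfg: CueConfig):
    """Sparse affinity between coarse-grid pixels: exp(-max signal crossed
    on the straight line between them / sigma)."""
    H, W = s.shape
    idx = np.arange(H * W).reshape(H, W)
    offsets = []
    R = cfg.affinity_radius
    for dr in range(-R, R + 1):
        for dc in range(-R, R + 1):
            if (dr, dc) > (0, 0) and 0 < dr * dr + dc * dc <= R * R:
                offsets.append((dr, dc))
    rows, cols, vals = [], [], []
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), min(H, H - dr))
        c0 = slice(max(0, -dc), min(W, W - dc))
        r1 = slice(max(0, dr), min(H, H + dr))
        c1 = slice(max(0, dc), min(W, W + dc))
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        # max signal along the discrete line between endpoints
        n_steps = max(abs(dr), abs(dc)) + 1
        mx = np.zeros(len(a))
        ar, ac = a // W, a % W
        for t in np.linspace(0, 1, n_steps):
            rr = np.round(ar + t * dr).astype(int)
            cc = np.round(ac + t * dc).astype(int)
            np.maximum(mx, s[rr, cc], out=mx)
        w = np.exp(-mx / cfg.affinity_sigma)
        rows.append(a)
        cols.append(b)
        vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Wmat = sparse.coo_matrix(
        (np.concatenate([vals, vals]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(H * W, H * W),
    ).tocsr()
    return Wmat


def _component_eigenvectors(Wmat, k: int):
    """Smallest generalized eigenvectors of (D - W) v = λ D v, solved per
    connected component; returns (n_nodes, k) vectors and weights 1/sqrt(λ)."""
    n = Wmat.shape[0]
    n_comp, labels = connected_components(Wmat, directed=False)
    vecs, weights = [], []
    for comp in range(n_comp):
        sel = np.nonzero(labels == comp)[0]
        if len(sel) < k + 2:
            continue
        Wc = Wmat[sel][:, sel]
        d = np.asarray(Wc.sum(axis=1)).ravel()
        d = np.maximum(d, 1e-12)
        dinv = 1.0 / np.sqrt(d)
        L = sparse.diags(d) - Wc
        Ln = sparse.diags(dinv) @ L @ sparse.diags(dinv)
        Ln = (Ln + Ln.T) / 2
        try:
            lam, u = eigsh(Ln, k=k + 1, sigma=-1e-6, which="LM")
        except Exception:
            lam, u = eigsh(Ln + 1e-8 * sparse.eye(len(sel)), k=k + 1, which="SM")
        order = np.argsort(lam)
        lam, u = lam[order], u[:, order]
        for j in range(1, min(k + 1, u.shape[1])):  # skip constant vector
            v = np.zeros(n)
            v[sel] = dinv * u[:, j]
            lj = max(lam[j], 1e-10)
            vecs.append(v)
            weights.append(1.0 / np.sqrt(lj))
    return vecs, weights


def spectral_globalization(
    signal: OrientedContourSignal, cfg: CueConfig = None
) -> OrientedContourSignal:
    """Globalized oriented signal (sPb): eigenvectors of the affinity-graph
    Laplacian on a downsampled grid, read out through oriented directional
    derivatives and summed with 1/sqrt(λ) weights."""
    cfg = cfg or CueConfig()
    f = cfg.globalization_grid_factor
    s = signal.max_over_orientations().astype(float)
    H, W = s.shape
    Hc, Wc = H // f, W // f
    coarse = s[: Hc * f, : Wc * f].reshape(Hc, f, Wc, f).max(axis=(1, 3))
    Wmat = _intervening_contour_affinity(coarse, cfg)
    vecs, weights = _component_eigenvectors(Wmat, cfg.n_eigenvectors)
    thetas = orientation_bins(signal.n_orientations)
    out = np.zeros_like(signal.strength, dtype=float)
    for v, wk in zip(vecs, weights):
        vc = v.reshape(Hc, Wc)
        vf = np.kron(vc, np.ones((f, f)))[:H, :W]  # nearest-neighbour upsample
        if vf.shape != (H, W):
            vf = np.pad(vf, ((0, H - vf.shape[0]), (0, W - vf.shape[1])), mode="edge")
        vf = ndimage.gaussian_filter(vf, 1.0)
        gr = ndimage.sobel(vf, axis=0) / 8.0
        gc = ndimage.sobel(vf, axis=1) / 8.0
        for o, theta in enumerate(thetas):
            # derivative along the normal of an edge oriented at theta
            nr, nc = np.cos(theta), -np.sin(theta)
            out[o] += wk * np.abs(gr * nr + gc * nc)
    # gate by the input's own contrast: with a (near-)uniform affinity graph
    # the eigenvectors carry only the grid's shape, not contours — a zero
    # input must yield zero oriented contrast
    return OrientedContourSignal(
        grid=signal.grid, strength=_normalize01(out) * float(s.max())
    )


def gpb(image, cfg: CueConfig = None) -> OrientedContourSignal:
    """Globalized probability of boundary: mPb + spb_weight · sPb, normalized."""
    cfg = cfg or CueConfig()
    local = mpb(image, cfg)
    if cfg.spb_weight == 0:
        return local
    glob = spectral_globalization(local, cfg)
    combined = local.strength + cfg.spb_weight * glob.strength
    return OrientedContourSignal(
        grid=local.grid, strength=_normalize01(combined, cfg.norm_percentile)
    )


# ---------------------------------------------------------------------------
# combination with the FCN detector


def _lift_orientations(
    prob: np.ndarray, n_orientations: int, mode: str
) -> np.ndarray:
    p = _normalize01(np.asarray(prob, dtype=float))
    if mode == "replicate":
        return np.repeat(p[None], n_orientations, axis=0)
    if mode != "structure-tensor":
        raise ValueError(f"unknown lift mode {mode!r}")
    ps = ndimage.gaussian_filter(p, 1.5)
    gr = ndimage.sobel(ps, axis=0) / 8.0
    gc = ndimage.sobel(ps, axis=1) / 8.0
    jrr = ndimage.gaussian_filter(gr * gr, 2.0)
    jcc = ndimage.gaussian_filter(gc * gc, 2.0)
    jrc = ndimage.gaussian_filter(gr * gc, 2.0)
    # gradient direction of the dominant eigenvector; the boundary tangent
    # is perpendicular to it
    two_phi = np.arctan2(2 * jrc, jcc - jrr)
    grad_dir = 0.5 * two_phi  # angle of gradient from c-axis (in r,c frame)
    tangent = np.mod(grad_dir + np.pi / 2, np.pi)
    tr = jrr + jcc
    det_ = jrr * jcc - jrc**2
    disc = np.sqrt(np.maximum(tr**2 / 4 - det_, 0))
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    coherence = np.where(tr > 1e-12, (lam1 - lam2) / (lam1 + lam2 + 1e-12), 0.0)
    out = np.empty((n_orientations, *p.shape))
    for o, theta in enumerate(orientation_bins(n_orientations)):
        d = np.mod(theta - tangent, np.pi)
        d = np.minimum(d, np.pi - d)
        window = coherence * np.cos(d) ** 2 + (1 - coherence)
        out[o] = p * window
    return out


def combine_with_fcn(
    gpb_signal: OrientedContourSignal,
    fcn_map: BoundaryProbabilityMap,
    alpha_fcn: float = 0.5,
    mode: str = "structure-tensor",
) -> OrientedContourSignal:
    """alpha · lifted-FCN + (1 − alpha) · gPb, kept within [0, 1]."""
    if not 0 <= alpha_fcn <= 1:
        raise ValueError("alpha_fcn must be in [0, 1]")
    prob = fcn_map.prob if hasattr(fcn_map, "prob") else np.asarray(fcn_map)
    if prob.shape != gpb_signal.grid.shape:
        raise ValueError("FCN map grid does not match the oriented signal")
    lifted = _lift_orientations(prob, gpb_signal.n_orientations, mode)
    combined = alpha_fcn * lifted + (1 - alpha_fcn) * gpb_signal.strength
    mx = combined.max()
    if mx > 1:
        combined = combined / mx
    return OrientedContourSignal(grid=gpb_signal.grid, strength=combined)


class CueExtractor(BaseEstimator):
    """Transformer-shaped surface over the cue pipeline.

    ``transform(image)`` returns the gPb oriented signal;
    ``transform(image, fcn_map=...)`` additionally blends in the FCN
    probability with weight ``alpha_fcn``."""

    def __init__(self, **cue_params):
        self.cue_params = cue_params

    def fit(self, X=None, y=None):
        return self

    def get_config(self) -> CueConfig:
        return CueConfig(**self.cue_params)

    def transform(self, image, fcn_map=None) -> OrientedContourSignal:
        cfg = self.get_config()
        sig = gpb(image, cfg)
        if fcn_map is not None:
            sig = combine_with_fcn(sig, fcn_map, cfg.alpha_fcn, cfg.lift_mode)
        return sig
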