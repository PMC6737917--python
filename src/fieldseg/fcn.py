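"""Semantic field-boundary detection with an encoder-decoder FCN.

The detector is an encoder-decoder fully convolutional network in the
SegNet style: an encoder of 3x3 conv + batch-norm + ReLU blocks with 2x2
max-pooling, and a decoder that upsamples with the pooling indices recorded
by the paired encoder pooling layers (index unpooling) before densifying
with further convolutions.  Pixels are classified boundary / non-boundary
with a cross-entropy loss whose boundary-class weight (default 10) counters
the strong class imbalance.  Training uses randomly extracted patches and
the Adam optimizer.

The default architecture is the 13-conv / 5-pool layout; a "tiny" preset
(2 blocks, 16/32 filters) keeps CPU experiments fast — the full layout is
configuration, not code change.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .grids import MultibandRaster, RasterGrid
from .reference import BoundaryMask

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "BoundaryProbabilityMap",
    "SegNet",
    "FCNBoundaryDetector",
    "sample_patches",
    "weighted_loss",
    "train",
    "predict_boundary",
    "n_iterations",
    "TINY_BLOCKS",
    "FULL_BLOCKS",
]

# encoder as (n_conv_layers, n_filters) per block; decoder mirrors it
FULL_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))  # 13 convs, 5 pools
TINY_BLOCKS = ((2, 16), (2, 32))


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    encoder_blocks: tuple = FULL_BLOCKS
    n_classes: int = 2

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if not self.encoder_blocks:
            raise ValueError("at least one encoder block required")
        object.__setattr__(
            self, "encoder_blocks", tuple(tuple(b) for b in self.encoder_blocks)
        )

    @property
    def n_blocks(self) -> int:
        return len(self.encoder_blocks)

    @property
    def pool_factor(self) -> int:
        return 2**self.n_blocks

    @classmethod
    def tiny(cls, in_channels: int = 1) -> "NetworkConfig":
        return cls(in_channels=in_channels, encoder_blocks=TINY_BLOCKS)


@dataclass(frozen=True)
class TrainConfig:
    patch_size: int = 96
    n_patches: int = 6000
    batch_size: int = 32
    epochs: int = 300
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    boundary_class_weight: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.boundary_class_weight < 1:
            raise ValueError("boundary_class_weight must be >= 1")
        for name in ("patch_size", "n_patches", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class BoundaryProbabilityMap:
    """Per-pixel boundary-class probability in [0, 1] on a grid."""

    grid: RasterGrid
    prob: np.ndarray

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=np.float32)
        if self.prob.shape != self.grid.shape:
            raise ValueError("probability map shape does not match grid")
        if self.prob.min() < -1e-6 or self.prob.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")


def n_iterations(n_patches: int, batch_size: int, epochs: int) -> int:
    """Optimizer iterations for one training run: ceil(n/batch) per epoch."""
    return math.ceil(n_patches / batch_size) * epochs


class SegNet:
    """The assembled network: paired pooling/unpooling, explicit backprop."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers = []
        self._pools = []
        ch = cfg.in_channels
        for n_conv, filt in cfg.encoder_blocks:
            for _ in range(n_conv):
                self.layers += [
                    nn.Conv2D(ch, filt, rng),
                    nn.BatchNorm2D(filt),
                    nn.ReLU(),
                ]
                ch = filt
            pool = nn.MaxPool2x2()
            self._pools.append(pool)
            self.layers.append(pool)
        blocks = cfg.encoder_blocks
        for i in range(len(blocks) - 1, -1, -1):
            n_conv, filt = blocks[i]
            out_filt = blocks[i - 1][1] if i > 0 else blocks[0][1]
            self.layers.append(nn.MaxUnpool2x2(self._pools[i]))
            for j in range(n_conv):
                out = out_filt if j == n_conv - 1 else filt
                self.layers += [
                    nn.Conv2D(ch, out, rng),
                    nn.BatchNorm2D(out),
                    nn.ReLU(),
                ]
                ch = out
        self.layers.append(nn.Conv2D(ch, cfg.n_classes, rng))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h, w = x.shape[2:]
        f = self.cfg.pool_factor
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} must be divisible by {f} (pooling depth)"
            )
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # --- checkpointing -------------------------------------------------
    def state_arrays(self) -> dict:
        out = {}
        for i, layer in enumerate(self.layers):
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                if hasattr(layer, attr):
                    out[f"l{i}_{attr}"] = getattr(layer, attr)
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        for i, layer in enumerate(self.layers):
            for attr in ("W", "b", "gamma", "beta", "running_mean", "running_var"):
                key = f"l{i}_{attr}"
                if hasattr(layer, attr):
                    setattr(layer, attr, np.asarray(arrays[key]))


def sample_patches(
    image: MultibandRaster | np.ndarray,
    ref: BoundaryMask | np.ndarray,
    n: int,
    size: int,
    seed: int,
):
    """n image/label patch pairs at uniform random positions fully inside
    the extent; deterministic for a seed. Returns (x, y, corners)."""
    img = image.data if isinstance(image, MultibandRaster) else np.asarray(image)
    lab = ref.mask if isinstance(ref, BoundaryMask) else np.asarray(ref)
    if img.ndim == 2:
        img = img[None]
    H, W = img.shape[1:]
    if size > min(H, W):
        raise ValueError(f"patch size {size} exceeds image dims {H}x{W}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, H - size + 1, n)
    cols = rng.integers(0, W - size + 1, n)
    x = np.stack([img[:, r : r + size, c : c + size] for r, c in zip(rows, cols)]) if n else np.zeros((0, img.shape[0], size, size))
    y = np.stack([lab[r : r + size, c : c + size] for r, c in zip(rows, cols)]) if n else np.zeros((0, size, size))
    return (
        np.asarray(x, dtype=np.float32),
        np.asarray(y, dtype=np.int64),
        np.column_stack([rows, cols]),
    )


def weighted_loss(predicted_probs, labels, w_boundary: float) -> float:
    """Mean class-weighted cross-entropy (weight w_boundary on boundary
    pixels, 1 elsewhere); reduces to plain cross-entropy at w_boundary=1."""
    loss, _ = nn.weighted_cross_entropy(
        np.asarray(predicted_probs), np.asarray(labels), w_boundary
    )
    return loss


class FCNBoundaryDetector(BaseEstimator):
    """Encoder-decoder FCN boundary detector with an sklearn-style surface.

    Parameters mirror NetworkConfig and TrainConfig.  ``fit`` takes a list
    of co-registered (image, reference-mask) training tiles, samples
    patches, and trains with Adam; ``predict_proba`` runs tiled
    full-resolution inference; ``predict`` thresholds it.

    Fitted attributes: ``model_``, ``loss_history_``, ``n_iterations_``.
    """

    def __init__(
        self,
        in_channels: int = 1,
        encoder_blocks: tuple = TINY_BLOCKS,
        patch_size: int = 96,
        n_patches: int = 6000,
        batch_size: int = 32,
        epochs: int = 300,
        learning_rate: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        boundary_class_weight: float = 10.0,
        seed: int = 0,
        tile: int = 256,
        overlap: int = 32,
    ):
        self.in_channels = in_channels
        self.encoder_blocks = encoder_blocks
        self.patch_size = patch_size
        self.n_patches = n_patches
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.boundary_class_weight = boundary_class_weight
        self.seed = seed
        self.tile = tile
        self.overlap = overlap

    # ------------------------------------------------------------------
    def _configs(self):
        net = NetworkConfig(
            in_channels=self.in_channels, encoder_blocks=tuple(self.encoder_blocks)
        )
        tr = TrainConfig(
            patch_size=self.patch_size,
            n_patches=self.n_patches,
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            beta1=self.beta1,
            beta2=self.beta2,
            boundary_class_weight=self.boundary_class_weight,
            seed=self.seed,
        )
        return net, tr

    def fit(self, X, y):
        """X: list of images (MultibandRaster or (C,H,W) arrays);
        y: list of co-registered boundary masks."""
        net_cfg, tr_cfg = self._configs()
        if tr_cfg.patch_size % net_cfg.pool_factor:
            raise ValueError(
                f"patch_size {tr_cfg.patch_size} incompatible with pooling depth "
                f"(must be divisible by {net_cfg.pool_factor})"
            )
        if not isinstance(X, (list, tuple)):
            X, y = [X], [y]
        per = [tr_cfg.n_patches // len(X)] * len(X)
        per[0] += tr_cfg.n_patches - sum(per)
        xs, ys = [], []
        for i, (img, lab) in enumerate(zip(X, y)):
            px, py, _ = sample_patches(
                img, lab, per[i], tr_cfg.patch_size, seed=tr_cfg.seed + 7919 * i
            )
            xs.append(px)
            ys.append(py)
        patches = (np.concatenate(xs), np.concatenate(ys))
        self._fit_patches(patches, net_cfg, tr_cfg)
        return self

    def _fit_patches(self, patches, net_cfg, tr_cfg):
        x_all, y_all = patches
        if x_all.shape[1] != net_cfg.in_channels:
            raise ValueError("patch channel count does not match in_channels")
        rng = np.random.default_rng(tr_cfg.seed)
        model = SegNet(net_cfg, rng)
        opt = nn.Adam(
            model.layers,
            lr=tr_cfg.learning_rate,
            beta1=tr_cfg.beta1,
            beta2=tr_cfg.beta2,
        )
        n = x_all.shape[0]
        nb = math.ceil(n / tr_cfg.batch_size)
        history = []
        for _ in range(tr_cfg.epochs):
            order = rng.permutation(n)
            for b in range(nb):
                sel = order[b * tr_cfg.batch_size : (b + 1) * tr_cfg.batch_size]
                logits = model.forward(x_all[sel], train=True)
                probs = nn.softmax(logits)
                loss, grad = nn.weighted_cross_entropy(
                    probs, y_all[sel], tr_cfg.boundary_class_weight
                )
                model.backward(grad)
                opt.step()
                history.append(loss)
        self.model_ = model
        self.loss_history_ = np.asarray(history)
        self.n_iterations_ = len(history)
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, image) -> BoundaryProbabilityMap:
        """Full-resolution boundary probability by tiled inference with
        feathered overlap blending (identical to whole-image inference on
        images that fit one tile)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("detector is not fitted")
        if isinstance(image, MultibandRaster):
            grid, img = image.grid, image.data
        else:
            img = np.asarray(image)
            if img.ndim == 2:
                img = img[None]
            grid = RasterGrid(width=img.shape[2], height=img.shape[1])
        if img.shape[0] != self.model_.cfg.in_channels:
            raise ValueError(
                f"image has {img.shape[0]} bands, detector expects "
                f"{self.model_.cfg.in_channels}"
            )
        prob = _tiled_inference(
            self.model_, img.astype(np.float32), self.tile, self.overlap
        )
        return BoundaryProbabilityMap(grid=grid, prob=prob)

    def predict(self, image, threshold: float = 0.5):
        pm = self.predict_proba(image)
        return pm.prob >= threshold

    # --- checkpoint ----------------------------------------------------
    def save(self, path) -> None:
        net_cfg, tr_cfg = self._configs()
        meta = {
            "network": dataclasses.asdict(net_cfg),
            "train": dataclasses.asdict(tr_cfg),
            "tile": self.tile,
            "overlap": self.overlap,
        }
        np.savez(
            path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.model_.state_arrays(),
        )

    @classmethod
    def load(cls, path) -> "FCNBoundaryDetector":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        net = meta["network"]
        tr = meta["train"]
        est = cls(
            in_channels=net["in_channels"],
            encoder_blocks=tuple(tuple(b) for b in net["encoder_blocks"]),
            tile=meta["tile"],
            overlap=meta["overlap"],
            **{k: tr[k] for k in (
                "patch_size", "n_patches", "batch_size", "epochs",
                "learning_rate", "beta1", "beta2", "boundary_class_weight", "seed",
            )},
        )
        model = SegNet(est._configs()[0], np.random.default_rng(0))
        model.load_state_arrays(arrays)
        est.model_ = model
        est.loss_history_ = np.asarray([])
        est.n_iterations_ = 0
        return est


def _pad_to_multiple(img: np.ndarray, f: int):
    H, W = img.shape[1:]
    ph = (-H) % f
    pw = (-W) % f
    if ph or pw:
        img = np.pad(img, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return img, H, W


def _tiled_inference(model: SegNet, img: np.ndarray, tile: int, overlap: int):
    f = model.cfg.pool_factor
    img, H, W = _pad_to_multiple(img, f)
    Hp, Wp = img.shape[1:]
    step = tile - overlap
    acc = np.zeros((Hp, Wp), dtype=np.float64)
    wacc = np.zeros((Hp, Wp), dtype=np.float64)
    ramp = np.minimum(np.arange(1, tile + 1), np.arange(tile, 0, -1)).astype(float)
    ramp = np.minimum(ramp, overlap + 1)
    wt = np.outer(ramp, ramp)
    r0s = list(range(0, max(Hp - tile, 0) + 1, step))
    c0s = list(range(0, max(Wp - tile, 0) + 1, step))
    if r0s[-1] + tile < Hp:
        r0s.append(Hp - tile)
    if c0s[-1] + tile < Wp:
        c0s.append(Wp - tile)
    for r0 in r0s:
        for c0 in c0s:
            th = min(tile, Hp)
            tw = min(tile, Wp)
            patch = img[None, :, r0 : r0 + th, c0 : c0 + tw]
            logits = model.forward(patch, train=False)
            prob = nn.softmax(logits)[0, 1]
            acc[r0 : r0 + th, c0 : c0 + tw] += prob * wt[:th, :tw]
            wacc[r0 : r0 + th, c0 : c0 + tw] += wt[:th, :tw]
    return np.clip((acc / wacc)[:H, :W], 0.0, 1.0).astype(np.float32)


def train(patches, net_config: NetworkConfig, train_config: TrainConfig):
    """Functional wrapper: train a detector on pre-sampled (x, y) patches."""
    est = FCNBoundaryDetector(
        in_channels=net_config.in_channels,
        encoder_blocks=net_config.encoder_blocks,
        patch_size=train_config.patch_size,
        n_patches=train_config.n_patches,
        batch_size=train_config.batch_size,
        epochs=train_config.epochs,
        learning_rate=train_config.learning_rate,
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        boundary_class_weight=train_config.boundary_class_weight,
        seed=train_config.seed,
    )
    est._fit_patches(patches, net_config, train_config)
    return est, est.loss_history_


def predict_boundary(
    detector: FCNBoundaryDetector, image, tile: int = 256, overlap: int = 32
) -> BoundaryProbabilityMap:
    """Functional wrapper over tiled inference."""
    detector.tile, detector.overlap = tile, overlap
    return detector.predict_proba(image)
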