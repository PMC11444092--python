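"""U-Net deformation corrector: model, training loop, inference.

The corrector is a dimension-configurable U-Net (default 3 resolution
levels) mapping a 1-channel deformed/reconstructed activity image to a
same-shape corrected image: per level two 3^d convolutions + ReLU, max
pooling (stride 2) down, transposed convolution (stride 2) up, with
skip connections between matching levels and channel count doubling
per down-step.  Training minimizes the mean-absolute (L1) deviation
between prediction and ground-truth label with Adam at batch size 1,
mirroring how the deformation-recovery task is posed: the pairing
(deformed input, true label) *is* the supervision; no other prior is
imposed.

The implementation is a compact numpy CNN stack (:mod:`._layers`) with
explicit backpropagation; training is seed-reproducible bit-for-bit on
a fixed machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._layers import Conv, MaxPool, ReLU, Sequential, UpConv
from .grid import ImageVolume

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet",
    "build_model",
    "train",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture settings.  ``levels`` counts resolution levels
    (so ``levels - 1`` poolings); channels double per level starting
    from ``base_channels``."""

    spatial_dims: int = 2
    levels: int = 3
    base_channels: int = 16
    in_channels: int = 1
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.spatial_dims not in (2, 3):
            raise ValueError("spatial_dims must be 2 or 3")
        if self.levels < 2:
            raise ValueError("a U-Net needs at least 2 levels")


@dataclass
class TrainConfig:
    """Optimization settings: L1 loss, Adam, batch size 1."""

    learning_rate: float = 1e-4
    epochs: int = 100
    seed: int = 0
    norm_constant: float | None = None  # dataset-level; labels' 99th pct if None
    shuffle: bool = True
    checkpoint_every: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _conv_block(cin, cout, ndim, rng):
    return Sequential(
        Conv(cin, cout, ndim, 3, rng), ReLU(), Conv(cout, cout, ndim, 3, rng), ReLU()
    )


class UNet:
    """Encoder–bottleneck–decoder with skip connections.

    Inputs whose spatial dims are not divisible by ``2**(levels-1)``
    are reflect-padded internally and cropped on output, so the
    output spatial shape always equals the input spatial shape.
    """

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        nd = cfg.spatial_dims
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2**l for l in range(cfg.levels)]
        self.enc = []
        cin = cfg.in_channels
        for l in range(cfg.levels - 1):
            self.enc.append(_conv_block(cin, ch[l], nd, rng))
            cin = ch[l]
        self.pools = [MaxPool(nd) for _ in range(cfg.levels - 1)]
        self.bottleneck = _conv_block(ch[-2], ch[-1], nd, rng)
        self.ups = []
        self.dec = []
        for l in reversed(range(cfg.levels - 1)):
            self.ups.append(UpConv(ch[l + 1], ch[l], nd, rng))
            self.dec.append(_conv_block(2 * ch[l], ch[l], nd, rng))
        self.final = Conv(ch[0], cfg.out_channels, nd, 1, rng)
        self.norm_constant: float | None = None
        self.train_seed: int | None = None

    # -- parameter plumbing -------------------------------------------------
    def modules(self):
        return [*self.enc, self.bottleneck, *self.ups, *self.dec, self.final]

    @property
    def params(self):
        return [p for m in self.modules() for p in m.params]

    @property
    def grads(self):
        return [g for m in self.modules() for g in m.grads]

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)

    # -- forward / backward -------------------------------------------------
    def _pad_amounts(self, spatial):
        mult = 2 ** (self.cfg.levels - 1)
        pads = []
        for s in spatial:
            if s < mult:
                raise ValueError(
                    f"input dim {s} smaller than the net's reduction factor {mult}"
                )
            r = (-s) % mult
            pads.append((r // 2, r - r // 2))
        return pads

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = self.cfg.spatial_dims
        if x.ndim == nd:
            x = x[None]
        if x.ndim != nd + 1 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected ({self.cfg.in_channels}, *spatial) input")
        self._pads = self._pad_amounts(x.shape[1:])
        self._in_spatial = x.shape[1:]
        h = np.pad(x, [(0, 0)] + self._pads, mode="reflect")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[0])
            h = dec.forward(np.concatenate([skip, h], axis=0))
        h = self.final.forward(h)
        crop = tuple(
            slice(p0, p0 + s) for (p0, _), s in zip(self._pads, self._in_spatial)
        )
        return h[(slice(None),) + crop]

    def backward(self, dy: np.ndarray) -> None:
        nd = self.cfg.spatial_dims
        if dy.ndim == nd:
            dy = dy[None]
        padded = [s + p0 + p1 for s, (p0, p1) in zip(self._in_spatial, self._pads)]
        full = np.zeros((dy.shape[0], *padded))
        crop = tuple(
            slice(p0, p0 + s) for (p0, _), s in zip(self._pads, self._in_spatial)
        )
        full[(slice(None),) + crop] = dy
        h = self.final.backward(full)
        skip_grads = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = dec.backward(h)
            skip_grads.append(g[:c_skip])
            h = up.backward(g[c_skip:])
        h = self.bottleneck.backward(h)
        # skip_grads were appended shallowest-first, i.e. encoder order
        for block, pool, sg in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            h = pool.backward(h)
            h = block.backward(h + sg)
        # h is now the input gradient; reflect-pad contributions fold back
        # into the interior, but the input itself carries no parameters.


def build_model(cfg: UNetConfig) -> UNet:
    """Construct a U-Net with seed-reproducible initialization."""
    return UNet(cfg)


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, ImageVolume) else np.asarray(vol, float)


def train(model: UNet, pairs, cfg: TrainConfig, checkpoint_dir=None):
    """Train on ``(input, label)`` pairs (``LabeledPair`` or tuples),
    batch size 1, L1 loss on intensities normalized by a dataset-level
    constant (the labels' 99th percentile unless given).

    Returns the per-epoch mean training loss history; the model is
    updated in place and remembers the normalization constant.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one training pair")

    def unpack(p):
        if hasattr(p, "label"):
            return _as_array(p.input), _as_array(p.label)
        x, t = p
        return _as_array(x), _as_array(t)

    data = [unpack(p) for p in pairs]
    shape0 = data[0][0].shape
    for x, t in data:
        if x.shape != shape0 or t.shape != shape0:
            raise ValueError("all training pairs must share one grid")
    norm = cfg.norm_constant
    if norm is None:
        norm = float(np.percentile(np.stack([t for _, t in data]), 99))
    if norm <= 0:
        norm = 1.0
    model.norm_constant = norm
    model.train_seed = cfg.seed

    opt = _Adam(model.params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = []
    n_vox = float(np.prod(shape0))
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(data)) if cfg.shuffle else np.arange(len(data))
        losses = []
        for i in order:
            x, t = data[i]
            pred = model.forward(x / norm)[0]
            resid = pred - t / norm
            loss = float(np.abs(resid).mean())
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            model.zero_grad()
            model.backward(np.sign(resid) / n_vox)
            opt.step(model.grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if (
            checkpoint_dir is not None
            and cfg.checkpoint_every
            and (epoch + 1) % cfg.checkpoint_every == 0
        ):
            save_checkpoint(model, f"{checkpoint_dir}/ckpt_epoch{epoch + 1:05d}.npz")
    return history


def predict(model: UNet, image) -> ImageVolume | np.ndarray:
    """Apply the trained corrector: normalize by the training constant,
    run the net, clamp negatives to 0 (activity images), denormalize."""
    norm = model.norm_constant or 1.0
    arr = _as_array(image)
    if arr.ndim != model.cfg.spatial_dims:
        raise ValueError(
            f"model expects a {model.cfg.spatial_dims}D image, got {arr.ndim}D"
        )
    out = model.forward(arr / norm)[0]
    out = np.maximum(out, 0.0) * norm
    if isinstance(image, ImageVolume):
        return ImageVolume(out, image.grid)
    return out


def save_checkpoint(model: UNet, path) -> None:
    meta = {
        "config": asdict(model.cfg),
        "norm_constant": model.norm_constant,
        "train_seed": model.train_seed,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path, allow_pickle=False) as fh:
        meta = json.loads(str(fh["meta"]))
        model = UNet(UNetConfig(**meta["config"]))
        for i, p in enumerate(model.params):
            p[...] = fh[f"param_{i}"]
    model.norm_constant = meta["norm_constant"]
    model.train_seed = meta["train_seed"]
    return model
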