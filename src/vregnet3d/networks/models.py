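"""Network architectures: centroid regression net and V-net-style segmenter.

Both are fully convolutional encoder-decoders over 5x5x5 stride-1
zero-padded convolutions, 2x2x2 max-pool downsampling and stride-2
transposed convolutions whose output is cropped to exactly double each
spatial dimension, so the output grid always equals the input grid when the
input sides are multiples of ``2**n_levels``.  The segmentation network adds
V-net-style additive skip connections and a softmax head; the regression
network is skip-free with a single-channel linear head.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .layers import (
    BatchNorm3D, Conv3D, ConvTranspose3D, Dropout, Layer, MaxPool3D,
    ReLU, Softmax,
)

__all__ = [
    "RegressionNetConfig", "SegmentationNetConfig",
    "RegressionNet", "SegmentationNet",
    "build_regression_net", "build_segmentation_net",
]


@dataclass
class RegressionNetConfig:
    n_levels: int = 3
    base_channels: int = 16
    kernel_voxels: int = 5
    dropout_rate: float = 0.1
    in_channels: int = 1
    target_scale: float = 10000.0

    def to_dict(self):
        return asdict(self)


@dataclass
class SegmentationNetConfig:
    n_levels: int = 3
    base_channels: int = 8
    kernel_voxels: int = 5
    dropout_rate: float = 0.0

    def to_dict(self):
        return asdict(self)


class Model:
    """Minimal container with explicit forward/backward and flat params."""

    def __init__(self):
        self.layers: list[Layer] = []

    def _register(self, layer: Layer) -> Layer:
        self.layers.append(layer)
        return layer

    def parameters(self):
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name)

    def get_param(self, key):
        i, name = key
        return self.layers[i].params[name]

    def get_grad(self, key):
        i, name = key
        return self.layers[i].grads.get(name)

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, val in layer.params.items():
                state[f"{i}.{name}"] = val.copy()
            if isinstance(layer, BatchNorm3D):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = state[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm3D):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()

    def _check_shape(self, x: np.ndarray, n_levels: int) -> None:
        if x.ndim != 5:
            raise ValueError(f"expected (B,C,x,y,z) input, got shape {x.shape}")
        div = 2 ** n_levels
        if any(s % div for s in x.shape[-3:]):
            raise ValueError(
                f"spatial dims {x.shape[-3:]} must be multiples of "
                f"2^n_levels = {div}")

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Inference on a single (C,x,y,z) or (x,y,z) volume."""
        v = np.asarray(volume, dtype=np.float64)
        if v.ndim == 3:
            v = v[None]
        out = self.forward(v[None], training=False)[0]
        return out

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class RegressionNet(Model):
    """Encoder-decoder mapping a nucleus-probability volume to a centroid
    density map (single linear output channel)."""

    def __init__(self, cfg: RegressionNetConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        k = cfg.kernel_voxels
        L = cfg.n_levels
        self.enc = []
        cin = cfg.in_channels
        ch = cfg.base_channels
        for _ in range(L):
            block = [
                self._register(Conv3D(cin, ch, k, rng)),
                self._register(BatchNorm3D(ch)),
                self._register(ReLU()),
                self._register(Dropout(cfg.dropout_rate, rng)),
                self._register(MaxPool3D()),
            ]
            self.enc.append(block)
            cin, ch = ch, ch * 2
        self.mid = [
            self._register(Conv3D(cin, cin, k, rng)),
            self._register(BatchNorm3D(cin)),
            self._register(ReLU()),
        ]
        self.dec = []
        for lvl in range(L - 1, -1, -1):
            cout = cfg.base_channels * 2 ** max(lvl - 1, 0)
            block = [
                self._register(ConvTranspose3D(cin, cout, k, rng)),
                self._register(BatchNorm3D(cout)),
                self._register(ReLU()),
            ]
            self.dec.append(block)
            cin = cout
        self.head = self._register(Conv3D(cin, 1, 1, rng))
        self._order = [l for blk in self.enc for l in blk] + self.mid \
            + [l for blk in self.dec for l in blk] + [self.head]

    def forward(self, x, training=False):
        self._check_shape(x, self.cfg.n_levels)
        for layer in self._order:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self._order):
            dy = layer.backward(dy)
        return dy


class SegmentationNet(Model):
    """V-net-style volumetric semantic segmenter with additive skips."""

    def __init__(self, n_classes: int, cfg: SegmentationNetConfig,
                 rng: np.random.Generator):
        super().__init__()
        if n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        self.cfg = cfg
        self.n_classes = n_classes
        k = cfg.kernel_voxels
        L = cfg.n_levels
        chans = [cfg.base_channels * 2 ** l for l in range(L)]
        cin = 1
        self.enc_blocks, self.pools = [], []
        for ch in chans:
            self.enc_blocks.append([
                self._register(Conv3D(cin, ch, k, rng)),
                self._register(BatchNorm3D(ch)),
                self._register(ReLU()),
            ])
            self.pools.append(self._register(MaxPool3D()))
            cin = ch
        self.mid = [
            self._register(Conv3D(cin, cin, k, rng)),
            self._register(BatchNorm3D(cin)),
            self._register(ReLU()),
        ]
        self.ups, self.dec_blocks = [], []
        for lvl in range(L - 1, -1, -1):
            ch = chans[lvl]
            self.ups.append([
                self._register(ConvTranspose3D(cin, ch, k, rng)),
                self._register(BatchNorm3D(ch)),
                self._register(ReLU()),
            ])
            self.dec_blocks.append([
                self._register(Conv3D(ch, ch, k, rng)),
                self._register(BatchNorm3D(ch)),
                self._register(ReLU()),
            ])
            cin = ch
        self.head = self._register(Conv3D(cin, n_classes, 1, rng))
        self.softmax = self._register(Softmax())

    def forward(self, x, training=False, pre_softmax=False):
        self._check_shape(x, self.cfg.n_levels)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, training=training)
            skips.append(x)
            x = pool.forward(x, training=training)
        for layer in self.mid:
            x = layer.forward(x, training=training)
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            for layer in up:
                x = layer.forward(x, training=training)
            x = x + skip
            for layer in dec:
                x = layer.forward(x, training=training)
        x = self.head.forward(x, training=training)
        if pre_softmax:
            return x
        return self.softmax.forward(x, training=training)

    def backward(self, dy):
        dy = self.softmax.backward(dy)
        dy = self.head.backward(dy)
        dskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec_blocks)):
            for layer in reversed(dec):
                dy = layer.backward(dy)
            dskips.append(dy)  # additive skip: gradient passes through
            for layer in reversed(up):
                dy = layer.backward(dy)
        for layer in reversed(self.mid):
            dy = layer.backward(dy)
        # decoder unwinds shallowest-first, so dskips[j] pairs with skips[j];
        # the encoder unwinds deepest-first and reads them back to front
        for j, (block, pool) in enumerate(
                zip(reversed(self.enc_blocks), reversed(self.pools))):
            dy = pool.backward(dy)
            dy = dy + dskips[len(dskips) - 1 - j]
            for layer in reversed(block):
                dy = layer.backward(dy)
        return dy

    def nucleus_probability(self, volume: np.ndarray) -> np.ndarray:
        """Per-voxel probability of the nucleus class (last channel)."""
        return self.predict(volume)[-1]

    def pre_classification(self, volume: np.ndarray) -> np.ndarray:
        """Class scores before the softmax voxel-classification layer.

        The nucleus-class score map is the input handed to the regression
        network, which homogenizes nucleus appearance.
        """
        v = np.asarray(volume, dtype=np.float64)
        if v.ndim == 3:
            v = v[None]
        return self.forward(v[None], training=False, pre_softmax=True)[0]


def build_regression_net(cfg: RegressionNetConfig | None = None,
                         seed: int = 0) -> RegressionNet:
    """Deterministically construct a Glorot-initialized regression net."""
    return RegressionNet(cfg or RegressionNetConfig(),
                         np.random.default_rng(seed))


def build_segmentation_net(n_classes: int,
                           cfg: SegmentationNetConfig | None = None,
                           seed: int = 0) -> SegmentationNet:
    """Deterministically construct a Glorot-initialized segmentation net."""
    return SegmentationNet(n_classes, cfg or SegmentationNetConfig(),
                           np.random.default_rng(seed))
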