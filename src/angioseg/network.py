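"""The bottleneck-residual 3D U-Net (ResU-Net).

One constructor serves all stages of the cascade: the two bone nets, the
vessel net, and the repair-stage backbone. The encoder applies ``levels``
convolutional downsampling units and the decoder the matching transposed
convolutional upsampling units with skip connections; ``n_blocks``
bottleneck-residual blocks (stacks of 1x1x1 / 3x3x3 / 1x1x1 convolutions with
an identity shortcut and channel contraction in the middle) are distributed
across the decoder resolution levels. Every convolution is followed by a
LeakyReLU (negative slope 0.1); the head is one sigmoid channel per class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Conv1x1, Conv3x3, DownConv, LeakyReLU, Param, Sigmoid, UpConv


def leaky_activation(x, negative_slope: float = 0.1):
    """Piecewise activation: ``f(x) = slope*x`` for x < 0, ``x`` otherwise."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, negative_slope * x, x)
    return out.item() if out.ndim == 0 else out


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; the defaults are the reference design."""

    in_channels: int = 1
    n_classes: int = 1
    base_width: int = 8
    levels: int = 4
    n_blocks: int = 8
    negative_slope: float = 0.1
    # Initial output-head bias. A negative value starts the per-class
    # probabilities low, which stabilizes Dice training on sparse foregrounds
    # (the untrained net otherwise predicts ~0.5 everywhere).
    head_bias: float = -2.0

    def __post_init__(self) -> None:
        if self.levels < 1 or self.n_blocks < 1 or self.base_width < 1:
            raise ValueError("levels, n_blocks and base_width must all be >= 1")
        if self.in_channels < 1 or self.n_classes < 1:
            raise ValueError("in_channels and n_classes must be >= 1")


class BottleneckBlock:
    """Residual unit: 1x1x1 contract -> 3x3x3 -> 1x1x1 expand, plus identity.

    Activation follows each convolution; the shortcut is added after the conv
    stack, so a block with all-zero weights is exactly the identity map.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 negative_slope: float = 0.1):
        mid = max(channels // 2, 1)
        self.c_in = Conv1x1(channels, mid, rng, negative_slope)
        self.c_mid = Conv3x3(mid, mid, rng, negative_slope)
        self.c_out = Conv1x1(mid, channels, rng, negative_slope)
        self.acts = [LeakyReLU(negative_slope) for _ in range(3)]

    def params(self):
        return self.c_in.params() + self.c_mid.params() + self.c_out.params()

    def forward(self, x):
        h = self.acts[0].forward(self.c_in.forward(x))
        h = self.acts[1].forward(self.c_mid.forward(h))
        h = self.acts[2].forward(self.c_out.forward(h))
        return x + h

    def backward(self, dy):
        dh = self.c_out.backward(self.acts[2].backward(dy))
        dh = self.c_mid.backward(self.acts[1].backward(dh))
        dh = self.c_in.backward(self.acts[0].backward(dh))
        return dy + dh


def _split_blocks(n_blocks: int, levels: int) -> list[int]:
    """Distribute blocks across decoder levels, deepest levels first."""
    per = [n_blocks // levels] * levels
    for i in range(n_blocks % levels):
        per[levels - 1 - i] += 1
    return per


class ResUNet:
    """Encoder-decoder with skips and decoder-side bottleneck-residual blocks."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        w = [cfg.base_width * 2 ** i for i in range(cfg.levels + 1)]
        ns = cfg.negative_slope
        self.stem = Conv3x3(cfg.in_channels, w[0], rng, ns)
        self.stem_act = LeakyReLU(ns)
        self.downs = [DownConv(w[i], w[i + 1], rng, ns) for i in range(cfg.levels)]
        self.down_acts = [LeakyReLU(ns) for _ in range(cfg.levels)]
        self.bottom = Conv3x3(w[cfg.levels], w[cfg.levels], rng, ns)
        self.bottom_act = LeakyReLU(ns)
        self.ups = [UpConv(w[i + 1], w[i], rng, ns) for i in range(cfg.levels)]
        self.up_acts = [LeakyReLU(ns) for _ in range(cfg.levels)]
        self.merges = [Conv3x3(2 * w[i], w[i], rng, ns) for i in range(cfg.levels)]
        self.merge_acts = [LeakyReLU(ns) for _ in range(cfg.levels)]
        per_level = _split_blocks(cfg.n_blocks, cfg.levels)
        self.blocks = [[BottleneckBlock(w[i], rng, ns) for _ in range(per_level[i])]
                       for i in range(cfg.levels)]
        self.head = Conv1x1(w[0], cfg.n_classes, rng, ns)
        self.head.b.data[:] = cfg.head_bias
        self.out_act = Sigmoid()
        self.widths = w

    # -- introspection ----------------------------------------------------
    def params(self) -> list[Param]:
        out = self.stem.params()
        for d in self.downs:
            out += d.params()
        out += self.bottom.params()
        for i in range(self.config.levels):
            out += self.ups[i].params() + self.merges[i].params()
            for blk in self.blocks[i]:
                out += blk.params()
        out += self.head.params()
        return out

    def describe(self) -> dict:
        return {
            "n_bottleneck_blocks": sum(len(b) for b in self.blocks),
            "n_down_units": len(self.downs),
            "n_up_units": len(self.ups),
            "levels": self.config.levels,
            "widths": list(self.widths),
            "n_classes": self.config.n_classes,
            "in_channels": self.config.in_channels,
            "n_parameters": count_parameters(self),
        }

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        cfg = self.config
        if x.ndim != 5 or x.shape[-1] != cfg.in_channels:
            raise ValueError(
                f"expected input (N, D, H, W, {cfg.in_channels}), got {x.shape}")
        div = 2 ** cfg.levels
        if any(s % div for s in x.shape[1:4]):
            raise ValueError(
                f"spatial dims {x.shape[1:4]} must be divisible by 2^levels = {div}")
        x = x.astype(np.float32, copy=False)
        h = self.stem_act.forward(self.stem.forward(x))
        skips = []
        for i in range(cfg.levels):
            skips.append(h)
            h = self.down_acts[i].forward(self.downs[i].forward(h))
        h = self.bottom_act.forward(self.bottom.forward(h))
        for i in reversed(range(cfg.levels)):
            h = self.up_acts[i].forward(self.ups[i].forward(h))
            h = np.concatenate([h, skips[i]], axis=-1)
            h = self.merge_acts[i].forward(self.merges[i].forward(h))
            for blk in self.blocks[i]:
                h = blk.forward(h)
        return self.out_act.forward(self.head.forward(h))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cfg = self.config
        dh = self.head.backward(self.out_act.backward(dy))
        dskips = [None] * cfg.levels
        for i in range(cfg.levels):
            for blk in reversed(self.blocks[i]):
                dh = blk.backward(dh)
            dh = self.merges[i].backward(self.merge_acts[i].backward(dh))
            w_i = self.widths[i]
            dskips[i] = dh[..., w_i:]
            dh = self.ups[i].backward(self.up_acts[i].backward(dh[..., :w_i]))
        dh = self.bottom.backward(self.bottom_act.backward(dh))
        for i in reversed(range(cfg.levels)):
            dh = self.downs[i].backward(self.down_acts[i].backward(dh))
            dh = dh + dskips[i]
        return self.stem.backward(self.stem_act.backward(dh))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.params())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, net has {len(params)}")
        for i, p in enumerate(params):
            src = arrays[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch at p{i}: {src.shape} vs {p.data.shape}")
            p.data = src.astype(np.float32)
            p.grad = np.zeros_like(p.data)


def build_resunet(config: NetworkConfig, seed: int = 0) -> ResUNet:
    """Construct a ResU-Net; defaults give 8 bottleneck blocks and 4 down/4 up."""
    return ResUNet(config, seed=seed)


def count_parameters(net) -> int:
    """Exact trainable scalar count of a network or layer."""
    return int(sum(p.size for p in net.params()))


def save_network(net: ResUNet, path_npz, path_json=None) -> None:
    """Save weights as .npz with a JSON architecture sidecar."""
    np.savez_compressed(str(path_npz), **net.state_arrays())
    if path_json is not None:
        with open(str(path_json), "w") as fh:
            json.dump(asdict(net.config), fh, indent=2)


def load_network(path_npz, config: NetworkConfig | None = None,
                 path_json=None) -> ResUNet:
    if config is None:
        with open(str(path_json)) as fh:
            config = NetworkConfig(**json.load(fh))
    net = ResUNet(config, seed=0)
    with np.load(str(path_npz)) as data:
        net.load_state_arrays({k: data[k] for k in data.files})
    return net
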