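"""Configurable MultiRes encoder-decoder for binary dense prediction.

Each level replaces the plain double convolution of a U-shaped network
with a MultiRes block: three chained 3x3 convolutions whose outputs are
concatenated and summed with a 1x1-convolved shortcut, the branch widths
splitting roughly 1/6, 1/3, 1/2 of the level's total width
``W = alpha * base_width * 2^level``.  Skip connections are replaced by
Res paths — chains of 3x3 convolutions with 1x1 residual shortcuts whose
length shrinks with depth (4, 3, 2, 1 for four levels).  A final 1x1
convolution plus sigmoid yields a per-pixel foreground probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor, add, concat, maxpool2, relu, sigmoid
from .layers import BatchNorm2d, Conv2d, ConvTranspose2x2, Module

__all__ = ["NetworkConfig", "MultiResUNet", "build_multiresunet", "count_parameters",
           "save_model", "load_model"]


@dataclass(frozen=True)
class NetworkConfig:
    input_channels: int = 1
    n_levels: int = 4
    base_width: int = 16
    alpha: float = 1.67
    output_classes: int = 1

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"n_levels must be >= 1, got {self.n_levels}")
        if self.base_width < 4:
            raise ValueError(f"base_width must be >= 4, got {self.base_width}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.input_channels < 1 or self.output_classes != 1:
            raise ValueError("input_channels must be >= 1 and output_classes must be 1")


def branch_widths(total: float) -> tuple[int, int, int]:
    """Split a level width into three branches ~(1/6, 1/3, 1/2).

    Widths round to nearest; the remainder goes to the widest branch.
    """
    w = int(round(total))
    w1 = int(round(w / 6.0))
    w2 = int(round(w / 3.0))
    w3 = w - w1 - w2
    if min(w1, w2, w3) < 1:
        raise ValueError(f"level width {total} rounds to a zero-channel branch: {(w1, w2, w3)}")
    return w1, w2, w3


class MultiResBlock(Module):
    def __init__(self, in_channels: int, total_width: float, rng):
        w1, w2, w3 = branch_widths(total_width)
        self.widths = (w1, w2, w3)
        self.out_channels = w1 + w2 + w3
        self.conv1 = Conv2d(in_channels, w1, 3, rng)
        self.bn1 = BatchNorm2d(w1)
        self.conv2 = Conv2d(w1, w2, 3, rng)
        self.bn2 = BatchNorm2d(w2)
        self.conv3 = Conv2d(w2, w3, 3, rng)
        self.bn3 = BatchNorm2d(w3)
        self.shortcut = Conv2d(in_channels, self.out_channels, 1, rng)
        self.bn_short = BatchNorm2d(self.out_channels)
        self.bn_out = BatchNorm2d(self.out_channels)

    def __call__(self, x: Tensor) -> Tensor:
        b1 = relu(self.bn1(self.conv1(x)))
        b2 = relu(self.bn2(self.conv2(b1)))
        b3 = relu(self.bn3(self.conv3(b2)))
        cat = concat([b1, b2, b3])
        short = self.bn_short(self.shortcut(x))
        return self.bn_out(relu(add(cat, short)))


class ResPath(Module):
    """Skip-connection chain: n steps of 3x3 conv with 1x1 residual shortcut."""

    def __init__(self, channels: int, length: int, rng):
        self.convs = [Conv2d(channels, channels, 3, rng) for _ in range(length)]
        self.bns = [BatchNorm2d(channels) for _ in range(length)]
        self.shortcuts = [Conv2d(channels, channels, 1, rng) for _ in range(length)]
        self.bn_shorts = [BatchNorm2d(channels) for _ in range(length)]
        self.bn_outs = [BatchNorm2d(channels) for _ in range(length)]

    def __call__(self, x: Tensor) -> Tensor:
        for conv, bn, sc, bn_sc, bn_out in zip(
            self.convs, self.bns, self.shortcuts, self.bn_shorts, self.bn_outs
        ):
            main = relu(bn(conv(x)))
            short = bn_sc(sc(x))
            x = bn_out(relu(add(main, short)))
        return x


class MultiResUNet(Module):
    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        L = config.n_levels
        widths = [config.alpha * config.base_width * (2**l) for l in range(L + 1)]

        self.enc_blocks: list[MultiResBlock] = []
        self.res_paths: list[ResPath] = []
        in_ch = config.input_channels
        enc_out: list[int] = []
        for l in range(L):
            block = MultiResBlock(in_ch, widths[l], rng)
            self.enc_blocks.append(block)
            self.res_paths.append(ResPath(block.out_channels, L - l, rng))
            enc_out.append(block.out_channels)
            in_ch = block.out_channels

        self.bottleneck = MultiResBlock(in_ch, widths[L], rng)

        self.ups: list[ConvTranspose2x2] = []
        self.dec_blocks: list[MultiResBlock] = []
        up_in = self.bottleneck.out_channels
        for l in reversed(range(L)):
            up = ConvTranspose2x2(up_in, enc_out[l], rng)
            block = MultiResBlock(2 * enc_out[l], widths[l], rng)
            self.ups.append(up)
            self.dec_blocks.append(block)
            up_in = block.out_channels

        self.head = Conv2d(up_in, config.output_classes, 1, rng, bias=True)

    def forward(self, x) -> Tensor:
        """Probability field for a (N, C, H, W) batch; H, W divisible by 2^L."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        n, c, h, w = x.data.shape
        L = self.config.n_levels
        if c != self.config.input_channels:
            raise ValueError(f"expected {self.config.input_channels} input channels, got {c}")
        if h % (2**L) or w % (2**L):
            raise ValueError(f"spatial sides {h}x{w} must be divisible by {2**L}")
        skips = []
        for block, path in zip(self.enc_blocks, self.res_paths):
            x = block(x)
            skips.append(path(x))
            x = maxpool2(x)
        x = self.bottleneck(x)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = concat([up(x), skip])
            x = block(x)
        return sigmoid(self.head(x))

    __call__ = forward


def build_multiresunet(config: NetworkConfig, seed: int = 0) -> MultiResUNet:
    """Construct a model with reproducible weight initialization."""
    return MultiResUNet(config, seed=seed)


def count_parameters(model: MultiResUNet) -> int:
    return sum(p.data.size for p in model.parameters())


def _state_arrays(model: MultiResUNet) -> dict[str, np.ndarray]:
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    i = 0
    for bn in _iter_batchnorms(model):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
        i += 1
    return arrays


def _iter_batchnorms(module: Module):
    for value in module.__dict__.values():
        yield from _bns_of(value)


def _bns_of(value):
    if isinstance(value, BatchNorm2d):
        yield value
    elif isinstance(value, Module):
        yield from _iter_batchnorms(value)
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _bns_of(item)


def save_model(model: MultiResUNet, path: str | Path) -> None:
    """Save weights + running stats to one .npz with the config embedded."""
    path = Path(path)
    arrays = _state_arrays(model)
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> MultiResUNet:
    path = Path(path)
    with np.load(path) as data:
        config = NetworkConfig(**json.loads(bytes(data["config_json"].tobytes()).decode()))
        model = build_multiresunet(config)
        for i, p in enumerate(model.parameters()):
            p.data = data[f"param_{i}"].astype(np.float32)
        for i, bn in enumerate(_iter_batchnorms(model)):
            bn.running_mean = data[f"bn_mean_{i}"].astype(np.float32)
            bn.running_var = data[f"bn_var_{i}"].astype(np.float32)
    return model
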