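"""Network architectures: the direct classifier (DoubleConv CNN + five-layer
FNN with dropout and softmax output) and a 3D U-Net style encoder-decoder
with skip connections for dens segmentation."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import BatchNorm3d, Conv3d, DoubleConv, Linear, Module
from ..errors import ParameterError

__all__ = ["M1Config", "UNetConfig", "M1Net", "UNet3d"]


@dataclass(frozen=True)
class M1Config:
    """DoubleConv channel widths, FNN hidden widths (the output layer with 2
    classes is appended, giving five dense layers in total) and dropout."""

    double_conv_channels: tuple = (4, 8)
    fnn_layers: tuple = (64, 32, 16, 8)
    dropout_rate: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if len(self.fnn_layers) != 4:
            raise ParameterError("fnn_layers must list 4 hidden widths (5 layers with output)")


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 2
    base_channels: int = 8
    dice_weight: float = 0.5
    ce_weight: float = 0.5

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.dice_weight < 0 or self.ce_weight < 0 or self.dice_weight + self.ce_weight == 0:
            raise ParameterError("loss weights must be >= 0 and not both zero")


class M1Net(Module):
    """Single-stage fracture classifier over whole (preprocessed) volumes."""

    def __init__(self, cfg: M1Config, input_shape: tuple, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.input_shape = tuple(input_shape)
        chans = cfg.double_conv_channels
        self.blocks = []
        cin = 1
        for c in chans:
            self.blocks.append(DoubleConv(cin, c, rng))
            cin = c
        factor = 2 ** len(chans)
        for s in self.input_shape:
            if s % factor != 0:
                raise ParameterError(
                    f"input_shape {input_shape} not divisible by pooling factor {factor}"
                )
        flat = cin * int(np.prod([s // factor for s in self.input_shape]))
        widths = [flat, *cfg.fnn_layers, 2]
        self.fnn = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]

    def forward(self, x: np.ndarray, training: bool, rng=None) -> Tensor:
        """``x`` is (N, D, H, W); returns (N, 2) class logits."""
        if rng is None:
            rng = np.random.default_rng(0)
        t = Tensor(x[:, None, :, :, :])
        for block in self.blocks:
            t = block(t, training)
            t = ag.maxpool2(t)
        t = ag.reshape(t, (t.shape[0], -1))
        for i, lin in enumerate(self.fnn):
            t = lin(t)
            if i < len(self.fnn) - 1:
                t = ag.relu(t)
                t = ag.dropout(t, self.cfg.dropout_rate, rng, training)
        return t


class UNet3d(Module):
    """Encoder-decoder segmentation network with skip connections.

    The decoder upsamples (nearest-neighbour) and concatenates the matching
    encoder feature map before a DoubleConv; a 1x1x1 convolution emits
    per-voxel 2-class logits.
    """

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b = cfg.base_channels
        self.encoders = []
        cin = 1
        enc_out = []
        for level in range(cfg.depth):
            cout = b * 2**level
            self.encoders.append(DoubleConv(cin, cout, rng))
            enc_out.append(cout)
            cin = cout
        self.bottleneck = DoubleConv(cin, b * 2**cfg.depth, rng)
        self.decoders = []
        cin = b * 2**cfg.depth
        for level in reversed(range(cfg.depth)):
            skip = enc_out[level]
            cout = b * 2**level
            self.decoders.append(DoubleConv(cin + skip, cout, rng))
            cin = cout
        self.head = Conv3d(cin, 2, 1, rng)

    def forward(self, x: np.ndarray, training: bool) -> Tensor:
        """``x`` is (N, D, H, W); returns (N, 2, D, H, W) voxel logits."""
        t = Tensor(x[:, None, :, :, :])
        skips = []
        for enc in self.encoders:
            t = enc(t, training)
            skips.append(t)
            t = ag.maxpool2(t)
        t = self.bottleneck(t, training)
        for dec, skip in zip(self.decoders, reversed(skips)):
            t = ag.upsample2(t)
            t = ag.concat_channels(t, skip)
            t = dec(t, training)
        return self.head(t)
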