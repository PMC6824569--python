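"""The 27-layer residual U-net operating on full-size sinograms.

Layer accounting matches the reference table for the full-size configuration
(input 720 x 731, 64 base channels, 4 down-samplings): one input layer, three
full-resolution convolutions, four encoder stages of [stride-2 down-sampling
convolution doubling the channels, 3x3 convolution], four decoder stages of
[2x transposed convolution halving the channels, two 3x3 convolutions on the
skip-concatenated maps], one 1-channel 3x3 convolution, a residual addition
of the network input, and a final whole-map normalization — 27 layers at
depth 4, ``5 * depth + 7`` in general.

Every convolution and transposed convolution is followed by feature-map
normalization and ReLU, except the 1-channel output convolution, which is
linear.  Down-sampling is a trainable 2x2 stride-2 convolution by default;
max/mean-pooling variants pair the fixed pooling with a 1x1 convolution for
the channel doubling so all feature-map shapes are unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from sinoct.network.layers import (
    ChannelNorm,
    Conv2D,
    ConvTranspose2D,
    GlobalNorm,
    MaxPool2x2,
    MeanPool2x2,
    ReLU,
)
from sinoct.network.normalization import NormalizedGrid

__all__ = ["LayerSpec", "SinoUNet", "build_unet", "forward_pass"]

POOLING_MODES = ("strided_conv", "max_pool", "mean_pool")

Shape3 = Tuple[int, int, int]


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table."""

    index: int
    kind: str  # input | conv | conv_transpose | add | norm
    in_shape: Shape3
    out_shape: Shape3
    stride: Optional[Tuple[int, int]] = None
    kernel: Optional[Tuple[int, int]] = None


class _ConvBlock:
    """conv (or transposed conv) + optional feature-map norm + ReLU."""

    def __init__(self, conv, normed: bool = True, activated: bool = True):
        self.conv = conv
        self.norm = ChannelNorm(conv.c_out) if normed else None
        self.act = ReLU() if activated else None

    def forward(self, x: np.ndarray, out_hw=None) -> np.ndarray:
        if out_hw is not None:
            h = self.conv.forward(x, out_hw)
        else:
            h = self.conv.forward(x)
        if self.norm is not None:
            h = self.norm.forward(h)
        if self.act is not None:
            h = self.act.forward(h)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.act is not None:
            dy = self.act.backward(dy)
        if self.norm is not None:
            dy = self.norm.backward(dy)
        return self.conv.backward(dy)

    @property
    def layers(self):
        out = [self.conv]
        if self.norm is not None:
            out.append(self.norm)
        return out


class _DownBlock:
    """Stride-2 spatial halving with channel doubling.

    ``strided_conv``: a single trainable 2x2 stride-2 convolution (its four
    window coefficients per filter are the learned down-sampling weights).
    ``max_pool`` / ``mean_pool``: the fixed 2x2 pooling followed by a 1x1
    convolution for the channel doubling.
    """

    def __init__(self, c_in: int, mode: str):
        self.mode = mode
        if mode == "strided_conv":
            self.pool = None
            self.conv_block = _ConvBlock(Conv2D(c_in, 2 * c_in, kernel=2, stride=2))
        elif mode == "max_pool":
            self.pool = MaxPool2x2()
            self.conv_block = _ConvBlock(Conv2D(c_in, 2 * c_in, kernel=1, stride=1))
        elif mode == "mean_pool":
            self.pool = MeanPool2x2()
            self.conv_block = _ConvBlock(Conv2D(c_in, 2 * c_in, kernel=1, stride=1))
        else:
            raise ValueError(f"pooling_mode must be one of {POOLING_MODES}, got {mode!r}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pool is not None:
            x = self.pool.forward(x)
        return self.conv_block.forward(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.conv_block.backward(dy)
        if self.pool is not None:
            dy = self.pool.backward(dy)
        return dy

    @property
    def layers(self):
        return self.conv_block.layers


class SinoUNet:
    """Residual U-net: ``output = global_norm(residual_conv(...) + input)``."""

    def __init__(
        self,
        input_shape: Tuple[int, int],
        base_channels: int = 64,
        depth: int = 4,
        pooling_mode: str = "strided_conv",
    ):
        h, w = input_shape
        if base_channels < 1:
            raise ValueError(f"base_channels must be >= 1, got {base_channels}")
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if h < 2**depth or w < 2**depth:
            raise ValueError(
                f"input shape {input_shape} too small for {depth} down-samplings"
            )
        if pooling_mode not in POOLING_MODES:
            raise ValueError(
                f"pooling_mode must be one of {POOLING_MODES}, got {pooling_mode!r}"
            )
        self.input_shape = (int(h), int(w))
        self.base_channels = int(base_channels)
        self.depth = int(depth)
        self.pooling_mode = pooling_mode

        c = base_channels
        self.head = [
            _ConvBlock(Conv2D(1, c)),
            _ConvBlock(Conv2D(c, c)),
            _ConvBlock(Conv2D(c, c)),
        ]
        self.down_blocks: List[_DownBlock] = []
        self.enc_convs: List[_ConvBlock] = []
        ch = c
        for _ in range(depth):
            self.down_blocks.append(_DownBlock(ch, pooling_mode))
            ch *= 2
            self.enc_convs.append(_ConvBlock(Conv2D(ch, ch)))
        self.up_blocks: List[_ConvBlock] = []
        self.dec_convs: List[Tuple[_ConvBlock, _ConvBlock]] = []
        for _ in range(depth):
            self.up_blocks.append(_ConvBlock(ConvTranspose2D(ch, ch // 2)))
            ch //= 2
            self.dec_convs.append(
                (_ConvBlock(Conv2D(2 * ch, ch)), _ConvBlock(Conv2D(ch, ch)))
            )
        self.final_conv = _ConvBlock(Conv2D(c, 1), normed=False, activated=False)
        self.global_norm = GlobalNorm()
        self.layer_specs = self._build_specs()

    # ------------------------------------------------------------------
    # architecture table

    def _axis_sizes(self, n: int) -> List[int]:
        sizes = [n]
        for _ in range(self.depth):
            sizes.append(math.ceil(sizes[-1] / 2))
        return sizes

    def _build_specs(self) -> List[LayerSpec]:
        h, w = self.input_shape
        hs, ws = self._axis_sizes(h), self._axis_sizes(w)
        c = self.base_channels
        specs = [LayerSpec(1, "input", (h, w, 1), (h, w, 1))]
        i = 2

        def add(kind, ins, outs, stride, kernel):
            nonlocal i
            specs.append(LayerSpec(i, kind, ins, outs, stride, kernel))
            i += 1

        add("conv", (h, w, 1), (h, w, c), (1, 1), (3, 3))
        add("conv", (h, w, c), (h, w, c), (1, 1), (3, 3))
        add("conv", (h, w, c), (h, w, c), (1, 1), (3, 3))
        ch = c
        for d in range(self.depth):
            add(
                "conv",
                (hs[d], ws[d], ch),
                (hs[d + 1], ws[d + 1], 2 * ch),
                (2, 2),
                (2, 2),
            )
            ch *= 2
            add("conv", (hs[d + 1], ws[d + 1], ch), (hs[d + 1], ws[d + 1], ch), (1, 1), (3, 3))
        for d in range(self.depth - 1, -1, -1):
            add(
                "conv_transpose",
                (hs[d + 1], ws[d + 1], ch),
                (hs[d], ws[d], ch // 2),
                (2, 2),
                (3, 3),
            )
            ch //= 2
            add("conv", (hs[d], ws[d], 2 * ch), (hs[d], ws[d], ch), (1, 1), (3, 3))
            add("conv", (hs[d], ws[d], ch), (hs[d], ws[d], ch), (1, 1), (3, 3))
        add("conv", (h, w, c), (h, w, 1), (1, 1), (3, 3))
        add("add", (h, w, 2), (h, w, 1), None, None)
        add("norm", (h, w, 1), (h, w, 1), None, None)
        return specs

    @property
    def n_layers(self) -> int:
        return len(self.layer_specs)

    # ------------------------------------------------------------------
    # parameters

    def _blocks(self):
        blocks = list(self.head) + list(self.down_blocks) + list(self.enc_convs)
        for up, (ca, cb) in zip(self.up_blocks, self.dec_convs):
            blocks += [up, ca, cb]
        blocks.append(self.final_conv)
        return blocks

    def trainable_layers(self):
        out = []
        for b in self._blocks():
            out.extend(b.layers)
        return out

    def parameters(self) -> List[np.ndarray]:
        out = []
        for layer in self.trainable_layers():
            out.extend(layer.params)
        return out

    def gradients(self) -> List[np.ndarray]:
        out = []
        for layer in self.trainable_layers():
            out.extend(layer.grads)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ------------------------------------------------------------------
    # forward / backward

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full forward pass on a 2-D ``(H, W)`` grid; returns a 2-D grid."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != self.input_shape:
            raise ValueError(
                f"input shape {x.shape} != network input shape {self.input_shape}"
            )
        h = x[:, :, None]
        self._x_in = h
        for block in self.head:
            h = block.forward(h)
        skips = [h]
        for d in range(self.depth):
            h = self.down_blocks[d].forward(h)
            h = self.enc_convs[d].forward(h)
            if d < self.depth - 1:
                skips.append(h)
        self._skip_shapes = [s.shape for s in skips]
        for d in range(self.depth):
            skip = skips[self.depth - 1 - d]
            h = self.up_blocks[d].forward(h, out_hw=skip.shape[:2])
            h = np.concatenate([h, skip], axis=2)
            ca, cb = self.dec_convs[d]
            h = ca.forward(h)
            h = cb.forward(h)
        r = self.final_conv.forward(h)
        y = self.global_norm.forward(r + self._x_in)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("non-finite values in network output")
        return y[:, :, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate a 2-D output gradient; fills every layer's grads."""
        d = self.global_norm.backward(np.asarray(dy, dtype=np.float64)[:, :, None])
        dx_in = d  # residual branch straight to the input
        d = self.final_conv.backward(d)
        dskips = [None] * self.depth  # indexed like skips (0 = head output)
        for dd in range(self.depth - 1, -1, -1):
            ca, cb = self.dec_convs[dd]
            d = cb.backward(d)
            d = ca.backward(d)
            skip_idx = self.depth - 1 - dd
            n_up = d.shape[2] // 2
            d_up, d_skip = d[:, :, :n_up], d[:, :, n_up:]
            dskips[skip_idx] = d_skip
            d = self.up_blocks[dd].backward(d_up)
        for dd in range(self.depth - 1, -1, -1):
            if dd < self.depth - 1:
                d = d + dskips[dd + 1]
            d = self.enc_convs[dd].backward(d)
            d = self.down_blocks[dd].backward(d)
        d = d + dskips[0]
        for block in reversed(self.head):
            d = block.backward(d)
        return (d + dx_in)[:, :, 0]

    def predict(self, x: NormalizedGrid) -> NormalizedGrid:
        """Inference on a normalized grid; propagates the source statistics
        so the restored sinogram can be mapped back to physical units."""
        y = self.forward(x.values)
        return NormalizedGrid(y, x.source_mean, x.source_std)

    # ------------------------------------------------------------------
    # (de)serialization of the parameter state

    def state_arrays(self) -> List[np.ndarray]:
        return self.parameters()

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, network expects {len(params)}"
            )
        for i, (p, a) in enumerate(zip(params, arrays)):
            if p.shape != a.shape:
                raise ValueError(
                    f"checkpoint array {i} has shape {a.shape}, "
                    f"network parameter expects {p.shape}"
                )
            p[...] = a


def build_unet(
    input_shape: Tuple[int, int],
    base_channels: int = 64,
    depth: int = 4,
    pooling_mode: str = "strided_conv",
) -> SinoUNet:
    """Construct the residual sinogram U-net (weights zero until initialized)."""
    return SinoUNet(input_shape, base_channels, depth, pooling_mode)


def forward_pass(net: SinoUNet, x: NormalizedGrid) -> NormalizedGrid:
    """Run the network on a normalized grid (inference semantics)."""
    return net.predict(x)
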