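"""Depth-Attention-UNet: a dual-encoder attention U-Net for RGB-D input.

Two parallel encoder streams — one for the 3-channel color image, one for
the 1-channel depth map — each apply two 3x3 convolutions + ReLU per level
followed by 2x max pooling.  At every level the two streams' pre-pooling
features are fused (elementwise sum by default, or concatenation + 1x1
projection); the fused features feed the decoder's skip connections through
additive attention gates, while each stream continues downward from its own
unfused features.  The decoder mirrors the encoder with nearest-neighbor 2x
upsampling + 3x3 convolution, gating each fused skip with the coarser
decoder feature, and ends in a 1x1 head producing per-pixel tree/background
scores.

A single-encoder ``AttentionUNet`` baseline (RGB only, no fusion) is
provided for architectural comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class SegNetConfig:
    """Network + training configuration.

    Defaults follow the full-scale training recipe (512x512 input, batch 8,
    initial learning rate 1e-3, 200 optimization steps, 64 base channels over
    5 levels); tests scale ``base_channels``/``levels``/``input_size`` down.
    """

    input_size: int = 512
    levels: int = 5
    base_channels: int = 64
    fusion: str = "sum"              # "sum" or "concat_project"
    batch_size: int = 8
    learning_rate: float = 1e-3
    total_steps: int = 200

    def __post_init__(self) -> None:
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if self.input_size % (2 ** (self.levels - 1)):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.levels - 1}")
        if self.fusion not in ("sum", "concat_project"):
            raise ValueError("fusion must be 'sum' or 'concat_project'")

    def channels(self) -> List[int]:
        return [self.base_channels * 2 ** i for i in range(self.levels)]


class _DoubleConv:
    """Two 3x3 conv + ReLU blocks."""

    def __init__(self, rng, cin: int, cout: int):
        self.w1 = nn.he_init(rng, (cout, cin, 3, 3), fan_in=cin * 9)
        self.b1 = nn.zeros_param((cout,))
        self.w2 = nn.he_init(rng, (cout, cout, 3, 3), fan_in=cout * 9)
        self.b2 = nn.zeros_param((cout,))

    def __call__(self, x: Tensor) -> Tensor:
        x = nn.relu(nn.conv2d(x, self.w1, self.b1))
        return nn.relu(nn.conv2d(x, self.w2, self.b2))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


class _Conv1x1:
    def __init__(self, rng, cin: int, cout: int):
        self.w = nn.he_init(rng, (cout, cin, 1, 1), fan_in=cin)
        self.b = nn.zeros_param((cout,))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv2d(x, self.w, self.b, pad=0)

    def params(self):
        return [self.w, self.b]


class _AttentionGate:
    """Additive attention: att = sigma(psi(ReLU(Wg g + Wx x))); returns x*att.

    ``g`` is the (already upsampled) coarser decoder feature, ``x`` the fused
    skip feature at the same resolution; the inter-channel width is half the
    skip width, and the single-channel attention map broadcasts over channels.
    """

    def __init__(self, rng, c_skip: int, c_gate: int):
        inter = max(1, c_skip // 2)
        self.wg = _Conv1x1(rng, c_gate, inter)
        self.wx = _Conv1x1(rng, c_skip, inter)
        self.psi = _Conv1x1(rng, inter, 1)

    def __call__(self, g: Tensor, x: Tensor) -> Tensor:
        att = nn.sigmoid(self.psi(nn.relu(nn.add(self.wg(g), self.wx(x)))))
        return nn.mul(x, att)

    def params(self):
        return self.wg.params() + self.wx.params() + self.psi.params()


class _UpConv:
    """2x nearest upsampling followed by a 3x3 conv halving the channels."""

    def __init__(self, rng, cin: int, cout: int):
        self.w = nn.he_init(rng, (cout, cin, 3, 3), fan_in=cin * 9)
        self.b = nn.zeros_param((cout,))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(nn.conv2d(nn.upsample2x(x), self.w, self.b))

    def params(self):
        return [self.w, self.b]


class _Decoder:
    """Shared decoder: attention-gated skips + double convs + 1x1 head."""

    def __init__(self, rng, chans: List[int]):
        self.ups, self.gates, self.blocks = [], [], []
        for i in range(len(chans) - 2, -1, -1):
            self.ups.append(_UpConv(rng, chans[i + 1], chans[i]))
            self.gates.append(_AttentionGate(rng, c_skip=chans[i], c_gate=chans[i]))
            self.blocks.append(_DoubleConv(rng, 2 * chans[i], chans[i]))
        self.head = _Conv1x1(rng, chans[0], 1)

    def __call__(self, bottom: Tensor, skips: List[Tensor]) -> Tensor:
        d = bottom
        for up, gate, block, skip in zip(self.ups, self.gates, self.blocks,
                                         reversed(skips)):
            g = up(d)
            d = block(nn.concat([gate(g, skip), g], axis=1))
        return self.head(d)

    def params(self):
        out = []
        for part in (*self.ups, *self.gates, *self.blocks, self.head):
            out += part.params()
        return out


class DepthAttentionUNet:
    """Dual-encoder (RGB + depth) attention U-Net with per-level fusion."""

    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        chans = config.channels()
        self.rgb_enc = [_DoubleConv(rng, cin, cout) for cin, cout
                        in zip([3] + chans[:-1], chans)]
        self.depth_enc = [_DoubleConv(rng, cin, cout) for cin, cout
                          in zip([1] + chans[:-1], chans)]
        if config.fusion == "concat_project":
            self.fusers = [_Conv1x1(rng, 2 * c, c) for c in chans]
        else:
            self.fusers = None
        self.decoder = _Decoder(rng, chans)

    def _fuse(self, a: Tensor, b: Tensor, level: int) -> Tensor:
        if self.fusers is None:
            return nn.add(a, b)
        return self.fusers[level](nn.concat([a, b], axis=1))

    def forward(self, rgb: np.ndarray, depth: np.ndarray) -> Tensor:
        """rgb: (N,3,H,W) in [0,1]; depth: (N,1,H,W) in [0,1] -> (N,1,H,W) logits."""
        xr, xd = Tensor(rgb), Tensor(depth)
        skips = []
        for lvl in range(self.config.levels):
            fr = self.rgb_enc[lvl](xr)
            fd = self.depth_enc[lvl](xd)
            fused = self._fuse(fr, fd, lvl)
            if lvl < self.config.levels - 1:
                skips.append(fused)
                # streams continue from their own unfused features
                xr, xd = nn.maxpool2x2(fr), nn.maxpool2x2(fd)
            else:
                bottom = fused
        return self.decoder(bottom, skips)

    def params(self) -> List[Tensor]:
        out = []
        for block in self.rgb_enc + self.depth_enc:
            out += block.params()
        if self.fusers is not None:
            for f in self.fusers:
                out += f.params()
        return out + self.decoder.params()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))


class AttentionUNet:
    """Single-encoder (RGB only) attention U-Net baseline."""

    def __init__(self, config: SegNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        chans = config.channels()
        self.enc = [_DoubleConv(rng, cin, cout) for cin, cout
                    in zip([3] + chans[:-1], chans)]
        self.decoder = _Decoder(rng, chans)

    def forward(self, rgb: np.ndarray, depth: Optional[np.ndarray] = None) -> Tensor:
        x = Tensor(rgb)
        skips = []
        for lvl in range(self.config.levels):
            f = self.enc[lvl](x)
            if lvl < self.config.levels - 1:
                skips.append(f)
                x = nn.maxpool2x2(f)
            else:
                bottom = f
        return self.decoder(bottom, skips)

    def params(self) -> List[Tensor]:
        out = []
        for block in self.enc:
            out += block.params()
        return out + self.decoder.params()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))


def build_network(config: SegNetConfig, seed: int = 0,
                  dual_encoder: bool = True):
    """Construct the RGB-D network (or the RGB-only baseline)."""
    cls = DepthAttentionUNet if dual_encoder else AttentionUNet
    return cls(config, seed=seed)


def save_weights(net, path) -> None:
    """Persist network parameters + config to an .npz archive."""
    import json

    arrays = {f"param_{i}": p.data for i, p in enumerate(net.params())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(net.config.__dict__).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_weights(path) -> DepthAttentionUNet:
    """Reconstruct a DepthAttentionUNet from :func:`save_weights` output."""
    import json

    with np.load(path) as data:
        cfg = SegNetConfig(**json.loads(bytes(data["config_json"]).decode()))
        net = DepthAttentionUNet(cfg, seed=0)
        params = net.params()
        for i, p in enumerate(params):
            stored = data[f"param_{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(f"weight {i} shape {stored.shape} != {p.data.shape}")
            p.data = stored.astype(np.float64)
    return net
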