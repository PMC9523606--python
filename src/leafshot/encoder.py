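"""The embedding network f_theta: a four-block backbone with per-block
feature taps, cascaded or parallel multi-scale fusion, channel attention,
and global average pooling to an embedding vector.

The backbone doubles channels and (ceil-)halves resolution at every block,
so the four taps have channels (C, 2C, 4C, 8C). Cascaded fusion walks
deep-to-shallow, upsampling the running feature 2x (nearest-neighbour,
center-crop/pad to the next tap's size) and concatenating, accumulating
channels 8C -> 12C -> 14C -> 15C; parallel fusion upsamples every tap
straight to the shallowest resolution and concatenates once, giving the
same 15C channels. Channel attention (the channel branch of CBAM) pools
the fused map spatially by average and max, pushes both descriptors
through one shared one-hidden-layer MLP, sums, and gates each channel with
a sigmoid weight in (0, 1).

Three ablation arms differ only in config flags: the plain backbone
(fusion=none, attention=none), + cascaded fusion, + fusion and attention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, Module, Conv2d, Linear, BatchNorm2d

__all__ = [
    "EncoderConfig",
    "Encoder",
    "FeatureMapSet",
    "cascade_fuse",
    "parallel_fuse",
    "ChannelAttention",
    "save_checkpoint",
    "load_checkpoint",
]

MIN_INPUT_SIZE = 16  # four ceil-halvings stay nondegenerate from here up


@dataclass(frozen=True)
class EncoderConfig:
    """Architecture switches of the embedding network.

    backbone : "conv4" or "resnet12".
    base_width : channels of the first block (doubled at each block).
    fusion : "none" | "cascaded" | "parallel".
    attention : "none" | "channel".
    reduction_ratio : r in the attention MLP hidden size max(C/r, 1).
    reduce_conv : optional 1x1 conv after fusion (off by default; the fused
        map feeds attention raw).
    """

    backbone: str = "conv4"
    base_width: int = 64
    fusion: str = "cascaded"
    attention: str = "channel"
    reduction_ratio: int = 16
    reduce_conv: int = 0  # 0 = off, else output channels of the 1x1 conv

    def __post_init__(self):
        if self.backbone not in ("conv4", "resnet12"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.fusion not in ("none", "cascaded", "parallel"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.attention not in ("none", "channel"):
            raise ValueError(f"unknown attention {self.attention!r}")
        if self.base_width < 1 or self.reduction_ratio < 1:
            raise ValueError("base_width and reduction_ratio must be >= 1")

    @property
    def fused_channels(self) -> int:
        """Embedding length: 15C fused (8+4+2+1 tap channels), 8C unfused."""
        if self.fusion == "none":
            return 8 * self.base_width
        if self.reduce_conv:
            return self.reduce_conv
        return 15 * self.base_width


class FeatureMapSet:
    """Ordered shallow-to-deep activation taps from the backbone."""

    def __init__(self, maps: list[Tensor]):
        if len(maps) != 4:
            raise ValueError("expected 4 feature maps")
        for a, b in zip(maps, maps[1:]):
            if b.shape[1] != 2 * a.shape[1]:
                raise ValueError("channels must double between taps")
            if b.shape[2] != -(-a.shape[2] // 2) or b.shape[3] != -(-a.shape[3] // 2):
                raise ValueError("resolution must ceil-halve between taps")
        self.maps = maps

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, i):
        return self.maps[i]


class _ConvBlock(Module):
    """conv3x3 -> BN -> ReLU -> ceil 2x2 maxpool."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x):
        return ad.maxpool2x2(self.bn(self.conv(x)).relu())


class _ResBlock(Module):
    """Three conv-BN(-ReLU) layers with a projection shortcut, then pool."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.c1 = Conv2d(cin, cout, 3, rng, bias=False)
        self.b1 = BatchNorm2d(cout)
        self.c2 = Conv2d(cout, cout, 3, rng, bias=False)
        self.b2 = BatchNorm2d(cout)
        self.c3 = Conv2d(cout, cout, 3, rng, bias=False)
        self.b3 = BatchNorm2d(cout)
        self.proj = Conv2d(cin, cout, 1, rng, pad=0, bias=False)
        self.bproj = BatchNorm2d(cout)

    def __call__(self, x):
        h = self.b1(self.c1(x)).relu()
        h = self.b2(self.c2(h)).relu()
        h = self.b3(self.c3(h))
        s = self.bproj(self.proj(x))
        return ad.maxpool2x2((h + s).relu())


def cascade_fuse(maps: FeatureMapSet) -> Tensor:
    """Deep-to-shallow iterative fuse: upsample 2x, align, concatenate.

    Channel bookkeeping with base width C: 8C -> 12C -> 14C -> 15C; output
    sits at the shallowest tap's resolution.
    """
    current = maps[3]
    for shallower in (maps[2], maps[1], maps[0]):
        up = ad.upsample2x(current)
        up = ad.crop_or_pad(up, shallower.shape[2], shallower.shape[3])
        current = ad.concat([up, shallower], axis=1)
    return current


def parallel_fuse(maps: FeatureMapSet) -> Tensor:
    """One-step fuse: every tap upsampled straight to the shallowest
    resolution, concatenated deep-first (matching cascaded channel order)."""
    th, tw = maps[0].shape[2], maps[0].shape[3]
    pieces = []
    for m in (maps[3], maps[2], maps[1]):
        up = m
        while up.shape[2] < th or up.shape[3] < tw:
            up = ad.upsample2x(up)
        pieces.append(ad.crop_or_pad(up, th, tw))
    pieces.append(maps[0])
    return ad.concat(pieces, axis=1)


class ChannelAttention(Module):
    """Per-channel sigmoid gate from pooled descriptors through a shared
    one-hidden-layer MLP: M = sigmoid(MLP(avgpool F) + MLP(maxpool F))."""

    def __init__(self, channels: int, reduction_ratio: int, rng):
        super().__init__()
        hidden = max(channels // reduction_ratio, 1)
        self.fc1 = Linear(channels, hidden, rng, bias=False)
        self.fc2 = Linear(hidden, channels, rng, bias=False)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def __call__(self, f: Tensor) -> tuple[Tensor, Tensor]:
        n, c = f.shape[0], f.shape[1]
        flat = f.reshape(n, c, -1)
        avg = flat.mean(axis=2)
        mx = flat.max(axis=2)
        m = (self._mlp(avg) + self._mlp(mx)).sigmoid()     # (n, c) in (0,1)
        out = f * m.reshape(n, c, 1, 1)
        return m, out


class Encoder(Module):
    """The full embedding network; returns (n, D) embeddings."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xE27C])
        w = config.base_width
        widths = [w, 2 * w, 4 * w, 8 * w]
        block = _ConvBlock if config.backbone == "conv4" else _ResBlock
        cin = 3
        for i, cout in enumerate(widths):
            setattr(self, f"block{i + 1}", block(cin, cout, rng))
            cin = cout
        if config.reduce_conv and config.fusion != "none":
            self.reduce = Conv2d(15 * w, config.reduce_conv, 1, rng, pad=0)
        else:
            self.reduce = None
        if config.attention == "channel":
            self.ca = ChannelAttention(
                config.fused_channels, config.reduction_ratio, rng
            )
        else:
            self.ca = None

    # -- stages ------------------------------------------------------------
    def extract_multiscale(self, x: Tensor) -> FeatureMapSet:
        """Run the backbone, tapping the activation after every block."""
        if x.shape[2] < MIN_INPUT_SIZE or x.shape[3] < MIN_INPUT_SIZE:
            raise ValueError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} is below the "
                f"minimum {MIN_INPUT_SIZE}"
            )
        maps = []
        h = x
        for i in range(4):
            h = getattr(self, f"block{i + 1}")(h)
            maps.append(h)
        return FeatureMapSet(maps)

    def fuse(self, maps: FeatureMapSet) -> Tensor:
        if self.config.fusion == "none":
            return maps[3]
        f = (cascade_fuse if self.config.fusion == "cascaded" else parallel_fuse)(maps)
        if self.reduce is not None:
            f = self.reduce(f)
        return f

    def attend(self, f: Tensor) -> tuple[Tensor | None, Tensor]:
        if self.ca is None:
            return None, f
        return self.ca(f)

    def __call__(self, x: Tensor) -> Tensor:
        f = self.fuse(self.extract_multiscale(x))
        _, f = self.attend(f)
        n, c = f.shape[0], f.shape[1]
        return f.reshape(n, c, -1).mean(axis=2)

    def embed(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode embedding of an (n, 3, H, W) array."""
        was_training = self.training
        self.eval()
        outs = []
        with ad.no_grad():
            for i in range(0, len(images), batch_size):
                outs.append(self(Tensor(images[i : i + batch_size])).data)
        self.train(was_training)
        return np.concatenate(outs) if outs else np.empty((0, self.config.fused_channels))


# -- checkpoint container ---------------------------------------------------

def save_checkpoint(path: str, encoder: Encoder, extra: dict | None = None) -> None:
    """Single-file container: npz of parameters + embedded JSON config."""
    meta = {"config": asdict(encoder.config), "extra": extra or {}}
    state = encoder.state_dict()
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> tuple[Encoder, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    enc = Encoder(EncoderConfig(**meta["config"]))
    enc.load_state_dict(state)
    return enc, meta["extra"]
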