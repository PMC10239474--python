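"""3D Swin-Conv-UNet for volumetric density restoration.

The network maps a density cube to an enhanced cube of the same size.
It is a UNet of swin-conv (SC) blocks: three encoder levels, one
bottleneck and three decoder levels, downsampling by stride-2
convolutions and upsampling by stride-2 transposed convolutions, with
encoder-to-decoder skip connections.

Each SC block projects its input with a 1x1x1 convolution, splits the
channels in half, runs a swin-transformer pair (window attention + MLP,
the second sub-block with shifted window partitioning) on one half and a
residual convolution branch (two 3x3x3 convolutions) on the other half
in parallel, concatenates the halves, projects back with a 1x1x1
convolution and adds the block input.

The published architecture's exact channel widths are not reproduced
here; the default is a reduced reference configuration whose box size /
window size contract (box divisible by 8 x window) and block structure
follow the original design.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from .autodiff import (Adam, Conv3d, ConvDown2, ConvUp2, LayerNorm, Linear,
                       Module, Tensor, concat, softmax)

__all__ = ["ScunetConfig", "SCUNet", "build_model",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1   # bumps when the normalisation convention changes


@dataclasses.dataclass
class ScunetConfig:
    """Architecture hyperparameters.

    ``box_size`` must be divisible by ``8 * window_size``: three stride-2
    downsamplings shrink the cube side by 8, and the deepest level must
    still tile into attention windows.
    """

    box_size: int = 48
    window_size: int = 3
    base_channels: int = 32
    channel_mults: tuple[int, ...] = (1, 2, 4, 8)   # 3 levels + bottleneck
    blocks_per_level: int = 1
    mlp_ratio: float = 2.0
    head_channels: int = 32     # attention heads = branch_channels // this
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.box_size % (8 * self.window_size) != 0:
            raise ValueError(
                f"box size {self.box_size} must be divisible by 8 x window "
                f"size ({8 * self.window_size})")
        if len(self.channel_mults) != 4:
            raise ValueError("channel_mults must give 3 levels + bottleneck")
        for m in self.channel_mults:
            if (self.base_channels * m) % 2 != 0:
                raise ValueError("channels must be even at every SC block "
                                 "(parallel split)")

    def level_channels(self) -> list[int]:
        return [self.base_channels * m for m in self.channel_mults]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ScunetConfig":
        d = json.loads(text)
        d["channel_mults"] = tuple(d["channel_mults"])
        return cls(**d)


def _window_partition(x: Tensor, w: int) -> tuple[Tensor, tuple[int, ...]]:
    """(B, C, D, H, W) -> (B * n_windows, w^3, C) token windows."""
    b, c, d, h, wd = x.shape
    t = x.transpose(0, 2, 3, 4, 1)                      # B, D, H, W, C
    t = t.reshape(b, d // w, w, h // w, w, wd // w, w, c)
    t = t.transpose(0, 1, 3, 5, 2, 4, 6, 7)             # B, nd, nh, nw, w, w, w, C
    return t.reshape(-1, w ** 3, c), (b, c, d, h, wd)


def _window_merge(tok: Tensor, w: int, dims: tuple[int, ...]) -> Tensor:
    b, c, d, h, wd = dims
    t = tok.reshape(b, d // w, h // w, wd // w, w, w, w, c)
    t = t.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    t = t.reshape(b, d, h, wd, c)
    return t.transpose(0, 4, 1, 2, 3)


class WindowAttention(Module):
    def __init__(self, rng, dim: int, heads: int):
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(rng, dim, 3 * dim)
        self.proj = Linear(rng, dim, dim)

    def __call__(self, tok: Tensor) -> Tensor:
        nw, t, c = tok.shape
        qkv = self.qkv(tok).reshape(nw, t, 3, self.heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)             # 3, nw, heads, T, hd
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = softmax((q * self.scale) @ k.transpose(0, 1, 3, 2), axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nw, t, c)
        return self.proj(out)


class SwinSubBlock(Module):
    """One transformer sub-block: windowed MSA + MLP with pre-norm."""

    def __init__(self, rng, dim: int, heads: int, window: int,
                 shifted: bool, mlp_ratio: float):
        self.window = window
        self.shift = window // 2 if shifted else 0
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(rng, dim, heads)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(rng, dim, hidden)
        self.fc2 = Linear(rng, hidden, dim)

    def __call__(self, x: Tensor) -> Tensor:
        w, s = self.window, self.shift
        h = x
        if s:
            h = h.roll((-s, -s, -s), (2, 3, 4))
        tok, dims = _window_partition(h, w)
        tok = tok + self.attn(self.norm1(tok))
        tok = tok + self.fc2(self.fc1(self.norm2(tok)).gelu())
        h = _window_merge(tok, w, dims)
        if s:
            h = h.roll((s, s, s), (2, 3, 4))
        return h


class SwinBranch(Module):
    """Two consecutive sub-blocks: regular then shifted window partition."""

    def __init__(self, rng, dim: int, heads: int, window: int, mlp_ratio: float):
        self.block1 = SwinSubBlock(rng, dim, heads, window, False, mlp_ratio)
        self.block2 = SwinSubBlock(rng, dim, heads, window, True, mlp_ratio)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class RConvBranch(Module):
    """Residual local branch: two 3x3x3 convolutions with ReLU."""

    def __init__(self, rng, dim: int):
        self.conv1 = Conv3d(rng, dim, dim, 3, gain=math.sqrt(2.0))  # pre-ReLU
        self.conv2 = Conv3d(rng, dim, dim, 3, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.conv2(self.conv1(x).relu())


class SCBlock(Module):
    """Parallel swin-transformer / residual-convolution block."""

    def __init__(self, rng, dim: int, window: int, mlp_ratio: float,
                 head_channels: int):
        half = dim // 2
        heads = max(1, half // head_channels)
        self.conv_in = Conv3d(rng, dim, dim, 1)
        self.swin = SwinBranch(rng, half, heads, window, mlp_ratio)
        self.rconv = RConvBranch(rng, half)
        # small output gain keeps the untrained block near the identity
        self.conv_out = Conv3d(rng, dim, dim, 1, gain=0.25)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv_in(x)
        half = h.shape[1] // 2
        a = self.swin(h[:, :half])
        b = self.rconv(h[:, half:])
        return x + self.conv_out(concat([a, b], axis=1))


class SCUNet(Module):
    """The full encoder-bottleneck-decoder network."""

    def __init__(self, cfg: ScunetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.level_channels()
        mk = lambda dim: [SCBlock(rng, dim, cfg.window_size, cfg.mlp_ratio,
                                  cfg.head_channels)
                          for _ in range(cfg.blocks_per_level)]
        self.head = Conv3d(rng, 1, ch[0], 3)
        self.enc1 = mk(ch[0])
        self.down1 = ConvDown2(rng, ch[0], ch[1])
        self.enc2 = mk(ch[1])
        self.down2 = ConvDown2(rng, ch[1], ch[2])
        self.enc3 = mk(ch[2])
        self.down3 = ConvDown2(rng, ch[2], ch[3])
        self.bottleneck = mk(ch[3])
        self.up3 = ConvUp2(rng, ch[3], ch[2])
        self.dec3 = mk(ch[2])
        self.up2 = ConvUp2(rng, ch[2], ch[1])
        self.dec2 = mk(ch[1])
        self.up1 = ConvUp2(rng, ch[1], ch[0])
        self.dec1 = mk(ch[0])
        self.tail = Conv3d(rng, ch[0], 1, 1, gain=0.5)

    @staticmethod
    def _run(blocks, x: Tensor) -> Tensor:
        for blk in blocks:
            x = blk(x)
        return x

    def __call__(self, batch: Tensor) -> Tensor:
        """Enhance a batch of cubes: (B, N, N, N) -> (B, N, N, N)."""
        if batch.ndim != 4 or batch.shape[-1] != self.cfg.box_size or \
                batch.shape[-2] != self.cfg.box_size or \
                batch.shape[-3] != self.cfg.box_size:
            raise ValueError(
                f"expected (B, {self.cfg.box_size}^3) input, got {batch.shape}")
        x = batch.reshape(batch.shape[0], 1, *batch.shape[1:])
        e1 = self._run(self.enc1, self.head(x))
        e2 = self._run(self.enc2, self.down1(e1))
        e3 = self._run(self.enc3, self.down2(e2))
        b = self._run(self.bottleneck, self.down3(e3))
        d3 = self._run(self.dec3, self.up3(b) + e3)
        d2 = self._run(self.dec2, self.up2(d3) + e2)
        d1 = self._run(self.dec1, self.up1(d2) + e1)
        out = self.tail(d1)
        return out.reshape(batch.shape)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference without graph construction."""
        from .autodiff.tensor import no_grad
        with no_grad():
            return self(Tensor(np.asarray(batch, dtype=np.float32))).data


def build_model(cfg: ScunetConfig) -> SCUNet:
    """Construct the network with deterministic seeded initialisation."""
    return SCUNet(cfg)


def save_checkpoint(model: SCUNet, path) -> None:
    state = model.state_dict()
    np.savez(path, __config__=model.cfg.to_json(),
             __version__=CHECKPOINT_VERSION, **state)


def load_checkpoint(path) -> SCUNet:
    with np.load(path, allow_pickle=False) as f:
        cfg = ScunetConfig.from_json(str(f["__config__"]))
        state = {k: f[k] for k in f.files if not k.startswith("__")}
    model = build_model(cfg)
    model.load_state_dict(state)
    return model
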