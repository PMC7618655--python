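"""Attention-gated hourglass network built on the numpy autodiff core.

Architecture: a stem bringing the input down to the heatmap resolution
(``input_size / heatmap_stride``), a single hourglass of ``depth``
down/up levels with residual blocks, an attention gate on every skip
connection (gating signal = the coarser decoder feature), and a 1x1
head emitting one response map per landmark.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, constant
from .heatmaps import HeatmapStack
from .layers import Conv2d, Module

__all__ = ["ModelConfig", "AttentionGate", "ResidualBlock", "HourglassNet", "build_hourglass",
           "save_checkpoint", "load_checkpoint"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    width: int = 8  # initial number of channels
    n_landmarks: int = 2
    input_size: int = 64
    heatmap_sigma: float = 1.5
    heatmap_stride: int = 4
    softargmax_beta: float = 15.0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ConfigurationError("width must be >= 1")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if self.heatmap_stride not in (1, 2, 4):
            raise ConfigurationError("heatmap_stride must be 1, 2 or 4")
        if self.input_size % (2**self.depth) != 0:
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )
        if (self.input_size // self.heatmap_stride) % (2**self.depth) != 0:
            raise ConfigurationError(
                f"heatmap resolution {self.input_size // self.heatmap_stride} not divisible "
                f"by 2^depth = {2**self.depth}"
            )


class ResidualBlock(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        # residual branch starts near zero so deep stacks neither explode
        # nor vanish at initialization (no normalization layers are used)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, init_scale=0.01)
        self.proj = None if c_in == c_out else Conv2d(c_in, c_out, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        identity = x if self.proj is None else self.proj(x)
        return (identity + self.conv2(self.conv1(x).relu())).relu()


class AttentionGate(Module):
    """Additive attention on a skip connection.

    ``skip`` is the encoder feature at resolution r; ``gate`` the coarser
    decoder feature at r/2.  Both are projected to an intermediate width,
    combined additively at the coarse resolution, squashed to a one-channel
    sigmoid coefficient map, upsampled, and multiplied into ``skip``.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 gate_channels: Optional[int] = None) -> None:
        inter = max(channels // 2, 1)
        self.theta = Conv2d(channels, inter, 1, rng)
        self.phi = Conv2d(gate_channels or channels, inter, 1, rng)
        self.psi = Conv2d(inter, 1, 1, rng)

    def coefficients(self, skip: Tensor, gate: Tensor) -> Tensor:
        a = (self.theta(skip.avg_pool2()) + self.phi(gate)).relu()
        return self.psi(a).sigmoid().upsample2()

    def __call__(self, skip: Tensor, gate: Tensor) -> Tensor:
        return skip * self.coefficients(skip, gate)


class HourglassNet(Module):
    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None) -> None:
        rng = rng or np.random.default_rng(0)
        self.config = config
        n = config.width
        # stem: full resolution -> heatmap resolution; runs at half width
        # above the heatmap resolution to keep full-resolution convs cheap
        n_pool = int(round(np.log2(config.heatmap_stride)))
        c_hi = n if n_pool == 0 else max(n // 2, 4)
        widths = [c_hi] * n_pool + [n]
        self.stem_convs = []
        c_in = 1
        for c_out in widths:
            self.stem_convs.append(Conv2d(c_in, c_out, 3, rng))
            c_in = c_out
        self._n_stem_pool = n_pool
        # channel widths double per level (capped) as in standard
        # encoder-decoder designs; N is the width at the top level
        level_w = [min(n * 2**i, 4 * n, 64) for i in range(config.depth + 1)]
        self.enc_blocks = [
            ResidualBlock(level_w[i], level_w[i], rng) for i in range(config.depth)
        ]
        self.down_projs = [
            Conv2d(level_w[i], level_w[i + 1], 1, rng) for i in range(config.depth)
        ]
        self.dec_blocks = [
            ResidualBlock(level_w[i], level_w[i], rng) for i in range(config.depth)
        ]
        self.up_projs = [
            Conv2d(level_w[i + 1], level_w[i], 1, rng) for i in range(config.depth)
        ]
        self.gates = [
            AttentionGate(level_w[i], rng, gate_channels=level_w[i + 1])
            for i in range(config.depth)
        ]
        self.bottom = ResidualBlock(level_w[config.depth], level_w[config.depth], rng)
        head_w = max(n, config.n_landmarks)
        self.head_pre = Conv2d(n, head_w, 3, rng)
        self.head = Conv2d(head_w, config.n_landmarks, 1, rng)

    @property
    def input_size(self) -> int:
        return self.config.input_size

    def _levels(self, x: Tensor, i: int) -> Tensor:
        skip = self.enc_blocks[i](x)
        down = self.down_projs[i](skip.avg_pool2())
        inner = self._levels(down, i + 1) if i + 1 < self.config.depth else self.bottom(down)
        up = self.up_projs[i](inner.upsample2())
        merged = up + self.gates[i](skip, inner)
        return self.dec_blocks[i](merged)

    def forward(self, batch: np.ndarray) -> Tensor:
        """(B, H, W) or (B, 1, H, W) float images -> (B, K, Hm, Wm) logits."""
        arr = np.asarray(batch, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        if arr.shape[2] != self.config.input_size or arr.shape[3] != self.config.input_size:
            raise ConfigurationError(
                f"expected {self.config.input_size}px square input, got {arr.shape[2:]} "
                f"(input size must be divisible by 2^depth = {2**self.config.depth})"
            )
        x = constant(arr)
        x = self.stem_convs[0](x).relu()
        for conv in self.stem_convs[1:]:
            x = conv(x.avg_pool2()).relu()
        x = self._levels(x, 0)
        return self.head(self.head_pre(x).relu())

    def predict_coords(self, batch: np.ndarray) -> Tensor:
        """Decoded landmark coordinates in input pixels, differentiable."""
        logits = self.forward(batch)
        map_xy = logits.soft_argmax(self.config.softargmax_beta)
        s = float(self.config.heatmap_stride)
        # (m + 0.5) * s - 0.5, as an affine graph op
        return map_xy.scale(s) + constant(np.float32(0.5 * s - 0.5))

    def predict(self, image: np.ndarray) -> HeatmapStack:
        """Single-image inference to a HeatmapStack."""
        logits = self.forward(np.asarray(image)[None]).data[0]
        return HeatmapStack(
            maps=logits,
            stride=float(self.config.heatmap_stride),
            beta=self.config.softargmax_beta,
        )


def build_hourglass(config: ModelConfig, seed: int = 0) -> HourglassNet:
    return HourglassNet(config, np.random.default_rng(seed))


def save_checkpoint(path, model: HourglassNet, extra: Optional[dict] = None) -> None:
    """Parameters as .npz with a JSON sidecar describing the config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path.with_suffix(".npz"), **state)
    digest = hashlib.sha256(
        b"".join(state[k].tobytes() for k in sorted(state))
    ).hexdigest()[:16]
    meta = {"config": asdict(model.config), "param_digest": digest}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> HourglassNet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    model = HourglassNet(config)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
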