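"""Heatmap encoding and soft-argmax decoding.

A map pixel ``m`` corresponds to input-pixel coordinate
``(m + 0.5) * stride - 0.5`` (block centres), so stride 1 is the
identity and round-trips are unbiased at any stride.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..geometry import LandmarkSchema, LandmarkSet

__all__ = ["HeatmapStack", "encode_heatmaps", "decode_heatmaps", "soft_argmax_2d", "DEFAULT_BETA"]

logger = logging.getLogger(__name__)

# Softmax sharpness used for decoding.  Encoded maps have peak value 1, so
# the background (value ~0) carries weight n_pixels * exp(-beta) relative
# to the peak, which is negligible for beta ~ 30 on any practical map size.
DEFAULT_BETA = 30.0


@dataclass(frozen=True)
class HeatmapStack:
    """Per-landmark 2-D response maps plus the scale back to input pixels."""

    maps: np.ndarray  # (n_landmarks, H, W)
    stride: float  # input pixels per map pixel
    beta: float = DEFAULT_BETA  # softmax sharpness to use when decoding

    def __post_init__(self) -> None:
        if self.maps.ndim != 3:
            raise ValueError(f"maps must be (K, H, W), got shape {self.maps.shape}")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("heatmaps contain non-finite values")
        if self.stride <= 0:
            raise ValueError("stride must be > 0")

    @property
    def n_landmarks(self) -> int:
        return self.maps.shape[0]

    def to_input_coords(self, map_xy: np.ndarray) -> np.ndarray:
        return (np.asarray(map_xy, dtype=float) + 0.5) * self.stride - 0.5

    def from_input_coords(self, input_xy: np.ndarray) -> np.ndarray:
        return (np.asarray(input_xy, dtype=float) + 0.5) / self.stride - 0.5


def encode_heatmaps(
    landmarks: LandmarkSet,
    input_size: int,
    stride: float = 4.0,
    sigma: float = 1.5,
) -> HeatmapStack:
    """Isotropic Gaussians (amplitude 1, sd ``sigma`` map pixels) per landmark."""
    arr = landmarks.as_array()
    outside = np.where(
        (arr[:, 0] < 0) | (arr[:, 0] > input_size - 1) | (arr[:, 1] < 0) | (arr[:, 1] > input_size - 1)
    )[0]
    if outside.size:
        raise ValueError(f"landmarks outside input bounds at indices {outside.tolist()}")
    side = int(round(input_size / stride))
    xs = np.arange(side)
    mx = (arr[:, 0] + 0.5) / stride - 0.5
    my = (arr[:, 1] + 0.5) / stride - 0.5
    dx2 = (xs[None, None, :] - mx[:, None, None]) ** 2
    dy2 = (xs[None, :, None] - my[:, None, None]) ** 2
    maps = np.exp(-(dx2 + dy2) / (2.0 * sigma**2))
    return HeatmapStack(maps=maps.astype(np.float32), stride=stride)


def soft_argmax_2d(maps: np.ndarray, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Softmax-expectation coordinates (x, y) per map, in map pixels."""
    maps = np.asarray(maps, dtype=np.float64)
    k, h, w = maps.shape
    flat_range = maps.max(axis=(1, 2)) - maps.min(axis=(1, 2))
    if np.any(flat_range == 0):
        warnings.warn("soft_argmax_2d: constant map(s); returning map centre")
        logger.warning("constant heatmap(s) decoded to map centre")
    z = beta * (maps - maps.max(axis=(1, 2), keepdims=True))
    e = np.exp(z)
    p = e / e.sum(axis=(1, 2), keepdims=True)
    xs = np.arange(w, dtype=float)
    ys = np.arange(h, dtype=float)
    ex = (p.sum(axis=1) * xs).sum(axis=1)
    ey = (p.sum(axis=2) * ys).sum(axis=1)
    return np.stack([ex, ey], axis=1)


def decode_heatmaps(
    h: HeatmapStack,
    schema: LandmarkSchema,
    beta: Optional[float] = None,
) -> LandmarkSet:
    """Soft-argmax each map and rescale to input-pixel coordinates."""
    if h.n_landmarks != schema.n_points:
        raise ValueError(f"{h.n_landmarks} maps but schema has {schema.n_points} points")
    map_xy = soft_argmax_2d(h.maps, beta=h.beta if beta is None else beta)
    return LandmarkSet.from_array(h.to_input_coords(map_xy), schema)
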