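"""Two-stage localization: global search -> reference frame -> local search.

The global model scans a downscaled whole image for two reference points
(the tibial plateau corners by default).  Those two points define a
similarity reference frame (position, orientation, scale); the local
model searches the resampled frame crop and its decoded landmarks are
mapped back to original image coordinates through the inverse frame
transform.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Protocol, Tuple

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import (
    DegenerateGeometryError,
    LandmarkSchema,
    LandmarkSet,
    Point2D,
    SimilarityTransform,
    transform_between_point_pairs,
)
from .nn.heatmaps import HeatmapStack, soft_argmax_2d

__all__ = [
    "ReferenceFrameSpec",
    "HeatmapModel",
    "OracleModel",
    "LocalizationError",
    "FrameDegenerateError",
    "resize_to_square",
    "global_search",
    "make_frame",
    "resample_to_frame",
    "localize",
]

logger = logging.getLogger(__name__)


class LocalizationError(RuntimeError):
    """A pipeline stage failed; ``stage`` identifies which."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class FrameDegenerateError(LocalizationError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(stage, message)


class HeatmapModel(Protocol):
    """Anything that turns a correctly sized image into a HeatmapStack."""

    def predict(self, image: np.ndarray) -> HeatmapStack: ...

    @property
    def input_size(self) -> int: ...


@dataclass(frozen=True)
class ReferenceFrameSpec:
    """Where the two reference points land in the crop.

    Default anchors: a horizontally centred pair at mid-height separated
    by ``anchor_separation_fraction`` of the crop width.
    """

    crop_size: int = 128
    anchor_separation_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.anchor_separation_fraction <= 1):
            raise ValueError("anchor_separation_fraction must be in (0, 1]")

    @property
    def anchors(self) -> Tuple[Point2D, Point2D]:
        cx = (self.crop_size - 1) / 2.0
        cy = (self.crop_size - 1) / 2.0
        half = 0.5 * self.anchor_separation_fraction * self.crop_size
        return Point2D(cx - half, cy), Point2D(cx + half, cy)


class OracleModel:
    """A stand-in model emitting fixed ground-truth heatmaps.

    Used for plumbing tests and baselines: it ignores the image content
    and returns Gaussians encoded at construction time.
    """

    def __init__(
        self,
        landmarks_in_input: np.ndarray,
        input_size: int,
        stride: float = 1.0,
        sigma: float = 1.5,
    ) -> None:
        arr = np.asarray(landmarks_in_input, dtype=float)
        self._input_size = input_size
        self._stack = _encode_raw(arr, input_size, stride, sigma)

    @property
    def input_size(self) -> int:
        return self._input_size

    def predict(self, image: np.ndarray) -> HeatmapStack:
        return self._stack


def _encode_raw(arr: np.ndarray, input_size: int, stride: float, sigma: float) -> HeatmapStack:
    side = int(round(input_size / stride))
    xs = np.arange(side)
    mx = (arr[:, 0] + 0.5) / stride - 0.5
    my = (arr[:, 1] + 0.5) / stride - 0.5
    maps = np.exp(
        -(
            (xs[None, None, :] - mx[:, None, None]) ** 2
            + (xs[None, :, None] - my[:, None, None]) ** 2
        )
        / (2.0 * sigma**2)
    )
    return HeatmapStack(maps=maps.astype(np.float32), stride=stride)


def resize_to_square(image: np.ndarray, size: int) -> Tuple[np.ndarray, float]:
    """Aspect-preserving bilinear resize padded (with the image minimum)
    to ``size`` x ``size``; returns the crop and the applied scale factor."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    scale = size / max(h, w)
    fill = float(image.min())
    vv, uu = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    src_y = (vv + 0.5) / scale - 0.5
    src_x = (uu + 0.5) / scale - 0.5
    out = map_coordinates(
        image, [src_y, src_x], order=1, mode="constant", cval=fill, prefilter=False
    )
    return out.astype(np.float32), scale


def global_search(
    image: np.ndarray, global_model: HeatmapModel
) -> Tuple[Point2D, Point2D]:
    """Detect the two reference points, returned in original-image coordinates
    (left plateau corner first, fixed by the model's channel order)."""
    resized, scale = resize_to_square(image, global_model.input_size)
    stack = global_model.predict(resized)
    if stack.n_landmarks != 2:
        raise LocalizationError("global", f"expected 2 reference maps, got {stack.n_landmarks}")
    map_xy = soft_argmax_2d(stack.maps, beta=stack.beta)
    input_xy = stack.to_input_coords(map_xy)
    orig_xy = (input_xy + 0.5) / scale - 0.5
    p1 = Point2D(float(orig_xy[0, 0]), float(orig_xy[0, 1]))
    p2 = Point2D(float(orig_xy[1, 0]), float(orig_xy[1, 1]))
    if p1.distance_to(p2) < 1.0:
        raise FrameDegenerateError("global", f"reference points nearly coincide: {p1}, {p2}")
    return p1, p2


def make_frame(
    ref_1: Point2D, ref_2: Point2D, frame_spec: ReferenceFrameSpec
) -> SimilarityTransform:
    """Image -> crop transform sending the reference points to the anchors."""
    a1, a2 = frame_spec.anchors
    try:
        return transform_between_point_pairs(ref_1, ref_2, a1, a2)
    except DegenerateGeometryError as exc:
        raise FrameDegenerateError("frame", str(exc)) from exc


def resample_to_frame(
    image: np.ndarray, t: SimilarityTransform, crop_size: int
) -> np.ndarray:
    """Bilinear resampling of the frame crop; out-of-bounds pixels take the
    image minimum (radiograph background)."""
    image = np.asarray(image, dtype=np.float32)
    inv = t.inverse()
    vv, uu = np.meshgrid(np.arange(crop_size), np.arange(crop_size), indexing="ij")
    crop_xy = np.stack([uu.ravel(), vv.ravel()], axis=1).astype(float)
    src = inv.apply_array(crop_xy)
    fill = float(image.min())
    out = map_coordinates(
        image,
        [src[:, 1], src[:, 0]],
        order=1,
        mode="constant",
        cval=fill,
        prefilter=False,
    )
    return out.reshape(crop_size, crop_size).astype(np.float32)


def localize(
    image: np.ndarray,
    global_model: HeatmapModel,
    local_model: HeatmapModel,
    frame_spec: ReferenceFrameSpec,
    schema: LandmarkSchema,
) -> LandmarkSet:
    """Full two-stage pipeline returning landmarks in image coordinates."""
    ref_1, ref_2 = global_search(image, global_model)
    frame = make_frame(ref_1, ref_2, frame_spec)
    if frame_spec.crop_size != local_model.input_size:
        raise LocalizationError(
            "local",
            f"frame crop size {frame_spec.crop_size} != local input {local_model.input_size}",
        )
    crop = resample_to_frame(image, frame, frame_spec.crop_size)
    try:
        stack = local_model.predict(crop)
    except Exception as exc:
        raise LocalizationError("local", str(exc)) from exc
    if stack.n_landmarks != schema.n_points:
        raise LocalizationError(
            "local", f"{stack.n_landmarks} maps but schema has {schema.n_points} points"
        )
    crop_xy = stack.to_input_coords(soft_argmax_2d(stack.maps, beta=stack.beta))
    image_xy = frame.inverse().apply_array(crop_xy)
    logger.debug(
        "localize: frame scale=%.4f rot=%.2fdeg", frame.scale, math.degrees(frame.rotation)
    )
    return LandmarkSet.from_array(image_xy, schema)
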