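"""Coordinate conventions, landmark containers and similarity-transform algebra.

Conventions used throughout the package:

* 0-based pixel indices, origin at the centre of the top-left pixel,
  ``x`` = column (increasing rightward), ``y`` = row (increasing downward).
* A positive rotation angle is counter-clockwise in a mathematical y-up
  frame, which appears clockwise when the image is displayed y-down.
  The rotation matrix is the standard ``[[cos, -sin], [sin, cos]]``
  applied to ``(x, y)`` column vectors.
* Transforms are similarities (scale + rotation + translation), never
  reflections or shears.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

__all__ = [
    "Point2D",
    "LandmarkSchema",
    "LandmarkSet",
    "SimilarityTransform",
    "DegenerateGeometryError",
    "MANDATORY_PAIR_ROLES",
    "MANDATORY_POINT_ROLES",
    "transform_apply",
    "transform_between_point_pairs",
    "transform_invert",
    "transform_compose",
    "midpoint",
]


class DegenerateGeometryError(ValueError):
    """Raised when geometry input is degenerate (e.g. coincident points)."""


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (x = column, y = row, both in pixels)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"Point2D coordinates must be finite, got ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


# Roles that map to an (index, index) pair of landmarks.
MANDATORY_PAIR_ROLES = (
    "femoral_shaft_pair_proximal",
    "femoral_shaft_pair_distal",
    "femoral_notch_pair",
    "tibial_shaft_pair_proximal",
    "tibial_shaft_pair_distal",
)

# Roles that map to a single landmark index.
MANDATORY_POINT_ROLES = (
    "plateau_corner_left",
    "plateau_corner_right",
)

RoleValue = Union[int, Tuple[int, int]]


@dataclass(frozen=True)
class LandmarkSchema:
    """Maps semantic anatomical roles to landmark indices.

    ``roles`` values are either a single ``int`` index (point roles) or a
    2-tuple of indices (pair roles).  All mandatory roles must be present
    and all referenced indices must be unique and within ``[0, n_points)``.
    """

    n_points: int
    roles: Dict[str, RoleValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        missing = [r for r in MANDATORY_PAIR_ROLES + MANDATORY_POINT_ROLES if r not in self.roles]
        if missing:
            raise ValueError(f"schema missing mandatory roles: {missing}")
        used: List[int] = []
        for role, value in self.roles.items():
            idxs = self._as_indices(role, value)
            for i in idxs:
                if not (0 <= i < self.n_points):
                    raise ValueError(f"role {role!r} index {i} outside [0, {self.n_points})")
            used.extend(idxs)
        if len(set(used)) != len(used):
            raise ValueError("schema role indices must be unique across roles")

    @staticmethod
    def _as_indices(role: str, value: RoleValue) -> Tuple[int, ...]:
        if role in MANDATORY_PAIR_ROLES:
            if not (isinstance(value, (tuple, list)) and len(value) == 2):
                raise ValueError(f"role {role!r} must be an index pair, got {value!r}")
            return (int(value[0]), int(value[1]))
        if isinstance(value, (tuple, list)):
            return tuple(int(v) for v in value)
        return (int(value),)

    def pair(self, role: str) -> Tuple[int, int]:
        value = self.roles[role]
        if not (isinstance(value, (tuple, list)) and len(value) == 2):
            raise ValueError(f"role {role!r} is not a pair role")
        return int(value[0]), int(value[1])

    def index(self, role: str) -> int:
        value = self.roles[role]
        if isinstance(value, (tuple, list)):
            raise ValueError(f"role {role!r} is not a single-point role")
        return int(value)

    def with_swapped_corners(self) -> "LandmarkSchema":
        """Schema with the plateau left/right corner roles exchanged."""
        roles = dict(self.roles)
        roles["plateau_corner_left"], roles["plateau_corner_right"] = (
            roles["plateau_corner_right"],
            roles["plateau_corner_left"],
        )
        return LandmarkSchema(self.n_points, roles)


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered 2-D landmarks plus the schema describing their roles."""

    points: Tuple[Point2D, ...]
    schema: LandmarkSchema

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) != self.schema.n_points:
            raise ValueError(
                f"landmark count {len(self.points)} != schema n_points {self.schema.n_points}"
            )

    @classmethod
    def from_array(cls, arr: np.ndarray, schema: LandmarkSchema) -> "LandmarkSet":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected (n, 2) array, got shape {arr.shape}")
        return cls(tuple(Point2D(float(x), float(y)) for x, y in arr), schema)

    def as_array(self) -> np.ndarray:
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def point_for(self, role: str) -> Point2D:
        return self.points[self.schema.index(role)]

    def pair_for(self, role: str) -> Tuple[Point2D, Point2D]:
        i, j = self.schema.pair(role)
        return self.points[i], self.points[j]

    def role_midpoint(self, role: str) -> Point2D:
        return midpoint(self.pair_for(role))

    def transformed(self, t: "SimilarityTransform") -> "LandmarkSet":
        return LandmarkSet.from_array(t.apply_array(self.as_array()), self.schema)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map p' = scale * R(rotation) @ p + translation."""

    scale: float
    rotation: float
    translation: Point2D

    def __post_init__(self) -> None:
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be finite and > 0, got {self.scale}")
        if not math.isfinite(self.rotation):
            raise ValueError("rotation must be finite")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, Point2D(0.0, 0.0))

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, p: Point2D) -> Point2D:
        v = self.matrix @ p.as_array()
        return Point2D(v[0] + self.translation.x, v[1] + self.translation.y)

    def apply_array(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.matrix.T + np.array([self.translation.x, self.translation.y])

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        tx, ty = -self.translation.x, -self.translation.y
        return SimilarityTransform(
            inv_scale,
            -self.rotation,
            Point2D(inv_scale * (c * tx - s * ty), inv_scale * (s * tx + c * ty)),
        )

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``inner`` first, then ``self``."""
        t = self.apply(inner.translation)
        return SimilarityTransform(self.scale * inner.scale, self.rotation + inner.rotation, t)


def transform_apply(t: SimilarityTransform, p: Point2D) -> Point2D:
    return t.apply(p)


def transform_invert(t: SimilarityTransform) -> SimilarityTransform:
    return t.inverse()


def transform_compose(outer: SimilarityTransform, inner: SimilarityTransform) -> SimilarityTransform:
    return outer.compose(inner)


def midpoint(pair: Tuple[Point2D, Point2D]) -> Point2D:
    a, b = pair
    return Point2D(0.5 * (a.x + b.x), 0.5 * (a.y + b.y))


def transform_between_point_pairs(
    src_a: Point2D, src_b: Point2D, dst_a: Point2D, dst_b: Point2D
) -> SimilarityTransform:
    """The unique reflection-free similarity mapping src_a→dst_a, src_b→dst_b.

    Solved in the complex plane: with z = x + iy, the constraint
    ``t(z) = m z + c`` with ``m = (zd_b - zd_a) / (zs_b - zs_a)`` maps both
    anchors exactly; scale and rotation are the modulus and argument of m.
    """
    zs = complex(src_b.x - src_a.x, src_b.y - src_a.y)
    zd = complex(dst_b.x - dst_a.x, dst_b.y - dst_a.y)
    if zs == 0:
        raise DegenerateGeometryError("source anchor points coincide")
    if zd == 0:
        raise DegenerateGeometryError("destination anchor points coincide")
    m = zd / zs
    scale = abs(m)
    rotation = cmath.phase(m)
    za = complex(src_a.x, src_a.y)
    c = complex(dst_a.x, dst_a.y) - m * za
    return SimilarityTransform(scale, rotation, Point2D(c.real, c.imag))


def signed_triangle_area(a: Point2D, b: Point2D, c: Point2D) -> float:
    """Twice-signed area; sign is preserved by any SimilarityTransform."""
    return (b.x - a.x) * (c.y - a.y) - (b.y - a.y) * (c.x - a.x)
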