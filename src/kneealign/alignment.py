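"""Signed anatomical tibiofemoral angle (aTFA) from named landmark subsets.

Two axis constructions are supported:

* ``fts``  — femoral axis through the proximal and distal femoral-shaft
  pair midpoints; tibial axis through the proximal and distal
  tibial-shaft pair midpoints.
* ``fnts`` — femoral axis through the proximal femoral-shaft pair
  midpoint and the femoral-notch pair midpoint; same tibial axis.

Sign convention (left knee, image displayed y-down, lateral side at
larger x): the aTFA is the signed angle between the distal prolongation
of the femoral axis and the tibial axis.  Lateral deviation of the
distal tibia (valgus) is positive; medial deviation (varus) is
negative.  Right-knee inputs are handled by pre-mirroring, which simply
negates the angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, LandmarkSet, Point2D

__all__ = [
    "AxisLine",
    "AtfaResult",
    "femoral_axis_fts",
    "femoral_axis_fnts",
    "tibial_axis",
    "atfa",
]

_METHODS = ("fts", "fnts")
_LATERALITIES = ("left", "right")


@dataclass(frozen=True)
class AxisLine:
    """A bone axis: anchor point plus unit direction.

    The femoral direction points proximally (away from the joint, towards
    the proximal shaft midpoint); the tibial direction points distally.
    """

    anchor: Point2D
    direction: Point2D

    def __post_init__(self) -> None:
        norm = math.hypot(self.direction.x, self.direction.y)
        if abs(norm - 1.0) > 1e-12:
            raise ValueError(f"direction must be a unit vector, |d| = {norm}")


@dataclass(frozen=True)
class AtfaResult:
    angle: float  # degrees, valgus positive
    method: str
    laterality: str

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.laterality not in _LATERALITIES:
            raise ValueError(f"laterality must be one of {_LATERALITIES}")
        if not abs(self.angle) < 90:
            raise ValueError(f"|aTFA| must be < 90 deg, got {self.angle}")


def _axis(toward: Point2D, away: Point2D) -> AxisLine:
    dx, dy = toward.x - away.x, toward.y - away.y
    norm = math.hypot(dx, dy)
    if norm < 1e-12:
        raise DegenerateGeometryError("axis anchor midpoints coincide")
    return AxisLine(anchor=away, direction=Point2D(dx / norm, dy / norm))


def femoral_axis_fts(l: LandmarkSet) -> AxisLine:
    """Femoral axis through the two shaft-pair midpoints, pointing proximally."""
    proximal = l.role_midpoint("femoral_shaft_pair_proximal")
    distal = l.role_midpoint("femoral_shaft_pair_distal")
    return _axis(toward=proximal, away=distal)


def femoral_axis_fnts(l: LandmarkSet) -> AxisLine:
    """Femoral axis through the proximal shaft midpoint and notch midpoint."""
    proximal = l.role_midpoint("femoral_shaft_pair_proximal")
    notch = l.role_midpoint("femoral_notch_pair")
    return _axis(toward=proximal, away=notch)


def tibial_axis(l: LandmarkSet) -> AxisLine:
    """Tibial axis through the two shaft-pair midpoints, pointing distally."""
    proximal = l.role_midpoint("tibial_shaft_pair_proximal")
    distal = l.role_midpoint("tibial_shaft_pair_distal")
    return _axis(toward=distal, away=proximal)


def _signed_deviation_deg(femoral: AxisLine, tibial: AxisLine) -> float:
    # Angle between the distal prolongation of the femoral axis and the
    # tibial direction; sign from the 2-D cross product in the y-down
    # image frame, mapped so lateral (larger-x) deviation is positive
    # for a left knee.
    px, py = -femoral.direction.x, -femoral.direction.y
    tx, ty = tibial.direction.x, tibial.direction.y
    dot = float(np.clip(px * tx + py * ty, -1.0, 1.0))
    cross = px * ty - py * tx
    return -math.degrees(math.atan2(cross, dot))


def atfa(l: LandmarkSet, method: str = "fnts", laterality: str = "left") -> AtfaResult:
    """Signed aTFA in degrees: valgus positive, varus negative."""
    method = method.lower()
    if method == "fts":
        femoral = femoral_axis_fts(l)
    elif method == "fnts":
        femoral = femoral_axis_fnts(l)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {_METHODS}")
    angle = _signed_deviation_deg(femoral, tibial_axis(l))
    if laterality == "right":
        angle = -angle
    elif laterality != "left":
        raise ValueError(f"unknown laterality {laterality!r}")
    return AtfaResult(angle=angle, method=method, laterality=laterality)
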