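"""Synthetic left-knee AP phantom generator with exact landmark ground truth.

Each phantom consists of two bright bone-like shafts (distal femur above,
proximal tibia below) meeting at a joint, rendered over a dark background,
blurred and corrupted with additive Gaussian noise.  The 40 ground-truth
landmarks outline both shafts and include every semantic role the
measurement pipeline needs (shaft pairs, notch pair, plateau corners).

Construction guarantees:

* the femoral shaft-pair midpoints and the notch-pair midpoint are
  collinear on the femoral axis, so the two femoral axis variants agree
  exactly on ground truth;
* the tibial axis subtends exactly ``true_atfa`` degrees (valgus
  positive) with the distal prolongation of the femoral axis;
* the plateau-corner landmarks sit on the joint line separated by the
  configured tibial shaft width (the evaluation reference length).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import LandmarkSchema, LandmarkSet, Point2D

__all__ = [
    "PhantomSpec",
    "PhantomRanges",
    "PhantomSample",
    "default_schema",
    "default_curve_topology",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "PhantomBoundsError",
]

N_POINTS = 40

# Fractional positions (of shaft length, measured from the joint end)
# of the femoral and tibial edge-point pairs.
_FEMUR_EDGE_U = (0.92, 0.76, 0.60, 0.46, 0.34, 0.16)
_TIBIA_EDGE_U = (0.12, 0.24, 0.36, 0.48, 0.60, 0.72, 0.82, 0.92)

_JOINT_GAP = 6.0  # px between joint centre and each shaft end


class PhantomBoundsError(ValueError):
    """Raised when posing pushes ground-truth landmarks outside the image."""


def default_schema() -> LandmarkSchema:
    """The reduced 40-point role-complete schema used by the phantom."""
    return LandmarkSchema(
        n_points=N_POINTS,
        roles={
            "femoral_shaft_pair_proximal": (0, 1),   # "red" pair, u = 0.92
            "femoral_shaft_pair_distal": (8, 9),     # "yellow" pair, u = 0.34
            "femoral_notch_pair": (12, 13),          # "purple" pair
            "tibial_shaft_pair_proximal": (22, 23),  # "black" pair, u = 0.24
            "tibial_shaft_pair_distal": (34, 35),    # "blue" pair, u = 0.92
            "plateau_corner_left": 18,
            "plateau_corner_right": 19,
        },
    )


def default_curve_topology() -> List[List[int]]:
    """Open polylines (ordered landmark indices) along each bone boundary."""
    femur = [0, 2, 4, 6, 8, 10, 16, 14, 12, 13, 15, 17, 11, 9, 7, 5, 3, 1]
    tibia = [18, 20, 22, 24, 26, 28, 30, 32, 34, 38, 39, 35, 33, 31, 29, 27, 25, 23, 21, 19]
    plateau = [18, 36, 37, 19]
    return [femur, tibia, plateau]


@dataclass(frozen=True)
class PhantomSpec:
    image_size: int = 256
    true_atfa: float = 0.0  # degrees, valgus positive
    femoral_shaft_width: float = 34.0
    tibial_shaft_width: float = 50.0
    joint_center: Optional[Point2D] = None
    shaft_length: float = 104.0
    global_rotation: float = 0.0  # degrees, whole-knee pose
    intensity_noise_sd: float = 4.0  # in 0-255 gray levels
    blur_sigma: float = 1.2
    implant: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.femoral_shaft_width <= 0 or self.tibial_shaft_width <= 0:
            raise ValueError("shaft widths must be > 0")
        if self.shaft_length <= 2 * max(self.femoral_shaft_width, self.tibial_shaft_width):
            raise ValueError("shaft_length must exceed twice the widest shaft")
        if abs(self.true_atfa) > 30:
            raise ValueError("|true_atfa| must be <= 30 degrees")

    def resolved_joint_center(self) -> Point2D:
        if self.joint_center is not None:
            return self.joint_center
        return Point2D(self.image_size / 2.0, self.image_size * 0.50)


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray  # float32 in [0, 1], shape (image_size, image_size)
    landmarks: LandmarkSet
    spec: PhantomSpec


def _rot(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s], [s, c]])


def _phantom_geometry(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Axis anchors/directions and the 40 landmark coordinates."""
    joint = spec.resolved_joint_center().as_array()
    # Femoral axis points proximally (up at zero rotation); tibial axis
    # points distally, rotated laterally (+x) by true_atfa for valgus.
    f_dir = _rot(spec.global_rotation) @ np.array([0.0, -1.0])
    t_dir = _rot(spec.global_rotation - spec.true_atfa) @ np.array([0.0, 1.0])
    # Perpendiculars chosen to point towards +x at zero rotation so the
    # first element of each pair is the smaller-x ("left") point.
    f_perp = np.array([-f_dir[1], f_dir[0]])
    t_perp = np.array([t_dir[1], -t_dir[0]])

    L, wf, wt = spec.shaft_length, spec.femoral_shaft_width, spec.tibial_shaft_width
    f0 = joint + _JOINT_GAP * f_dir  # distal femur end
    t0 = joint + _JOINT_GAP * t_dir  # tibial plateau line

    pts = np.zeros((N_POINTS, 2))
    for i, u in enumerate(_FEMUR_EDGE_U):
        c = f0 + u * L * f_dir
        pts[2 * i] = c - 0.5 * wf * f_perp
        pts[2 * i + 1] = c + 0.5 * wf * f_perp
    notch_c = f0 + 0.05 * L * f_dir
    pts[12] = notch_c - 0.15 * wf * f_perp
    pts[13] = notch_c + 0.15 * wf * f_perp
    # condyle flare
    pts[14] = f0 + 0.02 * L * f_dir - 0.65 * wf * f_perp
    pts[15] = f0 + 0.02 * L * f_dir + 0.65 * wf * f_perp
    pts[16] = f0 + 0.10 * L * f_dir - 0.55 * wf * f_perp
    pts[17] = f0 + 0.10 * L * f_dir + 0.55 * wf * f_perp

    pts[18] = t0 - 0.5 * wt * t_perp  # plateau corner left
    pts[19] = t0 + 0.5 * wt * t_perp  # plateau corner right
    for i, u in enumerate(_TIBIA_EDGE_U):
        c = t0 + u * L * t_dir
        pts[20 + 2 * i] = c - 0.5 * wt * t_perp
        pts[21 + 2 * i] = c + 0.5 * wt * t_perp
    emin_c = t0 + 0.02 * L * t_dir
    pts[36] = emin_c - 0.10 * wt * t_perp
    pts[37] = emin_c + 0.10 * wt * t_perp
    pts[38] = t0 + 1.0 * L * t_dir - 0.5 * wt * t_perp
    pts[39] = t0 + 1.0 * L * t_dir + 0.5 * wt * t_perp

    return {
        "points": pts,
        "joint": joint,
        "f_dir": f_dir,
        "t_dir": t_dir,
        "f_perp": f_perp,
        "t_perp": t_perp,
        "f0": f0,
        "t0": t0,
    }


def _fill_quad(img: np.ndarray, corners: np.ndarray, value: float) -> None:
    from skimage.draw import polygon

    rr, cc = polygon(corners[:, 1], corners[:, 0], shape=img.shape)
    img[rr, cc] = value


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; deterministic for a fixed ``spec.seed``."""
    geo = _phantom_geometry(spec)
    pts = geo["points"]
    size = spec.image_size
    margin = 2.0
    lo, hi = margin, size - 1 - margin
    if pts.min() < lo or pts.max() > hi:
        bad = int(np.argmax(np.maximum(lo - pts, pts - hi).max(axis=1)))
        raise PhantomBoundsError(
            f"landmark {bad} at ({pts[bad, 0]:.1f}, {pts[bad, 1]:.1f}) is outside the "
            f"image for image_size={size}; reduce shaft_length ({spec.shaft_length}) "
            f"or global_rotation ({spec.global_rotation})"
        )

    img = np.full((size, size), 0.06, dtype=np.float64)
    L, wf, wt = spec.shaft_length, spec.femoral_shaft_width, spec.tibial_shaft_width
    f_dir, t_dir = geo["f_dir"], geo["t_dir"]
    f_perp, t_perp = geo["f_perp"], geo["t_perp"]
    f0, t0 = geo["f0"], geo["t0"]

    def quad(base, axis, perp, u0, u1, half0, half1):
        return np.array(
            [
                base + u0 * axis - half0 * perp,
                base + u0 * axis + half0 * perp,
                base + u1 * axis + half1 * perp,
                base + u1 * axis - half1 * perp,
            ]
        )

    # femoral shaft and condylar flare
    _fill_quad(img, quad(f0, L * f_dir, f_perp, 0.10, 1.0, 0.5 * wf, 0.5 * wf), 0.72)
    _fill_quad(img, quad(f0, L * f_dir, f_perp, 0.0, 0.12, 0.65 * wf, 0.52 * wf), 0.78)
    # intercondylar notch: darker wedge at the distal femur centre
    _fill_quad(img, quad(f0, L * f_dir, f_perp, 0.0, 0.08, 0.15 * wf, 0.05 * wf), 0.40)
    # tibia
    _fill_quad(img, quad(t0, L * t_dir, t_perp, 0.0, 1.0, 0.5 * wt, 0.5 * wt), 0.68)
    # subtle plateau ridge
    _fill_quad(img, quad(t0, L * t_dir, t_perp, 0.0, 0.04, 0.5 * wt, 0.46 * wt), 0.76)
    if spec.implant:
        joint = geo["joint"]
        _fill_quad(img, quad(joint, L * t_dir, t_perp, -0.06, 0.10, 0.42 * wt, 0.40 * wt), 0.95)

    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=spec.blur_sigma)
    rng = np.random.default_rng(spec.seed)
    if spec.intensity_noise_sd > 0:
        img = img + rng.normal(0.0, spec.intensity_noise_sd / 255.0, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    landmarks = LandmarkSet.from_array(pts, default_schema())
    return PhantomSample(image=img, landmarks=landmarks, spec=spec)


@dataclass(frozen=True)
class PhantomRanges:
    """Uniform sampling ranges for randomized dataset generation."""

    atfa: Tuple[float, float] = (-15.0, 15.0)
    global_rotation: Tuple[float, float] = (-6.0, 6.0)
    femoral_shaft_width: Tuple[float, float] = (30.0, 38.0)
    tibial_shaft_width: Tuple[float, float] = (42.0, 49.0)
    shaft_length: Tuple[float, float] = (100.0, 110.0)
    joint_jitter: float = 6.0  # px, uniform square around the default centre
    intensity_noise_sd: Tuple[float, float] = (2.0, 6.0)
    image_size: int = 256
    implant_fraction: float = 0.0


def generate_dataset(
    n: int,
    ranges: Optional[PhantomRanges] = None,
    seed: int = 0,
) -> List[PhantomSample]:
    """Draw ``n`` phantoms with parameters uniform in ``ranges`` (one stream)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or PhantomRanges()
    rng = np.random.default_rng(seed)
    samples: List[PhantomSample] = []
    for _ in range(n):
        base = PhantomSpec(image_size=ranges.image_size)
        center = base.resolved_joint_center()
        jx, jy = rng.uniform(-ranges.joint_jitter, ranges.joint_jitter, size=2)
        spec = PhantomSpec(
            image_size=ranges.image_size,
            true_atfa=float(rng.uniform(*ranges.atfa)),
            femoral_shaft_width=float(rng.uniform(*ranges.femoral_shaft_width)),
            tibial_shaft_width=float(rng.uniform(*ranges.tibial_shaft_width)),
            joint_center=Point2D(center.x + jx, center.y + jy),
            shaft_length=float(rng.uniform(*ranges.shaft_length)),
            global_rotation=float(rng.uniform(*ranges.global_rotation)),
            intensity_noise_sd=float(rng.uniform(*ranges.intensity_noise_sd)),
            implant=bool(rng.uniform() < ranges.implant_fraction),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        samples.append(generate_phantom(spec))
    return samples


def write_dataset(samples: Sequence[PhantomSample], out_dir: Path) -> Path:
    """Write PNG images, PTS files and a manifest CSV; returns manifest path."""
    from . import io as kio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "points").mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "pts", "true_atfa", "laterality"])
        for i, sample in enumerate(samples):
            sid = f"phantom_{i:04d}"
            img_rel = f"images/{sid}.png"
            pts_rel = f"points/{sid}.pts"
            kio.write_image(out_dir / img_rel, sample.image)
            kio.write_pts(out_dir / pts_rel, sample.landmarks)
            writer.writerow([sid, img_rel, pts_rel, f"{sample.spec.true_atfa:.6f}", "left"])
    kio.write_schema(out_dir / "schema.yaml", default_schema())
    return manifest_path
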