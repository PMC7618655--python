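"""File I/O: images, PTS landmark files, schema files, manifests.

PTS dialect::

    version: 1
    n_points: K
    {
    x y
    ...
    }

Images are 8/16-bit grayscale PNG (or monochrome DICOM when pydicom is
installed); intensities are rescaled to floats in [0, 1].  Laterality is
always metadata carried by the manifest — never inferred from pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from PIL import Image

from .geometry import LandmarkSchema, LandmarkSet

__all__ = [
    "PtsParseError",
    "read_image",
    "write_image",
    "read_pts",
    "write_pts",
    "read_schema",
    "write_schema",
    "flip_to_left",
    "Manifest",
    "ManifestRow",
]


class PtsParseError(ValueError):
    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def read_image(path) -> Tuple[np.ndarray, Dict[str, object]]:
    """Load a grayscale image as float32 in [0, 1] plus source metadata."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    if suffix != ".png":
        raise ValueError(f"unsupported image format {suffix!r}: expected .png or .dcm")
    with Image.open(path) as im:
        if im.mode == "L":
            arr = np.asarray(im, dtype=np.float32) / 255.0
            bits = 8
        elif im.mode in ("I;16", "I;16B", "I"):
            arr = np.asarray(im, dtype=np.float32) / 65535.0
            bits = 16
        else:
            raise ValueError(
                f"unsupported PNG mode {im.mode!r}: grayscale (8/16-bit) required"
            )
    return arr, {"format": "png", "bits": bits, "path": str(path)}


def _read_dicom(path: Path) -> Tuple[np.ndarray, Dict[str, object]]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading DICOM requires the optional pydicom package") from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float32)
    if arr.ndim != 2:
        raise ValueError("DICOM image must be monochrome 2-D")
    lo, hi = float(arr.min()), float(arr.max())
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = 1.0 - arr
    return arr, {"format": "dicom", "path": str(path)}


def write_image(path, image: np.ndarray) -> None:
    """Write a float [0, 1] array as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(Path(path))


def read_pts(path, schema: Optional[LandmarkSchema] = None) -> LandmarkSet:
    """Parse a PTS file; pairs each error with its 1-based line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    idx = 0

    def expect(prefix: str) -> str:
        nonlocal idx
        if idx >= len(lines):
            raise PtsParseError(path, len(lines), f"unexpected end of file, expected {prefix!r}")
        line = lines[idx].strip()
        idx += 1
        if not line.startswith(prefix):
            raise PtsParseError(path, idx, f"expected {prefix!r}, got {line!r}")
        return line

    version_line = expect("version:")
    if version_line.split(":", 1)[1].strip() != "1":
        raise PtsParseError(path, idx, f"unsupported version in {version_line!r}")
    n_line = expect("n_points:")
    try:
        n_points = int(n_line.split(":", 1)[1])
    except ValueError:
        raise PtsParseError(path, idx, f"bad point count in {n_line!r}") from None
    expect("{")
    coords: List[Tuple[float, float]] = []
    while idx < len(lines):
        line = lines[idx].strip()
        idx += 1
        if line == "}":
            if len(coords) != n_points:
                raise PtsParseError(
                    path, idx, f"declared n_points {n_points} but found {len(coords)} rows"
                )
            if schema is None:
                schema = _anonymous_schema(n_points)
            return LandmarkSet.from_array(np.array(coords, dtype=float), schema)
        parts = line.split()
        if len(parts) != 2:
            raise PtsParseError(path, idx, f"expected 'x y', got {line!r}")
        try:
            coords.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise PtsParseError(path, idx, f"non-numeric coordinates in {line!r}") from None
    raise PtsParseError(path, len(lines), "missing closing '}'")


def _anonymous_schema(n_points: int) -> LandmarkSchema:
    """Fallback schema for bare PTS files (phantom layout when it fits)."""
    from .phantom import N_POINTS, default_schema

    if n_points == N_POINTS:
        return default_schema()
    raise ValueError(
        f"PTS file has {n_points} points and no schema was supplied; "
        "pass the matching LandmarkSchema explicitly"
    )


def write_pts(path, landmarks: LandmarkSet) -> None:
    with open(Path(path), "w", newline="\n") as fh:
        fh.write("version: 1\n")
        fh.write(f"n_points: {len(landmarks)}\n")
        fh.write("{\n")
        for p in landmarks.points:
            fh.write(f"{p.x:.6f} {p.y:.6f}\n")
        fh.write("}\n")


def read_schema(path) -> LandmarkSchema:
    data = yaml.safe_load(Path(path).read_text())
    roles = {
        name: tuple(v) if isinstance(v, list) else int(v)
        for name, v in data["roles"].items()
    }
    return LandmarkSchema(n_points=int(data["n_points"]), roles=roles)


def write_schema(path, schema: LandmarkSchema) -> None:
    roles = {
        name: list(v) if isinstance(v, (tuple, list)) else int(v)
        for name, v in schema.roles.items()
    }
    Path(path).write_text(
        yaml.safe_dump({"n_points": schema.n_points, "roles": roles}, sort_keys=False)
    )


def flip_to_left(
    image: np.ndarray, landmarks: LandmarkSet, laterality: str = "right"
) -> Tuple[np.ndarray, LandmarkSet]:
    """Mirror a right-knee image/landmark pair to left-knee orientation.

    Left-knee input passes through unchanged.  Uses the 0-based
    pixel-centre mirror ``x -> width - 1 - x`` and swaps the plateau
    left/right corner roles in the schema.
    """
    if laterality == "left":
        return image, landmarks
    if laterality != "right":
        raise ValueError(f"unknown laterality {laterality!r}")
    width = image.shape[1]
    flipped = image[:, ::-1].copy()
    arr = landmarks.as_array()
    arr[:, 0] = width - 1 - arr[:, 0]
    return flipped, LandmarkSet.from_array(arr, landmarks.schema.with_swapped_corners())


@dataclass(frozen=True)
class ManifestRow:
    id: str
    image: str
    pts: str
    laterality: str = "left"
    true_atfa: Optional[float] = None
    split: Optional[str] = None


@dataclass(frozen=True)
class Manifest:
    """Index of a dataset: one row per sample, paths relative to root."""

    root: Path
    rows: Tuple[ManifestRow, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest sample ids must be unique")

    @classmethod
    def read(cls, path, check_files: bool = True) -> "Manifest":
        path = Path(path)
        root = path.parent
        rows: List[ManifestRow] = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(
                    ManifestRow(
                        id=rec["id"],
                        image=rec["image"],
                        pts=rec["pts"],
                        laterality=rec.get("laterality", "left") or "left",
                        true_atfa=float(rec["true_atfa"]) if rec.get("true_atfa") else None,
                        split=rec.get("split") or None,
                    )
                )
        manifest = cls(root=root, rows=tuple(rows))
        if check_files:
            for row in manifest.rows:
                for rel in (row.image, row.pts):
                    if not (root / rel).exists():
                        raise FileNotFoundError(f"manifest references missing file {root / rel}")
        return manifest

    def __len__(self) -> int:
        return len(self.rows)

    def load(self, row: ManifestRow, schema: Optional[LandmarkSchema] = None):
        image, _ = read_image(self.root / row.image)
        landmarks = read_pts(self.root / row.pts, schema)
        return image, landmarks
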