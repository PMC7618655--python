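"""Localization metrics (rP2P/rP2C) and method-agreement statistics.

Localization errors are expressed relative to a per-image anatomical
reference length: the distance between the two tibial plateau-corner
ground-truth landmarks.  Agreement between two paired measurement
series is reported as ICC(2,1) with a 95% CI, mean absolute difference
(MAD) with SD, and Bland-Altman bias with SD and 95% limits of
agreement.  SD uses the n-1 denominator throughout; percentiles use
linear interpolation between closest order statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import atfa
from .geometry import LandmarkSet
from .io import Manifest, read_pts

__all__ = [
    "LocalizationScores",
    "AgreementReport",
    "p2p",
    "p2c",
    "reference_length",
    "summarize_localization",
    "icc_agreement",
    "mad_agreement",
    "bland_altman",
    "evaluate_run",
]

logger = logging.getLogger(__name__)


def p2p(pred: LandmarkSet, gt: LandmarkSet) -> np.ndarray:
    """Per-landmark Euclidean distances between prediction and ground truth."""
    if pred.schema.n_points != gt.schema.n_points:
        raise ValueError("schema mismatch between prediction and ground truth")
    return np.linalg.norm(pred.as_array() - gt.as_array(), axis=1)


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def p2c(
    pred: LandmarkSet, gt: LandmarkSet, curve_topology: Sequence[Sequence[int]]
) -> np.ndarray:
    """Per-landmark distance to the ground-truth boundary polyline(s)
    containing the landmark's own ground-truth counterpart."""
    if pred.schema.n_points != gt.schema.n_points:
        raise ValueError("schema mismatch between prediction and ground truth")
    membership: Dict[int, List[int]] = {}
    for ci, curve in enumerate(curve_topology):
        for idx in curve:
            membership.setdefault(int(idx), []).append(ci)
    pred_arr, gt_arr = pred.as_array(), gt.as_array()
    out = np.empty(len(pred_arr))
    for i, point in enumerate(pred_arr):
        if i not in membership:
            raise ValueError(f"landmark index {i} is not on any curve in the topology")
        best = math.inf
        for ci in membership[i]:
            curve = curve_topology[ci]
            for a_idx, b_idx in zip(curve[:-1], curve[1:]):
                best = min(
                    best, _point_segment_distance(point, gt_arr[a_idx], gt_arr[b_idx])
                )
        out[i] = best
    return out


def reference_length(gt: LandmarkSet) -> float:
    """Distance between the plateau-corner landmarks (tibial shaft width)."""
    left = gt.point_for("plateau_corner_left")
    right = gt.point_for("plateau_corner_right")
    length = left.distance_to(right)
    if length <= 0:
        raise ValueError("plateau corners coincide: zero reference length")
    return length


def summarize_localization(per_image_values: Sequence[float]) -> Dict[str, float]:
    """Mean / median / 95th percentile (linear interpolation) of per-image values."""
    values = np.asarray(per_image_values, dtype=float)
    if values.size == 0:
        raise ValueError("no per-image values to summarize")
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "p95": float(np.percentile(values, 95, method="linear")),
    }


@dataclass(frozen=True)
class LocalizationScores:
    per_image_p2p: np.ndarray  # pixels
    per_image_p2c: np.ndarray
    reference_lengths: np.ndarray
    rp2p: np.ndarray  # percent of reference length
    rp2c: np.ndarray

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for metric, vals in (("rP2P", self.rp2p), ("rP2C", self.rp2c)):
            s = summarize_localization(vals)
            rows.append({"metric": metric, **s})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AgreementReport:
    icc: float
    icc_ci95: Tuple[float, float]
    mad: float
    mad_sd: float
    baa_bias: float
    baa_sd: float
    loa95: Tuple[float, float]
    n: int
    icc_defined: bool = True


def icc_agreement(a: Sequence[float], b: Sequence[float]) -> Tuple[float, Tuple[float, float], bool]:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with the standard
    F-based 95% CI.  Returns ``(icc, (lo, hi), defined)``; ``defined`` is
    False when total variance is zero and the ICC is meaningless.
    """
    x = np.column_stack([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in ICC input")
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 paired observations")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    if np.allclose(x, grand):
        return float("nan"), (float("nan"), float("nan")), False
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom)

    if mse == 0 and msc == 0:
        return icc, (icc, icc), True
    alpha = 0.05
    r = icc
    with np.errstate(divide="ignore", invalid="ignore"):
        a_coef = k * r / (n * (1 - r)) if r != 1 else np.inf
        b_coef = 1 + k * r * (n - 1) / (n * (1 - r)) if r != 1 else np.inf
    if not np.isfinite(a_coef):
        return icc, (icc, icc), True
    v = (a_coef * msc + b_coef * mse) ** 2 / (
        (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return icc, (float(lower), float(upper)), True


def mad_agreement(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Mean and SD (n-1) of the absolute paired differences."""
    diff = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    if diff.size == 0:
        raise ValueError("empty input")
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd


def bland_altman(
    a: Sequence[float], b: Sequence[float], plot_path: Optional[Path] = None
) -> Tuple[float, float, Tuple[float, float]]:
    """Bias, SD and 95% limits of agreement of the paired differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter((a + b) / 2.0, diff, s=12, alpha=0.7)
        for y, style in ((bias, "-"), (loa[0], "--"), (loa[1], "--")):
            ax.axhline(y, linestyle=style, color="gray")
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return bias, sd, loa


def agreement_report(a: Sequence[float], b: Sequence[float]) -> AgreementReport:
    icc, ci, defined = icc_agreement(a, b)
    mad, mad_sd = mad_agreement(a, b)
    bias, sd, loa = bland_altman(a, b)
    return AgreementReport(
        icc=icc, icc_ci95=ci, mad=mad, mad_sd=mad_sd,
        baa_bias=bias, baa_sd=sd, loa95=loa, n=len(list(a)), icc_defined=defined,
    )


def evaluate_run(
    manifest: Manifest,
    predictions_dir: Path,
    curve_topology: Optional[Sequence[Sequence[int]]] = None,
    out_dir: Optional[Path] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, LocalizationScores]:
    """Compare predicted PTS files against a ground-truth manifest.

    Emits a localization summary (rP2P/rP2C mean/median/95%ile) and an
    agreement table (ICC+CI / MAD+SD / BAA bias+SD) between automated
    and ground-truth aTFA for both FTS and FNTS.  Missing predictions
    are logged and skipped.
    """
    from .phantom import default_curve_topology

    predictions_dir = Path(predictions_dir)
    topology = curve_topology if curve_topology is not None else default_curve_topology()

    per_p2p, per_p2c, ref_lengths = [], [], []
    angles: Dict[str, Dict[str, List[float]]] = {
        m: {"auto": [], "gt": []} for m in ("fts", "fnts")
    }
    missing = []
    for row in manifest.rows:
        pred_path = predictions_dir / f"{row.id}.pts"
        if not pred_path.exists():
            missing.append(row.id)
            continue
        gt = read_pts(manifest.root / row.pts)
        pred = read_pts(pred_path, gt.schema)
        img_p2p = float(p2p(pred, gt).mean())
        img_p2c = float(p2c(pred, gt, topology).mean())
        if img_p2c > img_p2p + 1e-9:
            raise AssertionError(
                f"metric ordering violated for {row.id}: rP2C {img_p2c} > rP2P {img_p2p}"
            )
        per_p2p.append(img_p2p)
        per_p2c.append(img_p2c)
        ref_lengths.append(reference_length(gt))
        for method in ("fts", "fnts"):
            try:
                auto = atfa(pred, method, row.laterality).angle
            except ValueError as exc:
                logger.warning("angle (%s) undefined for %s: %s", method, row.id, exc)
                continue
            angles[method]["auto"].append(auto)
            angles[method]["gt"].append(atfa(gt, method, row.laterality).angle)
    if missing:
        logger.warning("missing predictions for %d samples: %s", len(missing), missing[:10])
    if not per_p2p:
        raise ValueError("no samples with predictions to evaluate")

    scores = LocalizationScores(
        per_image_p2p=np.array(per_p2p),
        per_image_p2c=np.array(per_p2c),
        reference_lengths=np.array(ref_lengths),
        rp2p=100.0 * np.array(per_p2p) / np.array(ref_lengths),
        rp2c=100.0 * np.array(per_p2c) / np.array(ref_lengths),
    )
    loc_table = scores.summary_table()

    agreement_rows = []
    for method in ("fts", "fnts"):
        if len(angles[method]["auto"]) < 3:
            logger.warning(
                "fewer than 3 valid %s angle pairs; agreement row left undefined", method
            )
            agreement_rows.append(
                {
                    "method": method.upper(),
                    "n": len(angles[method]["auto"]),
                    "icc": float("nan"),
                    "icc_ci_low": float("nan"),
                    "icc_ci_high": float("nan"),
                    "mad": float("nan"),
                    "mad_sd": float("nan"),
                    "baa_bias": float("nan"),
                    "baa_sd": float("nan"),
                    "icc_defined": False,
                }
            )
            continue
        rep = agreement_report(angles[method]["auto"], angles[method]["gt"])
        agreement_rows.append(
            {
                "method": method.upper(),
                "n": rep.n,
                "icc": rep.icc,
                "icc_ci_low": rep.icc_ci95[0],
                "icc_ci_high": rep.icc_ci95[1],
                "mad": rep.mad,
                "mad_sd": rep.mad_sd,
                "baa_bias": rep.baa_bias,
                "baa_sd": rep.baa_sd,
                "icc_defined": rep.icc_defined,
            }
        )
    agree_table = pd.DataFrame(agreement_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        loc_table.to_csv(out_dir / "localization.csv", index=False)
        agree_table.to_csv(out_dir / "agreement.csv", index=False)
    return loc_table, agree_table, scores
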