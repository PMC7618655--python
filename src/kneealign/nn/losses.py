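"""Wing loss on coordinate residuals.

Piecewise: ``w * ln(1 + |x| / epsilon)`` for ``|x| < w``, else ``|x| - C``
with ``C = w - w * ln(1 + w / epsilon)`` so the two branches meet
continuously at ``|x| = w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..geometry import LandmarkSet

__all__ = ["WingLossParams", "wing_penalty", "wing_loss"]


@dataclass(frozen=True)
class WingLossParams:
    w: float = 10.0
    epsilon: float = 2.0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.epsilon <= 0:
            raise ValueError("w and epsilon must be > 0")

    @property
    def C(self) -> float:
        return self.w - self.w * math.log1p(self.w / self.epsilon)


def wing_penalty(residuals: np.ndarray, params: WingLossParams = WingLossParams()) -> np.ndarray:
    """Elementwise wing penalty of residuals (any shape)."""
    a = np.abs(np.asarray(residuals, dtype=np.float64))
    return np.where(a < params.w, params.w * np.log1p(a / params.epsilon), a - params.C)


def wing_loss(pred, target, params: WingLossParams = WingLossParams()) -> float:
    """Mean wing penalty over all coordinate residuals of two landmark sets.

    Accepts :class:`LandmarkSet` or plain ``(n, 2)`` arrays.
    """
    p = pred.as_array() if isinstance(pred, LandmarkSet) else np.asarray(pred, dtype=float)
    t = target.as_array() if isinstance(target, LandmarkSet) else np.asarray(target, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(wing_penalty(p - t, params).mean())
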