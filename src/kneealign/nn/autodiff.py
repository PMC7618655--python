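"""Minimal reverse-mode autodiff on numpy arrays.

Only the operations needed by the hourglass/attention-gate models are
provided: same-padded 3x3 and 1x1 convolutions, 2x average pooling,
2x nearest-neighbour upsampling, ReLU, sigmoid, broadcast add/multiply,
spatial soft-argmax and mean reduction.  Arrays are float32 throughout;
execution is single-threaded numpy, so results are bit-reproducible for
a fixed seed.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "constant", "parameter"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "needs_grad", "_parents")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: Sequence[Tuple["Tensor", Callable[[np.ndarray], np.ndarray]]] = (),
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = [(p, fn) for p, fn in parents if p.needs_grad]
        self.needs_grad = requires_grad or bool(self._parents)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of ``self`` (summed if non-scalar) into leaves."""
        order: List[Tensor] = []
        seen = set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.needs_grad:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(order):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, fn in t._parents:
                contrib = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + contrib
                else:
                    grads[id(p)] = contrib

    # ---- elementwise ----

    def __add__(self, other: "Tensor") -> "Tensor":
        out = self.data + other.data
        return Tensor(
            out,
            parents=[
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    def __mul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other
        out = a.data * b.data
        return Tensor(
            out,
            parents=[
                (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
                (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
            ],
        )

    def scale(self, k: float) -> "Tensor":
        return Tensor(self.data * np.float32(k), parents=[(self, lambda g: g * np.float32(k))])

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def sigmoid(self) -> "Tensor":
        x = self.data
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        e = np.exp(x[~pos])
        out[~pos] = e / (1.0 + e)
        return Tensor(out, parents=[(self, lambda g: g * out * (1.0 - out))])

    def mean(self) -> "Tensor":
        n = self.data.size
        return Tensor(
            np.asarray(self.data.mean()),
            parents=[(self, lambda g: np.full(self.data.shape, g / n, dtype=np.float32))],
        )

    # ---- spatial ops on (B, C, H, W) ----

    def conv2d(self, w: "Tensor", b: "Tensor") -> "Tensor":
        """Stride-1, same-padded convolution; kernel must be 1x1 or 3x3."""
        kh, kw = w.data.shape[2], w.data.shape[3]
        if (kh, kw) == (1, 1):
            out = np.einsum("bchw,ocyx->bohw", self.data, w.data, optimize=True)
            out += b.data[None, :, None, None]

            def d_x(g: np.ndarray) -> np.ndarray:
                return np.einsum("bohw,ocyx->bchw", g, w.data, optimize=True)

            def d_w(g: np.ndarray) -> np.ndarray:
                return np.einsum("bohw,bchw->oc", g, self.data, optimize=True).reshape(
                    w.data.shape
                )

        elif (kh, kw) == (3, 3):
            xp = np.pad(self.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
            patches = sliding_window_view(xp, (3, 3), axis=(2, 3))
            out = np.einsum("bchwij,ocij->bohw", patches, w.data, optimize=True)
            out += b.data[None, :, None, None]

            def d_x(g: np.ndarray) -> np.ndarray:
                gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1)))
                gpat = sliding_window_view(gp, (3, 3), axis=(2, 3))
                wf = w.data[:, :, ::-1, ::-1]
                return np.einsum("bohwij,ocij->bchw", gpat, wf, optimize=True)

            def d_w(g: np.ndarray) -> np.ndarray:
                return np.einsum("bchwij,bohw->ocij", patches, g, optimize=True)

        else:
            raise ValueError(f"unsupported kernel size {(kh, kw)}")

        def d_b(g: np.ndarray) -> np.ndarray:
            return g.sum(axis=(0, 2, 3))

        return Tensor(out, parents=[(self, d_x), (w, d_w), (b, d_b)])

    def avg_pool2(self) -> "Tensor":
        bsz, c, h, w = self.data.shape
        out = self.data.reshape(bsz, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

        def d_x(g: np.ndarray) -> np.ndarray:
            return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * np.float32(0.25)

        return Tensor(out, parents=[(self, d_x)])

    def upsample2(self) -> "Tensor":
        out = np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3)

        def d_x(g: np.ndarray) -> np.ndarray:
            bsz, c, h, w = g.shape
            return g.reshape(bsz, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

        return Tensor(out, parents=[(self, d_x)])

    def soft_argmax(self, beta: float) -> "Tensor":
        """Spatial softmax expectation per map: (B, K, H, W) -> (B, K, 2) x,y."""
        bsz, k, h, w = self.data.shape
        z = beta * (self.data - self.data.max(axis=(2, 3), keepdims=True))
        e = np.exp(z, dtype=np.float64)
        p = e / e.sum(axis=(2, 3), keepdims=True)
        xs = np.arange(w, dtype=np.float64)
        ys = np.arange(h, dtype=np.float64)
        ex = (p.sum(axis=2) * xs).sum(axis=2)  # (B, K)
        ey = (p.sum(axis=3) * ys).sum(axis=2)
        out = np.stack([ex, ey], axis=2)

        def d_x(g: np.ndarray) -> np.ndarray:
            gx = g[:, :, 0][:, :, None, None]
            gy = g[:, :, 1][:, :, None, None]
            dx = xs[None, None, None, :] - ex[:, :, None, None]
            dy = ys[None, None, :, None] - ey[:, :, None, None]
            return (beta * p * (gx * dx + gy * dy)).astype(np.float32)

        return Tensor(out, parents=[(self, d_x)])

    def wing_loss_to(self, target: np.ndarray, w: float, epsilon: float) -> "Tensor":
        """Mean wing loss of coordinate residuals against a constant target."""
        r = self.data.astype(np.float64) - np.asarray(target, dtype=np.float64)
        a = np.abs(r)
        c = w - w * np.log1p(w / epsilon)
        small = a < w
        vals = np.where(small, w * np.log1p(a / epsilon), a - c)
        n = r.size

        def d_x(g: np.ndarray) -> np.ndarray:
            dv = np.where(small, w / (epsilon + a), 1.0) * np.sign(r)
            return (g * dv / n).astype(np.float32)

        return Tensor(np.asarray(vals.mean()), parents=[(self, d_x)])


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def constant(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)
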