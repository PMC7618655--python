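"""Parameterized layers and the Adam optimizer."""

from __future__ import annotations

from typing import Dict, Iterable, List

import numpy as np

from .autodiff import Tensor, parameter

__all__ = ["Conv2d", "Module", "Adam"]


class Module:
    """Base class: anything with named parameter tensors."""

    def parameters(self) -> List[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self) -> List:
        out = []
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend((f"{name}.{k}", t) for k, t in value.named_parameters())
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(
                            (f"{name}.{i}.{k}", t) for k, t in item.named_parameters()
                        )
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, t in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {t.data.shape}")
            t.data = arr


class Conv2d(Module):
    """Stride-1 same-padded convolution (1x1 or 3x3), He-initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 init_scale: float = 1.0) -> None:
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        fan_in = c_in * kernel * kernel
        std = init_scale * np.sqrt(2.0 / fan_in)
        self.w = parameter(rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel)))
        self.b = parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.w, self.b)


class Adam:
    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / bias1
            v_hat = self.v[i] / bias2
            p.data = (p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                np.float32
            )
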