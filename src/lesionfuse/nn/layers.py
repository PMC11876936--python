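"""Layers and the Adam optimizer for the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d, matmul, add


class Module:
    """Base class: children and parameters discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}" if not prefix else f"{prefix}.{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(name))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{name}.{i}"))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, v in params.items():
            v.data = np.array(state[k], dtype=v.data.dtype, copy=True)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv3d(Module):
    """3-D convolution, kernel k, stride 1, 'same' zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float64):
        fan_in = c_in * k ** 3
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        w = np.zeros((c_out, c_in, k, k, k)) if zero_init else \
            rng.normal(0.0, scale, size=(c_out, c_in, k, k, k))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float64):
        scale = np.sqrt(2.0 / d_in)
        w = np.zeros((d_in, d_out)) if zero_init else \
            rng.normal(0.0, scale, size=(d_in, d_out))
        self.weight = Tensor(w.astype(dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Adam:
    """Adam with the standard bias-corrected moments, β=(0.9, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
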