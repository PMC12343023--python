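"""Trainable building blocks: parameters, linear layers, MLPs, Adam.

Parameter containers are deliberately flat: every :class:`Module` exposes
``named_parameters()`` returning ``{name: Tensor}``, which makes checkpoint
serialization a plain dict of arrays (see :func:`save_params` /
:func:`load_params`).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class; submodules/parameters are discovered via attributes."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{key}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Affine map on the last axis; Xavier-uniform init.

    `scale` multiplies the init range — pass 0.0 to start a layer at zero,
    which is how residual update heads are initialized to the identity.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float = 1.0):
        limit = scale * np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class MLP(Module):
    """Fully connected network with SiLU activations between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 final_scale: float = 1.0):
        self.layers = [
            Linear(dims[i], dims[i + 1], rng,
                   scale=final_scale if i == len(dims) - 2 else 1.0)
            for i in range(len(dims) - 1)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = ad.silu(x)
        return x


class Adam:
    """Adam with optional gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, clip_norm: float = 10.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def save_params(module: Module) -> dict[str, np.ndarray]:
    return {k: v.data.copy() for k, v in module.named_parameters().items()}

def load_params(module: Module, state: dict[str, np.ndarray]):
    params = module.named_parameters()
    missing = set(params) - set(state)
    if missing:
        raise KeyError(f"checkpoint missing parameters: {sorted(missing)}")
    for k, p in params.items():
        arr = np.asarray(state[k], dtype=np.float64)
        if arr.shape != p.data.shape:
            raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
        p.data = arr.copy()
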