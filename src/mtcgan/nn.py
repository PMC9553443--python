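"""Neural-network building blocks on top of :mod:`mtcgan.autodiff`.

Modules hold named parameters, compose hierarchically and serialise to flat
``{name: array}`` dictionaries.  Initialisation follows the usual Glorot /
He conventions; every module draws its weights from the ``numpy.random.
Generator`` it is given, so whole models are reproducible from one seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    conv1d,
    conv_transpose1d,
    embedding,
    layer_norm,
    masked_softmax,
)

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Conv1d",
    "ConvTranspose1d",
    "GRUCell",
    "Dropout",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Parameter container with recursive discovery of sub-modules."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}" if not prefix else f"{prefix}.{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full)
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, pad_id: int | None = 0):
        w = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d))
        if pad_id is not None:
            w[pad_id] = 0.0
        self.weight = Parameter(w)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gain, self.bias, self.eps)


class Conv1d(Module):
    """Channels-first 1-D convolution: (B, C_in, T) -> (B, C_out, T_out)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
    ):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose1d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        output_padding: int = 0,
    ):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_in, c_out, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding
        self.output_padding = output_padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose1d(
            x, self.weight, self.bias, self.stride, self.padding, self.output_padding
        )


class GRUCell(Module):
    """Gated recurrent unit with reset/update gates.

    The state update is
        r = sigmoid(W_r e + U_r p),  z = sigmoid(W_z e + U_z p),
        p' = tanh(W e + r * (U p)),  p_new = (1 - z) * p + z * p'.

    Note the convention: z gates how much of the *candidate* state is written
    (z * p'), and (1 - z) keeps the previous state.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.w_r = Linear(d_in, d_hidden, rng, bias=False)
        self.u_r = Linear(d_hidden, d_hidden, rng, bias=False)
        self.w_z = Linear(d_in, d_hidden, rng, bias=False)
        self.u_z = Linear(d_hidden, d_hidden, rng, bias=False)
        self.w = Linear(d_in, d_hidden, rng, bias=False)
        self.u = Linear(d_hidden, d_hidden, rng, bias=False)
        self.d_hidden = d_hidden

    def __call__(self, e: Tensor, p_prev: Tensor) -> Tensor:
        r = (self.w_r(e) + self.u_r(p_prev)).sigmoid()
        z = (self.w_z(e) + self.u_z(p_prev)).sigmoid()
        p_cand = (self.w(e) + r * self.u(p_prev)).tanh()
        return (1.0 - z) * p_prev + z * p_cand


class Dropout:
    """Inverted dropout; a no-op when `training` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class Adam:
    """Adam with optional global-norm gradient clipping and multiplicative decay."""

    def __init__(
        self,
        params,
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        clip_norm: float | None = 5.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def decay_lr(self, factor: float) -> None:
        self.lr *= factor

    def step(self) -> None:
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data) for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
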