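"""Small neural-network building blocks on top of the in-package autodiff."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, softplus

__all__ = ["Linear", "Module", "Adam", "sinusoidal_time_embedding"]


class Module:
    """Base class: tracks parameter tensors registered as attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(s, dtype=np.float64).copy()


def _collect(v):
    if isinstance(v, Tensor):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


class Linear(Module):
    """Affine map on the trailing axis, Glorot-initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-scale, scale, (n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, grad_clip: float | None = None) -> None:
        self.t += 1
        if grad_clip is not None:
            norm = np.sqrt(sum(float((p.grad ** 2).sum())
                               for p in self.params if p.grad is not None))
            scale = min(1.0, grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sinusoidal_time_embedding(t: np.ndarray, dim: int, max_t: int) -> np.ndarray:
    """Transformer-style sin/cos embedding of integer diffusion steps."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(float(max(max_t, 2))) * np.arange(half) / max(half - 1, 1))
    ang = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(ang), np.cos(ang)], axis=1)
    if emb.shape[1] < dim:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], dim - emb.shape[1]))], axis=1)
    return emb
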