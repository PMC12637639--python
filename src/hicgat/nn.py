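"""Neural-network building blocks on top of :mod:`hicgat.autograd`.

Modules hold named :class:`~hicgat.autograd.Tensor` parameters; ``state_dict``
/ ``load_state_dict`` give flat name->array checkpoints that serialize to
``.npz``.  Initialisation is He/Glorot style and fully determined by the
``numpy.random.Generator`` passed to the constructor, which is what makes
seeded training bit-reproducible.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "Adam",
    "ReduceLROnPlateau",
    "dropout",
]


class Module:
    """Base class: parameter registry plus train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def register(self, name: str, value):
        if isinstance(value, Module):
            self._modules[name] = value
            return value
        t = value if isinstance(value, Tensor) else Tensor(value)
        t.requires_grad = True
        self._params[name] = t
        return t

    def parameters(self) -> dict[str, Tensor]:
        out = dict(self._params)
        for mname, mod in self._modules.items():
            for pname, p in mod.parameters().items():
                out[f"{mname}.{pname}"] = p
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in params.items():
            # copy: optimizers update p.data in place and must not alias
            # the checkpoint arrays
            p.data = np.array(state[k], dtype=np.float64).reshape(p.data.shape)

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.w = self.register("w", rng.normal(0.0, scale, size=(d_in, d_out)))
        self.b = self.register("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    """Same-padded 1-D convolution, NCL layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = self.register("w", rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.b = self.register("b", np.zeros(c_out))
        self.pad = kernel // 2

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.w, self.b, self.pad)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register("gamma", np.ones(d))
        self.beta = self.register("beta", np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float = 3e-5,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-6):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored loss stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 1,
                 min_lr: float = 1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float):
        if loss < self.best - 1e-12:
            self.best = loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
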