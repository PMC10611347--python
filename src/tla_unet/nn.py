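"""Layers and optimizers built on the autograd core.

Modules follow the familiar torch-like contract: ``parameters()`` walks the
submodule tree, ``train()``/``eval()`` toggle batch-norm behaviour, and
``state_dict()``/``load_state_dict()`` expose flat name->array mappings for
checkpointing. Initialisation is fully seeded: every module receives a
``numpy.random.Generator`` at construction time.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor

# single-precision weights: halves memory traffic, ample for training;
# the autograd engine itself is dtype-generic (float64 in, float64 out)
DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class; submodules and parameters are discovered via __dict__."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, module in self._named_modules():
            for bname, buf in getattr(module, "_buffers", {}).items():
                state[f"{mname}{bname}"] = buf.copy()
        return state

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value._named_modules(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{name}.{i}.")

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers: dict[str, tuple[Module, str]] = {}
        for mname, module in self._named_modules():
            for bname in getattr(module, "_buffers", {}):
                buffers[f"{mname}{bname}"] = (module, bname)
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=params[name].data.dtype).copy()
            elif name in buffers:
                module, bname = buffers[name]
                module._buffers[bname] = np.asarray(value, dtype=DTYPE).copy()
            else:
                raise KeyError(f"unexpected state entry {name}")


def kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 padding: int | None = None):
        super().__init__()
        self.padding = (kernel // 2) if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm2d(Module):
    """Batch statistics while training, running averages in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=DTYPE),
            "running_var": np.ones(channels, dtype=DTYPE),
        }

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            self._buffers["running_mean"] = (
                (1 - self.momentum) * self._buffers["running_mean"]
                + self.momentum * mean.data.reshape(c))
            self._buffers["running_var"] = (
                (1 - self.momentum) * self._buffers["running_var"]
                + self.momentum * var.data.reshape(c))
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mean = self._buffers["running_mean"].reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self._buffers["running_var"] + self.eps)
            xhat = (x - mean) * inv.reshape(1, c, 1, 1)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mean = x.mean(axis=-1, keepdims=True)
        centred = x - mean
        var = (centred * centred).mean(axis=-1, keepdims=True)
        xhat = centred * (var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class DoubleConv(Module):
    """Two 3x3 conv+ReLU layers closed by batch normalization."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.norm = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv2(self.conv1(x).relu()).relu())


# ---------------------------------------------------------------------------
# Optimizers


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = False):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled  # AdamW when True
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdaDelta(Optimizer):
    def __init__(self, params, lr: float = 1.0, rho: float = 0.9,
                 eps: float = 1e-6, weight_decay: float = 0.0):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self.eg = [np.zeros_like(p.data) for p in self.params]
        self.ed = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self.eg, self.ed):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            delta = np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * delta * delta
            p.data -= self.lr * delta


OPTIMIZERS = {
    "sgd": lambda params, cfg: SGD(params, cfg.base_lr, cfg.momentum, cfg.weight_decay),
    "adam": lambda params, cfg: Adam(params, cfg.base_lr, weight_decay=cfg.weight_decay),
    "adamw": lambda params, cfg: Adam(params, cfg.base_lr, weight_decay=cfg.weight_decay,
                                      decoupled=True),
    "adadelta": lambda params, cfg: AdaDelta(params, cfg.base_lr,
                                             weight_decay=cfg.weight_decay),
}


def make_optimizer(name: str, params, cfg) -> Optimizer:
    try:
        factory = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; supported: {sorted(OPTIMIZERS)}"
        ) from None
    return factory(params, cfg)
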