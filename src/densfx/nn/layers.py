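"""Layer modules built on the autodiff engine.

Parameters are held as Tensors with ``requires_grad=True``; initialisation
draws from a generator passed in at construction so whole networks are
reproducible from one seed.
"""
from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    def parameters(self) -> list:
        params = []
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

    def named_state(self, prefix="") -> dict:
        state = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                state[key] = v.data.copy()
            elif isinstance(v, np.ndarray):
                state[key] = v.copy()
            elif isinstance(v, Module):
                state.update(v.named_state(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{key}.{i}."))
        return state

    def load_state(self, state: dict, prefix="") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = state[key].copy()
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state(state, f"{key}.{i}.")


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator):
        fan_in = cin * ksize**3
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize, ksize)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fin), size=(fin, fout)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(fout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add_bias(ag.matmul(x, self.weight), self.bias, axis=1)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.momentum,
            self.eps,
            training,
        )


class DoubleConv(Module):
    """Two 3x3x3 convolutions, each followed by batch norm and ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = Conv3d(cin, cout, 3, rng)
        self.bn1 = BatchNorm3d(cout)
        self.conv2 = Conv3d(cout, cout, 3, rng)
        self.bn2 = BatchNorm3d(cout)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        x = ag.relu(self.bn1(self.conv1(x), training))
        return ag.relu(self.bn2(self.conv2(x), training))
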