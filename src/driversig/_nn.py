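"""Minimal dense neural-network engine on numpy (float64).

Provides exactly what the drug-response model needs: fully-connected layers,
batch normalization, ReLU/sigmoid activations, a Sequential container with
manual backpropagation, and the Adam optimizer.  Everything is float64 and
seeded, so training is bitwise reproducible on a single thread.

Conventions: inputs are (batch, features) arrays; ``forward(x, training=...)``
caches what ``backward(dout)`` needs; parameter gradients accumulate into
``Parameter.grad`` and are cleared by ``Adam.zero_grad``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Parameter", "Dense", "BatchNorm", "ReLU", "Sigmoid", "Sequential", "Adam"]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays needed to reproduce inference (weights + running stats)."""
        return {p.name or str(i): p.value for i, p in enumerate(self.parameters())}

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for key, p in self._named_params().items():
            p.value = np.array(arrays[key], dtype=np.float64)
            p.grad = np.zeros_like(p.value)

    def _named_params(self) -> dict[str, Parameter]:
        return {p.name or str(i): p for i, p in enumerate(self.parameters())}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine layer x @ W + b with Glorot-uniform initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        if n_in < 1 or n_out < 1:
            raise ValueError("layer widths must be >= 1")
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)), "W")
        self.b = Parameter(np.zeros(n_out), "b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._x is not None
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm(Layer):
    """Batch normalization with running statistics for inference.

    Training normalizes by the batch mean and (biased) variance and updates the
    running statistics with momentum; inference applies the affine transform
    implied by the frozen running statistics.
    """

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(n), "gamma")
        self.beta = Parameter(np.zeros(n), "beta")
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            "gamma": self.gamma.value,
            "beta": self.beta.value,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        super().load_state({k: arrays[k] for k in ("gamma", "beta")})
        self.running_mean = np.array(arrays["running_mean"], dtype=np.float64)
        self.running_var = np.array(arrays["running_var"], dtype=np.float64)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            n = x.shape[0]
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = ("train", xhat, inv_std, n)
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            )
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
            self._cache = ("eval", xhat, inv_std, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        mode, xhat, inv_std, n = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        if mode == "eval":
            return dout * self.gamma.value * inv_std
        dxhat = dout * self.gamma.value
        return (
            inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._out * (1.0 - self._out)


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def state_arrays(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for key, arr in layer.state_arrays().items():
                out[f"{i}.{key}"] = arr
        return out

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            prefix = f"{i}."
            sub = {
                key[len(prefix):]: arr
                for key, arr in arrays.items()
                if key.startswith(prefix)
            }
            if sub:
                layer.load_state(sub)


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
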