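"""A small fully-connected autoencoder implemented in numpy.

Symmetric architecture: input -> hidden -> bottleneck -> hidden -> output,
with batch normalization, leaky-ReLU activation and dropout between layers,
trained by Adam on a mean-squared-error reconstruction objective.  All
randomness (weight init, shuffling, dropout masks) flows from a single
numpy Generator, so training is bit-reproducible for a fixed seed on one
device.
"""

from __future__ import annotations

import numpy as np


class _Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        # He-style init suits the leaky-rectifier units
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, g):
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self.W, self.gW), ("b", self.b, self.gb)]

    def state(self):
        return {"W": self.W, "b": self.b}


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._istd = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._istd
            return self.gamma * self._xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, g):
        n = g.shape[0]
        xhat, istd = self._xhat, self._istd
        self.ggamma = (g * xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gxhat = g * self.gamma
        return istd / n * (n * gxhat - gxhat.sum(axis=0) - xhat * (gxhat * xhat).sum(axis=0))

    def params(self):
        return [("gamma", self.gamma, self.ggamma), ("beta", self.beta, self.gbeta)]

    def state(self):
        return {
            "gamma": self.gamma,
            "beta": self.beta,
            "running_mean": self.running_mean,
            "running_var": self.running_var,
        }


class _LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train):
        if train:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, g):
        return np.where(self._neg, self.slope * g, g)

    def params(self):
        return []

    def state(self):
        return {}


class _Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = self.rng.random(x.shape) >= self.rate
        return x * self._mask / (1.0 - self.rate)

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask / (1.0 - self.rate)

    def params(self):
        return []

    def state(self):
        return {}


class AutoencoderNet:
    """input -> hidden -> bottleneck -> hidden -> output, MSE objective."""

    def __init__(
        self,
        n_input: int,
        hidden: int,
        bottleneck: int,
        dropout: float,
        leaky_slope: float,
        rng: np.random.Generator,
    ):
        self.dims = (n_input, hidden, bottleneck)
        self.rng = rng
        mk = lambda a, b: _Dense(rng, a, b)
        self.encoder = [
            mk(n_input, hidden),
            _BatchNorm(hidden),
            _LeakyReLU(leaky_slope),
            _Dropout(dropout, rng),
            mk(hidden, bottleneck),
            _BatchNorm(bottleneck),
            _LeakyReLU(leaky_slope),
        ]
        self.decoder = [
            _Dropout(dropout, rng),
            mk(bottleneck, hidden),
            _BatchNorm(hidden),
            _LeakyReLU(leaky_slope),
            _Dropout(dropout, rng),
            mk(hidden, n_input),
        ]
        self.layers = self.encoder + self.decoder
        self._adam = {}

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def encode(self, x):
        for layer in self.encoder:
            x = layer.forward(x, train=False)
        return x

    def train_batch(self, x, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        """One Adam step on reconstruction MSE; returns the batch loss."""
        out = self.forward(x, train=True)
        diff = out - x
        loss = float(np.mean(diff**2))
        g = 2.0 * diff / diff.size
        for layer in reversed(self.layers):
            g = layer.backward(g)
        self._t = getattr(self, "_t", 0) + 1
        t = self._t
        for i, layer in enumerate(self.layers):
            for name, p, grad in layer.params():
                key = (i, name)
                m, v = self._adam.get(key, (np.zeros_like(p), np.zeros_like(p)))
                m = beta1 * m + (1 - beta1) * grad
                v = beta2 * v + (1 - beta2) * grad**2
                self._adam[key] = (m, v)
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
        return loss

    def eval_loss(self, x):
        out = self.forward(x, train=False)
        return float(np.mean((out - x) ** 2))

    # -- serialization -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                arrays[f"layer{i}.{name}"] = arr
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.state():
                setattr(layer, name, np.array(arrays[f"layer{i}.{name}"]))
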