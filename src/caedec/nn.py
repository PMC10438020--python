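"""Convolutional autoencoder in plain numpy.

The encoder maps a record, presented as a 1-channel sequence of its d
encoded features, through two strided convolutions into a flattened map
and a fully connected layer onto an L-dimensional latent space; the
decoder mirrors it (fully connected, two fractionally strided
convolutions implemented as zero-upsampling followed by convolution)
and finishes with a sigmoid so reconstructions live in [0, 1].

Every layer implements forward/backward explicitly; gradients are
exercised against numerical differentiation in the test suite.  The
layer z = W.x_window + b with an elementwise activation g(z) is the
convolution primitive; hidden layers use ReLU, the final decoder layer
a sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "ConvSpec",
    "CAEModel",
    "conv_forward",
    "reconstruction_loss",
    "pretrain_cae",
    "Adam",
    "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


# ---------------------------------------------------------------------------
# activations

def _relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def _relu_grad(z: np.ndarray, g: np.ndarray) -> np.ndarray:
    return g * (z > 0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _sigmoid_grad(z: np.ndarray, g: np.ndarray) -> np.ndarray:
    s = _sigmoid(z)
    return g * s * (1.0 - s)


_ACT: dict[str, tuple[Callable, Callable]] = {
    "relu": (_relu, _relu_grad),
    "sigmoid": (_sigmoid, _sigmoid_grad),
    "linear": (lambda z: z, lambda z, g: g),
}


# ---------------------------------------------------------------------------
# convolution primitive

def _same_pad(lin: int, k: int, stride: int) -> tuple[int, int, int]:
    lout = -(-lin // stride)  # ceil
    total = max((lout - 1) * stride + k - lin, 0)
    return lout, total // 2, total - total // 2


def conv_forward(
    x: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    stride: int = 1,
    padding: Literal["valid", "same"] = "valid",
    activation: str = "linear",
) -> np.ndarray:
    """1-D convolution z = W.window + b per position and filter, then an
    elementwise activation.

    ``x`` is (n, c_in, L); ``weights`` is (c_out, c_in, k); returns
    (n, c_out, L_out).  'valid' requires k <= L.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(weights, dtype=float)
    n, cin, lin = x.shape
    cout, cin_w, k = w.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, kernel expects {cin_w}")
    if padding == "valid":
        if k > lin:
            raise ValueError(f"kernel length {k} exceeds input length {lin}")
        lout = (lin - k) // stride + 1
        xp = x
    else:
        lout, pl, pr = _same_pad(lin, k, stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
    idx = stride * np.arange(lout)[:, None] + np.arange(k)[None, :]
    windows = xp[:, :, idx]  # (n, cin, lout, k)
    z = np.einsum("ncok,fck->nfo", windows, w) + np.asarray(bias)[None, :, None]
    return _ACT[activation][0](z)


# ---------------------------------------------------------------------------
# layers

class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(Layer):
    """Strided 'same'-padded 1-D convolution with activation."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 activation: str, rng: np.random.Generator):
        fan_in = c_in * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.stride = stride
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, cin, lin = x.shape
        cout, _, k = self.w.shape
        lout, pl, pr = _same_pad(lin, k, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        idx = self.stride * np.arange(lout)[:, None] + np.arange(k)[None, :]
        self._cache = (xp, idx, pl, lin)
        windows = xp[:, :, idx]
        z = np.einsum("ncok,fck->nfo", windows, self.w) + self.b[None, :, None]
        self._z = z
        return _ACT[self.activation][0](z)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, idx, pl, lin = self._cache
        gz = _ACT[self.activation][1](self._z, g)  # (n, cout, lout)
        windows = xp[:, :, idx]
        self.dw[...] = np.einsum("nfo,ncok->fck", gz, windows)
        self.db[...] = gz.sum(axis=(0, 2))
        gw = np.einsum("nfo,fck->ncok", gz, self.w)  # grad wrt windows
        gxp = np.zeros_like(xp)
        np.add.at(gxp, (slice(None), slice(None), idx), gw)
        return gxp[:, :, pl:pl + lin]


class Upsample1D(Layer):
    """Zero-stuffing upsampling: inserts stride-1 zeros between samples.
    Composed with a stride-1 Conv1D this realizes a transposed
    (fractionally strided) convolution."""

    def __init__(self, stride: int):
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, lin = x.shape
        out = np.zeros((n, c, lin * self.stride))
        out[:, :, :: self.stride] = x
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g[:, :, :: self.stride]


class Crop1D(Layer):
    """Trim trailing positions to the target length (decoder output must
    match d exactly after upsampling overshoots)."""

    def __init__(self, target: int):
        self.target = target

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._lin = x.shape[2]
        if self._lin < self.target:
            raise ValueError("cannot crop below target length")
        return x[:, :, : self.target]

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.pad(g, ((0, 0), (0, 0), (0, self._lin - self.target)))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, channels: int, length: int):
        self.channels = channels
        self.length = length

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], self.channels, self.length)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(g.shape[0], -1)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, activation: str, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.activation = activation
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._z = x @ self.w + self.b
        return _ACT[self.activation][0](self._z)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gz = _ACT[self.activation][1](self._z, g)
        self.dw[...] = self._x.T @ gz
        self.db[...] = gz.sum(axis=0)
        return gz @ self.w.T


# ---------------------------------------------------------------------------
# model

@dataclass(frozen=True)
class ConvSpec:
    """Architecture: two strided conv layers per stage plus two fully
    connected layers; the final decoder convolution is sigmoid-activated."""

    filters: tuple[int, int] = (16, 32)
    kernel: int = 3
    stride: int = 2
    latent_dim: int = 10

    def __post_init__(self) -> None:
        if len(self.filters) != 2:
            raise ValueError("exactly two conv layers per stage")
        if self.kernel < 1 or self.stride < 1 or self.latent_dim < 1:
            raise ValueError("kernel, stride and latent_dim must be positive")


class CAEModel:
    """Encoder/decoder stack for d-dimensional records in [0, 1]."""

    def __init__(self, d: int, spec: ConvSpec = ConvSpec(), seed: int = 0):
        if spec.kernel > d:
            raise ValueError(f"kernel length {spec.kernel} exceeds input width {d}")
        rng = np.random.default_rng(seed)
        f1, f2 = spec.filters
        s, k = spec.stride, spec.kernel
        d1 = -(-d // s)
        d2 = -(-d1 // s)
        self.d = d
        self.spec = spec
        self.encoder: list[Layer] = [
            Conv1D(1, f1, k, s, "relu", rng),
            Conv1D(f1, f2, k, s, "relu", rng),
            Flatten(),
            Dense(f2 * d2, spec.latent_dim, "linear", rng),
        ]
        self.decoder: list[Layer] = [
            Dense(spec.latent_dim, f2 * d2, "relu", rng),
            Reshape(f2, d2),
            Upsample1D(s),
            Conv1D(f2, f1, k, 1, "relu", rng),
            Upsample1D(s),
            Conv1D(f1, 1, k, 1, "sigmoid", rng),
            Crop1D(d),
        ]
        if d2 * s * s < d:  # ceil-padding guarantees this never happens
            raise AssertionError("decoder underproduces positions")

    # -- forward / backward -------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Map (n, d) records in [0, 1] to the (n, L) latent space."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.d:
            raise ValueError(f"expected (n, {self.d}) input, got {x.shape}")
        h = x[:, None, :]
        for layer in self.encoder:
            h = layer.forward(h)
        return h

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Map (n, L) latent points to (n, d) reconstructions in [0, 1]."""
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected (n, {self.spec.latent_dim}) latent input, got {z.shape}"
            )
        h = z
        for layer in self.decoder:
            h = layer.forward(h)
        return h[:, 0, :]

    def backward_decoder(self, g_xhat: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(reconstruction) to the latent space."""
        g = g_xhat[:, None, :]
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        return g

    def backward_encoder(self, g_z: np.ndarray) -> None:
        g = g_z
        for layer in reversed(self.encoder):
            g = layer.backward(g)

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[np.ndarray]:
        out = []
        for layer in [*self.encoder, *self.decoder]:
            out.extend(layer.params())
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for layer in [*self.encoder, *self.decoder]:
            out.extend(layer.grads())
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint the architecture and all parameters (npz)."""
        arrays = {f"p{i}": p for i, p in enumerate(self.params())}
        np.savez(
            path,
            d=self.d,
            filters=np.asarray(self.spec.filters),
            kernel=self.spec.kernel,
            stride=self.spec.stride,
            latent_dim=self.spec.latent_dim,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CAEModel":
        data = np.load(path)
        spec = ConvSpec(
            filters=tuple(int(f) for f in data["filters"]),
            kernel=int(data["kernel"]),
            stride=int(data["stride"]),
            latent_dim=int(data["latent_dim"]),
        )
        model = cls(int(data["d"]), spec)
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        return model


# ---------------------------------------------------------------------------
# losses and pretraining

def reconstruction_loss(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean over records of the squared Euclidean reconstruction error
    ||x - xhat||^2; zero iff the reconstruction is exact."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {xhat.shape}")
    return float(np.mean(np.sum((x - xhat) ** 2, axis=1)))


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def pretrain_cae(
    x: np.ndarray,
    spec: ConvSpec = ConvSpec(),
    epochs: int = 50,
    learning_rate: float = 1e-3,
    batch_size: int = 256,
    seed: int = 0,
) -> tuple[CAEModel, np.ndarray]:
    """Train the autoencoder to minimize the reconstruction loss.

    Returns the trained model and the per-epoch loss trace (mean
    training loss over minibatches).  Fully reproducible for a fixed
    seed.  Raises :class:`DivergenceError` if the loss goes non-finite.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    model = CAEModel(d, spec, seed=seed)
    opt = Adam(model.params(), lr=learning_rate)
    rng = np.random.default_rng(seed + 1)
    trace = np.empty(epochs)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb = x[idx]
            z = model.encode(xb)
            xhat = model.decode(z)
            loss = reconstruction_loss(xb, xhat)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite reconstruction loss at epoch {epoch}")
            g_xhat = 2.0 * (xhat - xb) / len(xb)
            gz = model.backward_decoder(g_xhat)
            model.backward_encoder(gz)
            opt.step(model.grads())
            losses.append(loss)
            weights.append(len(xb))
        trace[epoch] = np.average(losses, weights=weights)
    return model, trace
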