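"""Minimal reverse-mode autodiff and neural layers on numpy.

Provides exactly what the neural model families need — dense, 1-D
convolution, GRU, and transformer-encoder layers with ReLU activations,
Adam, binary cross-entropy and mean-squared-error losses, and early
stopping on a validation set — in a few hundred lines of array code.
Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "Adam", "Dense", "Conv1d", "GRU", "TransformerEncoderBlock",
    "relu", "sigmoid", "tanh", "softmax", "layer_norm",
    "bce_with_logits", "mse_loss", "train_network",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph; data and grad are float64 arrays."""

    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor") -> None:
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            order.append(node)

        visit(self)
        for node in order:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)

        return Tensor(self.data + other.data, parents=(self, other), backward=back)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)

        return Tensor(self.data * other.data, parents=(self, other), backward=back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data ** 2, other.shape)

        return Tensor(self.data / other.data, parents=(self, other), backward=back)

    def __matmul__(self, other):
        other = self._lift(other)

        def back(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)

        return Tensor(self.data @ other.data, parents=(self, other), backward=back)

    def __getitem__(self, item):
        def back(g):
            if self.requires_grad:
                np.add.at(self.grad, item, g)

        return Tensor(self.data[item], parents=(self,), backward=back)

    def sum(self, axis=None, keepdims=False):
        def back(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += g
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self.grad += np.broadcast_to(g, self.shape)

        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        def back(g):
            if self.requires_grad:
                self.grad += g.reshape(self.shape)

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    def swapaxes(self, a, b):
        def back(g):
            if self.requires_grad:
                self.grad += np.swapaxes(g, a, b)

        return Tensor(np.swapaxes(self.data, a, b), parents=(self,), backward=back)


# -- nonlinearities and norms ----------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def back(g):
        if x.requires_grad:
            x.grad += g * mask

    return Tensor(x.data * mask, parents=(x,), backward=back)


def sigmoid(x: Tensor) -> Tensor:
    out = np.empty_like(x.data)
    pos = x.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    expx = np.exp(x.data[~pos])
    out[~pos] = expx / (1.0 + expx)

    def back(g):
        if x.requires_grad:
            x.grad += g * out * (1.0 - out)

    return Tensor(out, parents=(x,), backward=back)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def back(g):
        if x.requires_grad:
            x.grad += g * (1.0 - out ** 2)

    return Tensor(out, parents=(x,), backward=back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=axis, keepdims=True)
            x.grad += out * (g - dot)

    return Tensor(out, parents=(x,), backward=back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    inv = _rsqrt(var + eps)
    return centered * inv * gamma + beta


def _rsqrt(x: Tensor) -> Tensor:
    out = 1.0 / np.sqrt(x.data)

    def back(g):
        if x.requires_grad:
            x.grad += g * (-0.5) * out ** 3

    return Tensor(out, parents=(x,), backward=back)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """1-D convolution: x (N, Cin, L), w (Cout, Cin, K) → (N, Cout, Lout)."""
    n, cin, length = x.shape
    cout, _, k = w.shape
    lout = (length - k) // stride + 1
    idx = (np.arange(lout)[:, None] * stride + np.arange(k)[None, :])  # Lout × K
    cols = x.data[:, :, idx]  # N × Cin × Lout × K
    out = np.einsum("ncal,ocl->noa", cols, w.data, optimize=True) + b.data[None, :, None]

    def back(g):
        if w.requires_grad:
            w.grad += np.einsum("noa,ncal->ocl", g, cols, optimize=True)
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 2))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            contrib = np.einsum("noa,ocl->ncal", g, w.data, optimize=True)
            np.add.at(gx, (slice(None), slice(None), idx), contrib)
            x.grad += gx

    return Tensor(out, parents=(x, w, b), backward=back)


# -- layers ----------------------------------------------------------------

class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[-2] if len(shape) > 1 else shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Tensor(_glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = Tensor(rng.normal(0.0, scale, size=(c_out, c_in, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b, stride=self.stride)


class GRU(Module):
    """Single-layer gated recurrent unit over (N, T, F) input."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.wz = Tensor(_glorot(rng, n_in, n_hidden), requires_grad=True)
        self.uz = Tensor(_glorot(rng, n_hidden, n_hidden), requires_grad=True)
        self.bz = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.wr = Tensor(_glorot(rng, n_in, n_hidden), requires_grad=True)
        self.ur = Tensor(_glorot(rng, n_hidden, n_hidden), requires_grad=True)
        self.br = Tensor(np.zeros(n_hidden), requires_grad=True)
        self.wh = Tensor(_glorot(rng, n_in, n_hidden), requires_grad=True)
        self.uh = Tensor(_glorot(rng, n_hidden, n_hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(n_hidden), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, steps, _ = x.shape
        h = Tensor(np.zeros((n, self.n_hidden)))
        for t in range(steps):
            xt = x[:, t, :]
            z = sigmoid(xt @ self.wz + h @ self.uz + self.bz)
            r = sigmoid(xt @ self.wr + h @ self.ur + self.br)
            cand = tanh(xt @ self.wh + (r * h) @ self.uh + self.bh)
            h = (1.0 - z) * h + z * cand
        return h


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.wk = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.wv = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)
        self.wo = Tensor(_glorot(rng, d_model, d_model), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, t, d = x.shape

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, self.n_heads, self.d_head).swapaxes(1, 2)

        q, k, v = split(x @ self.wq), split(x @ self.wk), split(x @ self.wv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        out = (attn @ v).swapaxes(1, 2).reshape(n, t, d)
        return out @ self.wo


class TransformerEncoderBlock(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int,
                 rng: np.random.Generator):
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ff1 = Dense(d_model, d_ff, rng)
        self.ff2 = Dense(d_ff, d_model, rng)
        self.g1 = Tensor(np.ones(d_model), requires_grad=True)
        self.b1 = Tensor(np.zeros(d_model), requires_grad=True)
        self.g2 = Tensor(np.ones(d_model), requires_grad=True)
        self.b2 = Tensor(np.zeros(d_model), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        x = layer_norm(x + self.attn(x), self.g1, self.b1)
        return layer_norm(x + self.ff2(relu(self.ff1(x))), self.g2, self.b2)


# -- losses ----------------------------------------------------------------

def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy; y in {0, 1}."""
    z = logits.data
    # loss = max(z,0) - z*y + log(1+exp(-|z|))
    loss_val = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = np.empty_like(z)
    pos = z >= 0
    p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    p[~pos] = ez / (1.0 + ez)

    def back(g):
        if logits.requires_grad:
            logits.grad += g * (p - y) / z.size

    return Tensor(loss_val.mean(), parents=(logits,), backward=back)


def mse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    diff = pred - Tensor(y)
    return (diff * diff).mean()


# -- optimizer and training loop ------------------------------------------

class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g ** 2
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train_network(
    forward,
    params: list[Tensor],
    loss_fn,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 200,
    patience: int = 10,
) -> dict:
    """Mini-batch Adam with early stopping on validation loss.

    Keeps the best-validation-loss weights (restored before returning) and
    records per-epoch train/validation loss curves.
    """
    optimizer = Adam(params, lr=lr)
    n = x_train.shape[0]
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    stale = 0
    curves = {"train_loss": [], "val_loss": []}
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            take = order[start:start + batch_size]
            loss = loss_fn(forward(Tensor(x_train[take])), y_train[take])
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(take)
        val_loss = float(loss_fn(forward(Tensor(x_val)), y_val).data)
        curves["train_loss"].append(epoch_loss / n)
        curves["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.data.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    for p, state in zip(params, best_state):
        p.data = state
    return curves
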