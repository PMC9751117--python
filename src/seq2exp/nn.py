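"""A small feed-forward neural-network engine in numpy.

Implements exactly what the benchmark needs and nothing more: dense and 1-D
convolutional layers (channels-last), ReLU, max pooling, inverted dropout,
mean-squared-error loss, the Adam optimizer, early stopping on a validation
split, and two flavours of input attribution:

* plain input gradients (``input_gradient``), and
* reference-based multiplier backprop (``deeplift``) where the ReLU
  "derivative" is replaced by Δout/Δin between the input and a reference —
  the rescale rule.  For networks of dense + ReLU layers the resulting
  per-unit contributions sum exactly to f(x) − f(reference) (completeness);
  max-pool layers route contributions through the argmax unit, which breaks
  exact completeness for convolutional nets but keeps scores well defined.

Everything is deterministic given the Generator passed to ``fit``.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError, TrainingError, ValidationError

_EPS = 1e-9


class Layer:
    """Base layer; parametric layers override params/grads."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # reference-based multiplier propagation (DeepLIFT rescale style).
    # forward_pair stores activations for input and reference; multiplier
    # maps output multipliers to input multipliers.
    def forward_pair(self, x: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.forward(x), self.forward(r)

    def multiplier(self, m: np.ndarray) -> np.ndarray:
        return self.backward(m)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init_scale: float = 1.0):
        scale = init_scale * np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def forward_pair(self, x, r):
        return x @ self.W + self.b, r @ self.W + self.b

    def multiplier(self, m):
        return m @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._x = x
        return np.maximum(x, 0.0)

    def backward(self, dout):
        return dout * (self._x > 0)

    def forward_pair(self, x, r):
        self._dx = x - r
        self._dy = np.maximum(x, 0.0) - np.maximum(r, 0.0)
        self._gate = x > 0
        return np.maximum(x, 0.0), np.maximum(r, 0.0)

    def multiplier(self, m):
        ratio = np.where(np.abs(self._dx) > _EPS, self._dy / np.where(
            np.abs(self._dx) > _EPS, self._dx, 1.0), self._gate.astype(float))
        return m * ratio


class Conv1D(Layer):
    """Valid 1-D convolution on channels-last input (N, L, C) → (N, L−w+1, F)."""

    def __init__(self, c_in: int, filters: int, width: int, rng: np.random.Generator):
        self.c_in, self.filters, self.width = c_in, filters, width
        scale = np.sqrt(2.0 / (c_in * width))
        self.W = rng.normal(0.0, scale, size=(width * c_in, filters))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _cols(self, x):
        # (N, P, width, C) → (N, P, width*C)
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        win = np.moveaxis(win, -1, 2)  # (N, P, width, C)
        n, p = win.shape[0], win.shape[1]
        return np.ascontiguousarray(win).reshape(n, p, self.width * self.c_in)

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.c_in:
            raise ValidationError(f"Conv1D expects (N, L, {self.c_in}) input, got {x.shape}")
        if x.shape[1] < self.width:
            raise ValidationError("sequence shorter than kernel width")
        self._shape = x.shape
        self._cols_x = self._cols(x)
        return self._cols_x @ self.W + self.b

    def _scatter(self, dcols):
        n, p, _ = dcols.shape
        dx = np.zeros(self._shape)
        dcols = dcols.reshape(n, p, self.width, self.c_in)
        for w in range(self.width):
            dx[:, w : w + p, :] += dcols[:, :, w, :]
        return dx

    def backward(self, dout):
        n, p, f = dout.shape
        self.dW[...] = self._cols_x.reshape(-1, self.W.shape[0]).T @ dout.reshape(-1, f)
        self.db[...] = dout.sum(axis=(0, 1))
        return self._scatter(dout @ self.W.T)

    def forward_pair(self, x, r):
        self._shape = x.shape
        return (
            self._cols(x) @ self.W + self.b,
            self._cols(r) @ self.W + self.b,
        )

    def multiplier(self, m):
        return self._scatter(m @ self.W.T)


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the position axis; remainder truncated."""

    def __init__(self, size: int):
        if size < 1:
            raise ConfigurationError("pool size must be >= 1")
        self.size = size

    def _view(self, x):
        n, p, c = x.shape
        q = p // self.size
        return x[:, : q * self.size, :].reshape(n, q, self.size, c)

    def forward(self, x, train=False):
        self._shape = x.shape
        v = self._view(x)
        self._arg = v.argmax(axis=2)
        return v.max(axis=2)

    def backward(self, dout):
        n, q, c = dout.shape
        dv = np.zeros((n, q, self.size, c))
        np.put_along_axis(dv, self._arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(self._shape)
        dx[:, : q * self.size, :] = dv.reshape(n, q * self.size, c)
        return dx

    def forward_pair(self, x, r):
        # contributions routed through x's argmax unit (gradient-style)
        return self.forward(x), self._view(r).max(axis=2)

    def multiplier(self, m):
        return self.backward(m)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def forward_pair(self, x, r):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1), r.reshape(r.shape[0], -1)

    def multiplier(self, m):
        return m.reshape(self._shape)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ConfigurationError("dropout rate must be in [0,1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, train=False):
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def forward_pair(self, x, r):  # inference mode: identity
        return x, r

    def multiplier(self, m):
        return m


class Network:
    """Sequential network with MSE loss, Adam, and early stopping."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self._adam_state = None
        self.history: dict[str, list[float]] = {}

    # -- inference ---------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False).reshape(-1)

    # -- training ----------------------------------------------------------
    def _params_grads(self):
        ps, gs = [], []
        for layer in self.layers:
            ps.extend(layer.params())
            gs.extend(layer.grads())
        return ps, gs

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.layers for p in p.params()))

    def _adam_step(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        ps, gs = self._params_grads()
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in ps],
                "v": [np.zeros_like(p) for p in ps],
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for p, g, m, v in zip(ps, gs, st["m"], st["v"]):
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        batch_size: int = 64,
        lr: float = 1e-3,
        max_epochs: int = 100,
        patience: int = 15,
        val_fraction: float = 0.1,
    ) -> "Network":
        """Train with MSE loss, Adam (no schedule), and early stopping.

        A stratified ``val_fraction`` of the training sample (by target
        deciles) monitors the loss; training halts after ``patience`` epochs
        without improvement (never beyond ``max_epochs``) and the best
        weights are restored.
        """
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape[0] != len(y):
            raise ValidationError("rows(X) must equal len(y)")
        n_val = max(1, int(round(val_fraction * len(y)))) if len(y) >= 10 else 0
        if n_val:
            order = np.argsort(y, kind="stable")
            val_idx = order[np.arange(len(y)) % max(1, len(y) // n_val) == 0][:n_val]
            mask = np.ones(len(y), dtype=bool)
            mask[val_idx] = False
            X_tr, y_tr, X_val, y_val = X[mask], y[mask], X[val_idx], y[val_idx]
        else:
            X_tr, y_tr, X_val, y_val = X, y, X, y
        # start from the target mean: shifts the output bias so the initial
        # prediction is the baseline predictor, which saves many epochs on
        # small sample budgets
        last = self.layers[-1]
        if isinstance(last, Dense):
            shift = float(y_tr.mean() - self.forward(X_tr[: min(256, len(y_tr))]).mean())
            last.b += shift
        best_loss, best_params, wait = np.inf, None, 0
        self.history = {"train_loss": [], "val_loss": []}
        for _epoch in range(max_epochs):
            order = rng.permutation(len(y_tr))
            epoch_loss = 0.0
            for start in range(0, len(order), batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X_tr[idx], y_tr[idx]
                pred = self.forward(xb, train=True).reshape(-1)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise TrainingError("NaN/inf training loss")
                epoch_loss += loss * len(idx)
                dout = (2.0 * err / len(idx)).reshape(-1, 1)
                for layer in reversed(self.layers):
                    dout = layer.backward(dout)
                self._adam_step(lr)
            val_loss = float(np.mean((self.predict(X_val) - y_val) ** 2))
            self.history["train_loss"].append(epoch_loss / len(y_tr))
            self.history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-12:
                best_loss = val_loss
                best_params = [p.copy() for p, _ in zip_params(self)]
                wait = 0
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_params is not None:
            for (p, _), saved in zip(zip_params(self), best_params):
                p[...] = saved
        return self

    # -- attribution -------------------------------------------------------
    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """d output / d input for each row of ``x`` (scalar-output networks)."""
        out = self.forward(x, train=False)
        dout = np.ones_like(out)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def deeplift(self, x: np.ndarray, reference: np.ndarray) -> np.ndarray:
        """Rescale-rule contributions of each input unit vs ``reference``.

        Returns an array shaped like ``x``; for dense-ReLU networks the
        contributions of a row sum to f(x) − f(reference) exactly.
        """
        if reference.shape != x.shape:
            reference = np.broadcast_to(reference, x.shape).copy()
        a, r = x, reference
        for layer in self.layers:
            a, r = layer.forward_pair(a, r)
        m = np.ones_like(a)
        for layer in reversed(self.layers):
            m = layer.multiplier(m)
        return m * (x - reference)


def zip_params(net: Network):
    for layer in net.layers:
        for p in layer.params():
            yield p, layer


def build_mlp(
    input_dim: int,
    hidden: tuple[int, ...] = (64, 64, 64),
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Network:
    """Multilayer perceptron: dense-ReLU hidden layers, linear scalar output."""
    rng = rng or np.random.default_rng(0)
    dims = [input_dim, *hidden]
    layers: list[Layer] = []
    for a, b in zip(dims[:-1], dims[1:]):
        layers.append(Dense(a, b, rng))
        layers.append(ReLU())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
    # near-zero output head: the initial prediction is the target mean set
    # by fit(), which accelerates convergence on small sample budgets
    layers.append(Dense(dims[-1], 1, rng, init_scale=0.01))
    return Network(layers)


def build_cnn(
    L: int,
    conv_filters: tuple[int, ...] = (64, 128, 64),
    kernel_widths: tuple[int, ...] = (5, 5, 3),
    pool_sizes: tuple[int, ...] = (2, 2, 2),
    dense_widths: tuple[int, ...] = (128, 64, 32),
    dropout: float = 0.2,
    in_channels: int = 4,
    rng: np.random.Generator | None = None,
) -> Network:
    """Convolutional network on (N, L, 4) one-hot input, linear scalar output."""
    if not (len(conv_filters) == len(kernel_widths) == len(pool_sizes)):
        raise ConfigurationError("conv stage tuples must have equal length")
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = []
    c, p = in_channels, L
    for f, w, s in zip(conv_filters, kernel_widths, pool_sizes):
        if p < w:
            raise ConfigurationError(
                f"architecture does not fit length {L}: window {w} on {p} positions"
            )
        layers.append(Conv1D(c, f, w, rng))
        layers.append(ReLU())
        p = p - w + 1
        if s > 1:
            layers.append(MaxPool1D(s))
            p = p // s
            if p < 1:
                raise ConfigurationError(f"architecture does not fit length {L}: pooled to zero")
        c = f
    layers.append(Flatten())
    dim = p * c
    for h in dense_widths:
        layers.append(Dense(dim, h, rng))
        layers.append(ReLU())
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
        dim = h
    layers.append(Dense(dim, 1, rng, init_scale=0.01))
    return Network(layers)
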