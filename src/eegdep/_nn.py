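"""Minimal feed-forward/recurrent neural-network engine in NumPy.

Implements exactly what the classifier suite needs: dense, LSTM, GRU, 1-D
convolution, max-pooling, batch-norm and flatten layers; binary cross-entropy
with an L2 kernel penalty; Adam; mini-batch training with an 80/20
train/validation split and best-validation-loss checkpointing. Everything is
float64 and seeded, so training is deterministic for a fixed seed, and every
backward pass is verified against numerical differentiation in the test
suite.

Tensors are ``(batch, timesteps, features)`` for sequence layers and
``(batch, features)`` after flattening.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "LSTM",
    "GRU",
    "Conv1D",
    "MaxPool1D",
    "BatchNorm",
    "Flatten",
    "Sequential",
]

_EPS = 1e-12


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng, shape):
    fan_in, fan_out = shape[0] if len(shape) == 2 else np.prod(shape[:-1]), shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def reg_loss(self) -> float:
        return 0.0

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    """Fully connected layer with optional activation and L2 kernel penalty."""

    def __init__(self, n_in, n_out, activation=None, l2=0.0, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.l2 = l2
        self.params = {"W": _glorot(rng, (n_in, n_out)), "b": np.zeros(n_out)}

    def forward(self, x, training=False):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            out = _sigmoid(z)
        elif self.activation == "tanh":
            out = np.tanh(z)
        elif self.activation is None:
            out = z
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        self._out = out
        return out

    def backward(self, grad):
        if self.activation == "relu":
            dz = grad * (self._out > 0)
        elif self.activation == "sigmoid":
            dz = grad * self._out * (1.0 - self._out)
        elif self.activation == "tanh":
            dz = grad * (1.0 - self._out**2)
        else:
            dz = grad
        self.grads["W"] = self._x.T @ dz + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T

    def reg_loss(self):
        return float(self.l2 * np.sum(self.params["W"] ** 2))


class LSTM(Layer):
    """Standard LSTM (gate order i, f, g, o; forget-gate bias 1)."""

    def __init__(self, n_in, units, return_sequences=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.return_sequences = return_sequences
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.params = {
            "W": _glorot(rng, (n_in, 4 * units)),
            "U": _glorot(rng, (units, 4 * units)),
            "b": b,
        }

    def forward(self, x, training=False):
        B, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        outs = np.empty((B, T, H))
        for t in range(T):
            xt = x[:, t, :]
            a = xt @ W + h @ U + b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((xt, h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            outs[:, t, :] = h
        self._x_shape = x.shape
        return outs if self.return_sequences else h

    def backward(self, grad):
        B, T, D = self._x_shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros_like(self.params["b"])
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            if self.return_sequences:
                dh = grad[:, t, :] + dh_next
            else:
                dh = (grad if t == T - 1 else 0.0) + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            gW += xt.T @ da
            gU += h_prev.T @ da
            gb += da.sum(axis=0)
            dx[:, t, :] = da @ W.T
            dh_next = da @ U.T
            dc_next = dc * f
        self.grads = {"W": gW, "U": gU, "b": gb}
        return dx


class GRU(Layer):
    """GRU, gate order (z, r, h-candidate); h_new = (1-z)*h + z*h_cand."""

    def __init__(self, n_in, units, return_sequences=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.units = units
        self.return_sequences = return_sequences
        self.params = {
            "W": _glorot(rng, (n_in, 3 * units)),
            "U": _glorot(rng, (units, 3 * units)),
            "b": np.zeros(3 * units),
        }

    def forward(self, x, training=False):
        B, T, _ = x.shape
        H = self.units
        W, U, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, H))
        self._cache = []
        outs = np.empty((B, T, H))
        for t in range(T):
            xt = x[:, t, :]
            az = xt @ W[:, :H] + h @ U[:, :H] + b[:H]
            ar = xt @ W[:, H : 2 * H] + h @ U[:, H : 2 * H] + b[H : 2 * H]
            z = _sigmoid(az)
            r = _sigmoid(ar)
            ah = xt @ W[:, 2 * H :] + (r * h) @ U[:, 2 * H :] + b[2 * H :]
            hc = np.tanh(ah)
            h_new = (1.0 - z) * h + z * hc
            self._cache.append((xt, h, z, r, hc))
            h = h_new
            outs[:, t, :] = h
        self._x_shape = x.shape
        return outs if self.return_sequences else h

    def backward(self, grad):
        B, T, D = self._x_shape
        H = self.units
        W, U = self.params["W"], self.params["U"]
        gW = np.zeros_like(W)
        gU = np.zeros_like(U)
        gb = np.zeros_like(self.params["b"])
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, z, r, hc = self._cache[t]
            if self.return_sequences:
                dh = grad[:, t, :] + dh_next
            else:
                dh = (grad if t == T - 1 else 0.0) + dh_next
            dz = dh * (hc - h_prev)
            dhc = dh * z
            dh_prev = dh * (1.0 - z)
            dah = dhc * (1.0 - hc**2)
            drh = dah @ U[:, 2 * H :].T
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1 - z)
            dar = dr * r * (1 - r)
            gW[:, :H] += xt.T @ daz
            gW[:, H : 2 * H] += xt.T @ dar
            gW[:, 2 * H :] += xt.T @ dah
            gU[:, :H] += h_prev.T @ daz
            gU[:, H : 2 * H] += h_prev.T @ dar
            gU[:, 2 * H :] += (r * h_prev).T @ dah
            gb[:H] += daz.sum(axis=0)
            gb[H : 2 * H] += dar.sum(axis=0)
            gb[2 * H :] += dah.sum(axis=0)
            dx[:, t, :] = (
                daz @ W[:, :H].T + dar @ W[:, H : 2 * H].T + dah @ W[:, 2 * H :].T
            )
            dh_next = dh_prev + daz @ U[:, :H].T + dar @ U[:, H : 2 * H].T
        self.grads = {"W": gW, "U": gU, "b": gb}
        return dx


class Conv1D(Layer):
    """Valid 1-D convolution over the time axis, optional ReLU."""

    def __init__(self, n_in, filters, kernel_size=3, activation="relu", rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel_size = kernel_size
        self.activation = activation
        self.params = {
            "W": _glorot(rng, (kernel_size, n_in, filters)),
            "b": np.zeros(filters),
        }

    def forward(self, x, training=False):
        k = self.kernel_size
        xs = sliding_window_view(x, k, axis=1)  # (B, T_out, C, k)
        z = np.einsum("btck,kcf->btf", xs, self.params["W"]) + self.params["b"]
        self._xs, self._x_shape = xs, x.shape
        if self.activation == "relu":
            out = np.maximum(z, 0.0)
        elif self.activation is None:
            out = z
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        self._out = out
        return out

    def backward(self, grad):
        dz = grad * (self._out > 0) if self.activation == "relu" else grad
        self.grads["W"] = np.einsum("btck,btf->kcf", self._xs, dz)
        self.grads["b"] = dz.sum(axis=(0, 1))
        dx = np.zeros(self._x_shape)
        t_out = dz.shape[1]
        for j in range(self.kernel_size):
            dx[:, j : j + t_out, :] += dz @ self.params["W"][j].T
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling over time; trailing remainder dropped."""

    def __init__(self, pool_size=2):
        super().__init__()
        self.pool_size = pool_size

    def forward(self, x, training=False):
        B, T, C = x.shape
        p = self.pool_size
        t_out = T // p
        xr = x[:, : t_out * p, :].reshape(B, t_out, p, C)
        self._argmax = xr.argmax(axis=2)
        self._x_shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        B, T, C = self._x_shape
        p = self.pool_size
        t_out = T // p
        dxr = np.zeros((B, t_out, p, C))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros(self._x_shape)
        dx[:, : t_out * p, :] = dxr.reshape(B, t_out * p, C)
        return dx


class BatchNorm(Layer):
    """Batch normalization over the feature axis of (batch, features) input."""

    def __init__(self, dim, momentum=0.9, eps=1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.state = {"mean": np.zeros(dim), "var": np.ones(dim)}

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.state["mean"] = self.momentum * self.state["mean"] + (1 - self.momentum) * mu
            self.state["var"] = self.momentum * self.state["var"] + (1 - self.momentum) * var
        else:
            mu, var = self.state["mean"], self.state["var"]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        xhat, std = self._xhat, self._std
        self.grads["gamma"] = (grad * xhat).sum(axis=0)
        self.grads["beta"] = grad.sum(axis=0)
        dxhat = grad * self.params["gamma"]
        if not self._training:
            return dxhat / std
        B = grad.shape[0]
        return (
            dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)
        ) / std


class Flatten(Layer):
    def forward(self, x, training=False):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._x_shape)


def bce_loss(p, y):
    p = np.clip(p.ravel(), 1e-9, 1.0 - 1e-9)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Sequential:
    """Layer stack with Adam/BCE training and best-validation checkpointing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    # -- forward / backward -------------------------------------------------
    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict_proba(self, x) -> np.ndarray:
        return self.forward(np.asarray(x, np.float64), training=False).ravel()

    def loss(self, x, y, training=False) -> float:
        p = self.forward(x, training=training)
        return bce_loss(p, y) + sum(l.reg_loss() for l in self.layers)

    def _backward_from_proba(self, p, y):
        n = p.shape[0]
        pc = np.clip(p, 1e-9, 1.0 - 1e-9)
        grad = ((pc - y.reshape(pc.shape)) / (pc * (1.0 - pc))) / n
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    # -- weights ------------------------------------------------------------
    def get_weights(self):
        return [
            (
                {k: v.copy() for k, v in l.params.items()},
                {k: v.copy() for k, v in l.state.items()},
            )
            for l in self.layers
        ]

    def set_weights(self, weights):
        for layer, (params, state) in zip(self.layers, weights):
            for k, v in params.items():
                layer.params[k] = v.copy()
            for k, v in state.items():
                layer.state[k] = v.copy()

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X,
        y,
        epochs=100,
        batch_size=32,
        validation_fraction=0.2,
        learning_rate=1e-3,
        beta1=0.9,
        beta2=0.999,
        adam_eps=1e-7,
        checkpoint=True,
        seed=0,
    ):
        """Train with Adam on BCE; returns a history dict.

        A fixed fraction of the data (shuffled once, seeded) is held out for
        validation; when ``checkpoint`` is set, the weights with the lowest
        validation loss are restored after the final epoch.
        """
        X = np.asarray(X, np.float64)
        y = np.asarray(y, np.float64).ravel()
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = int(round(validation_fraction * n))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ValueError("no training samples left after validation split")
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m_state: dict = {}
        v_state: dict = {}
        step = 0
        history = {"loss": [], "val_loss": [], "val_accuracy": []}
        best = (np.inf, None, -1)
        for epoch in range(epochs):
            order = rng.permutation(train_idx.size)
            epoch_losses = []
            for start in range(0, order.size, batch_size):
                batch = order[start : start + batch_size]
                xb, yb = Xtr[batch], ytr[batch]
                p = self.forward(xb, training=True)
                loss = bce_loss(p, yb) + sum(l.reg_loss() for l in self.layers)
                epoch_losses.append(loss)
                for layer in self.layers:
                    layer.zero_grads()
                self._backward_from_proba(p, yb)
                step += 1
                for i, layer in enumerate(self.layers):
                    for name, g in layer.grads.items():
                        key = (i, name)
                        m = m_state.setdefault(key, np.zeros_like(g))
                        v = v_state.setdefault(key, np.zeros_like(g))
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g**2
                        mhat = m / (1 - beta1**step)
                        vhat = v / (1 - beta2**step)
                        layer.params[name] -= learning_rate * mhat / (
                            np.sqrt(vhat) + adam_eps
                        )
            history["loss"].append(float(np.mean(epoch_losses)))
            if n_val:
                pv = self.predict_proba(Xval)
                vloss = bce_loss(pv, yval) + sum(l.reg_loss() for l in self.layers)
                vacc = float(np.mean((pv >= 0.5) == (yval >= 0.5)))
                history["val_loss"].append(vloss)
                history["val_accuracy"].append(vacc)
                if checkpoint and vloss < best[0]:
                    best = (vloss, self.get_weights(), epoch)
        if checkpoint and best[1] is not None:
            self.set_weights(best[1])
            history["checkpoint_epoch"] = best[2]
        return history
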