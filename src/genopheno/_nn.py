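"""A small NumPy neural-network engine for the classifier kinds used here.

Layers: dense, dropout, 1-D convolution with global average pooling, LSTM,
GRU and bidirectional LSTM (each recurrent layer consumes a (batch, steps,
channels) sequence and emits its final hidden state). Training is plain
backpropagation (through time for the recurrent kinds) with softmax
cross-entropy, under SGD, RMSprop or Adam. Everything is seeded through
``numpy.random.Generator`` so runs are reproducible.

Gradients are exact and unit-tested against central finite differences.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: forward caches what backward needs; backward fills grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _glorot(rng, (n_in, n_out)), "b": np.zeros(n_out)}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Activation(Layer):
    """Elementwise sigmoid/relu/tanh, or row-wise softmax used as a hidden
    activation (one of the swept options)."""

    def __init__(self, name: str) -> None:
        super().__init__()
        if name not in ("sigmoid", "relu", "tanh", "softmax"):
            raise ValueError(f"unknown activation {name!r}")
        self.name = name

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.name == "relu":
            self._y = np.maximum(x, 0.0)
        elif self.name == "sigmoid":
            self._y = _sigmoid(x)
        elif self.name == "tanh":
            self._y = np.tanh(x)
        else:
            self._y = softmax(x)
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        y = self._y
        if self.name == "relu":
            return grad * (y > 0)
        if self.name == "sigmoid":
            return grad * y * (1.0 - y)
        if self.name == "tanh":
            return grad * (1.0 - y * y)
        # softmax jacobian: dz = y * (g - sum(g * y))
        s = (grad * y).sum(axis=-1, keepdims=True)
        return y * (grad - s)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1: (N, T, C) -> (N, T-k+1, F)."""

    def __init__(self, n_in: int, n_filters: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * n_in + n_filters))
        self.params = {
            "W": rng.uniform(-limit, limit, size=(kernel, n_in, n_filters)),
            "b": np.zeros(n_filters),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        n, t, _ = x.shape
        t_out = t - self.kernel + 1
        if t_out < 1:
            raise ValueError(f"sequence length {t} shorter than kernel {self.kernel}")
        W = self.params["W"]
        out = np.broadcast_to(self.params["b"], (n, t_out, W.shape[2])).copy()
        for j in range(self.kernel):
            out += x[:, j : j + t_out, :] @ W[j]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        t_out = grad.shape[1]
        W = self.params["W"]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for j in range(self.kernel):
            xs = x[:, j : j + t_out, :]
            dW[j] = np.einsum("ntc,ntf->cf", xs, grad)
            dx[:, j : j + t_out, :] += grad @ W[j].T
        self.grads["W"] = dW
        self.grads["b"] = grad.sum(axis=(0, 1))
        return dx


class GlobalAvgPool1D(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state (N, H).

    Gate order in the packed weight matrices is input, forget, candidate,
    output. Forget-gate bias starts at 1.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        h = n_hidden
        self.n_hidden = h
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0
        self.params = {
            "Wx": _glorot(rng, (n_in, 4 * h)),
            "Wh": _glorot(rng, (h, 4 * h)),
            "b": b,
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, t, _ = x.shape
        h = self.n_hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        hs = np.zeros((t + 1, n, h))
        cs = np.zeros((t + 1, n, h))
        gates = np.empty((t, n, 4 * h))
        for step in range(t):
            z = x[:, step, :] @ Wx + hs[step] @ Wh + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[step + 1] = f * cs[step] + i * g
            hs[step + 1] = o * np.tanh(cs[step + 1])
            gates[step] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates)
        return hs[t]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, hs, cs, gates = self._cache
        n, t, _ = x.shape
        h = self.n_hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = grad.copy()
        dc = np.zeros((n, h))
        for step in range(t - 1, -1, -1):
            i = gates[step][:, :h]
            f = gates[step][:, h : 2 * h]
            g = gates[step][:, 2 * h : 3 * h]
            o = gates[step][:, 3 * h :]
            tanh_c = np.tanh(cs[step + 1])
            do = dh * tanh_c
            dct = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di = dct * g
            df = dct * cs[step]
            dg = dct * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, step, :].T @ dz
            dWh += hs[step].T @ dz
            db += dz.sum(axis=0)
            dx[:, step, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dct * f
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class GRU(Layer):
    """Single GRU layer returning the final hidden state.

    Candidate uses the reset gate applied to the previous hidden state
    before its matmul: n = tanh(x Wxn + (r * h) Whn + bn).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        h = self.n_hidden = n_hidden
        self.params = {
            "Wxz": _glorot(rng, (n_in, h)), "Whz": _glorot(rng, (h, h)), "bz": np.zeros(h),
            "Wxr": _glorot(rng, (n_in, h)), "Whr": _glorot(rng, (h, h)), "br": np.zeros(h),
            "Wxn": _glorot(rng, (n_in, h)), "Whn": _glorot(rng, (h, h)), "bn": np.zeros(h),
        }

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, t, _ = x.shape
        h = self.n_hidden
        p = self.params
        hs = np.zeros((t + 1, n, h))
        zs = np.empty((t, n, h))
        rs = np.empty((t, n, h))
        ns = np.empty((t, n, h))
        for step in range(t):
            xt, hp = x[:, step, :], hs[step]
            z = _sigmoid(xt @ p["Wxz"] + hp @ p["Whz"] + p["bz"])
            r = _sigmoid(xt @ p["Wxr"] + hp @ p["Whr"] + p["br"])
            cand = np.tanh(xt @ p["Wxn"] + (r * hp) @ p["Whn"] + p["bn"])
            hs[step + 1] = (1.0 - z) * cand + z * hp
            zs[step], rs[step], ns[step] = z, r, cand
        self._cache = (x, hs, zs, rs, ns)
        return hs[t]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, hs, zs, rs, ns = self._cache
        n, t, _ = x.shape
        p = self.params
        d = {k: np.zeros_like(v) for k, v in p.items()}
        dx = np.zeros_like(x)
        dh = grad.copy()
        for step in range(t - 1, -1, -1):
            xt, hp = x[:, step, :], hs[step]
            z, r, cand = zs[step], rs[step], ns[step]
            dcand = dh * (1.0 - z)
            dz = dh * (hp - cand)
            dh_prev = dh * z
            dan = dcand * (1.0 - cand * cand)
            d["Wxn"] += xt.T @ dan
            d["Whn"] += (r * hp).T @ dan
            d["bn"] += dan.sum(axis=0)
            drh = dan @ p["Whn"].T
            dr = drh * hp
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            for name, da in (("z", daz), ("r", dar)):
                d[f"Wx{name}"] += xt.T @ da
                d[f"Wh{name}"] += hp.T @ da
                d[f"b{name}"] += da.sum(axis=0)
                dh_prev += da @ p[f"Wh{name}"].T
            dx[:, step, :] = dan @ p["Wxn"].T + daz @ p["Wxz"].T + dar @ p["Wxr"].T
            dh = dh_prev
        self.grads = d
        return dx


class BiLSTM(Layer):
    """Forward and backward LSTM over the same sequence, final states concatenated."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fwd = LSTM(n_in, n_hidden, rng)
        self.bwd = LSTM(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    @property
    def params(self) -> dict[str, np.ndarray]:  # type: ignore[override]
        out = {f"fwd_{k}": v for k, v in self.fwd.params.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.params.items()})
        return out

    @params.setter
    def params(self, value) -> None:  # Layer.__init__ assigns {}
        pass

    @property
    def grads(self) -> dict[str, np.ndarray]:  # type: ignore[override]
        out = {f"fwd_{k}": v for k, v in self.fwd.grads.items()}
        out.update({f"bwd_{k}": v for k, v in self.bwd.grads.items()})
        return out

    @grads.setter
    def grads(self, value) -> None:
        pass

    def zero_grads(self) -> None:
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        hf = self.fwd.forward(x, training)
        hb = self.bwd.forward(x[:, ::-1, :], training)
        return np.concatenate([hf, hb], axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        h = self.n_hidden
        dxf = self.fwd.backward(grad[:, :h])
        dxb = self.bwd.backward(grad[:, h:])
        return dxf + dxb[:, ::-1, :]


class _Optimizer:
    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.state: dict[tuple[int, str], dict[str, np.ndarray]] = {}

    def step(self, layers: Sequence[Layer]) -> None:
        for li, layer in enumerate(layers):
            params = layer.params
            grads = layer.grads
            for name, g in grads.items():
                self._update(params[name], g, (li, name))

    def _update(self, p: np.ndarray, g: np.ndarray, key) -> None:
        raise NotImplementedError


class SGD(_Optimizer):
    def _update(self, p, g, key) -> None:
        p -= self.lr * g


class RMSprop(_Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7) -> None:
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, p, g, key) -> None:
        s = self.state.setdefault(key, {"v": np.zeros_like(p)})
        s["v"] = self.rho * s["v"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


class Adam(_Optimizer):
    def __init__(self, lr: float, b1: float = 0.9, b2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__(lr)
        self.b1, self.b2, self.eps = b1, b2, eps

    def _update(self, p, g, key) -> None:
        s = self.state.setdefault(key, {"m": np.zeros_like(p), "v": np.zeros_like(p), "t": 0})
        s["t"] += 1
        s["m"] = self.b1 * s["m"] + (1 - self.b1) * g
        s["v"] = self.b2 * s["v"] + (1 - self.b2) * g * g
        mhat = s["m"] / (1 - self.b1 ** s["t"])
        vhat = s["v"] / (1 - self.b2 ** s["t"])
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


_DEFAULT_LR = {"sgd": 0.05, "adam": 0.01, "rmsprop": 0.01}


def make_optimizer(name: str, lr: Optional[float] = None) -> _Optimizer:
    name = name.lower()
    if name not in _DEFAULT_LR:
        raise ValueError(f"unknown optimizer {name!r}")
    lr = lr if lr is not None else _DEFAULT_LR[name]
    return {"sgd": SGD, "adam": Adam, "rmsprop": RMSprop}[name](lr)


class Sequential:
    """A feed-forward stack trained with softmax cross-entropy.

    ``sequence_input`` marks networks whose first layer consumes a
    (batch, steps, channels) tensor; 2-D feature matrices are then reshaped
    to one channel per step.
    """

    def __init__(self, layers: Sequence[Layer], n_classes: int = 2, sequence_input: bool = False) -> None:
        self.layers = list(layers)
        self.n_classes = n_classes
        self.sequence_input = sequence_input
        self.history: dict[str, list[float]] = {}

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.sequence_input and X.ndim == 2:
            X = X[:, :, None]
        return X

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, training)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return softmax(self._forward(self._prepare(X), training=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def parameter_snapshot(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": p.copy()
            for i, layer in enumerate(self.layers)
            for name, p in layer.params.items()
        }

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        batch_size: int = 10,
        validation_split: float = 0.2,
        optimizer: str = "adam",
        learning_rate: Optional[float] = None,
        seed: int = 0,
    ) -> dict[str, list[float]]:
        """Mini-batch training; returns per-epoch history (loss, accuracy,
        val_accuracy). The validation fraction is held out of the seeded
        permutation before any update."""
        X = self._prepare(X)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        n_val = int(round(n * validation_split))
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xt, yt = X[train_idx], y[train_idx]
        opt = make_optimizer(optimizer, learning_rate)
        onehot = np.eye(self.n_classes)
        history: dict[str, list[float]] = {"loss": [], "accuracy": [], "val_accuracy": []}
        for _ in range(epochs):
            order = rng.permutation(len(Xt))
            losses = []
            correct = 0
            for start in range(0, len(Xt), batch_size):
                idx = order[start : start + batch_size]
                xb, yb = Xt[idx], yt[idx]
                for layer in self.layers:
                    layer.zero_grads()
                logits = self._forward(xb, training=True)
                probs = softmax(logits)
                eps = 1e-12
                losses.append(float(-np.log(probs[np.arange(len(yb)), yb] + eps).mean()))
                correct += int((probs.argmax(axis=1) == yb).sum())
                grad = (probs - onehot[yb]) / len(yb)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step(self.layers)
            history["loss"].append(float(np.mean(losses)) if losses else float("nan"))
            history["accuracy"].append(correct / max(len(Xt), 1))
            if n_val:
                val_pred = self.predict(X[val_idx])
                history["val_accuracy"].append(float((val_pred == y[val_idx]).mean()))
            else:
                history["val_accuracy"].append(history["accuracy"][-1])
        self.history = history
        return history
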