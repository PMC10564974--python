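"""A compact CNN-LSTM time-series classifier in pure NumPy.

The network is a single 1-D convolution with ReLU and max pooling,
followed by two LSTM layers with dropout, and a dense softmax head.
Training uses Adam with sparse categorical cross-entropy and full
backpropagation through time.  Everything is implemented on NumPy
arrays so that training is exactly reproducible from a seed on a single
CPU; gradients are verified against finite differences in the test
suite.

The implementation favours batched matrix products: the input-to-gate
contributions of each LSTM are computed for all time steps in one GEMM,
and only the recurrent term runs in the per-step loop.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["NetworkConfig", "CNNLSTM"]


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters.

    The defaults are the reference configuration: conv(50 filters,
    kernel 12) + maxpool(2), LSTM(50) -> LSTM(10) with dropout 0.10,
    dense softmax over 6 classes, Adam at learning rate 5e-4, batch
    size 1024, 200 epochs, 0.95/0.025/0.025 train/validation/test
    split.  Scaled-down runs override epochs/batch size/learning rate.
    """

    conv_filters: int = 50
    conv_kernel: int = 12
    pool_size: int = 2
    lstm_units_1: int = 50
    lstm_units_2: int = 10
    dropout_rate: float = 0.10
    n_classes: int = 6
    learning_rate: float = 5e-4
    batch_size: int = 1024
    epochs: int = 200
    split: tuple[float, float, float] = (0.95, 0.025, 0.025)

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("train/validation/test split must sum to 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")

    @classmethod
    def desk_scale(cls) -> "NetworkConfig":
        """Configuration for CPU-scale experiments (thousands of
        training examples rather than tens of thousands).  The
        architecture is unchanged from the reference; only the
        optimisation is rescaled — a larger learning rate matched to
        the smaller batches, 30 epochs — and the held-out share is
        enlarged so test metrics are measured on enough examples to be
        stable."""
        return cls(
            learning_rate=1e-3,
            batch_size=256,
            epochs=30,
            split=(0.8, 0.1, 0.1),
        )


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMLayer:
    """Single LSTM layer.  Gates are laid out as [i, f, o, g] so the
    three sigmoid gates activate in one vectorised call; the forget
    gate carries a bias of 1."""

    def __init__(self, rng, n_in: int, n_units: int, dtype) -> None:
        h = n_units
        self.Wx = _glorot(rng, (n_in, 4 * h), dtype)
        self.Wh = _glorot(rng, (h, 4 * h), dtype)
        self.b = np.zeros(4 * h, dtype=dtype)
        self.b[h : 2 * h] = 1.0  # forget gate bias
        self.n_units = h

    def params(self, prefix: str) -> dict[str, np.ndarray]:
        return {f"{prefix}.Wx": self.Wx, f"{prefix}.Wh": self.Wh, f"{prefix}.b": self.b}

    def forward(self, X: np.ndarray):
        """X: (B, T, n_in) -> H: (B, T, units) plus a BPTT cache."""
        B, T, _ = X.shape
        h = self.n_units
        pre_x = X @ self.Wx + self.b  # input-to-gate terms, all steps at once
        A = np.empty((B, T, 4 * h), dtype=X.dtype)   # activated gates [i,f,o,g]
        C = np.empty((B, T, h), dtype=X.dtype)
        TC = np.empty((B, T, h), dtype=X.dtype)
        H = np.empty((B, T, h), dtype=X.dtype)
        h_t = np.zeros((B, h), dtype=X.dtype)
        c_t = np.zeros((B, h), dtype=X.dtype)
        for t in range(T):
            a = pre_x[:, t] + h_t @ self.Wh
            act = A[:, t]
            act[:, : 3 * h] = _sigmoid(a[:, : 3 * h])
            np.tanh(a[:, 3 * h :], out=act[:, 3 * h :])
            i, f, o, g = (
                act[:, :h],
                act[:, h : 2 * h],
                act[:, 2 * h : 3 * h],
                act[:, 3 * h :],
            )
            c_t = f * c_t
            c_t += i * g
            tc = np.tanh(c_t)
            h_t = o * tc
            C[:, t], TC[:, t], H[:, t] = c_t, tc, h_t
        cache = (X, A, C, TC, H)
        return H, cache

    def backward(self, dH: np.ndarray, cache):
        """dH: gradient on the output sequence (B, T, units).

        Returns (dX, grads)."""
        X, A, C, TC, H = cache
        B, T, _ = X.shape
        h = self.n_units
        dWh = np.zeros_like(self.Wh)
        dA = np.empty((B, T, 4 * h), dtype=X.dtype)
        dh_next = np.zeros((B, h), dtype=X.dtype)
        dc_next = np.zeros((B, h), dtype=X.dtype)
        zeros = np.zeros((B, h), dtype=X.dtype)
        for t in range(T - 1, -1, -1):
            act = A[:, t]
            i, f, o, g = (
                act[:, :h],
                act[:, h : 2 * h],
                act[:, 2 * h : 3 * h],
                act[:, 3 * h :],
            )
            tc = TC[:, t]
            c_prev = C[:, t - 1] if t > 0 else zeros
            h_prev = H[:, t - 1] if t > 0 else zeros
            dh = dH[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            da = dA[:, t]
            da[:, :h] = (dc * g) * i * (1.0 - i)
            da[:, h : 2 * h] = (dc * c_prev) * f * (1.0 - f)
            da[:, 2 * h : 3 * h] = do * o * (1.0 - o)
            da[:, 3 * h :] = (dc * i) * (1.0 - g * g)
            dWh += h_prev.T @ da
            dh_next = da @ self.Wh.T
            dc_next = dc * f
        flatX = X.reshape(B * T, -1)
        flatdA = dA.reshape(B * T, 4 * h)
        dWx = flatX.T @ flatdA
        db = flatdA.sum(axis=0)
        dX = (flatdA @ self.Wx.T).reshape(X.shape)
        return dX, {"Wx": dWx, "Wh": dWh, "b": db}


class CNNLSTM:
    """conv1d + maxpool + LSTM x2 (dropout) + dense softmax."""

    def __init__(
        self,
        config: NetworkConfig,
        input_len: int = 500,
        rng_seed=None,
        dtype=np.float32,
    ) -> None:
        self.config = config
        self.input_len = input_len
        self.dtype = dtype
        rng = np.random.default_rng(rng_seed)
        c = config
        self.Wc = _glorot(rng, (c.conv_kernel, c.conv_filters), dtype)
        self.bc = np.zeros(c.conv_filters, dtype=dtype)
        self.lstm1 = _LSTMLayer(rng, c.conv_filters, c.lstm_units_1, dtype)
        self.lstm2 = _LSTMLayer(rng, c.lstm_units_1, c.lstm_units_2, dtype)
        self.Wd = _glorot(rng, (c.lstm_units_2, c.n_classes), dtype)
        self.bd = np.zeros(c.n_classes, dtype=dtype)
        self._adam_state: Optional[dict] = None
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": [], "val_acc": []}

    # ---- parameter bookkeeping -------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        p = {"Wc": self.Wc, "bc": self.bc, "Wd": self.Wd, "bd": self.bd}
        p.update(self.lstm1.params("lstm1"))
        p.update(self.lstm2.params("lstm2"))
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for name, arr in params.items():
            target = self.parameters()[name]
            if target.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            target[...] = arr

    # ---- forward / backward ----------------------------------------
    def _forward(self, X: np.ndarray, train: bool, rng: Optional[np.random.Generator]):
        c = self.config
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"expected inputs of shape (batch, {self.input_len})")
        B = X.shape[0]
        win = sliding_window_view(X, c.conv_kernel, axis=1)  # (B, Tc, K)
        Z = win @ self.Wc + self.bc                          # (B, Tc, F)
        relu_mask = Z > 0
        A = Z * relu_mask
        Tc = A.shape[1]
        Tp = Tc // c.pool_size
        A4 = A[:, : Tp * c.pool_size].reshape(B, Tp, c.pool_size, c.conv_filters)
        pool_idx = A4.argmax(axis=2)
        P = np.take_along_axis(A4, pool_idx[:, :, None, :], axis=2)[:, :, 0, :]

        H1, cache1 = self.lstm1.forward(P)
        if train and c.dropout_rate > 0:
            mask1 = (rng.random(H1.shape) >= c.dropout_rate) / (1.0 - c.dropout_rate)
            mask1 = mask1.astype(self.dtype)
        else:
            mask1 = None
        H1d = H1 if mask1 is None else H1 * mask1

        H2, cache2 = self.lstm2.forward(H1d)
        h_last = H2[:, -1]
        if train and c.dropout_rate > 0:
            mask2 = (rng.random(h_last.shape) >= c.dropout_rate) / (1.0 - c.dropout_rate)
            mask2 = mask2.astype(self.dtype)
        else:
            mask2 = None
        h_drop = h_last if mask2 is None else h_last * mask2

        logits = h_drop @ self.Wd + self.bd
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache = (win, relu_mask, pool_idx, cache1, mask1, cache2, mask2, h_drop, Tp)
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache):
        c = self.config
        win, relu_mask, pool_idx, cache1, mask1, cache2, mask2, h_drop, Tp = cache
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {}
        grads["Wd"] = h_drop.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dh = dlogits @ self.Wd.T
        if mask2 is not None:
            dh = dh * mask2

        H2len = cache2[0].shape[1]
        dH2 = np.zeros((B, H2len, c.lstm_units_2), dtype=self.dtype)
        dH2[:, -1] = dh
        dH1d, g2 = self.lstm2.backward(dH2, cache2)
        for k, v in g2.items():
            grads[f"lstm2.{k}"] = v
        if mask1 is not None:
            dH1d = dH1d * mask1
        dP, g1 = self.lstm1.backward(dH1d, cache1)
        for k, v in g1.items():
            grads[f"lstm1.{k}"] = v

        # un-pool: route gradient to the argmax positions
        dA4 = np.zeros(
            (B, Tp, c.pool_size, c.conv_filters), dtype=self.dtype
        )
        np.put_along_axis(dA4, pool_idx[:, :, None, :], dP[:, :, None, :], axis=2)
        Tc = relu_mask.shape[1]
        dA = np.zeros((B, Tc, c.conv_filters), dtype=self.dtype)
        dA[:, : Tp * c.pool_size] = dA4.reshape(B, Tp * c.pool_size, c.conv_filters)
        dZ = dA * relu_mask
        flat_win = win.reshape(-1, c.conv_kernel)
        flat_dZ = dZ.reshape(-1, c.conv_filters)
        grads["Wc"] = flat_win.T @ flat_dZ
        grads["bc"] = flat_dZ.sum(axis=0)
        return grads

    def loss_and_grads(self, X, y, rng: Optional[np.random.Generator] = None):
        """Mean sparse categorical cross-entropy and its gradients."""
        train = rng is not None
        probs, cache = self._forward(X, train=train, rng=rng)
        y = np.asarray(y, dtype=int)
        eps = np.finfo(self.dtype).tiny
        loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
        grads = self._backward(probs, y, cache)
        return loss, grads

    # ---- optimisation ----------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": {k: np.zeros_like(v) for k, v in self.parameters().items()},
                "v": {k: np.zeros_like(v) for k, v in self.parameters().items()},
            }
        st = self._adam_state
        st["t"] += 1
        b1, b2, eps = 0.9, 0.999, 1e-7
        t = st["t"]
        for name, p in self.parameters().items():
            g = grads[name].astype(self.dtype)
            st["m"][name] = b1 * st["m"][name] + (1 - b1) * g
            st["v"][name] = b2 * st["v"][name] + (1 - b2) * g * g
            mhat = st["m"][name] / (1 - b1**t)
            vhat = st["v"][name] / (1 - b2**t)
            p -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(self.dtype)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: Optional[int] = None,
        batch_size: Optional[int] = None,
        learning_rate: Optional[float] = None,
        rng_seed=None,
        validation: Optional[tuple[np.ndarray, np.ndarray]] = None,
        verbose: bool = False,
    ) -> dict[str, list[float]]:
        """Minibatch Adam training; returns the loss history."""
        c = self.config
        epochs = c.epochs if epochs is None else epochs
        batch_size = c.batch_size if batch_size is None else batch_size
        lr = c.learning_rate if learning_rate is None else learning_rate
        rng = np.random.default_rng(rng_seed)
        X = np.asarray(X, dtype=self.dtype)
        y = np.asarray(y, dtype=int)
        n = len(X)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, grads = self.loss_and_grads(X[idx], y[idx], rng=rng)
                self._adam_step(grads, lr)
                losses.append(loss)
            self.history["loss"].append(float(np.mean(losses)))
            if validation is not None:
                pv = self.predict_proba(validation[0])
                yv = np.asarray(validation[1], dtype=int)
                vl = float(-np.mean(np.log(pv[np.arange(len(yv)), yv] + 1e-12)))
                va = float(np.mean(pv.argmax(axis=1) == yv))
                self.history["val_loss"].append(vl)
                self.history["val_acc"].append(va)
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs} loss={self.history['loss'][-1]:.4f}"
                if validation is not None:
                    msg += (
                        f" val_loss={self.history['val_loss'][-1]:.4f}"
                        f" val_acc={self.history['val_acc'][-1]:.3f}"
                    )
                print(msg)
        return self.history

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities, shape (n, n_classes)."""
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        out = []
        for start in range(0, len(X), batch_size):
            probs, _ = self._forward(X[start : start + batch_size], train=False, rng=None)
            out.append(probs)
        return np.concatenate(out, axis=0)
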