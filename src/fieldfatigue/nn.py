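"""Minimal 1-D convolutional network for window-level fatigue regression.

Topology (fixed shape, configurable widths):

    Conv1D(c1, k) -> ReLU -> Conv1D(c2, k) -> ReLU -> MaxPool(2)
    -> Flatten -> Dense(h) -> ReLU -> Dense(1)

trained with the Adam optimizer on mean-absolute-error loss.  Implemented
directly on numpy (im2col convolutions, analytic backprop, verified against
numerical gradients in the test suite).  Hidden activations are ReLU and the
output is linear; kernel size defaults to 7 samples with "same" padding and
stride 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["CnnSpec", "CNN1DRegressor", "SWEEP_PRESET", "FINAL_PRESET", "DESK_PRESET"]


@dataclass(frozen=True)
class CnnSpec:
    """Hyperparameters of the window-regression CNN."""

    conv1_filters: int = 128
    conv2_filters: int = 128
    dense_width: int = 128
    kernel_size: int = 7
    pool: int = 2
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conv1_filters", "conv2_filters", "dense_width", "kernel_size",
                     "pool", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "CnnSpec":
        return replace(self, **kw)


#: initial sweep topology: wide layers, 50 epochs
SWEEP_PRESET = CnnSpec(conv1_filters=256, conv2_filters=256, dense_width=128, epochs=50)
#: optimized final topology
FINAL_PRESET = CnnSpec(conv1_filters=128, conv2_filters=128, dense_width=128, epochs=100)
#: reduced widths for desk-scale experiments on synthetic sessions
DESK_PRESET = CnnSpec(conv1_filters=16, conv2_filters=16, dense_width=32, epochs=100)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, W, F) -> (B, W, k, F) patches with zero 'same' padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
    # sliding over the time axis yields (B, W, F, k); put k before F
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2))


def _col2im(dpatches: np.ndarray, width: int, k: int) -> np.ndarray:
    """Fold (B, W, k, F) patch gradients back to the (B, W, F) input."""
    b, _, _, f = dpatches.shape
    p = k // 2
    dxp = np.zeros((b, width + 2 * p, f))
    for j in range(k):
        dxp[:, j: j + width, :] += dpatches[:, :, j, :]
    return dxp[:, p: p + width, :]


class CNN1DRegressor:
    """Maps (W, F) sensor windows to one regression value in label units."""

    def __init__(self, window: int, n_channels: int, spec: Optional[CnnSpec] = None):
        spec = spec or CnnSpec()
        if window % spec.pool != 0:
            raise ValueError("window width must be divisible by the pool size")
        self.window = int(window)
        self.n_channels = int(n_channels)
        self.spec = spec
        k, c1, c2, h = spec.kernel_size, spec.conv1_filters, spec.conv2_filters, spec.dense_width
        flat = (window // spec.pool) * c2
        rng = np.random.default_rng(spec.seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((k * n_channels, c1), k * n_channels),
            "b1": np.zeros(c1),
            "W2": he((k * c1, c2), k * c1),
            "b2": np.zeros(c2),
            "W3": he((flat, h), flat),
            "b3": np.zeros(h),
            "W4": rng.normal(0.0, np.sqrt(1.0 / h), size=(h, 1)),
            "b4": np.zeros(1),
        }
        self._adam_m = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_v = {n: np.zeros_like(p) for n, p in self.params.items()}
        self._adam_t = 0
        self.loss_trace: list[float] = []
        self.scaling = None  # optional ScalingParams attached by the trainer

    # ---------------------------------------------------------------- forward
    def _forward(self, x: np.ndarray, want_cache: bool):
        p = self.params
        k = self.spec.kernel_size
        b, w, _ = x.shape

        pat1 = _im2col(x, k).reshape(b * w, -1)
        z1 = (pat1 @ p["W1"] + p["b1"]).reshape(b, w, -1)
        a1 = np.maximum(z1, 0.0)

        pat2 = _im2col(a1, k).reshape(b * w, -1)
        z2 = (pat2 @ p["W2"] + p["b2"]).reshape(b, w, -1)
        a2 = np.maximum(z2, 0.0)

        pw = self.spec.pool
        a2r = a2.reshape(b, w // pw, pw, -1)
        arg = np.argmax(a2r, axis=2)
        pooled = np.take_along_axis(a2r, arg[:, :, None, :], axis=2)[:, :, 0, :]

        flat = pooled.reshape(b, -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        out = (a3 @ p["W4"] + p["b4"]).ravel()
        if not want_cache:
            return out, None
        cache = (x, pat1, z1, a1, pat2, z2, arg, flat, z3, a3)
        return out, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predictions for (D, W, F) windows, in input order."""
        x = np.asarray(x, float)
        if x.size == 0:
            return np.empty(0)
        if x.shape[1] != self.window or x.shape[2] != self.n_channels:
            raise ValueError(
                f"expected windows of shape ({self.window}, {self.n_channels}), "
                f"got {x.shape[1:]}"
            )
        # bounded batches keep the im2col workspace small
        outs = [self._forward(x[i: i + 1024], want_cache=False)[0]
                for i in range(0, x.shape[0], 1024)]
        return np.concatenate(outs)

    # --------------------------------------------------------------- backward
    def _backward(self, cache, dout: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        k, pw = self.spec.kernel_size, self.spec.pool
        x, pat1, z1, a1, pat2, z2, arg, flat, z3, a3 = cache
        b, w, _ = x.shape

        g = {}
        do = dout[:, None]                       # (B, 1)
        g["W4"] = a3.T @ do
        g["b4"] = do.sum(axis=0)
        da3 = do @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        g["W3"] = flat.T @ dz3
        g["b3"] = dz3.sum(axis=0)
        dflat = dz3 @ p["W3"].T

        c2 = p["b2"].size
        dpool = dflat.reshape(b, w // pw, c2)
        da2r = np.zeros((b, w // pw, pw, c2))
        np.put_along_axis(da2r, arg[:, :, None, :], dpool[:, :, None, :], axis=2)
        da2 = da2r.reshape(b, w, c2)
        dz2 = (da2 * (z2 > 0)).reshape(b * w, c2)
        g["W2"] = pat2.T @ dz2
        g["b2"] = dz2.sum(axis=0)
        dpat2 = (dz2 @ p["W2"].T).reshape(b, w, k, -1)
        da1 = _col2im(dpat2, w, k)

        c1 = p["b1"].size
        dz1 = (da1 * (z1 > 0)).reshape(b * w, c1)
        g["W1"] = pat1.T @ dz1
        g["b1"] = dz1.sum(axis=0)
        return g

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """MAE loss and parameter gradients for one batch."""
        out, cache = self._forward(x, want_cache=True)
        err = out - y
        loss = float(np.mean(np.abs(err)))
        dout = np.sign(err) / err.size
        return loss, self._backward(cache, dout)

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        lr = self.spec.learning_rate
        for n, p in self.params.items():
            g = grads[n].reshape(p.shape)
            self._adam_m[n] = b1 * self._adam_m[n] + (1 - b1) * g
            self._adam_v[n] = b2 * self._adam_v[n] + (1 - b2) * g * g
            mhat = self._adam_m[n] / (1 - b1**self._adam_t)
            vhat = self._adam_v[n] / (1 - b2**self._adam_t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -------------------------------------------------------------------- fit
    def fit(self, x: np.ndarray, y: np.ndarray) -> list[float]:
        """Train with Adam on MAE; returns the per-epoch training loss trace."""
        x = np.asarray(x, float)
        y = np.asarray(y, float).ravel()
        if x.shape[0] != y.shape[0] or x.shape[0] == 0:
            raise ValueError("training set empty or misaligned")
        rng = np.random.default_rng(self.spec.seed + 1)
        n, bs = x.shape[0], self.spec.batch_size
        for epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, bs):
                sel = order[i: i + bs]
                loss, grads = self.loss_and_grads(x[sel], y[sel])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}; "
                        "lower the learning rate or check the input scaling"
                    )
                self._adam_step(grads)
                losses.append(loss)
            self.loss_trace.append(float(np.mean(losses)))
        return self.loss_trace

    # ------------------------------------------------------------ persistence
    def save(self, path) -> None:
        meta = dict(window=self.window, n_channels=self.n_channels)
        spec = {f"spec_{k}": v for k, v in vars(self.spec).items()}
        np.savez(path, **self.params, **meta, **spec)

    @classmethod
    def load(cls, path) -> "CNN1DRegressor":
        with np.load(path) as z:
            spec = CnnSpec(**{
                k[5:]: (float(z[k]) if "rate" in k else int(z[k]))
                for k in z.files if k.startswith("spec_")
            })
            model = cls(int(z["window"]), int(z["n_channels"]), spec)
            for name in model.params:
                model.params[name] = z[name]
        return model
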