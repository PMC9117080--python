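"""A small 1-D convolutional network for the 7-component reduced features.

Architecture (fixed layer order): conv1d (F filters, kernel k, valid
padding) -> ReLU -> fully-connected 600 -> fully-connected 600 ->
fully-connected 3 -> softmax.  Trained with Adam on cross-entropy.

The input is only 7 values wide, so the whole network is a few hundred
thousand parameters and trains in seconds on a CPU; it is implemented
directly on NumPy arrays with explicit backpropagation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SmallCNN:
    """Three-class 1-D CNN classifier on short feature vectors.

    Parameters
    ----------
    n_filters, kernel : conv layer width (default 8 filters, kernel 3).
    hidden : width of the two fully-connected layers (default 600).
    lr, epochs, batch_size : Adam learning rate 1e-3, 200 epochs, batch 32.
    seed : seeds weight init and batch shuffling; fixed seed gives
        bit-identical training runs.
    """

    def __init__(
        self,
        n_filters: int = 8,
        kernel: int = 3,
        hidden: int = 600,
        n_classes: int = 3,
        lr: float = 1e-3,
        epochs: int = 200,
        batch_size: int = 32,
        seed: int = 0,
    ) -> None:
        self.n_filters = n_filters
        self.kernel = kernel
        self.hidden = hidden
        self.n_classes = n_classes
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.params: dict[str, np.ndarray] | None = None

    def _init_params(self, input_len: int, rng: np.random.Generator) -> None:
        conv_out = input_len - self.kernel + 1
        if conv_out < 1:
            raise ValueError(
                f"input length {input_len} shorter than kernel {self.kernel}"
            )
        self._conv_out = conv_out
        flat = conv_out * self.n_filters

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "Wc": he((self.n_filters, self.kernel), self.kernel),
            "bc": np.zeros(self.n_filters),
            "W1": he((flat, self.hidden), flat),
            "b1": np.zeros(self.hidden),
            "W2": he((self.hidden, self.hidden), self.hidden),
            "b2": np.zeros(self.hidden),
            "W3": he((self.hidden, self.n_classes), self.hidden),
            "b3": np.zeros(self.n_classes),
        }

    def _forward(self, X: np.ndarray):
        p = self.params
        Xw = sliding_window_view(X, self.kernel, axis=1)  # (n, T, k)
        conv = np.einsum("ntk,fk->ntf", Xw, p["Wc"]) + p["bc"]  # (n, T, F)
        relu = np.maximum(conv, 0.0)
        A = relu.reshape(X.shape[0], -1)  # (n, T*F)
        z1 = A @ p["W1"] + p["b1"]
        z2 = z1 @ p["W2"] + p["b2"]
        z3 = z2 @ p["W3"] + p["b3"]
        return Xw, conv, A, z1, z2, z3

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SmallCNN":
        """Train on rows of X with integer class indices y in 0..n_classes-1.

        Inputs are z-scored with training-set statistics (stored and
        reapplied at prediction time) so Adam sees comparably scaled
        channels regardless of the spread of the incoming components.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        X = (X - self._mu) / self._sd
        n = X.shape[0]
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        p = self.params

        Y = np.zeros((n, self.n_classes))
        Y[np.arange(n), y] = 1.0

        m = {k: np.zeros_like(v) for k, v in p.items()}
        v = {k: np.zeros_like(val) for k, val in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                Xb, Yb = X[idx], Y[idx]
                Xw, conv, A, z1, z2, z3 = self._forward(Xb)
                proba = _softmax(z3)
                nb = Xb.shape[0]

                dz3 = (proba - Yb) / nb
                grads = {
                    "W3": z2.T @ dz3,
                    "b3": dz3.sum(axis=0),
                }
                dz2 = dz3 @ p["W3"].T
                grads["W2"] = z1.T @ dz2
                grads["b2"] = dz2.sum(axis=0)
                dz1 = dz2 @ p["W2"].T
                grads["W1"] = A.T @ dz1
                grads["b1"] = dz1.sum(axis=0)
                dA = dz1 @ p["W1"].T
                drelu = dA.reshape(conv.shape) * (conv > 0)
                grads["Wc"] = np.einsum("ntf,ntk->fk", drelu, Xw)
                grads["bc"] = drelu.sum(axis=(0, 1))

                step += 1
                for k in p:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mhat = m[k] / (1 - beta1**step)
                    vhat = v[k] / (1 - beta2**step)
                    p[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        X = (np.asarray(X, dtype=np.float64) - self._mu) / self._sd
        *_, z3 = self._forward(X)
        return _softmax(z3)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)
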