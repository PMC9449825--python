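"""A compact 1-D convolutional classifier for raw sensor segments.

Architecture: three same-padded convolutional layers (128, 256 and 128
output channels; kernel sizes 8, 5, 3; stride 1; ReLU), global average
pooling over time, L2 normalization of the pooled embedding, and a
fully connected softmax head.  Training uses Adam on categorical
cross-entropy, batch size 32, for a fixed number of epochs (no early
stopping).  Implemented directly on numpy so it runs anywhere the rest
of the package runs; intended for desk-scale experiments rather than
GPU-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Conv1dClassifier"]

_EPS = 1e-8


def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    # (b, c, w) -> (b, c, w - k + 1, k)
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=2)


class _Conv1d:
    """Same-padded cross-correlation layer with stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))  # He initialization (ReLU follows)
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.pl = (k - 1) // 2
        self.pr = k - 1 - self.pl

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_pad = np.pad(x, ((0, 0), (0, 0), (self.pl, self.pr)))
        windows = _sliding(self._x_pad, self.k)
        return np.einsum("bctk,ock->bot", windows, self.w, optimize=True) + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        windows = _sliding(self._x_pad, self.k)
        self.dw = np.einsum("bot,bctk->ock", dy, windows, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        dy_pad = np.pad(dy, ((0, 0), (0, 0), (self.k - 1, self.k - 1)))
        dx_pad = np.einsum(
            "botk,ock->bct", _sliding(dy_pad, self.k), self.w[:, :, ::-1], optimize=True
        )
        w_orig = self._x_pad.shape[2] - self.pl - self.pr
        return dx_pad[:, :, self.pl : self.pl + w_orig]

    def params_grads(self):
        return [(self.w, self.dw), (self.b, self.db)]


@dataclass
class Conv1dClassifier:
    """Numpy 1-D CNN over segments shaped (n, width, channels)."""

    conv_channels: tuple[int, int, int] = (128, 256, 128)
    kernel_sizes: tuple[int, int, int] = (8, 5, 3)
    epochs: int = 100
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0
    loss_history: list = field(default_factory=list, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1dClassifier":
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("CNN expects segments of shape (n, width, channels)")
        self.classes_, y_idx = np.unique(np.asarray(y), return_inverse=True)
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.seed)

        c_in = X.shape[2]
        self._convs = []
        for c_out, k in zip(self.conv_channels, self.kernel_sizes):
            self._convs.append(_Conv1d(c_in, c_out, k, rng))
            c_in = c_out
        emb = self.conv_channels[-1]
        self._wf = rng.normal(0.0, np.sqrt(1.0 / emb), size=(n_classes, emb))
        self._bf = np.zeros(n_classes)

        params = [p for c in self._convs for p in (c.w, c.b)] + [self._wf, self._bf]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2 = 0.9, 0.999
        step = 0

        n = X.shape[0]
        self.loss_history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = np.moveaxis(X[idx], 1, 2)  # (b, channels, width)
                yb = y_idx[idx]
                loss, grads = self._loss_and_grads(xb, yb, n_classes)
                epoch_loss += loss * len(idx)
                step += 1
                lr_t = self.learning_rate * np.sqrt(1 - b2**step) / (1 - b1**step)
                for i, (p, g) in enumerate(grads):
                    m[i] = b1 * m[i] + (1 - b1) * g
                    v[i] = b2 * v[i] + (1 - b2) * g**2
                    p -= lr_t * m[i] / (np.sqrt(v[i]) + _EPS)
            self.loss_history.append(epoch_loss / n)
        return self

    def _forward(self, xb: np.ndarray, train: bool) -> np.ndarray:
        h = xb
        self._relu_masks = []
        for conv in self._convs:
            h = conv.forward(h)
            mask = h > 0
            h = h * mask
            if train:
                self._relu_masks.append(mask)
        g = h.mean(axis=2)  # global average pooling
        norm = np.linalg.norm(g, axis=1, keepdims=True) + _EPS
        z = g / norm
        if train:
            self._g, self._norm, self._z, self._width = g, norm, z, h.shape[2]
        return z @ self._wf.T + self._bf

    def _loss_and_grads(self, xb, yb, n_classes):
        logits = self._forward(xb, train=True)
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        bsz = len(yb)
        loss = -np.mean(np.log(probs[np.arange(bsz), yb] + _EPS))

        dlogits = probs.copy()
        dlogits[np.arange(bsz), yb] -= 1.0
        dlogits /= bsz
        dwf = dlogits.T @ self._z
        dbf = dlogits.sum(axis=0)
        dz = dlogits @ self._wf
        # back through L2 normalization
        dg = (dz - self._z * np.sum(self._z * dz, axis=1, keepdims=True)) / self._norm
        # back through GAP
        dh = np.repeat(dg[:, :, None], self._width, axis=2) / self._width
        grads = []
        for conv, mask in zip(reversed(self._convs), reversed(self._relu_masks)):
            dh = dh * mask
            dh = conv.backward(dh)
            grads = conv.params_grads() + grads
        grads = grads + [(self._wf, dwf), (self._bf, dbf)]
        return loss, grads

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, X.shape[0], 256):
            xb = np.moveaxis(X[start : start + 256], 1, 2)
            out.append(self._forward(xb, train=False))
        return np.concatenate(out, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if np.asarray(X).shape[0] == 0:
            return np.asarray(self.classes_)[:0]
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
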