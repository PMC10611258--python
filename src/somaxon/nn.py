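"""A small, deterministic convolutional network in pure numpy.

The tile classifier deliberately uses a compact CNN (4 conv blocks with
3x3 kernels, global average pooling, a linear 2-class head; ~20k
parameters) trained with Adam on softmax cross-entropy. Everything -
initialization, batch order, updates - is driven by explicit seeds, so
training twice with the same data and seed yields bit-identical weights.
That determinism is a core contract of the pipeline: with synthetic
studies the only reproducibility guarantee worth having is an exact one.

Implementation notes: convolutions use an im2col formulation so the inner
loops are BLAS matmuls; all tensors are float32; padding is 1 so conv
layers preserve spatial size and the three 2x2 max-pools reduce a 48x48
input to a 6x6 final activation grid (the grid Grad-CAM explains).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN"]


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col3(xp: np.ndarray) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (N, C*9, H*W) patch matrix."""
    N, C, Hp, Wp = xp.shape
    H, W = Hp - 2, Wp - 2
    cols = np.empty((N, C, 9, H, W), dtype=np.float32)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di:di + H, dj:dj + W]
            k += 1
    return cols.reshape(N, C * 9, H * W)


def _col2im3(dcols: np.ndarray, N: int, C: int, H: int, W: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3`; returns gradient w.r.t. unpadded input."""
    d = dcols.reshape(N, C, 9, H, W)
    dxp = np.zeros((N, C, H + 2, W + 2), dtype=np.float32)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + H, dj:dj + W] += d[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class _Conv3x3:
    """3x3 convolution, stride 1, zero padding 1."""

    def __init__(self, rng, c_in: int, c_out: int):
        self.W = _he_init(rng, (c_out, c_in * 9), fan_in=c_in * 9)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col3(xp)                        # (N, C*9, H*W)
        out = np.matmul(self.W, cols) + self.b[:, None]
        if keep:
            self._cache = (cols, (N, C, H, W))
        return out.reshape(N, -1, H, W)

    def backward(self, dout: np.ndarray):
        cols, (N, C, H, W) = self._cache
        d2 = dout.reshape(N, dout.shape[1], H * W)
        dW = np.einsum("nfx,ncx->fc", d2, cols, optimize=True)
        db = d2.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, d2)
        dx = _col2im3(dcols, N, C, H, W)
        self._cache = None
        return dx, dW, db


class _ReLU:
    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if keep:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2:
    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        N, C, H, W = x.shape
        xr = (x.reshape(N, C, H // 2, 2, W // 2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(N, C, H // 2, W // 2, 4))
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if keep:
            self._cache = (arg, (N, C, H, W))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, (N, C, H, W) = self._cache
        dxr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
        dx = (dxr.reshape(N, C, H // 2, W // 2, 2, 2)
                 .transpose(0, 1, 2, 4, 3, 5)
                 .reshape(N, C, H, W))
        self._cache = None
        return dx


class SmallCNN:
    """4-conv-block classifier: input (N, 1, S, S) -> logits (N, n_classes)."""

    def __init__(self, channels=(8, 16, 32, 32), input_side: int = 48,
                 n_classes: int = 2, seed: int = 0):
        if input_side % 8 != 0:
            raise ValueError("input_side must be divisible by 8 (three 2x2 pools)")
        rng = np.random.default_rng(seed)
        c0, c1, c2, c3 = channels
        self.channels = tuple(channels)
        self.input_side = int(input_side)
        self.n_classes = int(n_classes)
        self.conv = [
            _Conv3x3(rng, 1, c0),
            _Conv3x3(rng, c0, c1),
            _Conv3x3(rng, c1, c2),
            _Conv3x3(rng, c2, c3),
        ]
        self.relu = [_ReLU() for _ in range(4)]
        self.pool = [_MaxPool2() for _ in range(3)]
        self.Wd = _he_init(rng, (n_classes, c3), fan_in=c3)
        self.bd = np.zeros(n_classes, dtype=np.float32)
        self._adam = None

    # ------------------------------------------------------------------ fwd
    def _features(self, x: np.ndarray, keep: bool) -> np.ndarray:
        """Final conv activations (N, C, S/8, S/8), post-ReLU."""
        h = x
        for i in range(3):
            h = self.pool[i].forward(self.relu[i].forward(
                self.conv[i].forward(h, keep), keep), keep)
        return self.relu[3].forward(self.conv[3].forward(h, keep), keep)

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        return self._features(np.asarray(x, dtype=np.float32), keep=False)

    def forward(self, x: np.ndarray, keep: bool = False) -> np.ndarray:
        a = self._features(np.asarray(x, dtype=np.float32), keep)
        gap = a.mean(axis=(2, 3))
        if keep:
            self._a_shape = a.shape
            self._gap_cache = gap
        return gap @ self.Wd.T + self.bd

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def activation_gradient(self, class_idx: int, grid_shape: tuple) -> np.ndarray:
        """d logit_class / d final-conv-activation, shape (C, h, w).

        With global average pooling and a linear head the gradient is
        spatially uniform: W_head[class, c] / (h * w).
        """
        c, h, w = grid_shape
        g = np.broadcast_to(self.Wd[class_idx][:, None, None], (c, h, w))
        return (g / (h * w)).astype(np.float32)

    # ------------------------------------------------------------------ bwd
    def _backward(self, x, y, class_weights):
        """Weighted softmax cross-entropy loss + gradients for one batch."""
        n = len(y)
        logits = self.forward(x, keep=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        w = class_weights[y] if class_weights is not None else np.ones(n, np.float32)
        wsum = w.sum()
        loss = float(-(w * np.log(p[np.arange(n), y] + 1e-12)).sum() / wsum)
        dlogits = p.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits *= (w / wsum)[:, None]

        grads = {}
        # dense head
        gap = self._gap_cache
        grads["Wd"] = dlogits.T @ gap
        grads["bd"] = dlogits.sum(axis=0)
        dgap = dlogits @ self.Wd
        _, C, h, w = self._a_shape
        da = np.broadcast_to(dgap[:, :, None, None] / (h * w), self._a_shape).astype(np.float32)
        # conv stack in reverse
        d = self.relu[3].backward(da)
        d, grads["W3"], grads["b3"] = self.conv[3].backward(d)
        for i in (2, 1, 0):
            d = self.pool[i].backward(d)
            d = self.relu[i].backward(d)
            d, grads[f"W{i}"], grads[f"b{i}"] = self.conv[i].backward(d)
        return loss, grads

    # ------------------------------------------------------------------ fit
    def _params(self):
        items = []
        for i, c in enumerate(self.conv):
            items.append((f"W{i}", c, "W"))
            items.append((f"b{i}", c, "b"))
        items.append(("Wd", self, "Wd"))
        items.append(("bd", self, "bd"))
        return items

    def fit(self, x: np.ndarray, y: np.ndarray, *, epochs: int = 8,
            batch_size: int = 128, lr: float = 1e-3, seed: int = 0,
            class_weights: np.ndarray | None = None,
            augment: bool = False) -> list[float]:
        """Train in place; returns the per-epoch mean losses."""
        rng = np.random.default_rng(seed)
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        if class_weights is not None:
            class_weights = np.asarray(class_weights, dtype=np.float32)
        m = {k: np.zeros_like(getattr(o, a)) for k, o, a in self._params()}
        v = {k: np.zeros_like(getattr(o, a)) for k, o, a in self._params()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        for _ in range(epochs):
            perm = rng.permutation(len(y))
            losses = []
            for i in range(0, len(y), batch_size):
                idx = perm[i:i + batch_size]
                xb, yb = x[idx], y[idx]
                if augment:
                    xb = _augment_batch(xb, rng)
                loss, grads = self._backward(xb, yb, class_weights)
                losses.append(loss)
                step += 1
                for k, obj, attr in self._params():
                    g = grads[k].astype(np.float32)
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v[k] = b2 * v[k] + (1 - b2) * g * g
                    mh = m[k] / (1 - b1 ** step)
                    vh = v[k] / (1 - b2 ** step)
                    setattr(obj, attr,
                            getattr(obj, attr) - lr * mh / (np.sqrt(vh) + eps))
            history.append(float(np.mean(losses)))
        return history

    # ------------------------------------------------------------ serialize
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: getattr(o, a).copy() for k, o, a in self._params()}
        out["_channels"] = np.array(self.channels)
        out["_input_side"] = np.array([self.input_side])
        out["_n_classes"] = np.array([self.n_classes])
        return out

    @classmethod
    def from_state_dict(cls, state: dict[str, np.ndarray]) -> "SmallCNN":
        net = cls(channels=tuple(int(c) for c in state["_channels"]),
                  input_side=int(state["_input_side"][0]),
                  n_classes=int(state["_n_classes"][0]), seed=0)
        for k, o, a in net._params():
            setattr(o, a, np.asarray(state[k], dtype=np.float32).copy())
        return net


def _augment_batch(xb: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random 90-degree rotations and flips, per sample."""
    out = xb.copy()
    ks = rng.integers(0, 4, size=len(xb))
    flips = rng.integers(0, 2, size=len(xb))
    for i in range(len(xb)):
        t = np.rot90(out[i, 0], k=int(ks[i]))
        if flips[i]:
            t = t[:, ::-1]
        out[i, 0] = t
    return out
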