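"""Minimal numpy convolutional-network core used by the trainer.

Implements exactly what the segmentation demonstrator needs: same-padding
2-D convolution, ReLU, 2x2 max pooling, nearest 2x upsampling, channel
concatenation, a sigmoid/binary-cross-entropy head and an RMSprop
optimizer, with hand-written backpropagation.  Tensors are NHWC float32;
convolution is computed as one GEMM per kernel tap over the shifted input,
which avoids materializing k^2-expanded im2col buffers and keeps the
small-channel networks used here compute- rather than copy-bound.  All
weight initialization is seeded.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Conv2D:
    """Same-padding (zero) convolution with bias; He-normal seeded init.

    Weights are stored as (k, k, c_in, c_out); tap (i, j) acts on the input
    shifted by (i - k//2, j - k//2).
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None  # padded input kept for backward

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
            xp[:, p : p + h, p : p + w] = x
        else:
            xp = x
        out = np.empty((n * h * w, self.c_out), dtype=F32)
        out[:] = self.b
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i : i + h, j : j + w]).reshape(-1, c)
                out += xs @ self.w[i, j]
        if train:
            self._xp = xp
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, _ = dout.shape
        k, p, c = self.k, self.k // 2, self.c_in
        dflat = dout.reshape(-1, self.c_out)
        self.gb += dflat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = np.ascontiguousarray(xp[:, i : i + h, j : j + w]).reshape(-1, c)
                self.gw[i, j] += xs.T @ dflat
                dxp[:, i : i + h, j : j + w] += (dflat @ self.w[i, j].T).reshape(n, h, w, c)
        self._xp = None
        return dxp[:, p : p + h, p : p + w] if p else dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout):
        d = dout * self._mask
        self._mask = None
        return d


class MaxPool2:
    """2x2, stride 2; gradient routed to the first maximum of each window."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        flat = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w // 2, c, 4
        )
        if train:
            self._idx = flat.argmax(axis=-1)
            self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._shape
        dflat = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = (
            dflat.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )
        self._idx = self._shape = None
        return dx


class UpsampleNearest2:
    def forward(self, x, train=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    # max(z,0) - z*y + log(1 + exp(-|z|)) is stable for both signs of z
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    grad = ((p - y) / z.size).astype(F32)
    return float(loss.mean()), grad


class RMSprop:
    """Root-mean-squared-propagation: cache = rho*cache + (1-rho)*g^2."""

    def __init__(self, lr: float = 1e-4, rho: float = 0.9, eps: float = 1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, np.ndarray] = {}

    def step(self, params) -> None:
        for w, g in params:
            c = self._cache.setdefault(id(w), np.zeros_like(w))
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            w -= (self.lr * g / (np.sqrt(c) + self.eps)).astype(w.dtype)
            g[...] = 0.0


class UNet:
    """Symmetric encoder-decoder with skip connections and a sigmoid head.

    ``depth`` pooling stages, ``base`` filters at full resolution doubling
    per stage, two k x k convolutions per stage, nearest-neighbor upsampling
    followed by a k x k convolution on the decoder path, skip concatenation,
    and a 1x1 output convolution producing one per-pixel confidence channel.
    """

    def __init__(self, input_size: int, depth: int, base: int, k: int, seed: int = 0):
        if input_size % (2**depth) != 0:
            raise ValueError(f"input size {input_size} not divisible by 2^{depth}")
        self.input_size, self.depth, self.base, self.k = input_size, depth, base, k
        rng = np.random.default_rng(seed)
        self.enc: list[tuple] = []
        c_in = 1
        for d in range(depth):
            c = base * (2**d)
            self.enc.append((Conv2D(c_in, c, k, rng), ReLU(), Conv2D(c, c, k, rng), ReLU()))
            c_in = c
        cb = base * (2**depth)
        self.bottleneck = (Conv2D(c_in, cb, k, rng), ReLU(), Conv2D(cb, cb, k, rng), ReLU())
        self.dec: list[tuple] = []
        c_in = cb
        for d in reversed(range(depth)):
            c = base * (2**d)
            self.dec.append(
                (
                    UpsampleNearest2(),
                    Conv2D(c_in, c, k, rng),  # after upsampling
                    ReLU(),
                    Conv2D(2 * c, c, k, rng),  # after skip concatenation
                    ReLU(),
                    Conv2D(c, c, k, rng),
                    ReLU(),
                )
            )
            c_in = c
        self.head = Conv2D(c_in, 1, 1, rng)
        self.pools = [MaxPool2() for _ in range(depth)]
        self._skip_channels = [base * (2**d) for d in range(depth)]

    # -- parameter plumbing -------------------------------------------------
    def _convs(self) -> list[Conv2D]:
        convs = []
        for blk in self.enc:
            convs += [blk[0], blk[2]]
        convs += [self.bottleneck[0], self.bottleneck[2]]
        for blk in self.dec:
            convs += [blk[1], blk[3], blk[5]]
        convs.append(self.head)
        return convs

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self._convs())

    def params(self):
        out = []
        for c in self._convs():
            out += c.params()
        return out

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for c in self._convs():
            out += [c.w.copy(), c.b.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for c in self._convs():
            c.w[...] = next(it)
            c.b[...] = next(it)

    # -- forward / backward -------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, S, S, 1) float32 -> logits (N, S, S, 1)."""
        skips = []
        h = x.astype(F32)
        for blk, pool in zip(self.enc, self.pools):
            c1, r1, c2, r2 = blk
            h = r2.forward(c2.forward(r1.forward(c1.forward(h, train), train), train), train)
            skips.append(h)
            h = pool.forward(h, train)
        c1, r1, c2, r2 = self.bottleneck
        h = r2.forward(c2.forward(r1.forward(c1.forward(h, train), train), train), train)
        for i, blk in enumerate(self.dec):
            up, cu, ru, ca, ra, cb_, rb = blk
            h = ru.forward(cu.forward(up.forward(h, train), train), train)
            skip = skips[self.depth - 1 - i]
            h = np.concatenate([skip, h], axis=3)
            h = rb.forward(cb_.forward(ra.forward(ca.forward(h, train), train), train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = [None] * self.depth
        for i in reversed(range(len(self.dec))):
            up, cu, ru, ca, ra, cb_, rb = self.dec[i]
            d = ca.backward(ra.backward(cb_.backward(rb.backward(d))))
            c = self._skip_channels[self.depth - 1 - i]
            dskips[self.depth - 1 - i] = d[..., :c]
            d = up.backward(cu.backward(ru.backward(d[..., c:])))
        c1, r1, c2, r2 = self.bottleneck
        d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        for j in reversed(range(self.depth)):
            d = self.pools[j].backward(d)
            d = d + dskips[j]
            c1, r1, c2, r2 = self.enc[j]
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, train=False))

    def train_step(self, x: np.ndarray, y: np.ndarray, opt: RMSprop) -> float:
        logits = self.forward_logits(x, train=True)
        loss, dl = bce_with_logits(logits, y)
        self.backward(dl)
        opt.step(self.params())
        return loss
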