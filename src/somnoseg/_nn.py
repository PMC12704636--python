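"""Minimal 1-D convolutional network toolkit (numpy, manual backprop).

Implements exactly what the sleep/wake segmenter needs: same-padded
1-D convolutions via im2col, ELU, pair max-pooling, nearest-neighbour
upsampling, skip concatenation, a segment head (average pooling over a
fixed number of samples followed by a pointwise softmax classifier),
class-weighted cross-entropy, and Adam. Gradients are verified against
finite differences in the test suite.

Arrays are ``(batch, channels, samples)``; float32 by default with a
float64 mode for gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, N) -> (B*N_out, C*k) patch matrix with valid windows."""
    B, C, _ = x.shape
    v = sliding_window_view(x, k, axis=2)          # (B, C, N_out, k)
    v = v.transpose(0, 2, 1, 3)                    # (B, N_out, C, k)
    n_out = v.shape[1]
    return np.ascontiguousarray(v).reshape(B * n_out, C * k)


class Conv1d:
    """Same-padded 1-D convolution, odd kernel, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_in * k, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col = None
        self._shape = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, N = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        col = _im2col(xp, self.k)                   # (B*N, C*k)
        y = col @ self.W + self.b                   # (B*N, c_out)
        if train:
            self._col, self._shape = col, (B, C, N)
        return y.reshape(B, N, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, N = self._shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(B * N, self.c_out)
        self.dW += self._col.T @ dyf
        self.db += dyf.sum(axis=0)
        # dx = "full" correlation of dy with the flipped, transposed kernel
        W4 = self.W.reshape(self.c_in, self.k, self.c_out)
        W_hat = W4[:, ::-1, :].transpose(2, 1, 0).reshape(
            self.c_out * self.k, self.c_in)
        p = self.k // 2
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p)))
        col_dy = _im2col(dyp, self.k)               # (B*N, c_out*k)
        dx = (col_dy @ W_hat).reshape(B, N, self.c_in).transpose(0, 2, 1)
        self._col = None
        return np.ascontiguousarray(dx)


class Elu:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        y = np.where(mask, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        if train:
            self._y, self._mask = y, mask
        return y.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._mask, 1.0, self._y + self.alpha).astype(dy.dtype)


class MaxPool2:
    """Non-overlapping max pooling over sample pairs (N must be even)."""

    params: list = []

    def __init__(self):
        self._argmax = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, N = x.shape
        pairs = x.reshape(B, C, N // 2, 2)
        arg = pairs.argmax(axis=3)
        if train:
            self._argmax = arg
        return pairs.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, M = dy.shape
        dx = np.zeros((B, C, M, 2), dtype=dy.dtype)
        np.put_along_axis(dx, self._argmax[..., None], dy[..., None], axis=3)
        return dx.reshape(B, C, 2 * M)


class Upsample2:
    """Nearest-neighbour x2 upsampling along the sample axis."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, N = dy.shape
        return dy.reshape(B, C, N // 2, 2).sum(axis=3)


class AvgPoolSegments:
    """Average over fixed-size non-overlapping segments (the epoch head)."""

    params: list = []

    def __init__(self, m: int):
        self.m = m

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, N = x.shape
        return x.reshape(B, C, N // self.m, self.m).mean(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy / self.m, self.m, axis=2)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray):
    """Mean class-weighted CE over all cells.

    ``logits`` is (B, n_classes, M); ``labels`` (B, M) integer classes.
    Returns (loss, dlogits) with the gradient already normalized by the
    total weight so batch scale does not alter the step size.
    """
    p = softmax(logits.astype(np.float64), axis=1)
    B, K, M = p.shape
    w = class_weights[labels]                       # (B, M)
    idx_b = np.arange(B)[:, None]
    idx_m = np.arange(M)[None, :]
    p_true = p[idx_b, labels, idx_m]
    total_w = w.sum()
    loss = float(-(w * np.log(np.maximum(p_true, 1e-12))).sum() / total_w)
    dlogits = p.copy()
    dlogits[idx_b, labels, idx_m] -= 1.0
    dlogits *= (w / total_w)[:, None, :]
    return loss, dlogits.astype(logits.dtype)


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0


class UNet1d:
    """Encoder-decoder dense segmenter over the 128 Hz sample axis.

    One convolution + ELU per level; max-pool x2 between encoder
    levels; nearest-neighbour upsampling and skip concatenation in the
    decoder; filter counts grow by ~sqrt(2) per level. The head
    average-pools the full-resolution feature map over
    ``segment_samples`` and applies a pointwise 2-class classifier.
    """

    def __init__(self, in_channels: int, depth: int, base_filters: int,
                 kernel: int, segment_samples: int, n_classes: int = 2,
                 seed: int = 0, dtype=np.float32):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.in_channels = in_channels
        self.depth = depth
        self.base_filters = base_filters
        self.kernel = kernel
        self.segment_samples = segment_samples
        self.n_classes = n_classes
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = [max(1, int(round(base_filters * np.sqrt(2.0) ** i)))
             for i in range(depth + 1)]
        self.filters = f
        self.enc = []
        c_prev = in_channels
        for i in range(depth):
            self.enc.append((Conv1d(c_prev, f[i], kernel, rng, dtype), Elu(),
                             MaxPool2()))
            c_prev = f[i]
        self.bottom = (Conv1d(c_prev, f[depth], kernel, rng, dtype), Elu())
        self.dec = []
        c_prev = f[depth]
        for i in reversed(range(depth)):
            self.dec.append((Upsample2(),
                             Conv1d(c_prev + f[i], f[i], kernel, rng, dtype),
                             Elu()))
            c_prev = f[i]
        self.head_pool = AvgPoolSegments(segment_samples)
        self.head_conv = Conv1d(c_prev, n_classes, 1, rng, dtype)

    @property
    def params(self):
        ps = []
        for conv, _elu, _pool in self.enc:
            ps += conv.params
        ps += self.bottom[0].params
        for _up, conv, _elu in self.dec:
            ps += conv.params
        ps += self.head_conv.params
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (batch, {self.in_channels}, samples), got {x.shape}"
            )
        n = x.shape[2]
        if n % (2 ** self.depth) != 0:
            raise ValueError(f"sample count {n} not divisible by 2^{self.depth}")
        if n % self.segment_samples != 0:
            raise ValueError(
                f"sample count {n} not divisible by segment size "
                f"{self.segment_samples}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x)
        x = x.astype(self.dtype, copy=False)
        skips = []
        for conv, elu, pool in self.enc:
            h = elu.forward(conv.forward(x, train), train)
            skips.append(h)
            x = pool.forward(h, train)
        x = self.bottom[1].forward(self.bottom[0].forward(x, train), train)
        self._skip_channels = []
        for (up, conv, elu), skip in zip(self.dec, reversed(skips)):
            u = up.forward(x, train)
            x = np.concatenate([u, skip], axis=1)
            self._skip_channels.append(u.shape[1])
            x = elu.forward(conv.forward(x, train), train)
        pooled = self.head_pool.forward(x, train)
        return self.head_conv.forward(pooled, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head_pool.backward(self.head_conv.backward(dlogits))
        dskips = []
        for (up, conv, elu), c_up in zip(reversed(self.dec),
                                         reversed(self._skip_channels)):
            d = conv.backward(elu.backward(d))
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        d = self.bottom[0].backward(self.bottom[1].backward(d))
        for (conv, elu, pool), d_skip in zip(reversed(self.enc), reversed(dskips)):
            d = pool.backward(d) + d_skip
            d = conv.backward(elu.backward(d))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities, (B, n_classes, M), inference mode."""
        return softmax(self.forward(x, train=False).astype(np.float64), axis=1)

    # -- checkpointing ----------------------------------------------------
    def state_arrays(self) -> dict:
        return {f"p{i:03d}": p for i, (p, _g) in enumerate(self.params)}

    def load_state_arrays(self, arrays: dict) -> None:
        for i, (p, _g) in enumerate(self.params):
            src = arrays[f"p{i:03d}"]
            if src.shape != p.shape:
                raise ValueError("checkpoint shape mismatch")
            p[...] = src.astype(p.dtype)

    def clone(self) -> "UNet1d":
        other = UNet1d(self.in_channels, self.depth, self.base_filters,
                       self.kernel, self.segment_samples, self.n_classes,
                       self.seed, self.dtype)
        other.load_state_arrays(self.state_arrays())
        return other

    def checksum(self) -> float:
        return float(sum(np.abs(p).sum() for p, _ in self.params))
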