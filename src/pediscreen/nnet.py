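"""Minimal CPU neural-network engine for the spectral ECG classifier.

Implements exactly the pieces the classifier needs — 3x3 same-padding
convolutions (im2col + BLAS matmul), non-overlapping max pooling, dense
layers, ReLU, inverted dropout, a numerically stable sigmoid/binary
cross-entropy head, and Adam — with explicit forward/backward passes.
Keeping the engine explicit gives deterministic single-threaded training
and direct access to intermediate feature maps and their gradients, which
the grad-CAM saliency stage requires.

All arithmetic is float32; every source of randomness is an explicit
``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

F32 = np.float32


class Layer:
    """Base class: stateless unless it carries ``params``/``grads``."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 convolution, stride 1, same padding, NCHW layout."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        std = np.sqrt(2.0 / (in_ch * 9))
        self.params = {
            "W": rng.normal(0.0, std, (out_ch, in_ch, 3, 3)).astype(F32),
            "b": np.zeros(out_ch, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # win: (N, C, H, W, 3, 3) -> (C*9, N*H*W)
        return np.ascontiguousarray(
            win.transpose(1, 4, 5, 0, 2, 3).reshape(c * 9, n * h * w))

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        cols = self._im2col(x)
        Wm = self.params["W"].reshape(self.out_ch, -1)
        y = Wm @ cols + self.params["b"][:, None]
        if train:
            self._cols, self._x_shape = cols, x.shape
        return np.ascontiguousarray(
            y.reshape(self.out_ch, n, h, w).transpose(1, 0, 2, 3))

    def backward(self, dy):
        n, _, h, w = dy.shape
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(self.out_ch, -1)
        self.grads["W"][...] = (dyf @ self._cols.T).reshape(self.params["W"].shape)
        self.grads["b"][...] = dyf.sum(axis=1)
        dcols = self.params["W"].reshape(self.out_ch, -1).T @ dyf
        c = self.in_ch
        dcols = dcols.reshape(c, 3, 3, n, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=F32)
        for ky in range(3):
            for kx in range(3):
                dxp[:, :, ky:ky + h, kx:kx + w] += dcols[:, ky, kx].transpose(1, 0, 2, 3)
        self._cols = None
        return dxp[:, :, 1:h + 1, 1:w + 1]


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self.out = np.maximum(x, 0)
        return self.out

    def backward(self, dy):
        self.grad_out = dy  # kept for grad-CAM readout
        return dy * (self.out > 0)


class MaxPool2D(Layer):
    """Non-overlapping pooling; trailing rows/cols that do not fill a full
    window are cropped (e.g. 25 -> 12 under a 1x2 pool)."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        h2, w2 = h // self.ph, w // self.pw
        xr = x[:, :, :h2 * self.ph, :w2 * self.pw].reshape(
            n, c, h2, self.ph, w2, self.pw)
        out = xr.max(axis=(3, 5))
        if train:
            self._xr, self._out, self._xshape = xr, out, x.shape
        return out

    def backward(self, dy):
        n, c, h, w = self._xshape
        h2, w2 = h // self.ph, w // self.pw
        mask = self._xr == self._out[:, :, :, None, :, None]
        counts = mask.sum(axis=(3, 5), keepdims=True)
        dxr = mask * (dy[:, :, :, None, :, None] / counts)
        dx = np.zeros((n, c, h, w), dtype=F32)
        dx[:, :, :h2 * self.ph, :w2 * self.pw] = dxr.reshape(
            n, c, h2 * self.ph, w2 * self.pw)
        self._xr = self._out = None
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.params = {
            "W": rng.normal(0.0, std, (d_in, d_out)).astype(F32),
            "b": np.zeros(d_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, train=False, rng=None):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"][...] = self._x.T @ dy
        self.grads["b"][...] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    return float(loss.mean()), ((p - y) / len(y)).astype(F32)


class Adam:
    def __init__(self, layers: Sequence[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= (self.lr * (m[k] / b1t) /
                      (np.sqrt(v[k] / b2t) + self.eps)).astype(F32)


class SpectralConvNet:
    """Two-branch VGG-style network on the 2 x 12 x F spectral tensor.

    The amplitude and phase channels enter private two-convolution stems,
    are fused by channel concatenation, pass a trunk of 14 convolutions in
    five blocks with max pooling at block boundaries (frequency axis at
    every boundary, lead axis at the last two), and finish in three dense
    layers (the age/sex vector is concatenated before the first). With
    3 + 14 + 3 + 1-sigmoid counting weight layers as 2 stem convs per
    branch (4) + 14 trunk convs + 3 dense = 21 weight layers.

    ``conv_index`` for grad-CAM counts the amplitude stem (1-2) then the
    trunk (3-16).
    """

    def __init__(self, stem_width: int = 32, block_widths: Sequence[int] = (64, 128, 256, 512, 512),
                 block_sizes: Sequence[int] = (2, 3, 3, 3, 3),
                 dense_widths: Sequence[int] = (128, 32),
                 dropout: float = 0.2, input_shape: tuple[int, int] = (12, 400),
                 meta_dim: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = dict(stem_width=stem_width, block_widths=tuple(block_widths),
                        block_sizes=tuple(block_sizes), dense_widths=tuple(dense_widths),
                        dropout=dropout, input_shape=tuple(input_shape),
                        meta_dim=meta_dim)
        sw = stem_width
        self.amp_stem = [Conv2D(1, sw, rng), ReLU(), Conv2D(sw, sw, rng), ReLU()]
        self.phase_stem = [Conv2D(1, sw, rng), ReLU(), Conv2D(sw, sw, rng), ReLU()]

        h, w = input_shape
        self.trunk: list[Layer] = [MaxPool2D(1, 2)]
        w //= 2
        c_in = 2 * sw
        pools = [(1, 2), (1, 2), (1, 2), (2, 2), (2, 2)]
        for bi, (width, size) in enumerate(zip(block_widths, block_sizes)):
            for _ in range(size):
                self.trunk += [Conv2D(c_in, width, rng), ReLU()]
                c_in = width
            ph, pw = pools[bi]
            self.trunk.append(MaxPool2D(ph, pw))
            h, w = h // ph, w // pw
        self.feature_shape = (c_in, h, w)

        d_in = c_in * h * w + meta_dim
        self.head: list[Layer] = []
        for dw in dense_widths:
            self.head += [Dense(d_in, dw, rng), ReLU(), Dropout(dropout)]
            d_in = dw
        self.head.append(Dense(d_in, 1, rng))

        # grad-CAM indexing: amplitude stem ReLUs then trunk ReLUs
        self.conv_relus: list[tuple[Conv2D, ReLU]] = [
            (self.amp_stem[0], self.amp_stem[1]), (self.amp_stem[2], self.amp_stem[3])]
        conv = None
        for layer in self.trunk:
            if isinstance(layer, Conv2D):
                conv = layer
            elif isinstance(layer, ReLU) and conv is not None:
                self.conv_relus.append((conv, layer))
                conv = None

    # -- weight bookkeeping ------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return self.amp_stem + self.phase_stem + self.trunk + self.head

    @property
    def n_conv_layers(self) -> int:
        return len(self.conv_relus)

    @property
    def n_weight_layers(self) -> int:
        return sum(1 for l in self.layers if l.params)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for l in self.layers for p in l.params.values()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers:
            for k in l.params:
                l.params[k] = next(it).copy()

    # -- forward / backward ------------------------------------------------
    def forward(self, amp: np.ndarray, phase: np.ndarray, meta: np.ndarray,
                train: bool = False, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        a = np.ascontiguousarray(amp[:, None, :, :], dtype=F32)
        p = np.ascontiguousarray(phase[:, None, :, :], dtype=F32)
        for layer in self.amp_stem:
            a = layer.forward(a, train, rng)
        for layer in self.phase_stem:
            p = layer.forward(p, train, rng)
        x = np.concatenate([a, p], axis=1)
        self._stem_width = a.shape[1]
        for layer in self.trunk:
            x = layer.forward(x, train, rng)
        self._flat_shape = x.shape
        f = x.reshape(x.shape[0], -1)
        z = np.concatenate([f, meta.astype(F32)], axis=1)
        self._n_features = f.shape[1]
        for layer in self.head:
            z = layer.forward(z, train, rng)
        return z[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        dz = dlogit[:, None].astype(F32)
        for layer in reversed(self.head):
            dz = layer.backward(dz)
        df = dz[:, :self._n_features]
        dx = df.reshape(self._flat_shape)
        for layer in reversed(self.trunk):
            dx = layer.backward(dx)
        sw = self._stem_width
        da, dp = dx[:, :sw], dx[:, sw:]
        for layer in reversed(self.amp_stem):
            da = layer.backward(da)
        for layer in reversed(self.phase_stem):
            dp = layer.backward(dp)

    def predict_proba(self, amp, phase, meta, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(amp), batch_size):
            z = self.forward(amp[i:i + batch_size], phase[i:i + batch_size],
                             meta[i:i + batch_size], train=False)
            out.append(sigmoid(z))
        return np.concatenate(out)

    def conv_activation_and_grad(self, conv_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Post-ReLU feature maps of conv ``conv_index`` (1-based) and the
        gradient of the last backpropagated scalar w.r.t. them."""
        if not (1 <= conv_index <= len(self.conv_relus)):
            raise ValueError(
                f"conv_index {conv_index} outside 1..{len(self.conv_relus)}")
        relu = self.conv_relus[conv_index - 1][1]
        return relu.out, relu.grad_out
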