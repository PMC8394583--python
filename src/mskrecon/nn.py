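"""Minimal convolutional building blocks with explicit forward/backward passes.

The unrolled reconstruction needs only a small hierarchical encoder-decoder
regularizer, so rather than depending on a deep-learning framework the few
required layers (3x3 same-padding convolution, ReLU, 2x2 average pooling,
nearest-neighbor upsampling) are implemented directly in NumPy with
hand-derived gradients, plus an Adam optimizer.  Layers are functional: each
``forward`` returns ``(output, cache)`` and ``backward(cache, grad_out)``
returns the input gradient, accumulating parameter gradients on the layer.

Arrays are channel-first ``(C, H, W)``; weights are float64 by default
and float32 when built for single-precision training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ConvRegularizer", "Adam", "relu", "relu_bwd",
           "avgpool2", "avgpool2_bwd", "upsample2", "upsample2_bwd"]


class Conv2d:
    """3x3 convolution, stride 1, zero same-padding, with bias.

    ``zero_init=True`` starts weights and bias at exactly zero (used for the
    regularizer's output layer so an untrained network is the identity
    residual, i.e. contributes nothing).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 zero_init: bool = False, dtype=np.float64):
        self.c_in, self.c_out = c_in, c_out
        if zero_init:
            self.W = np.zeros((c_out, c_in, 3, 3), dtype=dtype)
        else:
            fan_in = c_in * 9
            self.W = (rng.standard_normal((c_out, c_in, 3, 3))
                      * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray):
        c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        y = np.empty((self.c_out, h, w), dtype=np.result_type(self.W, x))
        y[:] = self.b[:, None, None]
        # one (c_out, c_in) matmul per kernel offset; no im2col copies
        for di in range(3):
            for dj in range(3):
                y += np.tensordot(
                    self.W[:, :, di, dj], xp[:, di : di + h, dj : dj + w], axes=1
                )
        return y, (xp, (c, h, w))

    def backward(self, cache, dy: np.ndarray) -> np.ndarray:
        xp, (c, h, w) = cache
        dy_flat = dy.reshape(self.c_out, h * w)
        self.gb += dy_flat.sum(axis=1)
        dxp = np.zeros((c, h + 2, w + 2), dtype=np.result_type(self.W, dy))
        for di in range(3):
            for dj in range(3):
                sl = xp[:, di : di + h, dj : dj + w].reshape(c, h * w)
                self.gW[:, :, di, dj] += dy_flat @ sl.T
                dxp[:, di : di + h, dj : dj + w] += np.tensordot(
                    self.W[:, :, di, dj].T, dy, axes=1
                )
        return dxp[:, 1 : 1 + h, 1 : 1 + w]

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


def relu(x):
    m = x > 0
    return x * m, m


def relu_bwd(mask, dy):
    return dy * mask


def avgpool2(x):
    """2x2 mean pooling; odd trailing row/column is cropped."""
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : 2 * h2, : 2 * w2]
    y = xc.reshape(c, h2, 2, w2, 2).mean(axis=(2, 4))
    return y, (c, h, w)


def avgpool2_bwd(cache, dy):
    c, h, w = cache
    dx = np.zeros((c, h, w), dtype=dy.dtype)
    up = np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0
    dx[:, : up.shape[1], : up.shape[2]] = up
    return dx


def upsample2(x):
    y = np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)
    return y, x.shape


def upsample2_bwd(cache, dy):
    c, h, w = cache
    return dy[:, : 2 * h, : 2 * w].reshape(c, h, 2, w, 2).sum(axis=(2, 4))


class ConvRegularizer:
    """Small hierarchical encoder-decoder acting on 2-channel (real/imag)
    images, with additive skip connections between matching resolutions.

    ``n_levels`` resolutions; channel count doubles per level down.  The
    output convolution is zero-initialized so a freshly built regularizer
    returns exactly zero (the unrolled chain then reduces to plain
    data-consistency iterations).
    """

    def __init__(self, n_levels: int = 2, base_channels: int = 8,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng(0)
        if n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        self.n_levels = n_levels
        c = base_channels
        self.conv_in = Conv2d(2, c, rng, dtype=dtype)
        self.down = [
            Conv2d(c * 2**l, c * 2 ** (l + 1), rng, dtype=dtype)
            for l in range(n_levels - 1)
        ]
        self.up = [
            Conv2d(c * 2 ** (l + 1), c * 2**l, rng, dtype=dtype)
            for l in range(n_levels - 1)
        ]
        self.conv_out = Conv2d(c, 2, rng, zero_init=True, dtype=dtype)

    def forward(self, x: np.ndarray):
        e0, cin_cache = self.conv_in.forward(x)
        a0, m0 = relu(e0)
        enc = [a0]
        caches = {"cin": cin_cache, "m0": m0, "down": [], "up": []}
        feat = a0
        for conv in self.down:
            p, pc = avgpool2(feat)
            z, cc = conv.forward(p)
            feat, m = relu(z)
            enc.append(feat)
            caches["down"].append((pc, cc, m))
        for l in reversed(range(self.n_levels - 1)):
            u, uc = upsample2(feat)
            z, cc = self.up[l].forward(u)
            a, m = relu(z)
            feat = a + enc[l]
            caches["up"].append((uc, cc, m, l))
        out, cout_cache = self.conv_out.forward(feat)
        caches["cout"] = cout_cache
        return out, caches

    def backward(self, caches, dy: np.ndarray) -> np.ndarray:
        L = self.n_levels
        denc = [None] * L  # gradient w.r.t. each encoder activation enc[l]
        dfeat = self.conv_out.backward(caches["cout"], dy)
        # unwind the decoder: feat_l = relu(up[l](upsample(feat_{l+1}))) + enc[l]
        for uc, cc, m, l in reversed(caches["up"]):
            denc[l] = dfeat if denc[l] is None else denc[l] + dfeat
            dz = relu_bwd(m, dfeat)
            dfeat = upsample2_bwd(uc, self.up[l].backward(cc, dz))
        denc[L - 1] = dfeat if denc[L - 1] is None else denc[L - 1] + dfeat
        # unwind the encoder: enc[l+1] = relu(down[l](pool(enc[l])))
        for l in reversed(range(L - 1)):
            pc, cc, m = caches["down"][l]
            dz = relu_bwd(m, denc[l + 1])
            d = avgpool2_bwd(pc, self.down[l].backward(cc, dz))
            denc[l] = d if denc[l] is None else denc[l] + d
        dz0 = relu_bwd(caches["m0"], denc[0])
        return self.conv_in.backward(caches["cin"], dz0)

    def layers(self):
        return [self.conv_in, *self.down, *self.up, self.conv_out]

    def params(self):
        return [p for layer in self.layers() for p in layer.params()]


class Adam:
    """Adam over a fixed list of ``(value, grad)`` array pairs (in place)."""

    def __init__(self, params, lr=2e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (val, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * grad
            v *= self.b2
            v += (1.0 - self.b2) * grad**2
            val -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for _, grad in self.params:
            grad[...] = 0.0
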