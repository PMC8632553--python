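"""Minimal numpy neural-network engine for the raster detector.

Implements exactly the pieces the recurrent-convolutional detector needs —
a DFT-basis spectrogram front-end, 2-D convolution (im2col), batch
normalization, bidirectional GRU with backpropagation through time, a linear
head, binary cross-entropy on logits and Adam — with explicit forward/backward
passes.  Everything is float64 and fully deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: named parameters with matching gradient buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class SpectrogramFrontEnd(Layer):
    """Windowed DFT basis applied as a strided convolution over the waveform.

    Produces log-compressed magnitude spectra: for frame i the window covers
    samples ``[i*hop, i*hop + win)`` (the waveform is zero-padded so the frame
    count is ``ceil(n_samples / hop)``).  The cosine/sine basis is fixed by
    default; with ``trainable=True`` the basis matrices receive gradients.
    """

    def __init__(self, win: int, hop: int, trainable: bool = False) -> None:
        super().__init__()
        self.win, self.hop = win, hop
        self.n_bins = win // 2 + 1
        n = np.arange(win)
        k = np.arange(self.n_bins)[:, None]
        window = np.hanning(win)
        c_re = window * np.cos(2 * np.pi * k * n / win)
        c_im = -window * np.sin(2 * np.pi * k * n / win)
        if trainable:
            self.c_re = self.add_param("c_re", c_re)
            self.c_im = self.add_param("c_im", c_im)
        else:
            self.c_re, self.c_im = c_re, c_im
        self.trainable = trainable

    def n_frames(self, n_samples: int) -> int:
        return -(-n_samples // self.hop)

    def forward(self, waves: np.ndarray, train: bool = False) -> np.ndarray:
        b, n = waves.shape
        t = self.n_frames(n)
        padded = np.zeros((b, (t - 1) * self.hop + self.win))
        padded[:, :n] = waves
        idx = np.arange(self.win)[None, :] + self.hop * np.arange(t)[:, None]
        frames = padded[:, idx]  # (B, T, win)
        re = frames @ self.c_re.T
        im = frames @ self.c_im.T
        mag = np.sqrt(re**2 + im**2 + 1e-12)
        self._cache = (frames, re, im, mag)
        feat = np.log(mag + 1e-3)
        return feat.transpose(0, 2, 1)[:, None, :, :]  # (B, 1, bins, T)

    def backward(self, gout: np.ndarray) -> None:
        if not self.trainable:
            return
        frames, re, im, mag = self._cache
        gmag = gout[:, 0].transpose(0, 2, 1) / (mag + 1e-3)
        gre = gmag * re / mag
        gim = gmag * im / mag
        self.grads["c_re"] += np.einsum("btk,btn->kn", gre, frames)
        self.grads["c_im"] += np.einsum("btk,btn->kn", gim, frames)


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, ho, wo),
        strides=(s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw),
        writeable=False,
    )
    return view.reshape(b, c * kh * kw, ho * wo), ho, wo


class Conv2d(Layer):
    """3x3 same-padding convolution with configurable (freq, time) stride."""

    def __init__(self, c_in: int, c_out: int, stride: tuple[int, int], rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.stride = c_in, c_out, stride
        self.kh = self.kw = 3
        fan_in = c_in * self.kh * self.kw
        self.w = self.add_param("w", rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in))
        self.b = self.add_param("b", np.zeros(c_out))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        col, ho, wo = _im2col(x, self.kh, self.kw, *self.stride)
        out = np.einsum("of,bfp->bop", self.w, col) + self.b[None, :, None]
        self._cache = (x.shape, col)
        return out.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        b, _, ho, wo = gout.shape
        g = gout.reshape(b, self.c_out, ho * wo)
        self.grads["w"] += np.einsum("bop,bfp->of", g, col)
        self.grads["b"] += g.sum(axis=(0, 2))
        gcol = np.einsum("of,bop->bfp", self.w, g)
        return self._col2im(gcol, x_shape, ho, wo)

    def _col2im(self, gcol: np.ndarray, x_shape, ho: int, wo: int) -> np.ndarray:
        b, c, h, w = x_shape
        sh, sw = self.stride
        ph, pw = self.kh // 2, self.kw // 2
        gx = np.zeros((b, c, h + 2 * ph, w + 2 * pw))
        gcol = gcol.reshape(b, c, self.kh, self.kw, ho, wo)
        for i in range(self.kh):
            for j in range(self.kw):
                gx[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += gcol[:, :, i, j]
        return gx[:, :, ph : ph + h, pw : pw + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = self.add_param("gamma", np.ones(c))
        self.beta = self.add_param("beta", np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.grads["gamma"] += np.einsum("bchw,bchw->c", gout, xhat)
        self.grads["beta"] += gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma[None, :, None, None]
        if not train:
            return gxhat * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        term = gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True) - xhat * np.mean(
            gxhat * xhat, axis=(0, 2, 3), keepdims=True
        )
        del m
        return term * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask


class _GRUDirection(Layer):
    """One direction of a GRU layer; gate order (r, z, n), torch convention."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.h = n_hidden
        s_i = 1.0 / np.sqrt(n_in)
        s_h = 1.0 / np.sqrt(n_hidden)
        self.w_ih = self.add_param("w_ih", rng.uniform(-s_i, s_i, (3 * n_hidden, n_in)))
        self.w_hh = self.add_param("w_hh", rng.uniform(-s_h, s_h, (3 * n_hidden, n_hidden)))
        self.b_ih = self.add_param("b_ih", np.zeros(3 * n_hidden))
        self.b_hh = self.add_param("b_hh", np.zeros(3 * n_hidden))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        t, b, _ = x.shape
        hdim = self.h
        xp = x @ self.w_ih.T + self.b_ih
        h = np.zeros((b, hdim))
        hs = np.empty((t, b, hdim))
        cache = []
        for i in range(t):
            hp = h @ self.w_hh.T + self.b_hh
            r = sigmoid(xp[i, :, :hdim] + hp[:, :hdim])
            z = sigmoid(xp[i, :, hdim : 2 * hdim] + hp[:, hdim : 2 * hdim])
            nh = np.tanh(xp[i, :, 2 * hdim :] + r * hp[:, 2 * hdim :])
            h_new = (1 - z) * nh + z * h
            cache.append((h, hp[:, 2 * hdim :], r, z, nh))
            h = h_new
            hs[i] = h
        self._cache = (x, cache)
        return hs

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, cache = self._cache
        t, b, _ = x.shape
        hdim = self.h
        gxp = np.zeros((t, b, 3 * hdim))
        dh = np.zeros((b, hdim))
        for i in reversed(range(t)):
            h_prev, hp_n, r, z, nh = cache[i]
            dh = dh + gout[i]
            dz_pre = dh * (h_prev - nh) * z * (1 - z)
            dn_pre = dh * (1 - z) * (1 - nh**2)
            dr_pre = dn_pre * hp_n * r * (1 - r)
            dhp = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
            gxp[i, :, :hdim] = dr_pre
            gxp[i, :, hdim : 2 * hdim] = dz_pre
            gxp[i, :, 2 * hdim :] = dn_pre
            self.grads["w_hh"] += dhp.T @ h_prev
            self.grads["b_hh"] += dhp.sum(axis=0)
            dh = dh * z + dhp @ self.w_hh
        self.grads["w_ih"] += np.einsum("tbg,tbi->gi", gxp, x)
        self.grads["b_ih"] += gxp.sum(axis=(0, 1))
        return gxp @ self.w_ih


class BiGRU(Layer):
    """Bidirectional GRU layer; output concatenates both directions (T,B,2H)."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.fw = _GRUDirection(n_in, n_hidden, rng)
        self.bw = _GRUDirection(n_in, n_hidden, rng)

    @property
    def children(self) -> list[Layer]:
        return [self.fw, self.bw]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out_f = self.fw.forward(x, train)
        out_b = self.bw.forward(x[::-1], train)[::-1]
        return np.concatenate([out_f, out_b], axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h = self.fw.h
        gx_f = self.fw.backward(gout[:, :, :h])
        gx_b = self.bw.backward(gout[::-1, :, h:])[::-1]
        return gx_f + gx_b

    def n_params(self) -> int:
        return self.fw.n_params() + self.bw.n_params()

    def zero_grad(self) -> None:
        self.fw.zero_grad()
        self.bw.zero_grad()


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        s = 1.0 / np.sqrt(n_in)
        self.w = self.add_param("w", rng.uniform(-s, s, (n_out, n_in)))
        self.b = self.add_param("b", np.zeros(n_out))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = gout.reshape(-1, gout.shape[-1])
        self.grads["w"] += g2.T @ x2
        self.grads["b"] += g2.sum(axis=0)
        return gout @ self.w


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    loss = np.logaddexp(0.0, logits) - logits * targets
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss.mean()), grad


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.entries = []
        for layer in _flatten(layers):
            for name in layer.params:
                p, g = layer.params[name], layer.grads[name]
                self.entries.append([p, g, np.zeros_like(p), np.zeros_like(p)])
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for entry in self.entries:
            p, g, m, v = entry
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g**2 - v)
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _flatten(layers: list[Layer]) -> list[Layer]:
    out = []
    for layer in layers:
        if isinstance(layer, BiGRU):
            out.extend(layer.children)
        else:
            out.append(layer)
    return out


def zero_grads(layers: list[Layer]) -> None:
    for layer in layers:
        layer.zero_grad()
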