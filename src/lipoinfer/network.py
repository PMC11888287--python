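"""Convolutional regression network mapping input tensors to unit-scaled parameters.

A compact CNN engine written directly on NumPy: conv2D / max-pool / dense
layers with hand-derived backpropagation and an Adam update.  The first
convolution uses a (2, 2) kernel with row stride 2, so it straddles exactly
one engineered feature pair per step and can realize finite-difference
stencils such as dG/dt from a (t, G) pair.  For the concat-family layouts a
front convolution's output channels are unrolled into extra rows and
concatenated onto the (time-cropped) input before the main trunk.

Outputs live in parameter space rescaled to the unit interval; the final
activation is either ReLU or the scaled tanh (tanh(x)+1)/2, keeping
predictions positive before and after rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        return a[0] if (a and callable(a[0])) else (lambda f: f)

__all__ = ["ParamScaler", "lr_schedule", "NetworkConfig", "ConvNet",
           "mse_loss", "forward"]


# Fused 2x2-kernel conv kernels: every convolution in these architectures has
# a (2, 2) receptive field, so the stencil is unrolled explicitly.

@_njit(cache=True, fastmath=True)
def _nb_conv1_fwd(x, W, b, sr, sc, out):
    # single-input-channel 2x2 conv with hoisted weights (contiguous j loop)
    N = x.shape[0]
    Co, Ho, Wo = out.shape[1], out.shape[2], out.shape[3]
    for n in range(N):
        for o in range(Co):
            w00 = W[o, 0, 0, 0]
            w01 = W[o, 0, 0, 1]
            w10 = W[o, 0, 1, 0]
            w11 = W[o, 0, 1, 1]
            bo = b[o]
            for i in range(Ho):
                r = i * sr
                x0 = x[n, 0, r]
                x1 = x[n, 0, r + 1]
                for j in range(Wo):
                    q = j * sc
                    out[n, o, i, j] = (bo + w00 * x0[q] + w01 * x0[q + 1]
                                       + w10 * x1[q] + w11 * x1[q + 1])


@_njit(cache=True, fastmath=True)
def _nb_conv1_bwd(x, W, dout, sr, sc, dW, db, dx, need_dx):
    N = x.shape[0]
    Co, Ho, Wo = dout.shape[1], dout.shape[2], dout.shape[3]
    for n in range(N):
        for o in range(Co):
            w00 = W[o, 0, 0, 0]
            w01 = W[o, 0, 0, 1]
            w10 = W[o, 0, 1, 0]
            w11 = W[o, 0, 1, 1]
            g00 = 0.0
            g01 = 0.0
            g10 = 0.0
            g11 = 0.0
            gb = 0.0
            for i in range(Ho):
                r = i * sr
                x0 = x[n, 0, r]
                x1 = x[n, 0, r + 1]
                d = dout[n, o, i]
                for j in range(Wo):
                    q = j * sc
                    g = d[j]
                    gb += g
                    g00 += g * x0[q]
                    g01 += g * x0[q + 1]
                    g10 += g * x1[q]
                    g11 += g * x1[q + 1]
                if need_dx:
                    dx0 = dx[n, 0, r]
                    dx1 = dx[n, 0, r + 1]
                    for j in range(Wo):
                        q = j * sc
                        g = d[j]
                        dx0[q] += g * w00
                        dx0[q + 1] += g * w01
                        dx1[q] += g * w10
                        dx1[q + 1] += g * w11
            dW[o, 0, 0, 0] += g00
            dW[o, 0, 0, 1] += g01
            dW[o, 0, 1, 0] += g10
            dW[o, 0, 1, 1] += g11
            db[o] += gb


@_njit(cache=True, fastmath=True)
def _nb_pool12_fwd(x, out, left):
    N, C, H, Wo = out.shape
    for n in range(N):
        for c in range(C):
            for i in range(H):
                for j in range(Wo):
                    a = x[n, c, i, 2 * j]
                    b = x[n, c, i, 2 * j + 1]
                    if a >= b:
                        out[n, c, i, j] = a
                        left[n, c, i, j] = True
                    else:
                        out[n, c, i, j] = b
                        left[n, c, i, j] = False


@_njit(cache=True, fastmath=True)
def _nb_pool12_bwd(dout, left, dx):
    N, C, H, Wo = dout.shape
    for n in range(N):
        for c in range(C):
            for i in range(H):
                for j in range(Wo):
                    if left[n, c, i, j]:
                        dx[n, c, i, 2 * j] = dout[n, c, i, j]
                    else:
                        dx[n, c, i, 2 * j + 1] = dout[n, c, i, j]


# ---------------------------------------------------------------------------
# Output rescaling
# ---------------------------------------------------------------------------

class ParamScaler:
    """Linear map between physiological parameter ranges and [0, 1]."""

    def __init__(self, mins, maxs):
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        if np.any(self.maxs <= self.mins):
            raise ValueError("every parameter range needs max > min")

    @classmethod
    def from_ranges(cls, ranges: dict, names) -> "ParamScaler":
        return cls([ranges[n][0] for n in names], [ranges[n][1] for n in names])

    def scale(self, x):
        return (np.asarray(x) - self.mins) / (self.maxs - self.mins)

    def unscale(self, u):
        return np.asarray(u) * (self.maxs - self.mins) + self.mins

    def to_dict(self):
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist()}

    @classmethod
    def from_dict(cls, d):
        return cls(d["mins"], d["maxs"])


def lr_schedule(epoch: float, max_lr: float, peak_epoch: int, total_epochs: int) -> float:
    """Linear ramp 0 -> max_lr over [0, peak_epoch], cosine decay to max_lr/100."""
    if peak_epoch <= 0:
        raise ValueError("peak_epoch must be >= 1")
    if epoch <= peak_epoch:
        return max_lr * epoch / peak_epoch
    min_lr = max_lr / 100.0
    frac = min((epoch - peak_epoch) / max(total_epochs - peak_epoch, 1), 1.0)
    return min_lr + (max_lr - min_lr) * 0.5 * (1 + np.cos(np.pi * frac))


def mse_loss(pred: np.ndarray, true: np.ndarray):
    """Mean squared error over batch and parameters, plus its gradient."""
    diff = pred - true
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list

    def __init__(self):
        self.params = []  # list of [value, grad] pairs


class Conv2D(_Layer):
    def __init__(self, c_in, c_out, kernel=(2, 2), stride=(2, 1), rng=None, dtype=np.float32):
        super().__init__()
        kh, kw = kernel
        fan_in = c_in * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(c_out, c_in, kh, kw)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride
        self.needs_input_grad = True  # first layers switch this off
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def out_shape(self, h, w):
        kh, kw = self.kernel
        sr, sc = self.stride
        return (h - kh) // sr + 1, (w - kw) // sc + 1

    def forward(self, x):
        kh, kw = self.kernel
        sr, sc = self.stride
        n, c_in = x.shape[0], x.shape[1]
        ho, wo = self.out_shape(x.shape[2], x.shape[3])
        self._x_shape = x.shape
        if _HAVE_NUMBA and (kh, kw) == (2, 2) and c_in == 1:
            x = np.ascontiguousarray(x)
            out = np.empty((n, self.W.shape[0], ho, wo), dtype=x.dtype)
            _nb_conv1_fwd(x, self.W.astype(x.dtype, copy=False),
                          self.b.astype(x.dtype, copy=False), sr, sc, out)
            self._x = x
            return out
        # general case: im2col + BLAS
        win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        win = win[:, :, ::sr, ::sc]           # (N, Cin, Ho, Wo, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * ho * wo, -1)
        self._cols, self._hw = cols, (ho, wo)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T.astype(cols.dtype, copy=False) + self.b
        return np.ascontiguousarray(out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2))

    def backward(self, dout):
        kh, kw = self.kernel
        sr, sc = self.stride
        if _HAVE_NUMBA and (kh, kw) == (2, 2) and self._x_shape[1] == 1:
            dout = np.ascontiguousarray(dout)
            dx = np.zeros(self._x.shape, dtype=dout.dtype) \
                if self.needs_input_grad else np.zeros((1, 1, 2, 2), dtype=dout.dtype)
            dW = np.zeros_like(self.W)
            db = np.zeros_like(self.b)
            _nb_conv1_bwd(self._x, self.W.astype(dout.dtype, copy=False),
                          dout, sr, sc, dW, db, dx, self.needs_input_grad)
            self.dW += dW
            self.db += db
            return dx if self.needs_input_grad else None
        n = dout.shape[0]
        ho, wo = self._hw
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, dout.shape[1])
        self.dW += (dmat.T @ self._cols).reshape(self.W.shape)
        self.db += dmat.sum(axis=0)
        if not self.needs_input_grad:
            return None
        wmat = self.W.reshape(self.W.shape[0], -1).astype(dmat.dtype, copy=False)
        dcols = (dmat @ wmat).reshape(n, ho, wo, self.W.shape[1], kh, kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        for a in range(kh):
            for b in range(kw):
                dx[:, :, a:a + sr * ho:sr, b:b + sc * wo:sc] += dcols[:, :, :, :, a, b]
        return dx


class MaxPool2D(_Layer):
    """Non-overlapping max pooling; trailing rows/columns that do not fill a
    window are dropped."""

    def __init__(self, pool=(1, 2)):
        super().__init__()
        self.pool = pool

    def out_shape(self, h, w):
        return h // self.pool[0], w // self.pool[1]

    def forward(self, x):
        ph, pw = self.pool
        n, c, h, w = x.shape
        ho, wo = h // ph, w // pw
        self._x_shape = x.shape
        if (ph, pw) == (1, 2):  # the layout's standard time-axis pooling
            if _HAVE_NUMBA:
                out = np.empty((n, c, h, wo), dtype=x.dtype)
                self._left = np.empty((n, c, h, wo), dtype=np.bool_)
                _nb_pool12_fwd(np.ascontiguousarray(x), out, self._left)
                return out
            a = x[:, :, :, 0:2 * wo:2]
            b = x[:, :, :, 1:2 * wo:2]
            self._left = a >= b
            return np.maximum(a, b)
        xc = x[:, :, :ho * ph, :wo * pw]
        r = xc.reshape(n, c, ho, ph, wo, pw).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, ho, wo, ph * pw)
        self._argmax = r.argmax(axis=-1)
        return r.max(axis=-1)

    def backward(self, dout):
        ph, pw = self.pool
        n, c, h, w = self._x_shape
        ho, wo = dout.shape[2], dout.shape[3]
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        if (ph, pw) == (1, 2):
            if _HAVE_NUMBA:
                _nb_pool12_bwd(np.ascontiguousarray(dout), self._left, dx)
                return dx
            dx[:, :, :, 0:2 * wo:2] = np.where(self._left, dout, 0)
            dx[:, :, :, 1:2 * wo:2] = np.where(self._left, 0, dout)
            return dx
        flat = np.zeros((n, c, ho, wo, ph * pw), dtype=dout.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dout[..., None], axis=-1)
        dx[:, :, :ho * ph, :wo * pw] = (
            flat.reshape(n, c, ho, wo, ph, pw).transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, ho * ph, wo * pw))
        return dx


class Dense(_Layer):
    def __init__(self, n_in, n_out, rng, dtype=np.float32):
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [[self.W, self.dW], [self.b, self.db]]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0)


class Tanh(_Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout):
        return dout * (1.0 - self._y ** 2)


class ScaledTanh(_Layer):
    """(tanh(x) + 1) / 2, mapping outputs into (0, 1)."""

    def forward(self, x):
        self._th = np.tanh(x)
        return 0.5 * (self._th + 1.0)

    def backward(self, dout):
        return dout * 0.5 * (1.0 - self._th ** 2)


class Flatten(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    layout: str
    n_rows: int
    n_times: int
    npara: int
    final_activation: str = "scaled_tanh"   # or "relu"
    concat_channels: int = 2
    conv_channels: tuple = (6, 12)
    dense_width: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.final_activation not in ("relu", "scaled_tanh"):
            raise ValueError("final_activation must be 'relu' or 'scaled_tanh'")

    def to_dict(self):
        d = self.__dict__.copy()
        d["conv_channels"] = list(self.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


class ConvNet:
    """Feed-forward conv regression net per layout, with manual backprop."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        c1, c2 = config.conv_channels
        h, w = config.n_rows, config.n_times

        self.front = None
        if config.layout != "none":
            self.front = Conv2D(1, config.concat_channels, (2, 2), (2, 1),
                                rng=rng, dtype=dtype)
            self.front.needs_input_grad = False
            self.front_act = ReLU()
            fh, fw = self.front.out_shape(h, w)
            h, w = h + config.concat_channels * fh, fw  # rows grow, time crops by 1

        layers = []
        conv1 = Conv2D(1, c1, (2, 2), (2, 1), rng=rng, dtype=dtype)
        if self.front is None:
            conv1.needs_input_grad = False
        layers += [conv1, ReLU(), MaxPool2D((1, 2))]
        h, w = conv1.out_shape(h, w)
        h, w = layers[-1].out_shape(h, w)
        conv2 = Conv2D(c1, c2, (2, 2), (2, 1), rng=rng, dtype=dtype)
        layers += [conv2, ReLU(), MaxPool2D((1, 2))]
        h, w = conv2.out_shape(h, w)
        h, w = layers[-1].out_shape(h, w)
        layers.append(Flatten())
        layers.append(Dense(c2 * h * w, config.dense_width, rng=rng, dtype=dtype))
        layers.append(Tanh())
        layers.append(Dense(config.dense_width, config.npara, rng=rng, dtype=dtype))
        layers.append(ScaledTanh() if config.final_activation == "scaled_tanh" else ReLU())
        self.layers = layers

    # -- parameter plumbing -------------------------------------------------

    def parameters(self):
        out = []
        if self.front is not None:
            out.extend(self.front.params)
        for lay in self.layers:
            out.extend(lay.params)
        return out

    def zero_grad(self):
        for _, g in self.parameters():
            g[...] = 0.0

    def get_weights(self):
        return [w.copy() for w, _ in self.parameters()]

    def set_weights(self, weights):
        for (w, _), new in zip(self.parameters(), weights):
            w[...] = new

    # -- forward / backward -------------------------------------------------

    def forward(self, dI: np.ndarray) -> np.ndarray:
        cfg = self.config
        if dI.ndim != 3 or dI.shape[1:] != (cfg.n_rows, cfg.n_times):
            raise ValueError(
                f"layout {cfg.layout!r} expects input (N, {cfg.n_rows}, "
                f"{cfg.n_times}), got {dI.shape}")
        x = dI[:, None].astype(self.dtype)  # (N, 1, rows, times)
        if self.front is not None:
            ya = self.front_act.forward(self.front.forward(x))
            n, ca, fh, fw = ya.shape
            self._front_rows = ca * fh
            x = np.concatenate([x[:, :, :, :fw], ya.reshape(n, 1, ca * fh, fw)], axis=2)
        for lay in self.layers:
            x = lay.forward(x)
        return x

    def backward(self, dout: np.ndarray):
        """Backpropagate, accumulating parameter gradients.

        The gradient with respect to the input tensor is not materialized
        (the input is data, not a learnable quantity); returns None.
        """
        g = dout.astype(self.dtype)
        for lay in reversed(self.layers):
            g = lay.backward(g)
        if self.front is None:
            return None
        n = g.shape[0]
        n_raw = g.shape[2] - self._front_rows
        g_front = g[:, :, n_raw:]
        fw = g.shape[3]
        ca = self.front.W.shape[0]
        dya = g_front.reshape(n, ca, self._front_rows // ca, fw)
        self.front.backward(self.front_act.backward(dya))
        return None


def forward(net: ConvNet, dI: np.ndarray) -> np.ndarray:
    """Functional forward pass (deterministic given weights and input)."""
    return net.forward(dI)


class Adam:
    """Adam with an externally supplied per-step learning rate."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (w, g), m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            w -= lr * mhat / (np.sqrt(vhat) + self.eps)
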