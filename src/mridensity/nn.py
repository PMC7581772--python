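"""Minimal 3D neural-network engine in numpy.

Implements exactly the layer set the density regressor needs — strided 3D
convolution with TF-style "same" padding, PReLU, inverted dropout, flatten
and dense layers — with hand-written backprop and an Adam optimizer.  Every
layer additionally knows how to propagate DeepLIFT-rescale multipliers
(`propagate_multipliers`), which is what the Shapley-additive attribution
module builds on: linear layers pass multipliers through their weights
(bias-free transpose, identical to gradient backprop), and each nonlinearity
contributes the finite-difference slope
(f(a_x) - f(a_b)) / (a_x - a_b) between the explained input's and the
background's pre-activations, falling back to the local derivative when the
two nearly coincide.

Arrays are float64 throughout; convolution inputs are (B, C, D, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3D", "PReLU", "Dropout", "Flatten", "Dense", "Sequential", "Adam"]

_EPS_RESCALE = 1e-7  # near-equal-activation fallback threshold


def _same_pads(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """TF-convention 'same' padding: out = ceil(size/stride)."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    lo = total // 2
    return out, lo, total - lo


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def infer_cache(self, x):
        """Inference-mode forward returning (output, cache-for-multipliers)."""
        return self.forward(x, training=False), None

    def propagate_multipliers(self, m, cache_x, cache_b):
        raise NotImplementedError


class Conv3D(Layer):
    """3D convolution, kernel k^3, stride s, 'same' padding, bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 stride: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.s = in_channels, out_channels, kernel, stride
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        # He-style init suits the rectifier family
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel, kernel))
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _im2col(self, x):
        B, C, D, H, W = x.shape
        k, s = self.k, self.s
        dims_out, pads = [], []
        for n in (D, H, W):
            out, lo, hi = _same_pads(n, k, s)
            dims_out.append(out)
            pads.append((lo, hi))
        xp = np.pad(x, ((0, 0), (0, 0), *pads))
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        Do, Ho, Wo = dims_out
        win = win[:, :, :Do, :Ho, :Wo]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, Do * Ho * Wo, C * k**3)
        return cols, (B, C, D, H, W), (Do, Ho, Wo), pads

    def forward(self, x, training=False, rng=None):
        cols, in_shape, out_dims, pads = self._im2col(x)
        wmat = self.params["W"].reshape(self.cout, -1)
        out = cols @ wmat.T + self.params["b"]
        self._cache = (cols, in_shape, out_dims, pads)
        B = in_shape[0]
        return out.reshape(B, *out_dims, self.cout).transpose(0, 4, 1, 2, 3)

    def _cols_to_input(self, dcols, in_shape, out_dims, pads):
        B, C, D, H, W = in_shape
        k, s = self.k, self.s
        Do, Ho, Wo = out_dims
        Dp = D + pads[0][0] + pads[0][1]
        Hp = H + pads[1][0] + pads[1][1]
        Wp = W + pads[2][0] + pads[2][1]
        dxp = np.zeros((B, C, Dp, Hp, Wp))
        dwin = dcols.reshape(B, Do, Ho, Wo, C, k, k, k).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, :, i : i + s * Do : s, j : j + s * Ho : s, l : l + s * Wo : s] += dwin[..., i, j, l]
        return dxp[:, :, pads[0][0] : pads[0][0] + D, pads[1][0] : pads[1][0] + H, pads[2][0] : pads[2][0] + W]

    def _dout_to_dcols(self, dout):
        B = dout.shape[0]
        return dout.transpose(0, 2, 3, 4, 1).reshape(B, -1, self.cout)

    def backward(self, dout):
        cols, in_shape, out_dims, pads = self._cache
        dflat = self._dout_to_dcols(dout)
        wmat = self.params["W"].reshape(self.cout, -1)
        self.grads["W"] += np.einsum("bpf,bpc->fc", dflat, cols).reshape(self.params["W"].shape)
        self.grads["b"] += dflat.sum(axis=(0, 1))
        dcols = dflat @ wmat
        return self._cols_to_input(dcols, in_shape, out_dims, pads)

    def infer_cache(self, x):
        return self.forward(x), self._cache

    def propagate_multipliers(self, m, cache_x, cache_b):
        # linear layer: multipliers flow through the weights, bias excluded
        _, in_shape, out_dims, pads = cache_x
        dflat = self._dout_to_dcols(m)
        dcols = dflat @ self.params["W"].reshape(self.cout, -1)
        return self._cols_to_input(dcols, in_shape, out_dims, pads)


class PReLU(Layer):
    """Parametric rectifier with one learned negative-side slope per channel."""

    def __init__(self, n_channels: int, init_slope: float = 0.25, channel_axis: int = 1):
        super().__init__()
        self.axis = channel_axis
        self.params = {"alpha": np.full(n_channels, init_slope)}
        self.grads = {"alpha": np.zeros(n_channels)}

    def _alpha_shaped(self, ndim):
        shape = [1] * ndim
        shape[self.axis] = -1
        return self.params["alpha"].reshape(shape)

    def _f(self, x):
        return np.where(x > 0, x, self._alpha_shaped(x.ndim) * x)

    def forward(self, x, training=False, rng=None):
        self._cache = x
        return self._f(x)

    def backward(self, dout):
        x = self._cache
        a = self._alpha_shaped(x.ndim)
        neg = x <= 0
        axes = tuple(i for i in range(x.ndim) if i != self.axis)
        self.grads["alpha"] += np.sum(dout * x * neg, axis=axes)
        return dout * np.where(neg, a, 1.0)

    def infer_cache(self, x):
        return self.forward(x), x

    def propagate_multipliers(self, m, cache_x, cache_b):
        ax, ab = cache_x, cache_b
        delta = ax - ab
        slope_local = np.where(ax > 0, 1.0, self._alpha_shaped(ax.ndim))
        with np.errstate(divide="ignore", invalid="ignore"):
            slope_secant = (self._f(ax) - self._f(ab)) / delta
        slope = np.where(np.abs(delta) < _EPS_RESCALE, slope_local, slope_secant)
        return m * slope


class Dropout(Layer):
    """Inverted dropout: active in training mode only."""

    def __init__(self, rate: float = 0.5):
        super().__init__()
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def propagate_multipliers(self, m, cache_x, cache_b):
        return m  # identity at inference


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def infer_cache(self, x):
        return self.forward(x), x.shape

    def propagate_multipliers(self, m, cache_x, cache_b):
        return m.reshape(cache_x)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.params = {"W": w, "b": np.zeros(out_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x, training=False, rng=None):
        self._cache = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads["W"] += dout.T @ x
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"]

    def infer_cache(self, x):
        return self.forward(x), None

    def propagate_multipliers(self, m, cache_x, cache_b):
        return m @ self.params["W"]


class Sequential:
    """A plain layer stack with shared bookkeeping for training/attribution."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False, rng: np.random.Generator | None = None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grads(self):
        for layer in self.layers:
            for k in layer.grads:
                layer.grads[k][...] = 0.0

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name in layer.params:
                yield (li, name), layer.params[name], layer.grads[name]

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def get_weights(self):
        return [{k: v.copy() for k, v in layer.params.items()} for layer in self.layers]

    def set_weights(self, weights):
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k][...] = w[k]

    # -- DeepLIFT plumbing -------------------------------------------------
    def forward_with_caches(self, x):
        """Inference forward that keeps each layer's multiplier cache."""
        caches = []
        for layer in self.layers:
            x, cache = layer.infer_cache(x)
            caches.append(cache)
        return x, caches

    def backprop_multipliers(self, m, caches_x, caches_b):
        for layer, cx, cb in zip(reversed(self.layers), reversed(caches_x), reversed(caches_b)):
            m = layer.propagate_multipliers(m, cx, cb)
        return m


class Adam:
    """Adam with the usual bias-corrected first/second moment estimates."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(p) for key, p, _ in model.parameters()}
        self.v = {key: np.zeros_like(p) for key, p, _ in model.parameters()}

    def step(self):
        self.t += 1
        for key, p, g in self.model.parameters():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
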