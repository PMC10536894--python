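"""A compact CNN engine (numpy/scipy) for EEGNet-style architectures.

Implements exactly the layer set the fusion network needs — temporal
convolution, depthwise spatial convolution, separable temporal
convolution, batch normalization, ELU, average pooling, dropout, dense —
with hand-derived backward passes and an Adam optimizer. Arrays are
float32 in layout ``(batch, channels, time, features)``; a raw window
enters as ``(batch, C, T, 1)``.

Temporal convolutions use length-preserving ("same") padding with the
stride-1 convention pad_left = (k-1)//2, pad_right = k//2; the depthwise
spatial convolution spans all channels with no padding, collapsing the
channel axis to 1. Convolution backward passes w.r.t. the input go
through FFT-based convolution to avoid materializing (time × kernel)
window tensors for large kernels.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

_F32 = np.float32


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_F32)


class Layer:
    """Base: trainable ``params``/``grads`` and non-trainable ``state``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def apply_constraints(self) -> None:
        pass

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _same_pad(k: int) -> tuple[int, int]:
    return (k - 1) // 2, k // 2


class TemporalConv(Layer):
    """(1, k) convolution over time; single input feature map, no bias.

    Forward and both backward passes run through FFT convolution along
    the time axis, which keeps cost O(T log T) per feature even for
    kernels longer than the window.
    """

    def __init__(self, rng, n_filters: int, kernel_len: int):
        super().__init__()
        self.k = kernel_len
        self.params["W"] = _glorot(
            rng, (n_filters, kernel_len), kernel_len, kernel_len * n_filters
        )

    def forward(self, x, training):
        # x: (N, C, T, 1); correlation y[t, f] = sum_j xp[t+j] W[f, j]
        W = self.params["W"]
        k, T = self.k, x.shape[2]
        pl, pr = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        self._xp, self._T = xp, T
        w_rev = W.T[::-1, :][None, None, :, :]  # (1, 1, k, F)
        full = fftconvolve(xp, w_rev, axes=2)
        return full[:, :, k - 1 : k - 1 + T, :].astype(_F32)

    def backward(self, dy):
        W = self.params["W"]
        k, T = self.k, self._T
        pl, _ = _same_pad(k)
        # dW[f, j] = sum_{n,c,t} xp[t+j] dy[t, f]
        full = fftconvolve(self._xp, dy[:, :, ::-1, :], axes=2)
        self.grads["W"] = (
            full[:, :, T - 1 : T - 1 + k, :].sum(axis=(0, 1)).T.astype(_F32)
        )
        # dx[s] = sum_{f,j} dy[s + pl - j, f] W[f, j]
        full = fftconvolve(dy, W.T[None, None, :, :], axes=2)
        dx = full[:, :, pl : pl + T, :].sum(axis=3, keepdims=True)
        return dx.astype(_F32)


class DepthwiseSpatialConv(Layer):
    """(C, 1) depthwise convolution across all channels, depth multiplier D.

    Output feature order is (input feature, depth) flattened; the channel
    axis collapses to length 1. A unit max-norm constraint over the
    channel axis is applied after each optimizer step.
    """

    def __init__(self, rng, n_channels: int, in_features: int, depth_multiplier: int,
                 max_norm: float | None = 1.0):
        super().__init__()
        self.C, self.F, self.D = n_channels, in_features, depth_multiplier
        self.max_norm = max_norm
        self.params["W"] = _glorot(
            rng, (n_channels, in_features, depth_multiplier),
            n_channels, n_channels * depth_multiplier,
        )

    def forward(self, x, training):
        # x: (N, C, T, F) -> (N, 1, T, F*D), batched matmul per feature
        n, _, t, _ = x.shape
        xf = np.ascontiguousarray(x.transpose(3, 0, 2, 1)).reshape(
            self.F, n * t, self.C
        )
        self._xf, self._nt = xf, (n, t)
        wf = self.params["W"].transpose(1, 0, 2)  # (F, C, D)
        y = xf @ wf  # (F, N*T, D)
        y = y.reshape(self.F, n, t, self.D).transpose(1, 2, 0, 3)
        return np.ascontiguousarray(y).reshape(n, 1, t, self.F * self.D)

    def backward(self, dy):
        n, t = self._nt
        dyf = np.ascontiguousarray(
            dy.reshape(n, t, self.F, self.D).transpose(2, 0, 1, 3)
        ).reshape(self.F, n * t, self.D)
        dw = self._xf.transpose(0, 2, 1) @ dyf  # (F, C, D)
        self.grads["W"] = dw.transpose(1, 0, 2).astype(_F32)
        wf = self.params["W"].transpose(1, 0, 2)  # (F, C, D)
        dxf = dyf @ wf.transpose(0, 2, 1)  # (F, N*T, C)
        dx = dxf.reshape(self.F, n, t, self.C).transpose(1, 3, 2, 0)
        return np.ascontiguousarray(dx).astype(_F32)

    def apply_constraints(self):
        if self.max_norm is None:
            return
        W = self.params["W"]
        norms = np.sqrt((W**2).sum(axis=0, keepdims=True))
        np.multiply(
            W, np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12)),
            out=W, casting="unsafe",
        )


class SeparableConv(Layer):
    """Depthwise (1, k) temporal conv then pointwise mix to out_features."""

    def __init__(self, rng, in_features: int, kernel_len: int, out_features: int):
        super().__init__()
        self.k, self.Fin, self.Fout = kernel_len, in_features, out_features
        self.params["Wd"] = _glorot(
            rng, (in_features, kernel_len), kernel_len, kernel_len
        )
        self.params["Wp"] = _glorot(
            rng, (in_features, out_features), in_features, out_features
        )

    def forward(self, x, training):
        k, T = self.k, x.shape[2]
        pl, pr = _same_pad(k)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (0, 0)))
        self._xp, self._T = xp, T
        # per-feature temporal correlation
        wd_rev = self.params["Wd"].T[::-1, :][None, None, :, :]
        y1 = fftconvolve(xp, wd_rev, axes=2)[:, :, k - 1 : k - 1 + T, :]
        self._y1 = y1.astype(_F32)
        return self._y1 @ self.params["Wp"]

    def backward(self, dy):
        k, T = self.k, self._T
        pl, _ = _same_pad(k)
        y1f = self._y1.reshape(-1, self.Fin)
        self.grads["Wp"] = (y1f.T @ dy.reshape(-1, self.Fout)).astype(_F32)
        dy1 = dy @ self.params["Wp"].T
        full = fftconvolve(self._xp, dy1[:, :, ::-1, :], axes=2)
        self.grads["Wd"] = (
            full[:, :, T - 1 : T - 1 + k, :].sum(axis=(0, 1)).T.astype(_F32)
        )
        full = fftconvolve(dy1, self.params["Wd"].T[None, None, :, :], axes=2)
        return full[:, :, pl : pl + T, :].astype(_F32)


class BatchNorm(Layer):
    """Batch normalization over (batch, channel, time) per feature map."""

    def __init__(self, n_features: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(n_features, dtype=_F32)
        self.params["beta"] = np.zeros(n_features, dtype=_F32)
        self.state["moving_mean"] = np.zeros(n_features, dtype=_F32)
        self.state["moving_var"] = np.ones(n_features, dtype=_F32)

    def forward(self, x, training):
        if training:
            mu = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.state["moving_mean"] = (
                m * self.state["moving_mean"] + (1 - m) * mu
            ).astype(_F32)
            self.state["moving_var"] = (
                m * self.state["moving_var"] + (1 - m) * var
            ).astype(_F32)
        else:
            mu = self.state["moving_mean"]
            var = self.state["moving_var"]
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._xhat, self._ivar = xhat, ivar
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(_F32)

    def backward(self, dy):
        xhat, ivar = self._xhat, self._ivar
        axes = (0, 1, 2)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.grads["gamma"] = (dy * xhat).sum(axis=axes).astype(_F32)
        self.grads["beta"] = dy.sum(axis=axes).astype(_F32)
        dxhat = dy * self.params["gamma"]
        dx = (
            ivar / m
        ) * (
            m * dxhat
            - dxhat.sum(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes)
        )
        return dx.astype(_F32)


class ELU(Layer):
    def forward(self, x, training):
        y = np.where(x > 0, x, np.expm1(x))
        self._y = y
        return y.astype(_F32)

    def backward(self, dy):
        return (dy * np.where(self._y > 0, 1.0, self._y + 1.0)).astype(_F32)


class AvgPool(Layer):
    """Average pooling (1, p) along time; trailing remainder dropped."""

    def __init__(self, pool_len: int):
        super().__init__()
        self.p = pool_len

    def forward(self, x, training):
        n, c, t, f = x.shape
        t_out = t // self.p
        if t_out < 1:
            raise ValueError(f"pool length {self.p} exceeds time axis {t}")
        self._t_in = t
        xr = x[:, :, : t_out * self.p, :].reshape(n, c, t_out, self.p, f)
        return xr.mean(axis=3).astype(_F32)

    def backward(self, dy):
        n, c, t_out, f = dy.shape
        dx = np.repeat(dy / self.p, self.p, axis=2)
        if dx.shape[2] < self._t_in:
            pad = self._t_in - dx.shape[2]
            dx = np.pad(dx, ((0, 0), (0, 0), (0, pad), (0, 0)))
        return dx.astype(_F32)


class Dropout(Layer):
    def __init__(self, rng: np.random.Generator, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, training):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(_F32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(_F32)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out, dtype=_F32)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = (self._x.T @ dy).astype(_F32)
        self.grads["b"] = dy.sum(axis=0).astype(_F32)
        return (dy @ self.params["W"].T).astype(_F32)


# ---------------------------------------------------------------------------


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def categorical_crossentropy(logits, y_onehot):
    """Softmax + categorical CE; returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -(y_onehot * np.log(p + eps)).sum() / n
    dz = (p - y_onehot) / n
    return float(loss), dz.astype(_F32)


def binary_crossentropy(logits, y_onehot):
    """Element-wise BCE on softmax outputs, averaged over samples and
    classes (the convention of treating each one-hot output as an
    independent binary target); returns (loss, dlogits)."""
    p = softmax(logits.astype(np.float64))
    n, k = logits.shape
    eps = 1e-7
    pc = np.clip(p, eps, 1 - eps)
    loss = -(y_onehot * np.log(pc) + (1 - y_onehot) * np.log(1 - pc)).sum() / (n * k)
    g = (pc - y_onehot) / (pc * (1 - pc)) / (n * k)  # dL/dp
    # backprop through softmax: dz_i = p_i (g_i - sum_j g_j p_j)
    dz = p * (g - (g * p).sum(axis=1, keepdims=True))
    return float(loss), dz.astype(_F32)


LOSSES = {
    "binary_crossentropy": binary_crossentropy,
    "categorical_crossentropy": categorical_crossentropy,
}


class FusionNetwork:
    """Parallel branches over a shared input, concatenated into one head.

    ``branches`` is a list of layer lists; every branch must end in a
    Flatten. The head is a Dense layer over the concatenated branch
    features followed (conceptually) by softmax — ``forward`` returns
    logits, ``predict_proba`` applies the softmax.
    """

    def __init__(self, branches: list[list[Layer]], head: Dense,
                 input_shape: tuple[int, int]):
        self.branches = branches
        self.head = head
        self.input_shape = input_shape  # (C, T)
        self._branch_dims: list[int] | None = None

    # -- plumbing ----------------------------------------------------------
    def _iter_layers(self):
        for i, branch in enumerate(self.branches):
            for j, layer in enumerate(branch):
                yield f"branch{i}/layer{j}", layer
        yield "head/dense", self.head

    def parameters(self):
        for name, layer in self._iter_layers():
            for pname in layer.params:
                yield f"{name}/{pname}", layer, pname

    @property
    def trainable_parameter_count(self) -> int:
        return sum(layer.n_params for _, layer in self._iter_layers())

    @property
    def branch_feature_dims(self) -> list[int]:
        if self._branch_dims is None:
            x = np.zeros((1, *self.input_shape, 1), dtype=_F32)
            self.forward(x, training=False)
        return list(self._branch_dims)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._iter_layers():
            for pname, p in layer.params.items():
                out[f"{name}/{pname}"] = p.copy()
            for sname, s in layer.state.items():
                out[f"{name}/state/{sname}"] = s.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name, layer in self._iter_layers():
            for pname in layer.params:
                layer.params[pname] = weights[f"{name}/{pname}"].copy()
            for sname in layer.state:
                layer.state[sname] = weights[f"{name}/state/{sname}"].copy()

    def save_weights(self, path) -> None:
        np.savez(path, **self.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as npz:
            self.set_weights({k: npz[k] for k in npz.files})

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, training)
            outs.append(h)
        self._branch_dims = [o.shape[1] for o in outs]
        fused = np.concatenate(outs, axis=1)
        return self.head.forward(fused, training)

    def backward(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        offset = 0
        for branch, dim in zip(self.branches, self._branch_dims):
            dh = dfused[:, offset : offset + dim]
            offset += dim
            for layer in reversed(branch):
                dh = layer.backward(dh)

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax class probabilities for (N, C, T) windows, batched."""
        x = np.asarray(windows, dtype=_F32)[..., None]
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            out.append(softmax(logits.astype(np.float64)))
        return np.concatenate(out, axis=0)


class Adam:
    """Adam with bias correction; applies per-layer weight constraints
    (e.g. the depthwise max-norm) after each step."""

    def __init__(self, network: FusionNetwork, learning_rate: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.net = network
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(layer.params[p])
                  for name, layer, p in network.parameters()}
        self.v = {name: np.zeros_like(layer.params[p])
                  for name, layer, p in network.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, layer, pname in self.net.parameters():
            g = layer.grads[pname]
            m = self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            v = self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            layer.params[pname] -= (
                self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            ).astype(_F32)
        for _, layer in self.net._iter_layers():
            layer.apply_constraints()
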