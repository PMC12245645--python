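"""Minimal CPU neural-network engine (numpy + BLAS).

Implements exactly the pieces the localisation and baseline networks need:
3x3 same-padding convolutions via im2col GEMMs, 1x1 convolutions, ReLU,
2x2 max-pooling, nearest-neighbour x2 upsampling, inverted dropout, dense
layers, mean-squared-error loss and Adam.  Everything is float32 and every
source of randomness is an explicit ``numpy.random.Generator``, so training
and stochastic inference are bit-reproducible for a fixed seed.

Arrays are channels-LAST, ``(N, H, W, C)``: the im2col gather then reads
contiguous channel vectors, which is several times faster on CPU than the
channels-first layout.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, **kw):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv3x3(Layer):
    """3x3 convolution, stride 1, zero same-padding; He-normal init.

    Implemented as nine shift-and-accumulate GEMMs over the padded input,
    which avoids materialising the 9x-duplicated im2col patch matrix.
    Weights are stored as (cin, 9, cout) with kernel index k = ky*3 + kx.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 compute_dx: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / (9 * cin))
        self.cin, self.cout = cin, cout
        self.compute_dx = compute_dx
        self.params = {
            "W": rng.normal(0.0, std, size=(cin, 9, cout)).astype(F32),
            "b": np.zeros(cout, dtype=F32),
        }
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}
        self._cache = None

    def forward(self, x, **kw):
        x = np.ascontiguousarray(x, dtype=F32)
        n, h, w, c = x.shape
        xp = _pad1(x)
        wk = self.params["W"]
        y = np.empty((n, h, w, self.cout), dtype=F32)
        y[...] = self.params["b"]
        for k in range(9):
            ky, kx = divmod(k, 3)
            y += xp[:, ky:ky + h, kx:kx + w, :] @ np.ascontiguousarray(wk[:, k, :])
        self._cache = (x, xp, (n, h, w, c))
        return y

    def backward(self, dout):
        x, xp, (n, h, w, c) = self._cache
        dout = np.ascontiguousarray(dout, dtype=F32)
        self.grads["b"][...] = dout.sum(axis=(0, 1, 2))
        # both gradients consume the same nine shifted copies of dout; the
        # flattened input is a free view, so only |dout| is copied per offset
        x2d = x.reshape(-1, c)
        dp = _pad1(dout)
        dw = self.grads["W"]
        wk = self.params["W"]
        dx2d = np.zeros((n * h * w, c), dtype=F32) if self.compute_dx else None
        for k in range(9):
            ky, kx = divmod(k, 3)
            dk = np.ascontiguousarray(
                dp[:, 2 - ky:2 - ky + h, 2 - kx:2 - kx + w, :]
            ).reshape(-1, self.cout)
            dw[:, k, :] = x2d.T @ dk
            if dx2d is not None:
                dx2d += dk @ wk[:, k, :].T
        return None if dx2d is None else dx2d.reshape(n, h, w, c)


class Conv1x1(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / cin)
        self.cin, self.cout = cin, cout
        self.params = {
            "W": rng.normal(0.0, std, size=(cin, cout)).astype(F32),
            "b": np.zeros(cout, dtype=F32),
        }
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}
        self._cache = None

    def forward(self, x, **kw):
        n, h, w, c = x.shape
        mat = x.reshape(-1, c)
        y = mat @ self.params["W"] + self.params["b"]
        self._cache = (mat, (n, h, w, c))
        return y.reshape(n, h, w, self.cout)

    def backward(self, dout):
        mat, (n, h, w, c) = self._cache
        dmat = dout.reshape(-1, self.cout)
        self.grads["W"][...] = mat.T @ dmat
        self.grads["b"][...] = dmat.sum(axis=0)
        return (dmat @ self.params["W"].T).reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x, **kw):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    def forward(self, x, **kw):
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
        self._idx = np.argmax(xr, axis=3)
        self._shape = (n, h, w, c)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        n, h, w, c = self._shape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=F32)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :],
                          dout[:, :, :, None, :].astype(F32), axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx).reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, **kw):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dropout(Layer):
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)
        self._mask = None

    def forward(self, x, rng: np.random.Generator | None = None, **kw):
        if rng is None or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(F32) / F32(1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / nin)
        self.params = {"W": rng.normal(0.0, std, size=(nin, nout)).astype(F32),
                       "b": np.zeros(nout, dtype=F32)}
        self.grads = {"W": np.zeros_like(self.params["W"]),
                      "b": np.zeros_like(self.params["b"])}

    def forward(self, x, **kw):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Adam:
    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = []
        for layer in layers:
            for name in layer.params:
                self.slots.append(
                    (layer, name,
                     np.zeros_like(layer.params[name]),
                     np.zeros_like(layer.params[name]))
                )

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for layer, name, m, v in self.slots:
            g = layer.grads[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            layer.params[name] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(F32)


class UNet:
    """U-Net heatmap regressor with dropout after every pool/upsample.

    Encoder levels double the feature width (base ... base * 2^(levels-1));
    each level is two 3x3 conv + ReLU blocks, with 2x2 max-pool downsampling,
    nearest-neighbour upsampling, skip concatenation, and a linear 1x1 output
    head (trained against [0, 1] heatmaps with an MSE loss, no sigmoid).

    Input/output arrays are channels-last ``(N, H, W, C)``.
    """

    def __init__(self, in_channels: int = 21, out_channels: int = 1,
                 levels: int = 4, base_features: int = 8, dropout_p: float = 0.5,
                 rng: np.random.Generator | None = None):
        if levels < 2:
            raise ValueError("levels must be >= 2")
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.levels, self.base_features, self.dropout_p = levels, base_features, dropout_p
        feats = [base_features * 2**i for i in range(levels)]
        self.feats = feats

        self.enc = []
        cin = in_channels
        for i, f in enumerate(feats):
            # nothing consumes the input gradient, so the very first conv skips it
            self.enc.append([Conv3x3(cin, f, rng, compute_dx=(i > 0)), ReLU(),
                             Conv3x3(f, f, rng), ReLU()])
            cin = f
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.pool_drops = [Dropout(dropout_p) for _ in range(levels - 1)]
        self.ups = [Upsample2() for _ in range(levels - 1)]
        self.up_drops = [Dropout(dropout_p) for _ in range(levels - 1)]
        self.dec = []
        for i in range(levels - 2, -1, -1):
            cin = feats[i + 1] + feats[i]
            self.dec.append([Conv3x3(cin, feats[i], rng), ReLU(),
                             Conv3x3(feats[i], feats[i], rng), ReLU()])
        self.head = Conv1x1(feats[0], out_channels, rng)

    # -- plumbing -----------------------------------------------------------
    def layers(self):
        for block in self.enc + self.dec:
            yield from block
        yield from self.pools
        yield from self.pool_drops
        yield from self.ups
        yield from self.up_drops
        yield self.head

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                out[f"layer{i:03d}.{name}"] = p
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i:03d}.{name}"]

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[3] != self.in_channels:
            raise ValueError(
                f"expected (N, H, W, {self.in_channels}) input, got {x.shape}"
            )
        div = 2 ** (self.levels - 1)
        if x.shape[1] % div or x.shape[2] % div:
            raise ValueError(
                f"spatial dims {x.shape[1:3]} must be divisible by {div} "
                f"for a {self.levels}-level network"
            )

    def forward(self, x: np.ndarray, dropout_rng: np.random.Generator | None = None
                ) -> np.ndarray:
        """Forward pass; dropout is active iff ``dropout_rng`` is given."""
        x = np.ascontiguousarray(x, dtype=F32)
        self._check_input(x)
        skips = []
        h = x
        for i, block in enumerate(self.enc):
            for layer in block:
                h = layer.forward(h)
            if i < self.levels - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
                h = self.pool_drops[i].forward(h, rng=dropout_rng)
        self._concat_sizes = []
        for j, block in enumerate(self.dec):
            h = self.ups[j].forward(h)
            h = self.up_drops[j].forward(h, rng=dropout_rng)
            skip = skips[-(j + 1)]
            self._concat_sizes.append((h.shape[3], skip.shape[3]))
            h = np.concatenate([h, skip], axis=3)
            for layer in block:
                h = layer.forward(h)
        return self.head.forward(h)

    def backward(self, dout: np.ndarray) -> None:
        d = self.head.backward(dout)
        dskips = [None] * (self.levels - 1)
        for j in range(len(self.dec) - 1, -1, -1):
            for layer in reversed(self.dec[j]):
                d = layer.backward(d)
            c_up, c_skip = self._concat_sizes[j]
            d_up, d_skip = d[..., :c_up], d[..., c_up:]
            dskips[-(j + 1)] = d_skip
            d = self.up_drops[j].backward(np.ascontiguousarray(d_up))
            d = self.ups[j].backward(d)
        for i in range(self.levels - 1, -1, -1):
            if i < self.levels - 1:
                d = self.pool_drops[i].backward(d)
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            for layer in reversed(self.enc[i]):
                d = layer.backward(d)


class LeNetRegressor:
    """Small LeNet-style CNN regressor: conv blocks + dense head, linear output.

    Channels-last input ``(N, H, W, C)``.
    """

    def __init__(self, in_channels: int, input_hw: tuple[int, int],
                 conv_features: tuple[int, ...] = (8, 16), dense_width: int = 32,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.input_hw = tuple(input_hw)
        self.conv_features = tuple(conv_features)
        self.dense_width = dense_width
        self.blocks = []
        cin = in_channels
        h, w = input_hw
        for i, f in enumerate(conv_features):
            if h % 2 or w % 2:
                raise ValueError("input dims must be divisible by 2 per conv block")
            self.blocks.append([Conv3x3(cin, f, rng, compute_dx=(i > 0)), ReLU(),
                                MaxPool2()])
            cin, h, w = f, h // 2, w // 2
        self.flat_dim = cin * h * w
        self.fc1 = Dense(self.flat_dim, dense_width, rng)
        self.act = ReLU()
        self.fc2 = Dense(dense_width, 1, rng)

    def layers(self):
        for block in self.blocks:
            yield from block
        yield self.fc1
        yield self.act
        yield self.fc2

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers())

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=F32)
        for block in self.blocks:
            for layer in block:
                h = layer.forward(h)
        self._conv_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.act.forward(self.fc1.forward(h))
        return self.fc2.forward(h)[:, 0]

    def backward(self, dout: np.ndarray) -> None:
        d = self.fc2.backward(dout[:, None].astype(F32))
        d = self.fc1.backward(self.act.backward(d))
        d = d.reshape(self._conv_shape)
        for block in reversed(self.blocks):
            for layer in reversed(block):
                d = layer.backward(d)

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers()):
            for name, p in layer.params.items():
                out[f"layer{i:03d}.{name}"] = p
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{i:03d}.{name}"]
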