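"""Minimal 3D convolutional network engine on numpy.

All networks in this package (the adversarial synthesizer and the
registration/segmentation detector) are built from the layers here. Design
constraints, in order: correctness of gradients (verified by
finite-difference tests), bit-reproducibility given a seed, and speed on a
single CPU at patch scale (32^3). Convolutions are lowered to a single BLAS
matmul per layer via an im2col buffer; backward passes are written by hand.

Tensors are (N, C, D, H, W) float32 arrays; a ``dtype`` argument on every
constructor allows float64 for numerical gradient checks.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

DEFAULT_DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name


class Layer:
    def params(self) -> List[Param]:
        return []

    def state(self) -> List[np.ndarray]:
        """All arrays needed to reproduce inference (params + buffers)."""
        return [p.data for p in self.params()]

    def load_state(self, arrays: List[np.ndarray]) -> None:
        own = self.state()
        if len(own) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src


def _he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


_OFFSETS3 = [(a, b, c) for a in range(3) for b in range(3) for c in range(3)]
_OFFSETS2 = [(a, b, c) for a in range(2) for b in range(2) for c in range(2)]

#: Global scratch-buffer pool shared by all convolution layers. The large
#: im2col buffers are transient within a single forward or backward call, so
#: one buffer per (role, shape, dtype) suffices for the whole process; this
#: bounds peak memory and avoids page-fault churn from per-step reallocation.
_SCRATCH: Dict[tuple, np.ndarray] = {}


def _scratch(role: str, shape, dtype) -> np.ndarray:
    key = (role, tuple(shape), np.dtype(dtype).str)
    buf = _SCRATCH.get(key)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        _SCRATCH[key] = buf
    return buf


class Conv3d(Layer):
    """3x3x3 (pad 1) or 1x1x1 convolution, stride 1."""

    def __init__(self, cin, cout, k=3, rng=None, dtype=DEFAULT_DTYPE, zero_init=False):
        if k not in (1, 3):
            raise ValueError("kernel size must be 1 or 3")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k**3
        if zero_init:
            w = np.zeros((cout, fan_in), dtype=dtype)
        else:
            w = _he_init(rng, (cout, fan_in), fan_in, dtype)
        self.w = Param(w, "conv_w")
        self.b = Param(np.zeros(cout, dtype=dtype), "conv_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _col(self, x):
        """im2col into a shared scratch buffer; valid only until the next
        convolution touches a buffer of the same shape."""
        N, C, D, H, W = x.shape
        V = D * H * W
        if self.k == 1:
            return x.reshape(N, C, V)
        xp = _scratch("pad", (N, C, D + 2, H + 2, W + 2), x.dtype)
        xp.fill(0)
        xp[:, :, 1:-1, 1:-1, 1:-1] = x
        col = _scratch("col", (N, C * 27, V), x.dtype)
        view = col.reshape(N, C, 27, V)
        for o, (dz, dy, dx) in enumerate(_OFFSETS3):
            view[:, :, o, :] = xp[:, :, dz : dz + D, dy : dy + H, dx : dx + W].reshape(
                N, C, V
            )
        return col

    def forward(self, x, train=True):
        N, C, D, H, W = x.shape
        col = self._col(x)
        out = np.matmul(self.w.data, col) + self.b.data[:, None]
        if train:
            self._cache = x  # col is rebuilt in backward (scratch is shared)
        return out.reshape(N, self.cout, D, H, W)

    def backward(self, g):
        x = self._cache
        N, C, D, H, W = x.shape
        V = D * H * W
        gf = g.reshape(N, self.cout, V)
        col = self._col(x)
        self.w.grad += np.matmul(gf, col.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += gf.sum(axis=(0, 2))
        dcol = np.matmul(
            self.w.data.T, gf, out=_scratch("dcol", (N, C * self.k**3, V), g.dtype)
        )
        if self.k == 1:
            return dcol.reshape(N, C, D, H, W).copy()
        dview = dcol.reshape(N, C, 27, V)
        dxp = _scratch("dpad", (N, C, D + 2, H + 2, W + 2), g.dtype)
        dxp.fill(0)
        for o, (dz, dy, dx) in enumerate(_OFFSETS3):
            dxp[:, :, dz : dz + D, dy : dy + H, dx : dx + W] += dview[:, :, o].reshape(
                N, C, D, H, W
            )
        return dxp[:, :, 1:-1, 1:-1, 1:-1].copy()


class ConvDown(Layer):
    """Strided 2x2x2 convolution (the pooling-by-striding of the residual
    blocks); halves every spatial dimension."""

    def __init__(self, cin, cout, rng=None, dtype=DEFAULT_DTYPE):
        self.cin, self.cout = cin, cout
        fan_in = cin * 8
        self.w = Param(_he_init(rng, (cout, fan_in), fan_in, dtype), "down_w")
        self.b = Param(np.zeros(cout, dtype=dtype), "down_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def _col(self, x):
        N, C, D, H, W = x.shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        V2 = D2 * H2 * W2
        col = _scratch("dcol2", (N, C * 8, V2), x.dtype)
        view = col.reshape(N, C, 8, V2)
        for o, (dz, dy, dx) in enumerate(_OFFSETS2):
            view[:, :, o, :] = x[:, :, dz::2, dy::2, dx::2].reshape(N, C, V2)
        return col

    def forward(self, x, train=True):
        N, C, D, H, W = x.shape
        if D % 2 or H % 2 or W % 2:
            raise ValueError("spatial dims must be even for 2x downsampling")
        col = self._col(x)
        out = np.matmul(self.w.data, col) + self.b.data[:, None]
        if train:
            self._cache = x
        return out.reshape(N, self.cout, D // 2, H // 2, W // 2)

    def backward(self, g):
        x = self._cache
        N, C, D, H, W = x.shape
        D2, H2, W2 = D // 2, H // 2, W // 2
        V2 = D2 * H2 * W2
        gf = g.reshape(N, self.cout, V2)
        col = self._col(x)
        self.w.grad += np.matmul(gf, col.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += gf.sum(axis=(0, 2))
        dview = np.matmul(self.w.data.T, gf).reshape(N, C, 8, V2)
        dx = np.zeros((N, C, D, H, W), dtype=g.dtype)
        for o, (dz, dy, dx_) in enumerate(_OFFSETS2):
            dx[:, :, dz::2, dy::2, dx_::2] += dview[:, :, o].reshape(N, C, D2, H2, W2)
        return dx


class ConvUp(Layer):
    """Transposed 2x2x2 stride-2 convolution; doubles every spatial dim."""

    def __init__(self, cin, cout, rng=None, dtype=DEFAULT_DTYPE):
        self.cin, self.cout = cin, cout
        self.w = Param(_he_init(rng, (cout * 8, cin), cin, dtype), "up_w")
        self.b = Param(np.zeros(cout, dtype=dtype), "up_b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        N, C, D, H, W = x.shape
        V = D * H * W
        xf = x.reshape(N, C, V)
        parts = np.matmul(self.w.data, xf).reshape(N, self.cout, 8, V)
        out = np.empty((N, self.cout, 2 * D, 2 * H, 2 * W), dtype=x.dtype)
        for o, (dz, dy, dx) in enumerate(_OFFSETS2):
            out[:, :, dz::2, dy::2, dx::2] = parts[:, :, o].reshape(N, self.cout, D, H, W)
        out += self.b.data[None, :, None, None, None]
        if train:
            self._cache = (x.shape, xf)
        return out

    def backward(self, g):
        (N, C, D, H, W), xf = self._cache
        V = D * H * W
        gparts = np.empty((N, self.cout, 8, V), dtype=g.dtype)
        for o, (dz, dy, dx) in enumerate(_OFFSETS2):
            gparts[:, :, o] = g[:, :, dz::2, dy::2, dx::2].reshape(N, self.cout, V)
        gpf = gparts.reshape(N, self.cout * 8, V)
        self.w.grad += np.matmul(gpf, xf.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += g.sum(axis=(0, 2, 3, 4))
        return np.matmul(self.w.data.T, gpf).reshape(N, C, D, H, W)


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W)."""

    def __init__(self, c, eps=1e-5, momentum=0.1, dtype=DEFAULT_DTYPE):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Param(np.ones(c, dtype=dtype), "bn_gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "bn_beta")
        self.run_mean = np.zeros(c, dtype=dtype)
        self.run_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def state(self):
        return [self.gamma.data, self.beta.data, self.run_mean, self.run_var]

    def forward(self, x, train=True):
        sh = (1, self.c, 1, 1, 1)
        if train:
            mu = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.run_mean += self.momentum * (mu.astype(self.run_mean.dtype) - self.run_mean)
            self.run_var += self.momentum * (var.astype(self.run_var.dtype) - self.run_var)
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(sh)) * ivar.reshape(sh)
            self._cache = (xhat, ivar)
        else:
            ivar = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean.reshape(sh)) * ivar.reshape(sh)
        return self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)

    def backward(self, g):
        xhat, ivar = self._cache
        sh = (1, self.c, 1, 1, 1)
        axes = (0, 2, 3, 4)
        n = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gsum = g.sum(axis=axes).reshape(sh)
        gx_sum = (g * xhat).sum(axis=axes).reshape(sh)
        return (
            self.gamma.data.reshape(sh)
            * ivar.reshape(sh)
            / n
            * (n * g - gsum - xhat * gx_sum)
        )


class ReLU(Layer):
    def forward(self, x, train=True):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g):
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=True):
        out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, g):
        return g * self._out * (1.0 - self._out)


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C)."""

    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, g):
        N, C, D, H, W = self._shape
        return np.broadcast_to(
            g[:, :, None, None, None] / (D * H * W), self._shape
        ).astype(g.dtype).copy()


class Linear(Layer):
    def __init__(self, cin, cout, rng=None, dtype=DEFAULT_DTYPE):
        self.w = Param(_he_init(rng, (cout, cin), cin, dtype), "lin_w")
        self.b = Param(np.zeros(cout, dtype=dtype), "lin_b")

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, g):
        self.w.grad += g.T @ self._x
        self.b.grad += g.sum(axis=0)
        return g @ self.w.data


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return list(itertools.chain.from_iterable(l.params() for l in self.layers))

    def state(self):
        return list(itertools.chain.from_iterable(l.state() for l in self.layers))

    def load_state(self, arrays):
        i = 0
        for l in self.layers:
            n = len(l.state())
            l.load_state(arrays[i : i + n])
            i += n

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class ResBlock(Layer):
    """Residual block: two 3x3x3 convolutions each followed by batch
    normalization; identity (or 1x1x1-projected) skip added before the
    final rectification."""

    def __init__(self, cin, cout, rng=None, dtype=DEFAULT_DTYPE):
        self.main = Sequential(
            Conv3d(cin, cout, 3, rng, dtype),
            BatchNorm3d(cout, dtype=dtype),
            ReLU(),
            Conv3d(cout, cout, 3, rng, dtype),
            BatchNorm3d(cout, dtype=dtype),
        )
        self.proj = None if cin == cout else Conv3d(cin, cout, 1, rng, dtype)
        self.relu = ReLU()

    def params(self):
        ps = self.main.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def state(self):
        s = self.main.state()
        if self.proj is not None:
            s += self.proj.state()
        return s

    def load_state(self, arrays):
        n = len(self.main.state())
        self.main.load_state(arrays[:n])
        if self.proj is not None:
            self.proj.load_state(arrays[n:])

    def forward(self, x, train=True):
        m = self.main.forward(x, train)
        s = x if self.proj is None else self.proj.forward(x, train)
        return self.relu.forward(m + s, train)

    def backward(self, g):
        g = self.relu.backward(g)
        gx = self.main.backward(g)
        gx = gx + (g if self.proj is None else self.proj.backward(g))
        return gx


class UNet3D(Layer):
    """Encoder/decoder with residual blocks and summation skip connections.

    ``depth`` downsamplings; channel width doubles per level from
    ``base_width`` (capped). The head is a 1x1x1 convolution to
    ``cout`` channels, optionally zero-initialized (used for displacement
    fields so training starts at the identity warp) and optionally followed
    by a sigmoid.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        base_width: int = 8,
        depth: int = 2,
        rng=None,
        final: Optional[str] = None,
        head_zero_init: bool = False,
        width_cap: int = 64,
        dtype=DEFAULT_DTYPE,
    ):
        widths = [min(base_width * 2**l, width_cap) for l in range(depth + 1)]
        self.depth = depth
        self.widths = widths
        self.stem = Conv3d(cin, widths[0], 3, rng, dtype)
        self.enc = [ResBlock(widths[l], widths[l], rng, dtype) for l in range(depth)]
        self.down = [ConvDown(widths[l], widths[l + 1], rng, dtype) for l in range(depth)]
        self.bottleneck = ResBlock(widths[depth], widths[depth], rng, dtype)
        self.up = [ConvUp(widths[l + 1], widths[l], rng, dtype) for l in range(depth)]
        self.dec = [ResBlock(widths[l], widths[l], rng, dtype) for l in range(depth)]
        self.head = Conv3d(widths[0], cout, 1, rng, dtype, zero_init=head_zero_init)
        if final not in (None, "sigmoid"):
            raise ValueError("final must be None or 'sigmoid'")
        self.final = Sigmoid() if final == "sigmoid" else None

    def _sublayers(self):
        yield self.stem
        yield from self.enc
        yield from self.down
        yield self.bottleneck
        yield from self.up
        yield from self.dec
        yield self.head
        if self.final is not None:
            yield self.final

    def params(self):
        return list(itertools.chain.from_iterable(l.params() for l in self._sublayers()))

    def state(self):
        return list(itertools.chain.from_iterable(l.state() for l in self._sublayers()))

    def load_state(self, arrays):
        i = 0
        for l in self._sublayers():
            n = len(l.state())
            l.load_state(arrays[i : i + n])
            i += n

    def forward(self, x, train=True):
        side = min(x.shape[2:])
        if side % (2**self.depth):
            raise ValueError(
                f"patch side {side} not divisible by 2^{self.depth}"
            )
        h = self.stem.forward(x, train)
        skips = []
        for l in range(self.depth):
            h = self.enc[l].forward(h, train)
            skips.append(h)
            h = self.down[l].forward(h, train)
        h = self.bottleneck.forward(h, train)
        for l in reversed(range(self.depth)):
            h = self.up[l].forward(h, train)
            h = h + skips[l]  # summation merge
            h = self.dec[l].forward(h, train)
        h = self.head.forward(h, train)
        if self.final is not None:
            h = self.final.forward(h, train)
        return h

    def backward(self, g):
        if self.final is not None:
            g = self.final.backward(g)
        g = self.head.backward(g)
        skip_grads = [None] * self.depth
        for l in range(self.depth):
            g = self.dec[l].backward(g)
            skip_grads[l] = g
            g = self.up[l].backward(g)
        g = self.bottleneck.backward(g)
        for l in reversed(range(self.depth)):
            g = self.down[l].backward(g)
            g = g + skip_grads[l]
            g = self.enc[l].backward(g)
        return self.stem.backward(g)


class ResNetScorer(Layer):
    """Patch discriminator: stem conv, ``n_blocks`` residual blocks each
    followed by stride-2 pooling, global average pool, linear head giving
    one real/fake logit per patch."""

    def __init__(self, cin=1, base_width=8, n_blocks=4, rng=None, width_cap=64,
                 dtype=DEFAULT_DTYPE):
        widths = [min(base_width * 2**l, width_cap) for l in range(n_blocks + 1)]
        layers: List[Layer] = [Conv3d(cin, widths[0], 3, rng, dtype)]
        for l in range(n_blocks):
            layers.append(ResBlock(widths[l], widths[l], rng, dtype))
            layers.append(ConvDown(widths[l], widths[l + 1], rng, dtype))
        self.body = Sequential(*layers)
        self.pool = GlobalAvgPool()
        self.headlin = Linear(widths[n_blocks], 1, rng, dtype)

    def params(self):
        return self.body.params() + self.headlin.params()

    def state(self):
        return self.body.state() + self.headlin.state()

    def load_state(self, arrays):
        n = len(self.body.state())
        self.body.load_state(arrays[:n])
        self.headlin.load_state(arrays[n:])

    def forward(self, x, train=True):
        h = self.body.forward(x, train)
        h = self.pool.forward(h, train)
        return self.headlin.forward(h, train)[:, 0]

    def backward(self, g):
        g = self.headlin.backward(g[:, None])
        g = self.pool.backward(g)
        return self.body.backward(g)


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: Sequence[Param], lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.b1) * (p.grad - m)
            v += (1 - self.b2) * (p.grad**2 - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# losses (each returns (scalar loss, gradient wrt its first argument))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits (numerically stable)."""
    t = np.broadcast_to(targets, logits.shape)
    loss = np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits)))
    p = 1.0 / (1.0 + np.exp(-logits))
    return float(loss.mean()), ((p - t) / logits.size).astype(logits.dtype)


def l1_loss(pred, target, weight=None) -> Tuple[float, np.ndarray]:
    """(Weighted) mean absolute error."""
    d = pred - target
    if weight is None:
        return float(np.abs(d).mean()), (np.sign(d) / d.size).astype(pred.dtype)
    wsum = float(weight.sum())
    if wsum == 0:
        return 0.0, np.zeros_like(pred)
    loss = float((weight * np.abs(d)).sum() / wsum)
    return loss, (weight * np.sign(d) / wsum).astype(pred.dtype)


def mse_loss(pred, target, weight=None) -> Tuple[float, np.ndarray]:
    d = pred - target
    if weight is None:
        return float((d**2).mean()), (2 * d / d.size).astype(pred.dtype)
    wsum = float(weight.sum())
    if wsum == 0:
        return 0.0, np.zeros_like(pred)
    return float((weight * d**2).sum() / wsum), (2 * weight * d / wsum).astype(pred.dtype)


def softmax_ce(
    logits: np.ndarray, labels: np.ndarray, class_weights: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """Per-voxel weighted cross-entropy.

    logits: (N, K, ...); labels: integer (N, ...); class_weights: (K,).
    """
    K = logits.shape[1]
    mx = logits.max(axis=1, keepdims=True)
    ex = np.exp(logits - mx)
    Z = ex.sum(axis=1, keepdims=True)
    p = ex / Z
    logp = (logits - mx) - np.log(Z)
    onehot = np.moveaxis(np.eye(K, dtype=logits.dtype)[labels], -1, 1)
    if class_weights is None:
        class_weights = np.ones(K, dtype=logits.dtype)
    w = class_weights[labels][:, None]  # (N,1,...)
    wsum = float(w.sum())
    loss = float(-(w * onehot * logp).sum() / wsum)
    grad = (w * (p - onehot) / wsum).astype(logits.dtype)
    return loss, grad


# ---------------------------------------------------------------------------
# differentiable trilinear warping


def warp3d(img: np.ndarray, disp: np.ndarray):
    """Warp ``img`` (N, C, D, H, W) by ``disp`` (N, 3, D, H, W) voxel units.

    out(v) = img sampled at v + disp(v), trilinear, 0 outside the field of
    view. Returns (out, cache) for :func:`warp3d_backward`, which gives the
    gradient with respect to the displacement.
    """
    N, C, D, H, W = img.shape
    if disp.shape != (N, 3, D, H, W):
        raise ValueError("displacement grid does not match the image grid")
    gz, gy, gx = np.meshgrid(
        np.arange(D, dtype=disp.dtype),
        np.arange(H, dtype=disp.dtype),
        np.arange(W, dtype=disp.dtype),
        indexing="ij",
    )
    z = gz[None] + disp[:, 0]
    y = gy[None] + disp[:, 1]
    x = gx[None] + disp[:, 2]
    z0 = np.floor(z).astype(np.int64)
    y0 = np.floor(y).astype(np.int64)
    x0 = np.floor(x).astype(np.int64)
    fz, fy, fx = z - z0, y - y0, x - x0
    out = np.zeros_like(img)
    corners = []
    nidx = np.arange(N)[:, None, None, None]
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                zi, yi, xi = z0 + dz, y0 + dy, x0 + dx
                valid = (
                    (zi >= 0) & (zi < D) & (yi >= 0) & (yi < H) & (xi >= 0) & (xi < W)
                )
                zc = np.clip(zi, 0, D - 1)
                yc = np.clip(yi, 0, H - 1)
                xc = np.clip(xi, 0, W - 1)
                v = img[nidx, :, zc, yc, xc]  # (N, D, H, W, C) via advanced idx
                v = np.moveaxis(v, -1, 1) * valid[:, None]
                wz = fz if dz else (1 - fz)
                wy = fy if dy else (1 - fy)
                wx = fx if dx else (1 - fx)
                out += (wz * wy * wx)[:, None] * v
                corners.append((v, dz, dy, dx))
    cache = (corners, fz, fy, fx)
    return out, cache


def warp3d_backward(g: np.ndarray, cache) -> np.ndarray:
    """Gradient of the warp output wrt the displacement field, (N,3,D,H,W)."""
    corners, fz, fy, fx = cache
    gz = np.zeros(fz.shape, dtype=g.dtype)
    gy = np.zeros_like(gz)
    gx = np.zeros_like(gz)
    for v, dz, dy, dx in corners:
        wz = fz if dz else (1 - fz)
        wy = fy if dy else (1 - fy)
        wx = fx if dx else (1 - fx)
        sz = 1.0 if dz else -1.0
        sy = 1.0 if dy else -1.0
        sx = 1.0 if dx else -1.0
        gv = (g * v).sum(axis=1)  # contract channels
        gz += gv * sz * wy * wx
        gy += gv * wz * sy * wx
        gx += gv * wz * wy * sx
    return np.stack([gz, gy, gx], axis=1)


def smoothness_penalty(disp: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean over voxels of the summed squared forward differences of each
    displacement channel along each axis; batched (N, 3, D, H, W).

    For a linear field d_c(v) = alpha * v_c this evaluates to 3 * alpha^2.
    """
    loss = 0.0
    grad = np.zeros_like(disp)
    N = disp.shape[0]
    for axis in (2, 3, 4):
        d = np.diff(disp, axis=axis)
        n = d[0, 0].size  # voxel count of the diff grid, per channel
        loss += float((d**2).sum() / (n * N))
        gd = 2.0 * d / (n * N)
        sl_lo = [slice(None)] * 5
        sl_hi = [slice(None)] * 5
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        grad[tuple(sl_hi)] += gd
        grad[tuple(sl_lo)] -= gd
    return loss, grad.astype(disp.dtype)


def collect_state(layers: Sequence[Layer]) -> List[np.ndarray]:
    return list(itertools.chain.from_iterable(l.state() for l in layers))


def load_state(layers: Sequence[Layer], arrays: List[np.ndarray]) -> None:
    i = 0
    for l in layers:
        n = len(l.state())
        l.load_state(arrays[i : i + n])
        i += n
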