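"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the translation networks need: broadcasted
arithmetic, matmul, pointwise nonlinearities, 2-D convolution via im2col,
reflection/zero padding, nearest-neighbour upsampling, instance
normalisation, spatial feature gathering, L2 normalisation, and a DFT power
term.  Gradients are accumulated through a topologically sorted tape.

The engine is dtype-agnostic (float32 in training, float64 in the numerical
gradient checks of the test-suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "neg", "sub", "pow_", "matmul",
    "relu", "leaky_relu", "tanh", "sigmoid", "logsigmoid",
    "exp", "log", "abs_", "sum_", "mean",
    "reshape", "transpose", "pad2d", "conv2d", "upsample_nearest2x",
    "instance_norm", "gather_hw", "l2_normalize", "fft_power_mean",
    "concat",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- convenience -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return pow_(self, p)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, _wrap(1.0 / other))
        return mul(self, pow_(_wrap(other), -1.0))

    # -- backprop --------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (9 residual blocks)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents and not node.requires_grad:
                # free intermediate gradients eagerly
                node.grad = None


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward, track: bool) -> Tensor:
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    track = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, track)


def mul(a: Tensor, b: Tensor) -> Tensor:
    track = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, track)


def neg(a: Tensor) -> Tensor:
    track = _needs_grad(a)

    def backward(g):
        _accum(a, -g)

    return _make(-a.data, (a,), backward, track)


def sub(a: Tensor, b: Tensor) -> Tensor:
    track = _needs_grad(a, b)

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(a.data - b.data, (a, b), backward, track)


def pow_(a: Tensor, p: float) -> Tensor:
    track = _needs_grad(a)
    out_data = a.data ** p

    def backward(g):
        _accum(a, g * (p * a.data ** (p - 1)))

    return _make(out_data, (a,), backward, track)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    track = _needs_grad(a, b)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accum(a, _unbroadcast(ga, a.data.shape))
        _accum(b, _unbroadcast(gb, b.data.shape))

    return _make(np.matmul(a.data, b.data), (a, b), backward, track)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward, track)


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    track = _needs_grad(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope).astype(a.data.dtype)

    def backward(g):
        _accum(a, g * scale)

    return _make(a.data * scale, (a,), backward, track)


def tanh(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    out_data = np.tanh(a.data)

    def backward(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), backward, track)


def sigmoid(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward, track)


def logsigmoid(a: Tensor) -> Tensor:
    """log(sigmoid(x)) computed stably as -log(1 + exp(-x))."""
    track = _needs_grad(a)
    out_data = -np.logaddexp(np.zeros((), dtype=a.data.dtype), -a.data)

    def backward(g):
        _accum(a, g / (1.0 + np.exp(a.data)))

    return _make(out_data, (a,), backward, track)


def exp(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), backward, track)


def log(a: Tensor) -> Tensor:
    track = _needs_grad(a)

    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward, track)


def abs_(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    sign = np.sign(a.data)

    def backward(g):
        _accum(a, g * sign)

    return _make(np.abs(a.data), (a,), backward, track)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    track = _needs_grad(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return _make(out_data, (a,), backward, track)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return sum_(a, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    track = _needs_grad(a)
    orig = a.data.shape

    def backward(g):
        _accum(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward, track)


def transpose(a: Tensor, axes) -> Tensor:
    track = _needs_grad(a)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward, track)


def concat(tensors: list, axis: int = 0) -> Tensor:
    track = any(_needs_grad(t) for t in tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward, track)


# ---------------------------------------------------------------------------
# image ops
# ---------------------------------------------------------------------------

def _unpad_axis_reflect(g: np.ndarray, p: int, axis: int) -> np.ndarray:
    """Adjoint of single-axis reflection padding (no edge repeat)."""
    sl = [slice(None)] * g.ndim
    sl[axis] = slice(p, g.shape[axis] - p)
    core = g[tuple(sl)].copy()
    if p > 0:
        left = [slice(None)] * g.ndim
        left[axis] = slice(p - 1, None, -1)
        tgt = [slice(None)] * g.ndim
        tgt[axis] = slice(1, p + 1)
        core[tuple(tgt)] += g[tuple(left)]
        right = [slice(None)] * g.ndim
        right[axis] = slice(g.shape[axis] - 1, g.shape[axis] - p - 1, -1)
        tgt[axis] = slice(core.shape[axis] - p - 1, core.shape[axis] - 1)
        core[tuple(tgt)] += g[tuple(right)]
    return core


def pad2d(a: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the trailing two axes of an NCHW tensor."""
    if pad == 0:
        return a
    track = _needs_grad(a)
    width = [(0, 0)] * (a.data.ndim - 2) + [(pad, pad), (pad, pad)]
    if mode == "reflect":
        out_data = np.pad(a.data, width, mode="reflect")

        def backward(g):
            g = _unpad_axis_reflect(g, pad, a.data.ndim - 2)
            g = _unpad_axis_reflect(g, pad, a.data.ndim - 1)
            _accum(a, g)
    elif mode == "zeros":
        out_data = np.pad(a.data, width, mode="constant")

        def backward(g):
            sl = [slice(None)] * g.ndim
            sl[-2] = slice(pad, g.shape[-2] - pad)
            sl[-1] = slice(pad, g.shape[-1] - pad)
            _accum(a, g[tuple(sl)])
    else:
        raise ValueError(f"unknown pad mode {mode!r}")

    return _make(out_data, (a,), backward, track)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    Batch-1 stride-1 calls take a kernel-offset (shift) accumulation path
    that avoids the large im2col transposes; everything else uses im2col.
    Both routes share the same contract and gradients.
    """
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    o, ci, kh, kw = wd.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, weight {ci}")
    if stride == 1 and n == 1:
        return _conv2d_shift(x, w, b)
    s = stride
    ho = (h - kh) // s + 1
    wo = (wdt - kw) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # N,C,Ho,Wo,kh,kw
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    col = col.reshape(n, ho * wo, c * kh * kw)      # N,P,K
    wflat = wd.reshape(o, -1)                        # O,K
    y = np.matmul(col, wflat.T)                      # N,P,O
    if b is not None:
        y = y + b.data
    out_data = np.ascontiguousarray(y.transpose(0, 2, 1)).reshape(n, o, ho, wo)
    track = _needs_grad(x, w) or (b is not None and _needs_grad(b))

    def backward(g):
        gy = np.ascontiguousarray(
            g.reshape(n, o, ho * wo).transpose(0, 2, 1))  # N,P,O
        if w.requires_grad or w._parents:
            gw = np.tensordot(gy, col, axes=([0, 1], [0, 1]))  # O,K
            _accum(w, gw.reshape(wd.shape))
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, gy.sum(axis=(0, 1)))
        if x.requires_grad or x._parents:
            gcol = np.matmul(gy, wflat)                       # N,P,K
            gcol = gcol.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            gx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcol[:, :, i, j]
            _accum(x, gx)

    return _make(out_data, (x, w) if b is None else (x, w, b), backward, track)


def _conv2d_shift(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Stride-1, batch-1 convolution as a sum of shifted 1x1 matmuls."""
    xd = x.data[0]                                   # C,Hp,Wp
    wd = w.data
    o, c, kh, kw = wd.shape
    hp, wp = xd.shape[1:]
    ho, wo = hp - kh + 1, wp - kw + 1
    track = _needs_grad(x, w) or (b is not None and _needs_grad(b))
    acc = np.zeros((o, ho * wo), dtype=xd.dtype)
    slices: list = []
    for i in range(kh):
        for j in range(kw):
            xs = xd[:, i:i + ho, j:j + wo].reshape(c, -1)  # copies (strided)
            acc += wd[:, :, i, j] @ xs
            if track:
                slices.append(xs)
    if b is not None:
        acc = acc + b.data[:, None]
    out_data = acc.reshape(1, o, ho, wo)

    def backward(g):
        g2 = np.ascontiguousarray(g.reshape(o, ho * wo))
        want_x = x.requires_grad or x._parents
        want_w = w.requires_grad or w._parents
        gw = np.empty_like(wd) if want_w else None
        gx = np.zeros_like(xd) if want_x else None
        idx = 0
        for i in range(kh):
            for j in range(kw):
                xs = slices[idx]
                idx += 1
                if want_w:
                    gw[:, :, i, j] = g2 @ xs.T
                if want_x:
                    gx[:, i:i + ho, j:j + wo] += (wd[:, :, i, j].T @ g2).reshape(c, ho, wo)
        if want_w:
            _accum(w, gw)
        if want_x:
            _accum(x, gx[None])
        if b is not None and (b.requires_grad or b._parents):
            _accum(b, g2.sum(axis=1))

    return _make(out_data, (x, w) if b is None else (x, w, b), backward, track)


def upsample_nearest2x(a: Tensor) -> Tensor:
    track = _needs_grad(a)
    out_data = a.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def backward(g):
        n, c, h2, w2 = g.shape
        _accum(a, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (a,), backward, track)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes (no affine)."""
    xd = x.data
    mu = xd.mean(axis=(-2, -1), keepdims=True)
    var = xd.var(axis=(-2, -1), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (xd - mu) * inv
    track = _needs_grad(x)

    def backward(g):
        m = xd.shape[-2] * xd.shape[-1]
        gm = g.mean(axis=(-2, -1), keepdims=True)
        gym = (g * y).mean(axis=(-2, -1), keepdims=True)
        _accum(x, inv * (g - gm - y * gym))
        del m

    return _make(y, (x,), backward, track)


def gather_hw(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick feature vectors at flattened spatial indices: NCHW -> (N, P, C)."""
    n, c, h, w = x.data.shape
    idx = np.asarray(idx, dtype=np.intp)
    if idx.ndim != 1:
        raise ValueError("idx must be a 1-D array of flat spatial indices")
    if idx.size and (idx.min() < 0 or idx.max() >= h * w):
        raise ValueError("patch location out of bounds for feature map")
    flat = x.data.reshape(n, c, h * w)
    out_data = np.ascontiguousarray(flat[:, :, idx].transpose(0, 2, 1))  # N,P,C
    track = _needs_grad(x)

    def backward(g):
        gx = np.zeros((n, c, h * w), dtype=x.data.dtype)
        np.add.at(gx, (slice(None), slice(None), idx), g.transpose(0, 2, 1))
        _accum(x, gx.reshape(n, c, h, w))

    return _make(out_data, (x,), backward, track)


def l2_normalize(a: Tensor, eps: float = 1e-12) -> Tensor:
    """Unit-normalise along the last axis."""
    norm = np.sqrt((a.data ** 2).sum(axis=-1, keepdims=True)) + eps
    y = a.data / norm
    track = _needs_grad(a)

    def backward(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _accum(a, (g - y * dot) / norm)

    return _make(y, (a,), backward, track)


def fft_power_mean(a: Tensor) -> Tensor:
    """Mean over frequency bins of |DFT2(a)|^2 (unnormalised forward DFT).

    By Parseval's theorem this equals (H*W) times the pixel-domain mean
    square, which yields the exact analytic gradient 2*a/len(leading dims).
    The forward pass genuinely evaluates the DFT.
    """
    f = np.fft.fft2(a.data, axes=(-2, -1))
    out_data = np.asarray(np.mean(np.abs(f) ** 2), dtype=a.data.dtype)
    track = _needs_grad(a)
    lead = int(np.prod(a.data.shape[:-2])) if a.data.ndim > 2 else 1

    def backward(g):
        _accum(a, g * (2.0 / lead) * a.data)

    return _make(out_data, (a,), backward, track)
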