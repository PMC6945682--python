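"""Minimal reverse-mode automatic differentiation on numpy arrays.

This engine powers the differentiable losses and the disparity network. It
implements exactly the operator set the method needs — elementwise
arithmetic, activations, global reductions, 2-D convolution, box filtering,
nearest-neighbour upsampling, edge padding, concatenation, horizontal
flipping and the 1-D bilinear warp used for view synthesis — each with an
analytic backward pass. Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted tape.

Arrays follow the NCHW layout where spatial structure matters; elementwise
ops broadcast like numpy and un-broadcast their gradients accordingly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "parameter", "sigmoid", "elu", "exp",
           "absolute", "square", "concat", "pad_edge2d", "upsample2x",
           "flip_h", "conv2d", "box_filter", "warp1d", "masked_mean"]


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------ tape
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or not t.requires_grad:
                continue
            if not t._parents:
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------ operators
    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b,
                       lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b,
                       lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b,
                       lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b,
                       lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unary(self, lambda a: -a, lambda g, a: -g)

    def __pow__(self, k):
        if not np.isscalar(k):
            raise TypeError("only scalar exponents are supported")
        return _unary(self, lambda a: a ** k,
                      lambda g, a: g * k * a ** (k - 1))

    def sum(self):
        t = self
        return Tensor(self.data.sum(keepdims=False), parents=(t,),
                      backward=lambda g: (np.broadcast_to(g, t.data.shape),))

    def mean(self):
        return self.sum() / self.data.size

    def reshape(self, *shape):
        t = self
        old = self.data.shape
        return Tensor(self.data.reshape(*shape), parents=(t,),
                      backward=lambda g: (g.reshape(old),))

    def __getitem__(self, key):
        t = self

        def backward(g):
            gx = np.zeros_like(t.data)
            gx[key] = g
            return (gx,)

        return Tensor(self.data[key].copy(), parents=(t,), backward=backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a, b, fwd, bwd) -> Tensor:
    # keep python scalars at the array operand's dtype (no float64 creep)
    if isinstance(a, Tensor) and np.isscalar(b):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and np.isscalar(a):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        ga, gb = bwd(g, a.data, b.data)
        return (_unbroadcast(ga, a.data.shape) if ga is not None else None,
                _unbroadcast(gb, b.data.shape) if gb is not None else None)

    return Tensor(fwd(a.data, b.data), parents=(a, b), backward=backward)


def _unary(a, fwd, bwd) -> Tensor:
    a = as_tensor(a)
    return Tensor(fwd(a.data), parents=(a,),
                  backward=lambda g: (bwd(g, a.data),))


# ------------------------------------------------------------ activations

def exp(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))
    out._backward = lambda g: (g * out.data,)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: (g * out.data * (1.0 - out.data),)
    return out


def elu(a, alpha: float = 1.0) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    expneg = np.exp(np.minimum(a.data, 0.0))
    val = np.where(pos, a.data, alpha * (expneg - 1.0))
    return Tensor(val, parents=(a,), backward=lambda g: (
        g * np.where(pos, 1.0, alpha * expneg),))


def absolute(a) -> Tensor:
    return _unary(a, np.abs, lambda g, x: g * np.sign(x))


def square(a) -> Tensor:
    return _unary(a, np.square, lambda g, x: 2.0 * g * x)


# ------------------------------------------------------- shape utilities

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=backward)


def _edge_pad_backward(g: np.ndarray, h: int, w: int, pad: int) -> np.ndarray:
    """Adjoint of edge-replicated padding: fold pad gradients onto edges."""
    p = pad
    g2 = g[..., :, p:w + p].copy()
    g2[..., :, 0] += g[..., :, :p].sum(axis=-1)
    g2[..., :, -1] += g[..., :, w + p:].sum(axis=-1)
    gx = g2[..., p:h + p, :].copy()
    gx[..., 0, :] += g2[..., :p, :].sum(axis=-2)
    gx[..., -1, :] += g2[..., h + p:, :].sum(axis=-2)
    return gx


def pad_edge2d(a, pad: int) -> Tensor:
    """Edge-replicated padding of the two trailing spatial axes."""
    a = as_tensor(a)
    h, w = a.data.shape[-2:]
    iy = np.clip(np.arange(-pad, h + pad), 0, h - 1)
    ix = np.clip(np.arange(-pad, w + pad), 0, w - 1)
    out_data = a.data[..., iy[:, None], ix[None, :]]

    def backward(g):
        return (_edge_pad_backward(g, h, w, pad),)

    return Tensor(out_data, parents=(a,), backward=backward)


def upsample2x(a) -> Tensor:
    """Nearest-neighbour 2x upsampling of the trailing two axes."""
    a = as_tensor(a)
    s = a.data.shape
    out_data = np.broadcast_to(
        a.data[..., :, None, :, None],
        s[:-2] + (s[-2], 2, s[-1], 2)).reshape(s[:-2] + (2 * s[-2], 2 * s[-1]))

    def backward(g):
        s = g.shape
        g4 = g.reshape(*s[:-2], s[-2] // 2, 2, s[-1] // 2, 2)
        return (g4.sum(axis=(-3, -1)),)

    return Tensor(out_data, parents=(a,), backward=backward)


def flip_h(a) -> Tensor:
    """Horizontal (last-axis) flip."""
    a = as_tensor(a)
    return Tensor(a.data[..., ::-1].copy(), parents=(a,),
                  backward=lambda g: (g[..., ::-1].copy(),))


# ------------------------------------------------------------ conv / pool

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           pad_mode: str = "zeros") -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, (O,C,kh,kw) weights.

    Computed as a sum of kernel-shifted tensordots, which keeps the working
    set at the input size instead of materialising an im2col matrix.
    ``pad_mode`` is 'zeros' or 'edge'.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError("channel mismatch in conv2d")
    if padding:
        if pad_mode == "zeros":
            xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                                 (padding, padding)))
        elif pad_mode == "edge":
            xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                                 (padding, padding)), mode="edge")
        else:
            raise ValueError("pad_mode must be 'zeros' or 'edge'")
    else:
        xp = x.data
    hp, wp = xp.shape[-2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    out = np.zeros((n, ho, wo, o), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + (ho - 1) * stride + 1:stride,
                    j:j + (wo - 1) * stride + 1:stride]
            out += np.tensordot(xs, w.data[:, :, i, j], axes=([1], [1]))
    out_nchw = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if b is not None:
        out_nchw += b.data[None, :, None, None]

    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (n, ho, wo, o)
        gw = np.empty_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                sl = np.s_[:, :, i:i + (ho - 1) * stride + 1:stride,
                           j:j + (wo - 1) * stride + 1:stride]
                gw[:, :, i, j] = np.tensordot(gt, xp[sl],
                                              axes=([0, 1, 2], [0, 2, 3]))
                gxp[sl] += np.tensordot(gt, w.data[:, :, i, j],
                                        axes=([3], [0])).transpose(0, 3, 1, 2)
        if padding:
            if pad_mode == "edge":
                gx = _edge_pad_backward(gxp, h, wd, padding)
            else:
                gx = gxp[:, :, padding:hp - padding, padding:wp - padding]
        else:
            gx = gxp
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    return Tensor(out_nchw, parents=parents, backward=backward)


def box_filter(a, k: int) -> Tensor:
    """Valid k x k mean filter over the trailing two axes."""
    a = as_tensor(a)
    win = np.lib.stride_tricks.sliding_window_view(
        a.data, (k, k), axis=(a.ndim - 2, a.ndim - 1))
    out_data = win.mean(axis=(-2, -1))

    def backward(g):
        gx = np.zeros_like(a.data)
        gk = g / (k * k)
        ho, wo = g.shape[-2:]
        for i in range(k):
            for j in range(k):
                gx[..., i:i + ho, j:j + wo] += gk
        return (gx,)

    return Tensor(out_data, parents=(a,), backward=backward)


# -------------------------------------------------------------- warping

def warp1d(source, disparity, sign: int) -> tuple[Tensor, np.ndarray]:
    """Bilinear horizontal warp: out(x) = source(x + sign * d(x)).

    Returns the warped tensor and the principled validity mask — a plain
    numpy array flagging pixels whose sampling coordinate lies inside
    [0, W-1], computed analytically from the disparity. Gradients flow to
    both the source and the disparity; outside the valid range the
    disparity gradient is zero (the sample is clamped).
    """
    source, disparity = as_tensor(source), as_tensor(disparity)
    shape = np.broadcast_shapes(source.data.shape, disparity.data.shape)
    src = np.broadcast_to(source.data, shape)
    dsp = np.broadcast_to(disparity.data, shape)
    w = shape[-1]
    xs = np.arange(w, dtype=src.dtype)
    cx = xs + sign * dsp
    mask = ((cx >= 0) & (cx <= w - 1)).astype(src.dtype)
    cxc = np.clip(cx, 0.0, float(w - 1))
    x0 = np.clip(np.floor(cxc).astype(np.int64), 0, w - 2)
    frac = cxc - x0
    s0 = np.take_along_axis(src, x0, axis=-1)
    s1 = np.take_along_axis(src, x0 + 1, axis=-1)
    out_data = (1.0 - frac) * s0 + frac * s1
    interior = (cx > 0) & (cx < w - 1)

    size = int(np.prod(shape))
    row_base = (np.arange(size // w) * w).repeat(w).reshape(shape)

    def backward(g):
        flat0 = (row_base + x0).ravel()
        gsrc = (np.bincount(flat0, weights=(g * (1.0 - frac)).ravel(),
                            minlength=size)
                + np.bincount(flat0 + 1, weights=(g * frac).ravel(),
                              minlength=size)).reshape(shape)
        gdsp = np.where(interior, g * sign * (s1 - s0), 0.0)
        return (_unbroadcast(gsrc.astype(g.dtype), source.data.shape),
                _unbroadcast(gdsp, disparity.data.shape))

    out = Tensor(out_data, parents=(source, disparity), backward=backward)
    return out, mask


def masked_mean(values, mask) -> Tensor:
    """Mean of ``values`` over mask-valid pixels; 0 if the mask is empty."""
    values = as_tensor(values)
    mask = np.asarray(mask, dtype=values.data.dtype)
    total = float(mask.sum())
    if total == 0:
        import warnings

        warnings.warn("masked_mean over an empty mask; defining the mean as 0",
                      stacklevel=2)
        return Tensor(np.zeros((), dtype=values.data.dtype))
    return (values * mask).sum() / total
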