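"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal engine powering the segmentation network: a ``Tensor`` wraps
an ndarray and records enough of the computation graph to backpropagate
through convolutions, pooling, instance normalisation, bilinear grid
sampling (with gradients to both the sampled values and the sampling
coordinates — the ingredient that lets learning flow through field
composition and prior warping) and ordinary arithmetic.

Only what the network needs is implemented; shapes follow the usual
``[N, C, H, W]`` convention for image-like data.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "astensor",
    "concat",
    "conv2d",
    "maxpool2",
    "avgpool2",
    "upsample_bilinear",
    "spatial_matmul",
    "replicate_pad2",
    "instance_norm",
    "grid_sample",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer mixed ndarray/Tensor arithmetic to our operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self.accumulate(_unbroadcast(g, self.data.shape))
            other.accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self.accumulate(_unbroadcast(g / other.data, self.data.shape))
            other.accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._backward = bwd if out.requires_grad else None
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bwd(g):
            self.accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd if out.requires_grad else None
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[key] = g  # basic slicing only: no index repeats
            self.accumulate(full)

        out._backward = bwd if out.requires_grad else None
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            self.accumulate(g.reshape(self.data.shape))

        out._backward = bwd if out.requires_grad else None
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self.accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bwd(g):
            self.accumulate(g * (self.data > 0))

        out._backward = bwd if out.requires_grad else None
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))

        def bwd(g):
            self.accumulate(g * (1.0 - t**2))

        out._backward = bwd if out.requires_grad else None
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t.accumulate(piece)

    out._backward = bwd if out.requires_grad else None
    return out


# -- convolution -------------------------------------------------------

def _windows(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Zero-padded sliding windows: ``[N, C, Ho, Wo, k, k]`` view."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    return sliding_window_view(x, (k, k), axis=(2, 3))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int) -> np.ndarray:
    k = w.shape[-1]
    win = _windows(x, k, pad)
    out = np.einsum("nchwkl,ockl->nohw", win, w, optimize=True)
    if b is not None:
        out += b[None, :, None, None]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation), stride 1, zero padding ``pad``."""
    x, w = astensor(x), astensor(w)
    parents = (x, w) if b is None else (x, w, astensor(b))
    bt = None if b is None else parents[2]
    out = Tensor(
        _conv_forward(x.data, w.data, None if bt is None else bt.data, pad),
        parents=parents,
    )
    k = w.data.shape[-1]

    def bwd(g):
        if w.requires_grad:
            win = _windows(x.data, k, pad)
            dw = np.einsum("nohw,nchwkl->ockl", g, win, optimize=True)
            w.accumulate(dw)
        if bt is not None and bt.requires_grad:
            bt.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            w_rot = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # C,O,k,k
            dx = _conv_forward(g, np.ascontiguousarray(w_rot), None, k - 1 - pad)
            x.accumulate(dx)

    out._backward = bwd if out.requires_grad else None
    return out


# -- pooling / resizing ------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (H and W must be even)."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    v = v.reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out = Tensor(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def bwd(g):
        dv = np.zeros_like(v)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dx = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(dx.reshape(n, c, h, w))

    out._backward = bwd if out.requires_grad else None
    return out


def avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (the "linear" downsampling mode)."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = Tensor(v.mean(axis=(3, 5)), parents=(x,))

    def bwd(g):
        dx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        x.accumulate(dx)

    out._backward = bwd if out.requires_grad else None
    return out


def replicate_pad2(x: Tensor, p: int) -> Tensor:
    """Edge-replicating spatial padding of ``[N, C, H, W]`` by ``p``."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    ri = np.clip(np.arange(-p, h + p), 0, h - 1)
    ci = np.clip(np.arange(-p, w + p), 0, w - 1)
    out = Tensor(x.data[:, :, ri[:, None], ci[None, :]], parents=(x,))

    def bwd(g):
        # fold the replicated border rows/cols back onto the edges
        gr = g[:, :, p:-p, :].copy()
        gr[:, :, 0, :] += g[:, :, :p, :].sum(axis=2)
        gr[:, :, -1, :] += g[:, :, -p:, :].sum(axis=2)
        dx = gr[:, :, :, p:-p].copy()
        dx[:, :, :, 0] += gr[:, :, :, :p].sum(axis=3)
        dx[:, :, :, -1] += gr[:, :, :, -p:].sum(axis=3)
        x.accumulate(dx)

    out._backward = bwd if out.requires_grad else None
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation with affine parameters."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = (x.data - mu) * inv
    gb = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xn * gb + beta.data.reshape(1, -1, 1, 1), parents=(x, gamma, beta))

    def bwd(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xn).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxn = g * gb
            m1 = dxn.mean(axis=(2, 3), keepdims=True)
            m2 = (dxn * xn).mean(axis=(2, 3), keepdims=True)
            x.accumulate(inv * (dxn - m1 - xn * m2))

    out._backward = bwd if out.requires_grad else None
    return out


# -- bilinear sampling -------------------------------------------------

def _gather(flat: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """``flat``: [N, C, HW]; ``idx``: [N, P] -> [N, C, P]."""
    return np.take_along_axis(flat, idx[:, None, :], axis=2)


def grid_sample(
    source: Tensor,
    rows,
    cols,
    mode: str = "border",
) -> Tensor:
    """Bilinear sampling of ``source`` [N, C, H, W] at fractional coords.

    ``rows``/``cols`` have shape [N, Ho, Wo] in source pixel units and
    may be Tensors (gradients flow into them) or plain arrays.
    ``mode="border"`` clamps coordinates to the image edge;
    ``mode="zeros"`` returns 0 outside the source domain.  Coordinate
    gradients vanish where clamping or zeroing is active.
    """
    source = astensor(source)
    rows_t = rows if isinstance(rows, Tensor) else None
    cols_t = cols if isinstance(cols, Tensor) else None
    r = rows.data if rows_t is not None else np.asarray(rows)
    c = cols.data if cols_t is not None else np.asarray(cols)
    n, ch, h, w = source.data.shape
    ho, wo = r.shape[1], r.shape[2]
    rf = r.reshape(n, -1)
    cf = c.reshape(n, -1)

    if mode == "border":
        in_r = (rf >= 0) & (rf <= h - 1)
        in_c = (cf >= 0) & (cf <= w - 1)
        rq = np.clip(rf, 0.0, h - 1)
        cq = np.clip(cf, 0.0, w - 1)
    elif mode == "zeros":
        in_r = (rf >= 0) & (rf <= h - 1)
        in_c = (cf >= 0) & (cf <= w - 1)
        rq, cq = rf, cf
    else:
        raise ValueError(f"unknown mode {mode!r}")

    r0 = np.clip(np.floor(rq), 0, h - 2).astype(np.intp)
    c0 = np.clip(np.floor(cq), 0, w - 2).astype(np.intp)
    wr = rq - r0
    wc = cq - c0

    flat = source.data.reshape(n, ch, h * w)
    i00 = r0 * w + c0
    v00 = _gather(flat, i00)
    v01 = _gather(flat, i00 + 1)
    v10 = _gather(flat, i00 + w)
    v11 = _gather(flat, i00 + w + 1)

    if mode == "zeros":
        # a corner contributes only if its interpolation weight belongs
        # to an in-range sample; zero the whole sample when outside
        valid = (in_r & in_c)[:, None, :]
        wr = np.clip(wr, 0.0, 1.0)
        wc = np.clip(wc, 0.0, 1.0)
    else:
        valid = None

    wrb = wr[:, None, :]
    wcb = wc[:, None, :]
    out_flat = (
        v00 * (1 - wrb) * (1 - wcb)
        + v01 * (1 - wrb) * wcb
        + v10 * wrb * (1 - wcb)
        + v11 * wrb * wcb
    )
    if valid is not None:
        out_flat = out_flat * valid

    parents = [source]
    if rows_t is not None:
        parents.append(rows_t)
    if cols_t is not None:
        parents.append(cols_t)
    out = Tensor(out_flat.reshape(n, ch, ho, wo), parents=tuple(parents))

    def bwd(g):
        gf = g.reshape(n, ch, -1)
        if valid is not None:
            gf = gf * valid
        if source.requires_grad:
            # scatter-add via one bincount over all four corners
            plane = (np.arange(n * ch) * (h * w))[:, None]
            idx_nc = np.broadcast_to(
                i00[:, None, :], (n, ch, i00.shape[-1])
            ).reshape(n * ch, -1) + plane
            pieces_i = []
            pieces_v = []
            for off, wgt in (
                (0, (1 - wrb) * (1 - wcb)),
                (1, (1 - wrb) * wcb),
                (w, wrb * (1 - wcb)),
                (w + 1, wrb * wcb),
            ):
                pieces_i.append((idx_nc + off).ravel())
                pieces_v.append((gf * wgt).ravel())
            dflat = np.bincount(
                np.concatenate(pieces_i),
                weights=np.concatenate(pieces_v),
                minlength=n * ch * h * w,
            )
            source.accumulate(
                dflat.reshape(source.data.shape).astype(source.data.dtype)
            )
        if rows_t is not None and rows_t.requires_grad:
            dr = ((v10 - v00) * (1 - wcb) + (v11 - v01) * wcb) * gf
            dr = dr.sum(axis=1)
            dr *= in_r & in_c if mode == "zeros" else in_r
            rows_t.accumulate(dr.reshape(r.shape))
        if cols_t is not None and cols_t.requires_grad:
            dc = ((v01 - v00) * (1 - wrb) + (v11 - v10) * wrb) * gf
            dc = dc.sum(axis=1)
            dc *= in_r & in_c if mode == "zeros" else in_c
            cols_t.accumulate(dc.reshape(c.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def spatial_matmul(A: np.ndarray, x: Tensor, B: np.ndarray) -> Tensor:
    """Separable linear map of the spatial axes: ``A @ x @ B.T``.

    ``x`` is [N, C, H, W]; ``A`` [H2, H] acts on rows, ``B`` [W2, W] on
    columns.  ``A`` and ``B`` are fixed (no gradients); backpropagation
    applies the transposes.  Used for bilinear resizing and separable
    Gaussian smoothing, which are both row/column-separable.
    """
    x = astensor(x)
    out = Tensor(A @ x.data @ B.T, parents=(x,))

    def bwd(g):
        x.accumulate(A.T @ g @ B)

    out._backward = bwd if out.requires_grad else None
    return out


def _interp_matrix(h: int, factor: int, dtype=np.float32) -> np.ndarray:
    """[h*factor, h] voxel-centre-aligned linear interpolation weights.

    Fine index ``i`` samples coarse coordinate ``(i + 0.5)/factor - 0.5``
    with border clamping.
    """
    s = np.clip((np.arange(h * factor) + 0.5) / factor - 0.5, 0.0, h - 1)
    s0 = np.clip(np.floor(s).astype(int), 0, max(h - 2, 0))
    w = s - s0
    A = np.zeros((h * factor, h), dtype=dtype)
    rows = np.arange(h * factor)
    A[rows, s0] = 1.0 - w
    A[rows, np.minimum(s0 + 1, h - 1)] += w
    return A


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer ``factor`` (voxel-centre aligned)."""
    x = astensor(x)
    _, _, h, w = x.data.shape
    A = _interp_matrix(h, factor, x.data.dtype)
    B = _interp_matrix(w, factor, x.data.dtype)
    return spatial_matmul(A, x, B)


class Adam:
    """Adam optimiser over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
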