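"""Minimal reverse-mode automatic differentiation on numpy arrays.

The encoding models in this package are trained by gradient descent on a
Poisson likelihood. This module provides the small set of differentiable
primitives those models need — broadcasting arithmetic, exp/log/sqrt,
rectification, reductions, valid (optionally dilated) 2-D convolution,
stride-1 zero-padded average pooling, the factorized readout contraction
and the tent-basis output nonlinearity — as a tape of :class:`Tensor`
nodes with a topological-order backward pass.

Every primitive's gradient is exercised against central finite
differences in the test suite; the engine is deliberately eager and
single-threaded.
"""

from __future__ import annotations

import numpy as np


__all__ = ["Tensor", "astensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_owned")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        # float32 data passes through unchanged (training uses it for
        # speed); everything else is promoted to float64
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward
        self._grad_owned = False

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        # first contribution is stored by reference (backward closures
        # never mutate their argument); later ones allocate exactly once
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._grad_owned = True

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss node")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):     # dtype-preserving fast path
            def bwd(g):
                if self.requires_grad:
                    self._accum(g)

            return Tensor(self.data + other, parents=(self,), backward=bwd)
        other = astensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-astensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bwd(g):
                if self.requires_grad:
                    self._accum(g * other)

            return Tensor(self.data * other, parents=(self,), backward=bwd)
        other = astensor(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = astensor(other)
        inv = 1.0 / other.data          # one division; backward reuses it
        out = self.data * inv

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * inv, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-(g * out) * inv, other.shape))

        return Tensor(out, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        # fixed (non-learnable) exponent; learnable exponents go through exp/log
        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(self.data ** exponent, parents=(self,), backward=bwd)

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out)

        return Tensor(out, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out)

        return Tensor(out, parents=(self,), backward=bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.where(mask, self.data, 0.0), parents=(self,), backward=bwd)

    def clip_min(self, floor: float):
        """max(x, floor); subgradient 0 on the floored region."""
        mask = self.data > floor

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor(np.where(mask, self.data, floor), parents=(self,), backward=bwd)

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def crop(self, slices: tuple):
        """Static slice; backward scatters into the source shape."""
        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[slices] = g
                self._accum(full)

        return Tensor(self.data[slices], parents=(self,), backward=bwd)

    def reshape(self, *shape):
        src = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(src))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor(self.data.transpose(*axes), parents=(self,), backward=bwd)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def conv2d_bank(x: Tensor, w: Tensor) -> Tensor:
    """Valid cross-correlation of single-channel images with a filter bank.

    x: (B, H, W); w: (C, kh, kw) -> (B, C, H-kh+1, W-kw+1).
    """
    xd, wd = x.data, w.data
    kh, kw = wd.shape[-2:]
    win = np.lib.stride_tricks.sliding_window_view(xd, (kh, kw), axis=(-2, -1))
    out = np.tensordot(win, wd, axes=([3, 4], [1, 2]))      # (B,h,w,C)
    out = np.moveaxis(out, -1, 1)

    def bwd(g):
        gm = np.moveaxis(g, 1, -1)                          # (B,h,w,C)
        if w.requires_grad:
            w._accum(np.tensordot(gm, win, axes=([0, 1, 2], [0, 1, 2])))
        if x.requires_grad:
            # full correlation of grad with flipped kernels
            B, C, h, wdt = g.shape
            gpad = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            gwin = np.lib.stride_tricks.sliding_window_view(
                gpad, (kh, kw), axis=(-2, -1))              # (B,C,H,W,kh,kw)
            wf = wd[:, ::-1, ::-1]
            x._accum(np.einsum("bchwij,cij->bhw", gwin, wf, optimize=True))

    return Tensor(out, parents=(x, w), backward=bwd)


def dilated_conv2d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """Valid cross-correlation of multi-channel maps with dilated kernels.

    x: (B, Cin, H, W); w: (Cout, Cin, k, k) -> (B, Cout, h, w) with
    h = H - dilation*(k-1). Implemented as a sum over kernel taps so the
    adjoint is an exact scatter.
    """
    xd, wd = x.data, w.data
    cout, cin, k, _ = wd.shape
    B, _, H, W = xd.shape
    h = H - dilation * (k - 1)
    wdt = W - dilation * (k - 1)
    if h <= 0 or wdt <= 0:
        raise ValueError("feature maps too small for dilated valid convolution")
    out = np.zeros((B, cout, h, wdt))
    for i in range(k):
        for j in range(k):
            patch = xd[:, :, i * dilation:i * dilation + h,
                       j * dilation:j * dilation + wdt]
            out += np.einsum("oc,bchw->bohw", wd[:, :, i, j], patch, optimize=True)

    def bwd(g):
        if w.requires_grad:
            gw = np.empty_like(wd)
            for i in range(k):
                for j in range(k):
                    patch = xd[:, :, i * dilation:i * dilation + h,
                               j * dilation:j * dilation + wdt]
                    gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, patch,
                                               optimize=True)
            w._accum(gw)
        if x.requires_grad:
            gx = np.zeros_like(xd)
            for i in range(k):
                for j in range(k):
                    gx[:, :, i * dilation:i * dilation + h,
                       j * dilation:j * dilation + wdt] += np.einsum(
                        "oc,bohw->bchw", wd[:, :, i, j], g, optimize=True)
            x._accum(gx)

    return Tensor(out, parents=(x, w), backward=bwd)


try:
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _pow_fwd(L, n, out):                     # yn = exp(n_c * L)
        B, C, HW = L.shape
        for b in range(B):
            for c in range(C):
                nc = n[c]
                for i in range(HW):
                    out[b, c, i] = np.exp(nc * L[b, c, i])

    @njit(cache=True, fastmath=True)
    def _pow_bwd(g, yn, L, dn):                  # dn_c = sum g * yn * L
        B, C, HW = L.shape
        for b in range(B):
            for c in range(C):
                acc = 0.0
                for i in range(HW):
                    acc += g[b, c, i] * yn[b, c, i] * L[b, c, i]
                dn[c] += acc

    @njit(cache=True, fastmath=True)
    def _div_fwd(yn, mix, sn, z, inv):           # z = yn / (sn_c + mix)
        B, C, HW = yn.shape
        for b in range(B):
            for c in range(C):
                s = sn[c]
                for i in range(HW):
                    iv = 1.0 / (s + mix[b, c, i])
                    inv[b, c, i] = iv
                    z[b, c, i] = yn[b, c, i] * iv

    @njit(cache=True, fastmath=True)
    def _div_bwd(g, z, inv, dyn, dmix, dsn):
        B, C, HW = z.shape
        for b in range(B):
            for c in range(C):
                acc = 0.0
                for i in range(HW):
                    gi = g[b, c, i]
                    iv = inv[b, c, i]
                    dyn[b, c, i] = gi * iv
                    dd = -gi * z[b, c, i] * iv
                    dmix[b, c, i] = dd
                    acc += dd
                dsn[c] += acc

    @njit(cache=True, fastmath=True)
    def _box2d(x, half, out):
        """Zero-padded 2-D box mean over the last two axes (divisor =
        window^2); row-major running sums, no transposes."""
        n_maps, H, W = x.shape
        w = 2 * half + 1
        inv = 1.0 / w
        tmp = np.empty((H, W), dtype=x.dtype)
        acc = np.empty(W, dtype=x.dtype)
        for m in range(n_maps):
            # horizontal pass
            for i in range(H):
                s = 0.0
                for j in range(half):
                    s += x[m, i, j]
                for j in range(W):
                    if j + half < W:
                        s += x[m, i, j + half]
                    if j - half - 1 >= 0:
                        s -= x[m, i, j - half - 1]
                    tmp[i, j] = s * inv
            # vertical pass with a running row-sum vector
            for j in range(W):
                acc[j] = 0.0
            for i in range(half):
                for j in range(W):
                    acc[j] += tmp[i, j]
            for i in range(H):
                if i + half < H:
                    for j in range(W):
                        acc[j] += tmp[i + half, j]
                if i - half - 1 >= 0:
                    for j in range(W):
                        acc[j] -= tmp[i - half - 1, j]
                for j in range(W):
                    out[m, i, j] = acc[j] * inv

    HAVE_NUMBA = True
except ImportError:                              # pragma: no cover
    HAVE_NUMBA = False


def power_from_log(L: Tensor, n: Tensor) -> Tensor:
    """yn = exp(n_c * L) for a constant log-drive L (B, C, H, W).

    Fast path for training with frozen subunit filters: L = ln(y + eps)
    is precomputed, so only the per-channel exponent receives a gradient.
    """
    if not HAVE_NUMBA:
        return (L * n.reshape(1, -1, 1, 1)).exp()
    shape = L.data.shape
    Lf = L.data.reshape(shape[0], shape[1], -1)
    out = np.empty_like(Lf)
    _pow_fwd(Lf, n.data, out)

    def bwd(g):
        if n.requires_grad:
            dn = np.zeros_like(n.data)
            _pow_bwd(g.reshape(Lf.shape), out, Lf, dn)
            n._accum(dn)

    return Tensor(out.reshape(shape), parents=(L, n), backward=bwd)


def divide_by_denominator(yn: Tensor, mix: Tensor, sn: Tensor) -> Tensor:
    """z = yn / (sn_c + mix), fused with its backward pass."""
    if not HAVE_NUMBA:
        return yn / (sn.reshape(1, -1, 1, 1) + mix)
    shape = yn.data.shape
    ynf = yn.data.reshape(shape[0], shape[1], -1)
    mixf = mix.data.reshape(ynf.shape)
    z = np.empty_like(ynf)
    inv = np.empty_like(ynf)
    _div_fwd(ynf, mixf, sn.data, z, inv)

    def bwd(g):
        gf = g.reshape(ynf.shape)
        dyn = np.empty_like(ynf)
        dmix = np.empty_like(ynf)
        dsn = np.zeros_like(sn.data)
        _div_bwd(gf, z, inv, dyn, dmix, dsn)
        if yn.requires_grad:
            yn._accum(dyn.reshape(shape))
        if mix.requires_grad:
            mix._accum(dmix.reshape(shape))
        if sn.requires_grad:
            sn._accum(dsn)

    return Tensor(z.reshape(shape), parents=(yn, mix, sn), backward=bwd)


_band_cache: dict[tuple[int, int, str], np.ndarray] = {}


def _band_matrix(n: int, size: int, dtype) -> np.ndarray:
    """Symmetric banded matrix applying a zero-padded 1-D box mean."""
    key = (n, size, np.dtype(dtype).str)
    if key not in _band_cache:
        idx = np.arange(n)
        band = (np.abs(idx[:, None] - idx[None, :]) <= size // 2)
        _band_cache[key] = band.astype(dtype) / size
    return _band_cache[key]


def avg_pool_same(x: Tensor, size: int) -> Tensor:
    """Stride-1 average pooling over the last two axes, zero-padded to
    the same spatial shape (border windows are under-pooled: the divisor
    is always ``size**2``). The separable box operator is symmetric per
    axis, so backward reapplies the same operator."""
    H, W = x.data.shape[-2:]

    if HAVE_NUMBA:
        half = size // 2

        def run(a):
            maps = np.ascontiguousarray(a).reshape(-1, H, W)
            out = np.empty_like(maps)
            _box2d(maps, half, out)
            return out.reshape(a.shape)
    else:                                        # pragma: no cover
        bh = _band_matrix(H, size, x.data.dtype)
        bw = _band_matrix(W, size, x.data.dtype)

        def run(a):
            return np.matmul(np.matmul(bh, a), bw)

    def bwd(g):
        if x.requires_grad:
            x._accum(run(g))

    return Tensor(run(x.data), parents=(x,), backward=bwd)


def channel_mix(x: Tensor, p: Tensor) -> Tensor:
    """Weighted channel sum out_blhw = sum_k p_kl * x_bkhw.

    ``p`` is indexed (source k, target l), as in a normalization-weight
    matrix whose column l collects the pool feeding target channel l.
    All contractions are batched matrix products.
    """
    B, K, H, W = x.data.shape
    xr = x.data.reshape(B, K, H * W)
    pd = p.data.astype(x.data.dtype, copy=False)
    out = np.matmul(pd.T[None], xr).reshape(B, -1, H, W)

    def bwd(g):
        gr = g.reshape(B, -1, H * W)
        if x.requires_grad:
            x._accum(np.matmul(pd[None], gr).reshape(B, K, H, W))
        if p.requires_grad:
            p._accum(np.matmul(xr, gr.transpose(0, 2, 1)).sum(axis=0))

    return Tensor(out, parents=(x, p), backward=bwd)


def readout_contract(z: Tensor, a: Tensor, b: Tensor, q: Tensor) -> Tensor:
    """Factorized readout g_bi = sum_{c,h,w} z_bchw * a_ihw * b_ic + q_i.

    The rank-one per-neuron weight tensors are materialized once per call
    (cheap: neurons x channels x pixels) so both passes are single GEMMs.
    """
    zd = z.data
    B, C, H, W = zd.shape
    dt = zd.dtype
    ad = a.data.astype(dt, copy=False)
    bd = b.data.astype(dt, copy=False)
    wfull = (bd[:, :, None] * ad.reshape(ad.shape[0], 1, H * W))  # (I, C, HW)
    wflat = wfull.reshape(wfull.shape[0], -1)
    zflat = zd.reshape(B, -1)
    out = zflat @ wflat.T + q.data

    def bwd(g):
        g = g.astype(dt, copy=False)
        if z.requires_grad:
            z._accum((g @ wflat).reshape(B, C, H, W))
        if a.requires_grad or b.requires_grad:
            dw = (g.T @ zflat).reshape(wfull.shape)    # (I, C, HW)
            if a.requires_grad:
                a._accum((dw * bd[:, :, None]).sum(axis=1).reshape(ad.shape))
            if b.requires_grad:
                b._accum((dw * ad.reshape(ad.shape[0], 1, H * W)).sum(axis=2))
        if q.requires_grad:
            q._accum(g.sum(axis=0))

    return Tensor(out, parents=(z, a, b, q), backward=bwd)


def elu_star(g: Tensor) -> Tensor:
    """Shifted exponential linear unit: identity above 1, exp(g-1) below.

    Continuous and C1 at the branch point (both branches and slopes are 1).
    """
    gd = g.data
    mask = gd >= 1.0
    lo = np.exp(np.minimum(gd, 1.0) - 1.0)
    out = np.where(mask, gd, lo)

    def bwd(grad):
        if g.requires_grad:
            g._accum(grad * np.where(mask, 1.0, lo))

    return Tensor(out, parents=(g,), backward=bwd)


def tent_interp(g: Tensor, alpha: Tensor, grid: np.ndarray) -> Tensor:
    """h_i(g) = sum_j t_j(g) exp(alpha_ij) on a uniform tent grid.

    Inside the grid the tent functions form a partition of unity, so h is
    linear interpolation of exp(alpha); g is clamped to the grid range
    (outside it all tents vanish and the prediction would die).

    g: (B, N); alpha: (N, J); grid: (J,) uniform ascending.
    """
    x0, dx = grid[0], grid[1] - grid[0]
    J = grid.size
    expa = np.exp(alpha.data)                       # (N, J)
    gc = np.clip(g.data, x0, grid[-1])
    pos = (gc - x0) / dx
    idx = np.minimum(pos.astype(np.int64), J - 2)   # (B, N)
    frac = pos - idx
    cols = np.arange(g.data.shape[1])
    lo = expa[cols, idx]                            # (B, N)
    hi = expa[cols, idx + 1]
    out = (1.0 - frac) * lo + frac * hi
    interior = (g.data > x0) & (g.data < grid[-1])

    def bwd(grad):
        if g.requires_grad:
            g._accum(grad * (hi - lo) / dx * interior)
        if alpha.requires_grad:
            ga = np.zeros_like(expa)
            np.add.at(ga, (cols[None, :] * np.ones_like(idx), idx),
                      grad * (1.0 - frac) * lo)
            np.add.at(ga, (cols[None, :] * np.ones_like(idx), idx + 1),
                      grad * frac * hi)
            alpha._accum(ga)

    return Tensor(out, parents=(g, alpha), backward=bwd)
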