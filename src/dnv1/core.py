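"""Shared nonlinear core: convolutional subunits and divisive normalization.

The core maps a batch of normalized grayscale stimuli (B, 40, 40) to a
shared feature space (B, C, 28, 28). It has two stages:

1. *Subunit stage* — valid convolution with C filters (13 px, 0.37 deg),
   batch normalization without re-scaling (BN*: standardize to unit
   variance, add a learned per-channel bias, no learned scale), and ReLU
   rectification, giving non-negative excitatory drives y_l.

2. *Normalization stage* — one of four variants:

   - ``subunit``: identity, z = y (the LN-LN baseline);
   - ``dn``: each channel's exponentiated drive y_l^{n_l} is divided by
     sigma_l^{n_l} plus a learned weighted sum over all channels of the
     spatially pooled drives <y_k^{n_k}> (5 px average pooling for
     approximate phase invariance);
   - ``dn_nonspecific``: same, but the incoming weights of each target
     channel are constrained equal across source channels;
   - ``dn_extended``: the weighted sum becomes a dilated valid
     convolution over space (dilation 5, one kernel tap per pooling
     window), so the normalization pool reaches beyond the receptive
     field; its weights factorize into two spatial pools per target
     channel and per-pool feature weights.

All constrained quantities (exponents, semi-saturation constants,
normalization weights, pool factors) are non-negative; together with
y >= 0 this keeps every denominator positive and the normalized feature
maps non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import (Tensor, astensor, avg_pool_same, channel_mix,
                       conv2d_bank, dilated_conv2d, divide_by_denominator,
                       power_from_log)

__all__ = [
    "BN_EPS", "BN_MOMENTUM", "POW_EPS",
    "SubunitParams", "DNParams", "ExtendedDNParams",
    "subunit_forward", "dn_forward", "extended_dn_forward",
    "subunit_variant", "make_nonspecific", "nonspecific_project",
]

BN_EPS = 1e-4          # variance floor in BN* standardization
BN_MOMENTUM = 0.9      # EMA weight on the old running statistic
POW_EPS = 1e-6         # y^n computed as exp(n*log(y+eps)): finite grads at y=0


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their constraints."""


@dataclass
class SubunitParams:
    """First-stage filters and BN* state.

    filters: (C, k, k); biases: (C,). ``bn_mean``/``bn_var`` are the
    running statistics used at evaluation time; ``use_bn=False`` selects
    identity standardization (bias still applied), which is convenient
    for hand-constructed models.
    """

    filters: np.ndarray
    biases: np.ndarray
    use_bn: bool = True
    bn_mean: np.ndarray | None = None
    bn_var: np.ndarray | None = None

    def __post_init__(self):
        self.filters = np.asarray(self.filters, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.filters.ndim != 3 or self.filters.shape[1] != self.filters.shape[2]:
            raise InvalidParameterError("filters must be (C, k, k) square")
        if self.filters.shape[1] % 2 == 0:
            raise InvalidParameterError("kernel side must be odd")
        if self.bn_var is not None and np.any(np.asarray(self.bn_var) <= 0):
            raise InvalidParameterError("bn variance entries must be positive")

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.filters.shape[1]


@dataclass
class DNParams:
    """Divisive-normalization parameters for the center model.

    exponents n: (C,), semi_saturation sigma: (C,), norm_weights p:
    (C source, C target); pool_size is the side of the denominator's
    average-pooling window.
    """

    exponents: np.ndarray
    semi_saturation: np.ndarray
    norm_weights: np.ndarray
    pool_size: int = 5

    def __post_init__(self):
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.semi_saturation = np.asarray(self.semi_saturation, dtype=float)
        self.norm_weights = np.asarray(self.norm_weights, dtype=float)
        if np.any(self.exponents < 0):
            raise InvalidParameterError("exponents must be >= 0")
        if np.any(self.semi_saturation < 0):
            raise InvalidParameterError("semi-saturation constants must be >= 0")
        if np.any(self.norm_weights < 0):
            raise InvalidParameterError("normalization weights must be >= 0")
        c = self.exponents.shape[0]
        if self.norm_weights.shape != (c, c):
            raise InvalidParameterError("norm_weights must be (C, C)")


@dataclass
class ExtendedDNParams:
    """Spatially-extended normalization with two factorized pools.

    spatial_pools c: (C target, U, V, 2) >= 0; feature_weights d:
    (C source, C target, 2) >= 0; the implied dilated kernel is
    p[l, k, u, v] = sum_m c[l, u, v, m] * d[k, l, m], elementwise >= 0.
    """

    exponents: np.ndarray
    semi_saturation: np.ndarray
    spatial_pools: np.ndarray
    feature_weights: np.ndarray
    kernel_size: int = 3
    dilation: int = 5
    pool_size: int = 5

    def __post_init__(self):
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.semi_saturation = np.asarray(self.semi_saturation, dtype=float)
        self.spatial_pools = np.asarray(self.spatial_pools, dtype=float)
        self.feature_weights = np.asarray(self.feature_weights, dtype=float)
        if self.kernel_size % 2 == 0 or self.kernel_size not in (1, 3, 5, 7):
            raise InvalidParameterError("normalization kernel side must be odd, in {1,3,5,7}")
        if self.spatial_pools.shape[1:3] != (self.kernel_size, self.kernel_size):
            raise InvalidParameterError("spatial_pools must be (C, k, k, 2)")
        if self.spatial_pools.shape[-1] != 2 or self.feature_weights.shape[-1] != 2:
            raise InvalidParameterError("two pool components per target channel required")
        for name, arr in (("exponents", self.exponents),
                          ("semi_saturation", self.semi_saturation),
                          ("spatial_pools", self.spatial_pools),
                          ("feature_weights", self.feature_weights)):
            if np.any(arr < 0):
                raise InvalidParameterError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# forward passes (Tensor in, Tensor out; wrap numpy inputs with astensor)
# ---------------------------------------------------------------------------

def _standardize_train(conv: Tensor, params: SubunitParams) -> Tensor:
    """BN* with batch statistics; updates the running EMA state in place."""
    mu = conv.mean(axis=(0, 2, 3), keepdims=True)
    var = ((conv - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
    out = (conv - mu) / (var + BN_EPS).sqrt()
    m = BN_MOMENTUM
    bmu, bvar = mu.data.ravel(), var.data.ravel()
    if params.bn_mean is None:
        params.bn_mean, params.bn_var = bmu.copy(), bvar.copy()
    else:
        params.bn_mean = m * params.bn_mean + (1 - m) * bmu
        params.bn_var = m * params.bn_var + (1 - m) * bvar
    return out


def subunit_forward(stimuli, params: SubunitParams, mode: str = "eval",
                    filters: Tensor | None = None,
                    biases: Tensor | None = None) -> Tensor:
    """Excitatory drives y = ReLU(BN*(w * x)).

    ``stimuli``: (B, H, W) normalized images. ``filters``/``biases`` may
    be passed as graph Tensors when training; otherwise the stored numpy
    arrays are used as constants. Output: (B, C, H-k+1, W-k+1), >= 0.
    """
    x = astensor(stimuli)
    if not np.all(np.isfinite(x.data)):
        raise ValueError("stimuli contain non-finite values")
    if x.data.ndim != 3:
        raise ValueError("stimuli must be a (batch, H, W) array")
    w = filters if filters is not None else astensor(params.filters)
    o = biases if biases is not None else astensor(params.biases)
    conv = conv2d_bank(x, w)
    if params.use_bn:
        if mode == "train":
            conv = _standardize_train(conv, params)
        elif mode == "eval":
            if params.bn_mean is None or params.bn_var is None:
                raise ValueError("eval mode requires initialized bn running statistics")
            dt = conv.data.dtype
            mu = params.bn_mean.reshape(1, -1, 1, 1).astype(dt)
            sd = np.sqrt(params.bn_var.reshape(1, -1, 1, 1) + BN_EPS).astype(dt)
            conv = (conv - mu) * (1.0 / sd)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return (conv + o.reshape(1, -1, 1, 1)).relu()


def _power(y: Tensor, n: Tensor) -> Tensor:
    """Elementwise y^n with per-channel learnable exponent, eps-shifted."""
    return ((y + POW_EPS).log() * n.reshape(1, -1, 1, 1)).exp()


def _sigma_pow(sigma: Tensor, n: Tensor) -> Tensor:
    return ((sigma + POW_EPS).log() * n).exp()


def dn_forward(driving, params: DNParams,
               tensors: dict[str, Tensor] | None = None,
               log_driving: Tensor | None = None) -> Tensor:
    """Center divisive normalization.

    z_l = y_l^{n_l} / (sigma_l^{n_l} + sum_k p_kl <y_k^{n_k}>), where
    <.> is stride-1 zero-padded average pooling of side ``pool_size``
    (exponentiation precedes pooling; spatial size preserved, border
    windows under-pooled).

    ``tensors`` may supply graph Tensors for ``n``, ``sigma``, ``p``.
    ``log_driving`` may supply a precomputed log(y + eps) (constant when
    the subunit stage is frozen), skipping the log each call.
    """
    t = tensors or {}
    n = t.get("n", astensor(params.exponents))
    sigma = t.get("sigma", astensor(params.semi_saturation))
    p = t.get("p", astensor(params.norm_weights))
    if log_driving is not None and not log_driving.requires_grad:
        yn = power_from_log(log_driving, n)
    elif log_driving is not None:
        yn = (log_driving * n.reshape(1, -1, 1, 1)).exp()
    else:
        yn = _power(astensor(driving), n)
    pooled = avg_pool_same(yn, params.pool_size)
    mix = channel_mix(pooled, p)
    sn = _sigma_pow(sigma, n)
    den_floor = sn.data + mix.data.min(axis=(0, 2, 3))
    if np.min(den_floor) < 1e-12:
        raise InvalidParameterError(
            "normalization denominator vanished (sigma = 0 with zero pool input)")
    return divide_by_denominator(yn, mix, sn)


def extended_dn_forward(driving, params: ExtendedDNParams,
                        tensors: dict[str, Tensor] | None = None) -> Tensor:
    """Spatially-extended divisive normalization.

    The channel-weighted sum of the center model becomes a valid
    convolution (dilation ``params.dilation``) of the pooled drives with
    the factorized kernel p[l, k, u, v] = sum_m c[l,u,v,m] d[k,l,m]; the
    numerator is cropped symmetrically to the denominator's spatial size
    before the elementwise division. With a 1x1 kernel this reduces to
    ``dn_forward`` with p_kl = sum_m c[l,0,0,m] d[k,l,m].
    """
    y = astensor(driving)
    t = tensors or {}
    n = t.get("n", astensor(params.exponents))
    sigma = t.get("sigma", astensor(params.semi_saturation))
    c = t.get("c", astensor(params.spatial_pools))
    d = t.get("d", astensor(params.feature_weights))
    k, dil = params.kernel_size, params.dilation

    yn = _power(y, n)
    pooled = avg_pool_same(yn, params.pool_size)
    # p[l, k, u, v] = sum_m c[l, u, v, m] * d[k, l, m]
    L, _, _, M = c.shape
    K = d.shape[0]
    cl = c.reshape(L, 1, k, k, M)
    dl = d.transpose(1, 0, 2).reshape(L, K, 1, 1, M)
    kernel = (cl * dl).sum(axis=-1)
    s = dilated_conv2d(pooled, kernel, dilation=dil)

    H, W = yn.shape[-2:]
    h, wdt = s.shape[-2:]
    if (H - h) % 2 or (W - wdt) % 2:
        raise ValueError("numerator/denominator size mismatch is not symmetric")
    r0, c0 = (H - h) // 2, (W - wdt) // 2
    yn_c = yn.crop((slice(None), slice(None), slice(r0, r0 + h), slice(c0, c0 + wdt)))
    den = _sigma_pow(sigma, n).reshape(1, -1, 1, 1) + s
    if np.min(den.data) < 1e-12:
        raise InvalidParameterError(
            "normalization denominator vanished (sigma = 0 with zero pool input)")
    return yn_c / den


def subunit_variant(driving) -> Tensor:
    """Identity normalization: the LN-LN baseline, z = y exactly."""
    return astensor(driving)


def nonspecific_project(p: np.ndarray) -> np.ndarray:
    """Project a weight matrix onto constant columns (each target channel
    receives the same weight from every source channel)."""
    return np.broadcast_to(p.mean(axis=0, keepdims=True), p.shape).copy()


def make_nonspecific(params: DNParams) -> DNParams:
    """Nonspecific-normalization control: C free weights instead of C^2.

    Returns parameters whose weight columns are constant; training keeps
    them in this set by re-projecting after every optimizer step.
    """
    return DNParams(
        exponents=params.exponents.copy(),
        semi_saturation=params.semi_saturation.copy(),
        norm_weights=nonspecific_project(params.norm_weights),
        pool_size=params.pool_size,
    )
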