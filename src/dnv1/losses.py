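"""Training objective: Poisson loss plus three regularizers.

The spike counts are modelled as Poisson given the predicted mean, so
(dropping the model-independent ln r! term) the data term is

    L_Poisson = sum_{i,j} (rhat_ij - r_ij ln rhat_ij).

Three penalties shape the solution: a Laplace-filter smoothness penalty
on the convolution kernels (receptive fields are spatially continuous),
an L1 penalty on the factorized readout (each neuron reads few locations
and few features; in the separable form the penalty is the product of
the two L1 norms per neuron), and a finite-difference smoothness penalty
on the output-nonlinearity coefficients (the nonlinearity should deviate
from ELU* only where the data insists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, conv2d_bank

__all__ = ["LossConfig", "LAPLACE_KERNEL", "poisson_loss", "smoothness_penalty",
           "sparsity_penalty", "output_nl_penalty", "total_loss"]

LAPLACE_KERNEL = np.array([[0.25, 0.5, 0.25],
                           [0.5, -3.0, 0.5],
                           [0.25, 0.5, 0.25]])

RATE_FLOOR = 1e-8


@dataclass
class LossConfig:
    """Regularizer weights; all non-negative."""

    lambda_smooth: float = 0.0
    lambda_sparse: float = 0.0
    lambda_out: float = 0.0

    def __post_init__(self):
        if min(self.lambda_smooth, self.lambda_sparse, self.lambda_out) < 0:
            raise ValueError("regularizer weights must be non-negative")


def poisson_loss(rhat, r, floor_counter: list | None = None) -> Tensor:
    """sum(rhat - r * ln rhat); rhat is floored at 1e-8 before the log.

    ``floor_counter``, if given, receives the number of floored entries.
    """
    rhat = astensor(rhat)
    r = np.asarray(r, dtype=float)
    n_floored = int(np.sum(rhat.data < RATE_FLOOR))
    if floor_counter is not None:
        floor_counter.append(n_floored)
    safe = rhat.clip_min(RATE_FLOOR)
    return (safe - astensor(r) * safe.log()).sum()


def smoothness_penalty(filters) -> Tensor:
    """sum over channels and valid positions of the squared Laplace-filtered
    kernels: zero for (interior-)constant kernels, large for pixel noise."""
    w = astensor(filters)
    lap = conv2d_bank(w, Tensor(LAPLACE_KERNEL[None]))
    return (lap ** 2).sum()


def sparsity_penalty(a, b) -> Tensor:
    """Separable readout L1: sum_i sum_{u,v,l} |a_uv,i| |b_l,i|
    = sum_i (sum|a_i|) (sum|b_i|). Weights are non-negative, so the
    absolute values are the values themselves."""
    a = astensor(a)
    b = astensor(b)
    return (a.sum(axis=(1, 2)) * b.sum(axis=1)).sum()


def output_nl_penalty(alpha) -> Tensor:
    """(1/N) sum over neurons of squared first and second finite
    differences of the tent coefficients; first differences run over
    adjacent pairs, second differences over interior points (boundary
    terms with undefined neighbours are skipped). Zero iff alpha is
    constant per neuron in the second term's presence of the first."""
    al = astensor(alpha)
    n = al.shape[0]
    d1 = al.crop((slice(None), slice(1, None))) - al.crop((slice(None), slice(None, -1)))
    mid = al.crop((slice(None), slice(1, -1)))
    d2 = (2.0 * mid - al.crop((slice(None), slice(None, -2)))
          - al.crop((slice(None), slice(2, None))))
    return ((d1 ** 2).sum() + (d2 ** 2).sum()) * (1.0 / n)


def total_loss(rhat, r, cfg: LossConfig, filters=None, a=None, b=None,
               alpha=None, floor_counter: list | None = None) -> Tensor:
    """L = L_Poisson + lambda_smooth L_smooth + lambda_sparse L_sparse
    + lambda_out L_out. Penalty terms whose parameters are not supplied
    (or whose weight is zero) are omitted from the graph."""
    loss = poisson_loss(rhat, r, floor_counter=floor_counter)
    if cfg.lambda_smooth and filters is not None:
        loss = loss + cfg.lambda_smooth * smoothness_penalty(filters)
    if cfg.lambda_sparse and a is not None and b is not None:
        loss = loss + cfg.lambda_sparse * sparsity_penalty(a, b)
    if cfg.lambda_out and alpha is not None:
        loss = loss + cfg.lambda_out * output_nl_penalty(alpha)
    return loss
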