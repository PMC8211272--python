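"""Per-neuron readout: factorized weights and learnable output nonlinearity.

Each neuron i reads the shared feature space z (B, C, H, W) through a
rank-one factorized, non-negative linear map

    g_i = sum_{u,v,l} a_{uv,i} b_{l,i} z_{uvl} + q_i,

where the spatial mask a localizes the receptive field and the feature
vector b selects the channels the neuron pools. The predicted mean spike
count is

    rhat_i = h_i(g_i) * ELU*(g_i),

with ELU*(g) = g for g >= 1 and exp(g - 1) otherwise, and h_i a learned
positive modulation expanded in a tent (piecewise-linear) basis on a
uniform grid x_j = -3, -2.82, ..., 6 with coefficients exp(alpha_ji).
With alpha = 0, h = 1 on the grid interior (the tents form a partition
of unity) and the nonlinearity is the plain ELU*. Outside the grid all
tents vanish; g is clamped to the grid range before evaluating h so
predictions do not die.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor, elu_star, readout_contract, tent_interp

__all__ = ["TentGrid", "ReadoutParams", "readout_forward", "tent_basis",
           "output_nonlinearity", "elu_star_values"]


@dataclass(frozen=True)
class TentGrid:
    """Uniform grid carrying the tent basis of the output nonlinearity."""

    start: float = -3.0
    stop: float = 6.0
    spacing: float = 0.18

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.spacing)) + 1
        return np.linspace(self.start, self.stop, n)

    def __len__(self) -> int:
        return self.points.size


@dataclass
class ReadoutParams:
    """spatial a: (N, H, W) >= 0; feature b: (N, C) >= 0; bias q: (N,);
    output-nonlinearity coefficients alpha: (N, J)."""

    spatial: np.ndarray
    feature: np.ndarray
    bias: np.ndarray
    alpha: np.ndarray
    grid: TentGrid = TentGrid()

    def __post_init__(self):
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.feature = np.asarray(self.feature, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if np.any(self.spatial < 0) or np.any(self.feature < 0):
            raise ValueError("readout weights must be non-negative")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha must be finite")
        if self.alpha.shape[1] != len(self.grid):
            raise ValueError("alpha second axis must match the tent grid")

    @property
    def n_neurons(self) -> int:
        return self.spatial.shape[0]


def readout_forward(z, params: ReadoutParams,
                    tensors: dict[str, Tensor] | None = None) -> Tensor:
    """Pre-nonlinearity activations g (B, N); linear and, because the
    weights are non-negative, monotone non-decreasing in every z entry."""
    zt = astensor(z)
    t = tensors or {}
    a = t.get("a", astensor(params.spatial))
    b = t.get("b", astensor(params.feature))
    q = t.get("q", astensor(params.bias))
    if zt.shape[-2:] != a.shape[-2:]:
        raise ValueError(
            f"feature-map spatial size {zt.shape[-2:]} does not match "
            f"spatial readout {a.shape[-2:]}")
    return readout_contract(zt, a, b, q)


def tent_basis(x: float | np.ndarray, grid: TentGrid = TentGrid()) -> np.ndarray:
    """Evaluate all tent functions t_j at x.

    t_j peaks at 1 on its grid point, falls linearly to 0 at the two
    neighbours (support width 2*spacing); strictly inside the grid the
    basis sums to 1.
    """
    pts = grid.points
    x = np.asarray(x, dtype=float)
    d = 1.0 - np.abs(x[..., None] - pts) / grid.spacing
    return np.maximum(d, 0.0)


def elu_star_values(g: np.ndarray) -> np.ndarray:
    """ELU*: identity above 1, exp(g-1) below; C1 at the branch point."""
    g = np.asarray(g, dtype=float)
    return np.where(g >= 1.0, g, np.exp(np.minimum(g, 1.0) - 1.0))


def output_nonlinearity(g, alpha, grid: TentGrid = TentGrid()) -> Tensor:
    """rhat = h(g) * ELU*(g) with h the tent-basis expansion of exp(alpha).

    g: (B, N) Tensor or array; alpha: (N, J). Returns (B, N), > 0 for
    finite g.
    """
    gt = astensor(g)
    at = astensor(alpha)
    h = tent_interp(gt, at, grid.points)
    return h * elu_star(gt)
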