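"""Gabor, plaid and windowed-grating stimuli, and optimal-Gabor search.

Stimuli are rendered at pixel centers (integer coordinates, origin at the
top-left) on a canvas matching the model input. A Gabor is parameterized
by its center (row, col), size s (the +-2 standard-deviation extent of an
isotropic Gaussian envelope, so the envelope std is s/4), spatial
frequency f in cycles per four envelope standard deviations (i.e. f/s
cycles per pixel), phase psi, carrier orientation phi (the wave-vector
angle, counterclockwise from the positive row axis; "orthogonal" means
phi + pi/2), and amplitude a (contrast c = 2a, capped by the intensity
range of the normalized training images: a_max = 2.52).

The optimal Gabor of a model unit is found by exhaustively evaluating a
parameter grid and taking the argmax of the unit's predicted response,
ties broken by the first hit in iteration order (amplitude, size,
frequency, orientation, phase, center-row, center-col — coarsest last
so vectorized center sweeps stay deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np

from .geometry import GeometryConfig

__all__ = ["A_MAX", "C_MAX", "D_MAX", "GaborParams", "GaborGrids",
           "render_gabor", "render_plaid", "render_grating",
           "coi_contrasts", "grating_diameters", "find_optimal_gabor"]

A_MAX = 2.52           # max Gabor amplitude (half the max contrast)
C_MAX = 2 * A_MAX      # max contrast seen during training
D_MAX = 120.0          # max grating diameter, px (3.43 deg)


@dataclass(frozen=True)
class GaborParams:
    center: tuple[float, float]   # (row, col), px
    size: float                   # +-2 envelope std, px
    frequency: float              # cycles per 4 envelope std
    phase: float                  # radians in [0, 2 pi)
    orientation: float            # radians in [0, pi)
    amplitude: float

    def __post_init__(self):
        if self.size <= 0 or self.frequency <= 0:
            raise ValueError("size and frequency must be positive")
        if self.amplitude > A_MAX + 1e-9:
            raise ValueError(f"amplitude exceeds a_max = {A_MAX}")


def _mesh(side: int):
    r = np.arange(side, dtype=float)
    return np.meshgrid(r, r, indexing="ij")


def render_gabor(params: GaborParams, side: int = 40,
                 geometry: GeometryConfig = GeometryConfig()) -> np.ndarray:
    """Render a Gabor on a zero-background canvas; |pixels| <= amplitude."""
    rr, cc = _mesh(side)
    u = rr - params.center[0]
    v = cc - params.center[1]
    std = params.size / 4.0
    envelope = np.exp(-(u ** 2 + v ** 2) / (2 * std ** 2))
    cpp = params.frequency / params.size     # cycles per pixel
    arg = 2 * np.pi * cpp * (u * np.cos(params.orientation)
                             + v * np.sin(params.orientation)) + params.phase
    return params.amplitude * envelope * np.cos(arg)


def render_plaid(optimal: GaborParams, c_opt: float, c_orth: float,
                 mask_phase: float, side: int = 40) -> np.ndarray:
    """Linear superposition of the optimal Gabor at contrast ``c_opt``
    with its 90-degree-rotated version at contrast ``c_orth`` and phase
    ``mask_phase``."""
    img = np.zeros((side, side))
    if c_opt > 0:
        img += render_gabor(replace(optimal, amplitude=c_opt / 2.0), side)
    if c_orth > 0:
        orth = replace(optimal, amplitude=c_orth / 2.0, phase=mask_phase,
                       orientation=(optimal.orientation + np.pi / 2) % np.pi)
        img += render_gabor(orth, side)
    return img


def render_grating(optimal: GaborParams, diameter: float,
                   side: int = 40, amplitude: float = A_MAX) -> np.ndarray:
    """Full-contrast sinusoidal grating with the optimal Gabor's
    orientation, frequency, phase and center, sharply masked to zero
    (mean gray) outside a circle of the given diameter."""
    if diameter <= 0:
        return np.zeros((side, side))
    rr, cc = _mesh(side)
    u = rr - optimal.center[0]
    v = cc - optimal.center[1]
    cpp = optimal.frequency / optimal.size
    arg = 2 * np.pi * cpp * (u * np.cos(optimal.orientation)
                             + v * np.sin(optimal.orientation)) + optimal.phase
    disc = (u ** 2 + v ** 2) <= (diameter / 2.0) ** 2
    return amplitude * np.cos(arg) * disc


def coi_contrasts() -> np.ndarray:
    """Contrast grid for the plaid experiment: 0 plus a 9-step geometric
    ladder topping out at half the maximum contrast."""
    ladder = np.minimum(0.01 * C_MAX * 1.63069 ** np.arange(9), 0.5 * C_MAX)
    return np.concatenate([[0.0], ladder])


def grating_diameters() -> np.ndarray:
    """15 geometric diameters up to d_max = 120 px (3.43 deg)."""
    return 0.05 * D_MAX * 1.23859 ** np.arange(15)


@dataclass(frozen=True)
class GaborGrids:
    """Search grids for the optimal-Gabor scan."""

    centers_row: np.ndarray
    centers_col: np.ndarray
    orientations: np.ndarray
    phases: np.ndarray
    sizes: np.ndarray
    frequencies: np.ndarray
    amplitudes: np.ndarray

    @classmethod
    def full(cls, side: int = 40) -> "GaborGrids":
        """The exhaustive grid: every pixel center, 12 orientations,
        8 phases, 8 geometric sizes (4..40 px), 10 geometric frequencies,
        6 geometric amplitudes up to a_max."""
        return cls(
            centers_row=np.arange(side, dtype=float),
            centers_col=np.arange(side, dtype=float),
            orientations=np.pi * np.arange(12) / 12,
            phases=2 * np.pi * np.arange(8) / 8,
            sizes=4.0 * 1.3895 ** np.arange(8),
            frequencies=(1.3 ** -1) * 1.3 ** np.arange(10),
            # the top rung is the maximum contrast itself (clip rounding)
            amplitudes=np.minimum(0.01 * A_MAX * 2.51189 ** np.arange(6), A_MAX),
        )

    @classmethod
    def reduced(cls, side: int = 40) -> "GaborGrids":
        """Coarse grid for desk-scale runs: 9x9 centers, 6 orientations,
        4 phases, 4 sizes, 5 frequencies, 3 amplitudes."""
        return cls(
            centers_row=np.linspace(4, side - 5, 9).round(),
            centers_col=np.linspace(4, side - 5, 9).round(),
            orientations=np.pi * np.arange(6) / 6,
            phases=2 * np.pi * np.arange(4) / 4,
            sizes=4.0 * 1.3895 ** np.arange(0, 8, 2),
            frequencies=(1.3 ** -1) * 1.3 ** np.arange(0, 10, 2),
            amplitudes=np.minimum(0.01 * A_MAX * 2.51189 ** np.array([3, 4, 5]),
                                  A_MAX),
        )

    @property
    def cardinality(self) -> int:
        return (self.centers_row.size * self.centers_col.size
                * self.orientations.size * self.phases.size * self.sizes.size
                * self.frequencies.size * self.amplitudes.size)


def find_optimal_gabor(model, grids: GaborGrids | None = None, side: int = 40,
                       batch_size: int = 512) -> list[GaborParams]:
    """Exhaustive grid argmax of the model prediction, per unit.

    Evaluates every grid combination once for all units of ``model``
    (anything with a ``predict(images) -> (B, N)`` method) and returns
    each unit's best :class:`GaborParams`. Deterministic: strictly
    greater responses win, so ties keep the earliest combination.
    """
    if grids is None:
        grids = GaborGrids.reduced(side)
    combos = list(product(grids.amplitudes, grids.sizes, grids.frequencies,
                          grids.orientations, grids.phases,
                          grids.centers_row, grids.centers_col))
    n_units = None
    best_resp = None
    best_idx = None
    for start in range(0, len(combos), batch_size):
        chunk = combos[start:start + batch_size]
        imgs = np.stack([
            render_gabor(GaborParams(center=(r, c), size=s, frequency=f,
                                     phase=ph, orientation=th, amplitude=a), side)
            for a, s, f, th, ph, r, c in chunk])
        resp = np.asarray(model.predict(imgs))
        if not np.all(np.isfinite(resp)):
            raise FloatingPointError("model returned non-finite predictions")
        if best_resp is None:
            n_units = resp.shape[1]
            best_resp = np.full(n_units, -np.inf)
            best_idx = np.zeros(n_units, dtype=int)
        mx = resp.max(axis=0)
        upd = mx > best_resp
        arg = resp.argmax(axis=0)
        best_idx[upd] = start + arg[upd]
        best_resp[upd] = mx[upd]
    out = []
    for i in range(n_units):
        a, s, f, th, ph, r, c = combos[best_idx[i]]
        out.append(GaborParams(center=(r, c), size=s, frequency=f, phase=ph,
                               orientation=th, amplitude=a))
    return out
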