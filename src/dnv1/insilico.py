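"""In-silico electrophysiology: cross-orientation inhibition and size tuning.

Both experiments probe a fitted (or constructed) model the way an
electrophysiologist probes a neuron. First each unit's optimal Gabor is
found by grid search (:func:`dnv1.stimuli.find_optimal_gabor`); then

- *cross-orientation inhibition*: plaids superimpose the optimal Gabor at
  contrast c_j with its orthogonal twin at contrast c_i, predictions are
  averaged over 8 mask phases, and the index

      COI(c_i, c_j) = 1 - rhat(c_i, c_j) / rhat(0, c_j)

  measures how much the mask suppresses the response relative to the
  optimal component alone; a unit counts as cross-orientation inhibited
  if any contrast combination reaches COI >= 0.10.

- *size tuning*: full-contrast gratings with the optimal parameters are
  shown through hard circular apertures of increasing diameter, and the
  suppression index SI = 1 - rhat_supp / rhat_max compares the full-field
  response to the curve's peak (0 = no surround suppression).

Both indices are ratios of predictions, hence invariant to scaling all
model outputs by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import (GaborParams, coi_contrasts, grating_diameters,
                      render_grating, render_plaid)

__all__ = ["COIResult", "SizeTuningResult", "coi_index", "size_tuning",
           "suppression_index", "COI_THRESHOLD"]

COI_THRESHOLD = 0.10
N_MASK_PHASES = 8


@dataclass
class COIResult:
    contrasts: np.ndarray          # shared contrast ladder (incl. 0)
    responses: np.ndarray          # (n_orth, n_opt) phase-averaged rhat
    coi: np.ndarray                # (n_orth, n_opt) masked array, NaN undefined
    max_coi: float
    inhibited: bool


def coi_index(model, unit: int, optimal: GaborParams,
              side: int = 40) -> COIResult:
    """Plaid contrast-tuning and the cross-orientation inhibition index
    for one unit. Entries with a zero reference response rhat(0, c_j)
    are undefined and returned as NaN."""
    cs = coi_contrasts()
    phases = 2 * np.pi * np.arange(N_MASK_PHASES) / N_MASK_PHASES
    imgs = np.stack([
        render_plaid(optimal, c_opt=cj, c_orth=ci, mask_phase=ph, side=side)
        for ci in cs for cj in cs for ph in phases])
    resp = np.asarray(model.predict(imgs))[:, unit]
    resp = resp.reshape(cs.size, cs.size, phases.size).mean(axis=2)
    ref = resp[0]                                  # mask contrast 0, per c_j
    with np.errstate(divide="ignore", invalid="ignore"):
        coi = 1.0 - resp / ref[None, :]
    coi[:, ref <= 0] = np.nan
    max_coi = float(np.nanmax(coi)) if np.isfinite(coi).any() else np.nan
    return COIResult(contrasts=cs, responses=resp, coi=coi, max_coi=max_coi,
                     inhibited=bool(max_coi >= COI_THRESHOLD))


@dataclass
class SizeTuningResult:
    diameters: np.ndarray
    responses: np.ndarray
    si: float                      # NaN if the curve never responds


def size_tuning(model, unit: int, optimal: GaborParams,
                side: int = 40) -> SizeTuningResult:
    """Size-tuning curve over the 15-diameter grid and its suppression
    index. The grating uses the optimal Gabor's phase (no phase
    averaging) and full contrast."""
    ds = grating_diameters()
    imgs = np.stack([render_grating(optimal, d, side=side) for d in ds])
    resp = np.asarray(model.predict(imgs))[:, unit]
    return SizeTuningResult(diameters=ds, responses=resp,
                            si=suppression_index(resp))


def suppression_index(curve: np.ndarray) -> float:
    """SI = 1 - rhat_supp / rhat_max; rhat_supp is the response at the
    largest (full-field) diameter. NaN when the curve peak is zero."""
    curve = np.asarray(curve, dtype=float)
    peak = curve.max()
    if peak <= 0:
        return float("nan")
    return float(1.0 - curve[-1] / peak)
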