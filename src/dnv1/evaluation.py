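"""Accuracy metrics with observation-noise correction.

Repeated presentations of the same image let us split a neuron's response
variance into a stimulus-driven (explainable) part and trial-to-trial
observation noise. The noise variance is the across-trial variance of the
response to a fixed image, averaged over images,

    sigma^2_noise = E_j[ Var_t(r_t | x_j) ],

and the explainable variance is Var[r] - sigma^2_noise. A model is scored
by the fraction of explainable variance explained,

    FEV = 1 - (MSE - sigma^2_noise) / Var_exp,

where the mean squared residual is taken over individual (image, trial)
observations so the noise correction is exact in expectation: a model
predicting each image's true mean rate scores 1 regardless of trial
noise, and the grand-mean predictor scores 0.

Trials may be missing (2-4 repeats per image); all estimators honour a
per-image trial mask. The across-trial variance uses the unbiased (n-1)
estimator; the residual mean uses 1/N as defined.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["noise_variance", "explainable_variance", "fev", "avg_correlation",
           "neuron_filter", "EV_RATIO_THRESHOLD"]

EV_RATIO_THRESHOLD = 0.15   # neurons below this explainable/total ratio are dropped


def _check(responses: np.ndarray, mask: np.ndarray | None):
    r = np.asarray(responses, dtype=float)
    if r.ndim != 3:
        raise ValueError("responses must be (images, trials, neurons)")
    if mask is None:
        mask = np.ones(r.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    return r, mask


def noise_variance(responses: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron observation-noise variance.

    Mean over images (with >= 2 observed trials) of the unbiased
    across-trial response variance. Neurons of a dataset without any
    multi-trial image come back NaN.
    """
    r, mask = _check(responses, mask)
    nt = mask.sum(axis=1)                              # trials per image
    usable = nt >= 2
    if not usable.any():
        return np.full(r.shape[2], np.nan)
    m = mask[..., None]
    mean = (r * m).sum(axis=1) / np.maximum(nt, 1)[:, None]
    ss = (((r - mean[:, None, :]) * m) ** 2).sum(axis=1)
    var = ss[usable] / (nt[usable, None] - 1)
    return var.mean(axis=0)


def explainable_variance(responses: np.ndarray,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """Per-neuron Var[r] - sigma^2_noise, with Var[r] the variance over
    all observed (image, trial) responses."""
    r, mask = _check(responses, mask)
    total = _total_variance(r, mask)
    return total - noise_variance(r, mask)


def _total_variance(r: np.ndarray, mask: np.ndarray) -> np.ndarray:
    m = mask[..., None]
    n = mask.sum()
    mean = (r * m).sum(axis=(0, 1)) / n
    return (((r - mean) * m) ** 2).sum(axis=(0, 1)) / n


def fev(responses: np.ndarray, predictions: np.ndarray,
        mask: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Per-neuron fraction of explainable variance explained and its mean.

    ``predictions`` (images, neurons) are broadcast over trials; residuals
    are computed against per-trial observations. Neurons with
    non-positive explainable variance are NaN-ed out with a warning and
    excluded from the mean.
    """
    r, mask = _check(responses, mask)
    rhat = np.asarray(predictions, dtype=float)
    sig2 = noise_variance(r, mask)
    var_exp = explainable_variance(r, mask)
    m = mask[..., None]
    n = mask.sum()
    mse = (((r - rhat[:, None, :]) * m) ** 2).sum(axis=(0, 1)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 1.0 - (mse - sig2) / var_exp
    bad = ~(var_exp > 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} neuron(s) with non-positive "
                      "explainable variance excluded from FEV", stacklevel=2)
        out[bad] = np.nan
    return out, float(np.nanmean(out))


def avg_correlation(mean_responses: np.ndarray, predictions: np.ndarray) -> float:
    """Mean over neurons of the Pearson correlation between per-image mean
    responses and predictions; neurons with a constant prediction (or a
    constant response) contribute 0."""
    r = np.asarray(mean_responses, dtype=float)
    rhat = np.asarray(predictions, dtype=float)
    rc = r - r.mean(axis=0)
    pc = rhat - rhat.mean(axis=0)
    denom = np.sqrt((rc ** 2).sum(axis=0) * (pc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (rc * pc).sum(axis=0) / denom
    corr[~np.isfinite(corr)] = 0.0
    return float(corr.mean())


def neuron_filter(responses: np.ndarray, mask: np.ndarray | None = None,
                  threshold: float = EV_RATIO_THRESHOLD) -> np.ndarray:
    """Boolean keep-mask: explainable-to-total variance ratio >= threshold."""
    r, mask = _check(responses, mask)
    total = _total_variance(r, mask)
    ve = explainable_variance(r, mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ve / total
    return np.asarray(ratio >= threshold)
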