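"""Post-fit interpretation of the learned normalization structure.

The central object is the image-averaged normalization-input matrix

    M_kl = E_images E_locations [ p_kl <y_k^{n_k}> ],

the average strength with which source channel k contributes to target
channel l's denominator (the pooled quantity that actually divides the
drive; the unpooled drive is available behind a flag). Combined with
per-filter orientation estimates, M is summarized three ways:

- *orientation split*: among pairs of oriented filters, normalizing input
  from sources within 45 degrees of the target's preferred orientation
  ("similar") vs. the rest, and their fold ratio;
- *10-degree bins*: the mean input as a function of the orientation
  difference, nine bins covering [0, 90] degrees;
- *cosine split*: similarity measured directly between the flattened
  filters (cosine > 0 vs. < 0), which also covers unoriented filters.

A nonspecific model has ratios near 1; orientation-specific normalization
shows up as similar > dissimilar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import POW_EPS, subunit_forward
from .model import EncodingModel
from .orientation import OrientationEstimate, estimate_orientation
from .autodiff import avg_pool_same, astensor

__all__ = ["NormInputMatrix", "SplitSummary", "normalization_input_matrix",
           "split_similar_dissimilar", "bin_by_orientation_difference",
           "cosine_similarity_split", "exponent_summary", "readout_contribution",
           "orientation_difference"]


@dataclass
class NormInputMatrix:
    matrix: np.ndarray                      # (source k, target l)
    estimates: list[OrientationEstimate]


def normalization_input_matrix(model: EncodingModel, images: np.ndarray,
                               pooled: bool = True,
                               batch_size: int = 512) -> NormInputMatrix:
    """Average normalizing input from each source to each target channel.

    Requires a center DN model (``dn`` or ``dn_nonspecific``). With
    ``pooled`` (default) the spatially pooled exponentiated drives enter,
    i.e. exactly the quantity summed in the denominator.
    """
    from .core import DNParams
    if not isinstance(model.dn, DNParams):
        raise ValueError("normalization-input analysis requires a center DN model")
    n = model.dn.exponents
    p = model.dn.norm_weights
    drive_mean = np.zeros(n.shape[0])
    count = 0
    for i in range(0, images.shape[0], batch_size):
        y = subunit_forward(images[i:i + batch_size], model.subunit, mode="eval")
        yn = ((y + POW_EPS).log() * astensor(n).reshape(1, -1, 1, 1)).exp()
        if pooled:
            yn = avg_pool_same(yn, model.dn.pool_size)
        drive_mean += yn.data.sum(axis=(0, 2, 3))
        count += yn.data.shape[0] * yn.data.shape[2] * yn.data.shape[3]
    drive_mean /= count
    matrix = p * drive_mean[:, None]
    estimates = [estimate_orientation(f) for f in model.subunit.filters]
    return NormInputMatrix(matrix=matrix, estimates=estimates)


def orientation_difference(theta_a: float, theta_b: float) -> float:
    """Acute angle between two orientations, in [0, pi/2]."""
    d = abs(theta_a - theta_b) % np.pi
    return min(d, np.pi - d)


@dataclass
class SplitSummary:
    similar_per_target: np.ndarray
    dissimilar_per_target: np.ndarray
    fold_ratio: float                 # inf when no dissimilar input, flagged
    capped: bool = False


def split_similar_dissimilar(result: NormInputMatrix,
                             threshold_deg: float = 45.0) -> SplitSummary:
    """Normalizing input from similarly oriented (< 45 deg) vs.
    dissimilarly oriented (>= 45 deg) sources, oriented filters only."""
    oriented = np.array([e.oriented for e in result.estimates])
    if oriented.sum() < 2:
        raise ValueError("need at least two oriented filters")
    thetas = np.array([e.theta for e in result.estimates])
    idx = np.flatnonzero(oriented)
    sim = np.zeros(idx.size)
    dis = np.zeros(idx.size)
    thr = np.deg2rad(threshold_deg)
    for j, l in enumerate(idx):
        for k in idx:
            d = orientation_difference(thetas[k], thetas[l])
            if d < thr:
                sim[j] += result.matrix[k, l]
            else:
                dis[j] += result.matrix[k, l]
    tot_dis = dis.sum()
    capped = bool(tot_dis <= 0)
    ratio = np.inf if capped else sim.sum() / tot_dis
    return SplitSummary(similar_per_target=sim, dissimilar_per_target=dis,
                        fold_ratio=float(ratio), capped=capped)


def bin_by_orientation_difference(results: NormInputMatrix | list[NormInputMatrix],
                                  width_deg: float = 10.0) -> np.ndarray:
    """Mean normalizing input per orientation-difference bin over [0, 90]
    degrees (nine bins at the default width); NaN marks empty bins.
    Accepts one fitted model's matrix or several (profiles averaged by
    pooling all pairs)."""
    if isinstance(results, NormInputMatrix):
        results = [results]
    n_bins = int(round(90.0 / width_deg))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for res in results:
        oriented = np.flatnonzero([e.oriented for e in res.estimates])
        thetas = np.array([e.theta for e in res.estimates])
        for l in oriented:
            for k in oriented:
                d = np.rad2deg(orientation_difference(thetas[k], thetas[l]))
                b = min(int(d // width_deg), n_bins - 1)
                sums[b] += res.matrix[k, l]
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


def cosine_similarity_split(result: NormInputMatrix,
                            filters: np.ndarray) -> SplitSummary:
    """Split by the cosine similarity of the flattened filters: similar
    when cosine > 0, dissimilar when < 0; exact-zero pairs join neither
    group. Covers unoriented filters too."""
    flat = np.asarray(filters, dtype=float).reshape(filters.shape[0], -1)
    norms = np.linalg.norm(flat, axis=1)
    cos = (flat @ flat.T) / np.outer(norms, norms)
    sim_mask = cos > 0
    dis_mask = cos < 0
    sim = (result.matrix * sim_mask).sum(axis=0)
    dis = (result.matrix * dis_mask).sum(axis=0)
    tot_dis = dis.sum()
    capped = bool(tot_dis <= 0)
    ratio = np.inf if capped else sim.sum() / tot_dis
    return SplitSummary(similar_per_target=sim, dissimilar_per_target=dis,
                        fold_ratio=float(ratio), capped=capped)


def exponent_summary(models: list[EncodingModel], bins: int = 20) -> dict:
    """Pooled histogram and mean of the DN exponents across models, with
    an oriented/unoriented breakdown per the filters' orientation flags."""
    if not models:
        raise ValueError("need at least one fitted model")
    all_n, oriented_n, unoriented_n = [], [], []
    for m in models:
        n = m.dn.exponents
        flags = np.array([estimate_orientation(f).oriented
                          for f in m.subunit.filters])
        all_n.append(n)
        oriented_n.append(n[flags])
        unoriented_n.append(n[~flags])
    all_n = np.concatenate(all_n)
    hist, edges = np.histogram(all_n, bins=bins)
    return {
        "mean": float(all_n.mean()),
        "histogram": hist,
        "bin_edges": edges,
        "oriented_mean": float(np.concatenate(oriented_n).mean())
        if any(a.size for a in oriented_n) else np.nan,
        "unoriented_mean": float(np.concatenate(unoriented_n).mean())
        if any(a.size for a in unoriented_n) else np.nan,
    }


def readout_contribution(feature_weights: np.ndarray | list[np.ndarray]) -> dict:
    """Per-channel readout contribution and its coefficient of variation.

    Each neuron's feature weights are scaled to unit sum across channels
    (removing the spatial/feature scaling degeneracy), averaged across
    neurons, optionally pooled across models; CV = std/mean across the
    channel means. Zero-weight neurons are excluded with a warning.
    """
    if isinstance(feature_weights, np.ndarray):
        feature_weights = [feature_weights]
    rows = []
    dropped = 0
    for b in feature_weights:
        b = np.asarray(b, dtype=float)
        sums = b.sum(axis=1)
        bad = sums <= 0
        dropped += int(bad.sum())
        if (~bad).any():
            rows.append(b[~bad] / sums[~bad, None])
    if dropped:
        warnings.warn(f"{dropped} neuron(s) with all-zero feature weights "
                      "excluded", stacklevel=2)
    if not rows:
        raise ValueError("no neurons with nonzero feature weights")
    pooled = np.concatenate(rows, axis=0)
    mean_per_channel = pooled.mean(axis=0)
    cv = float(mean_per_channel.std() / mean_per_channel.mean())
    return {"mean_per_channel": mean_per_channel, "cv": cv,
            "n_neurons": pooled.shape[0]}
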