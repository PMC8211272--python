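"""Synthetic stimuli and ground-truth populations for end-to-end testing.

Real recordings pair normalized natural-image stimuli with trial-repeated
spike counts. This module emulates their statistics without any download:

- *images*: 1/f-spectrum ("pink") noise, optionally mixed with oriented
  Gabor texture patches so the stimuli carry the oriented energy natural
  scenes have, optionally vignetted by a soft cosine aperture (1 degree
  inner diameter), and always standardized so the pooled pixel
  distribution has zero mean and unit variance;
- *ground truth*: a divisive-normalization encoding model with a Gabor
  filter bank spanning 8 orientations in quadrature pairs, normalization
  weights planted as p_kl proportional to exp(kappa * cos 2 dtheta_kl)
  (kappa = 0 gives a nonspecific pool), energy-reading one-hot readouts,
  and per-neuron gains calibrated so mean spike counts are moderate;
- *responses*: independent Poisson trial noise around the model's
  predicted means, 2-4 repeats per image, with image-level 64/16/20
  train/validation/test splits.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import Architecture, EncodingModel
from .core import DNParams, SubunitParams, subunit_forward
from .readout import ReadoutParams, TentGrid, elu_star_values
from .stimuli import GaborParams, render_gabor

__all__ = ["SyntheticConfig", "DatasetContainer", "generate_images",
           "preprocess_images", "make_ground_truth", "make_energy_model",
           "simulate_population", "make_dataset"]

SPLIT_FRACTIONS = (0.64, 0.16, 0.20)


@dataclass
class SyntheticConfig:
    """Conditions of a simulated experiment."""

    n_images: int = 4000
    n_neurons: int = 20
    trials: tuple[int, int] = (2, 4)     # inclusive repeat range per image
    channels: int = 16
    kernel_size: int = 13
    pool_size: int = 5
    kappa: float = 1.0                   # orientation-specificity of planted p
    exponent: float = 2.0                # planted DN exponent (energy-like)
    semi_saturation: float = 0.5
    target_mean_rate: float = 2.0        # spikes per trial, per neuron
    target_ev_ratio: float = 0.285       # explainable/total variance under Poisson noise
    style: str = "texture_mix"
    aperture: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_images, self.n_neurons, self.channels) <= 0:
            raise ValueError("counts must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not (1 <= self.trials[0] <= self.trials[1]):
            raise ValueError("invalid trial range")


@dataclass
class DatasetContainer:
    """Images, trial-masked responses, split labels and (for synthetic
    data) the generating model's parameters."""

    images: np.ndarray                 # (N, H, W) standardized
    responses: np.ndarray              # (N, T_max, neurons) integer counts
    mask: np.ndarray                   # (N, T_max) observed-trial flags
    split: np.ndarray                  # (N,) 'train' | 'val' | 'test'
    ground_truth: dict | None = None

    def save(self, path: str | Path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images)
            f.create_dataset("responses", data=self.responses)
            f.create_dataset("mask", data=self.mask)
            f.create_dataset("split", data=np.char.encode(self.split))
            if self.ground_truth:
                g = f.create_group("ground_truth")
                for k, v in self.ground_truth.items():
                    g.create_dataset(k, data=v)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetContainer":
        import h5py
        with h5py.File(path, "r") as f:
            gt = None
            if "ground_truth" in f:
                gt = {k: f["ground_truth"][k][()] for k in f["ground_truth"]}
            return cls(images=f["images"][()], responses=f["responses"][()],
                       mask=f["mask"][()].astype(bool),
                       split=np.char.decode(f["split"][()]), ground_truth=gt)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def _pink_noise(n: int, side: int, rng: np.random.Generator) -> np.ndarray:
    white = rng.normal(size=(n, side, side))
    spec = np.fft.fft2(white)
    fr = np.fft.fftfreq(side)
    rad = np.hypot(*np.meshgrid(fr, fr, indexing="ij"))
    rad[0, 0] = np.inf                      # kill DC
    imgs = np.fft.ifft2(spec / rad).real
    return imgs


def _texture_patches(n: int, side: int, rng: np.random.Generator,
                     patches_per_image: int = 6) -> np.ndarray:
    out = np.zeros((n, side, side))
    for i in range(n):
        for _ in range(patches_per_image):
            g = GaborParams(
                center=(rng.uniform(0, side - 1), rng.uniform(0, side - 1)),
                size=float(rng.uniform(8, 24)),
                frequency=float(rng.uniform(2, 4)),
                phase=float(rng.uniform(0, 2 * np.pi)),
                orientation=float(rng.uniform(0, np.pi)),
                amplitude=1.0)
            out[i] += render_gabor(g, side)
    return out


def _cosine_aperture(side: int, px_per_deg: float = 35.0) -> np.ndarray:
    c = (side - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(side) - c, np.arange(side) - c, indexing="ij")
    r = np.hypot(rr, cc)
    r0 = 0.5 * px_per_deg                  # 1 deg inner diameter
    r1 = side / 2.0
    w = np.clip((r - r0) / max(r1 - r0, 1e-9), 0.0, 1.0)
    return 0.5 * (1 + np.cos(np.pi * w))


def generate_images(n: int, seed: int = 0, style: str = "pink_noise",
                    aperture: bool = False, side: int = 40) -> np.ndarray:
    """Standardized stimulus images (pooled mean 0, std 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    imgs = _pink_noise(n, side, rng)
    imgs /= imgs.std()
    if style == "texture_mix":
        imgs = 0.5 * imgs + _texture_patches(n, side, rng)
    elif style != "pink_noise":
        raise ValueError(f"unknown style {style!r}")
    if aperture:
        imgs = imgs * _cosine_aperture(side)
    imgs = imgs - imgs.mean()
    imgs = imgs / imgs.std()
    return imgs


def preprocess_images(raw: np.ndarray, crop_side: int = 40) -> np.ndarray:
    """Study preprocessing for raw stimuli: 2x block-mean downsampling,
    symmetric central crop and population standardization."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3:
        raise ValueError("raw must be (N, H, W)")
    n, h, w = raw.shape
    if h < 2 * crop_side or w < 2 * crop_side:
        raise ValueError(f"raw images must be at least {2 * crop_side} px per side")
    h2, w2 = (h // 2) * 2, (w // 2) * 2
    ds = raw[:, :h2, :w2].reshape(n, h2 // 2, 2, w2 // 2, 2).mean(axis=(2, 4))
    r0 = (ds.shape[1] - crop_side) // 2
    c0 = (ds.shape[2] - crop_side) // 2
    out = ds[:, r0:r0 + crop_side, c0:c0 + crop_side]
    out = out - out.mean()
    std = out.std()
    return out / std if std > 0 else out


# ---------------------------------------------------------------------------
# ground truth and simulation
# ---------------------------------------------------------------------------

def _gabor_filter_bank(channels: int, kernel_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature Gabor pairs spanning channels//2 orientations; returns
    (filters, per-channel preferred orientation)."""
    n_orient = channels // 2
    c = (kernel_size - 1) / 2.0
    filters = np.zeros((channels, kernel_size, kernel_size))
    thetas = np.zeros(channels)
    for o in range(n_orient):
        theta = np.pi * o / n_orient
        for q, phase in enumerate((0.0, np.pi / 2)):
            g = GaborParams(center=(c, c), size=float(kernel_size - 1),
                            frequency=3.0, phase=phase, orientation=theta,
                            amplitude=1.0)
            f = render_gabor(g, kernel_size)
            f -= f.mean()
            f /= np.linalg.norm(f)
            filters[2 * o + q] = f
            thetas[2 * o + q] = theta
    return filters, thetas


def make_ground_truth(cfg: SyntheticConfig) -> EncodingModel:
    """Construct the generating DN model for a synthetic population.

    The normalization weights are planted as p_kl proportional to
    exp(kappa cos 2 dtheta_kl) and column-normalized against the mean
    pooled drives of a calibration image batch so every denominator stays
    O(1); readout gains are bisected per neuron so the mean predicted
    count matches ``cfg.target_mean_rate`` on the calibration batch.
    """
    rng = np.random.default_rng(cfg.seed)
    C = cfg.channels
    if C % 2 or C < 16:
        raise ValueError("channels must be even and >= 16 (8 distinct orientations)")
    filters, thetas = _gabor_filter_bank(C, cfg.kernel_size)
    subunit = SubunitParams(filters, np.zeros(C), use_bn=False)

    n = np.full(C, cfg.exponent)
    sigma = np.full(C, cfg.semi_saturation)
    dtheta = thetas[:, None] - thetas[None, :]
    raw_p = np.exp(cfg.kappa * np.cos(2 * dtheta))     # (source k, target l)

    calib = generate_images(256, seed=cfg.seed + 1, style=cfg.style,
                            aperture=cfg.aperture)
    y = subunit_forward(calib, subunit, mode="eval").data
    from .autodiff import Tensor, avg_pool_same
    from .core import POW_EPS
    yn = np.exp(np.log(y + POW_EPS) * n[None, :, None, None])
    pooled = avg_pool_same(Tensor(yn), cfg.pool_size).data
    drive = pooled.mean(axis=(0, 2, 3))                # per source channel
    p = raw_p / (drive @ raw_p)[None, :]               # column-normalized
    dn = DNParams(n, sigma, p, pool_size=cfg.pool_size)

    fs = 40 - cfg.kernel_size + 1
    N = cfg.n_neurons
    spatial = np.zeros((N, fs, fs))
    feature = np.zeros((N, C))
    n_orient = C // 2
    locs = rng.integers(fs // 4, 3 * fs // 4, size=(N, 2))
    for i in range(N):
        spatial[i, locs[i, 0], locs[i, 1]] = 1.0
        o = i % n_orient
        feature[i, 2 * o] = 1.0
        feature[i, 2 * o + 1] = 1.0
    readout = ReadoutParams(spatial, feature, np.zeros(N),
                            np.zeros((N, len(TentGrid()))))
    arch = Architecture(channels=C, kernel_size=cfg.kernel_size,
                        pool_size=cfg.pool_size, variant="dn", use_bn=False,
                        n_neurons=N)
    model = EncodingModel(arch, subunit, dn, readout)

    # Per-neuron gain and bias calibration. Two targets: the mean rate,
    # and the explainable-to-total variance ratio a Poisson observer
    # would see, Var(mu) / (Var(mu) + E[mu]) = target_ev_ratio. The gain
    # s sets the stimulus modulation, the bias q recenters the mean;
    # nested bisection (q inside, s outside) solves both.
    z = model.core_forward(calib).data
    base_g = np.einsum("bchw,ihw,ic->bi", z, spatial, feature, optimize=True)
    var_target = (cfg.target_ev_ratio / (1 - cfg.target_ev_ratio)
                  * cfg.target_mean_rate)

    def bias_for_mean(gi: np.ndarray, s: float) -> float:
        lo, hi = -20.0, 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if elu_star_values(s * gi + mid).mean() < cfg.target_mean_rate:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    bias = np.zeros(N)
    for i in range(N):
        gi = base_g[:, i]
        lo, hi = 1e-6, 1e4
        for _ in range(50):
            s = np.sqrt(lo * hi)
            q = bias_for_mean(gi, s)
            if elu_star_values(s * gi + q).var() < var_target:
                lo = s
            else:
                hi = s
        s = np.sqrt(lo * hi)
        bias[i] = bias_for_mean(gi, s)
        feature[i] *= s
    model.readout.feature = feature
    model.readout.bias = bias
    return model


def make_energy_model(n_orient: int = 4, p_self: float = 0.5,
                      p_cross: float = 2.0, p_other: float = 0.1,
                      sigma: float = 0.5, exponent: float = 2.0,
                      spatial_std: float = 3.0, gain: float = 1.0,
                      variant: str = "dn", kernel_size: int = 13) -> EncodingModel:
    """Hand-constructed oriented-energy model for in-silico experiments.

    2*n_orient quadrature Gabor channels; one model unit per orientation
    reads its quadrature pair through a Gaussian spatial mask (std in
    feature-map px) — the spatial summation a fitted readout shows. The
    ``dn`` variant plants strong cross-orientation normalization
    (``p_cross`` onto orthogonal channels, ``p_self`` within-channel,
    ``p_other`` elsewhere), the canonical circuit for cross-orientation
    inhibition; the ``subunit`` variant keeps the identical core without
    normalization.
    """
    C = 2 * n_orient
    filters, thetas = _gabor_filter_bank(C, kernel_size)
    subunit = SubunitParams(filters, np.zeros(C), use_bn=False)
    dn = None
    if variant == "dn":
        d = np.abs(thetas[:, None] - thetas[None, :]) % np.pi
        d = np.minimum(d, np.pi - d)
        p = np.where(d < 1e-6, p_self,
                     np.where(np.abs(d - np.pi / 2) < 1e-6, p_cross, p_other))
        dn = DNParams(np.full(C, exponent), np.full(C, sigma), p, pool_size=5)
    elif variant != "subunit":
        raise ValueError("variant must be 'dn' or 'subunit'")
    fs = 40 - kernel_size + 1
    ctr = (fs - 1) / 2.0
    rr, cc = np.meshgrid(np.arange(fs) - ctr, np.arange(fs) - ctr, indexing="ij")
    mask = np.exp(-(rr ** 2 + cc ** 2) / (2 * spatial_std ** 2))
    mask /= mask.sum()
    spatial = np.tile(mask, (n_orient, 1, 1))
    feature = np.zeros((n_orient, C))
    for i in range(n_orient):
        feature[i, 2 * i] = gain
        feature[i, 2 * i + 1] = gain
    readout = ReadoutParams(spatial, feature, np.zeros(n_orient),
                            np.zeros((n_orient, len(TentGrid()))))
    arch = Architecture(channels=C, kernel_size=kernel_size, variant=variant,
                        use_bn=False, n_neurons=n_orient)
    return EncodingModel(arch, subunit, dn, readout)


def simulate_population(model: EncodingModel, images: np.ndarray,
                        trials: tuple[int, int] = (2, 4),
                        seed: int = 0) -> DatasetContainer:
    """Poisson spike counts from the model's predicted means, with a
    random number of repeats per image and image-level 64/16/20 splits."""
    rng = np.random.default_rng(seed)
    rhat = model.predict(images)
    if not np.all(np.isfinite(rhat)) or np.any(rhat < 0):
        raise FloatingPointError("ground-truth means must be finite and >= 0")
    n_img, n_neu = rhat.shape
    t_max = trials[1]
    n_t = rng.integers(trials[0], trials[1] + 1, size=n_img)
    mask = np.arange(t_max)[None, :] < n_t[:, None]
    counts = rng.poisson(np.broadcast_to(rhat[:, None, :],
                                         (n_img, t_max, n_neu)))
    counts = counts * mask[..., None]

    order = rng.permutation(n_img)
    n_train = int(round(SPLIT_FRACTIONS[0] * n_img))
    n_val = int(round(SPLIT_FRACTIONS[1] * n_img))
    split = np.empty(n_img, dtype="<U5")
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "val"
    split[order[n_train + n_val:]] = "test"

    gt = {"rates": rhat}
    if model.dn is not None:
        gt.update(n=model.dn.exponents, sigma=model.dn.semi_saturation)
        if hasattr(model.dn, "norm_weights"):
            gt["p"] = model.dn.norm_weights
        else:
            gt["c"] = model.dn.spatial_pools
            gt["d"] = model.dn.feature_weights
    return DatasetContainer(images=images, responses=counts, mask=mask,
                            split=split, ground_truth=gt)


def make_dataset(cfg: SyntheticConfig) -> tuple[DatasetContainer, EncodingModel]:
    """Images + ground truth + Poisson responses in one call."""
    images = generate_images(cfg.n_images, seed=cfg.seed, style=cfg.style,
                             aperture=cfg.aperture)
    model = make_ground_truth(cfg)
    data = simulate_population(model, images, trials=cfg.trials,
                               seed=cfg.seed + 2)
    return data, model
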