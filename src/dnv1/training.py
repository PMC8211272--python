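"""Fitting encoding models: Adam with constraint projections, early
stopping with stepwise learning-rate decay, hyperparameter sampling and
multi-seed model selection.

The schedule follows the study design: initial learning rate 1e-3,
mini-batches of 256 (image, trial) observations, validation Poisson loss
evaluated every 100 steps; after 10 evaluations without improvement the
weights are rewound to the best checkpoint and the learning rate is
divided by 3, and training ends when this has happened 4 times. All
sign-constrained parameters (exponents, semi-saturation constants,
normalization weights and pool factors, readout weights) are projected
onto the non-negative orthant after every Adam step, which preserves
exact zeros; the nonspecific variant is additionally re-projected onto
constant weight columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .core import DNParams, ExtendedDNParams, nonspecific_project, subunit_forward
from .evaluation import avg_correlation
from .losses import LossConfig, total_loss
from .model import EncodingModel

__all__ = ["TrainConfig", "FitResult", "Adam", "train",
           "HyperparameterSpace", "sample_hyperparameters", "select_top_models"]

NONNEGATIVE = {"n", "sigma", "p", "c", "d", "a", "b"}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 256
    eval_every: int = 100
    patience: int = 10
    decay_factor: float = 3.0
    num_decays: int = 4
    max_steps: int | None = None
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.eval_every,
               self.patience, self.decay_factor, self.num_decays) <= 0:
            raise ValueError("schedule fields must be positive")


@dataclass
class FitResult:
    model: EncodingModel
    trace: list = field(default_factory=list)   # (step, train_loss, val_loss, val_corr)
    validation_loss: float = np.inf
    validation_score: float = -np.inf           # avg correlation at the best checkpoint
    test_score: float | None = None
    loss_config: LossConfig | None = None
    steps_run: int = 0


class Adam:
    """Adaptive-moment gradient descent over a dict of numpy parameters."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _trainable_arrays(model: EncodingModel, freeze_filters: bool) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    if not freeze_filters:
        out["w"] = model.subunit.filters
        out["o"] = model.subunit.biases
    dn = model.dn
    if isinstance(dn, DNParams):
        out.update(n=dn.exponents, sigma=dn.semi_saturation, p=dn.norm_weights)
    elif isinstance(dn, ExtendedDNParams):
        out.update(n=dn.exponents, sigma=dn.semi_saturation,
                   c=dn.spatial_pools, d=dn.feature_weights)
    ro = model.readout
    out.update(a=ro.spatial, b=ro.feature, q=ro.bias, alpha=ro.alpha)
    return {k: np.array(v, dtype=float) for k, v in out.items()}


def _write_back(model: EncodingModel, arrays: dict[str, np.ndarray]) -> None:
    if "w" in arrays:
        model.subunit.filters = arrays["w"].copy()
        model.subunit.biases = arrays["o"].copy()
    dn = model.dn
    if isinstance(dn, DNParams):
        dn.exponents = arrays["n"].copy()
        dn.semi_saturation = arrays["sigma"].copy()
        dn.norm_weights = arrays["p"].copy()
    elif isinstance(dn, ExtendedDNParams):
        dn.exponents = arrays["n"].copy()
        dn.semi_saturation = arrays["sigma"].copy()
        dn.spatial_pools = arrays["c"].copy()
        dn.feature_weights = arrays["d"].copy()
    ro = model.readout
    ro.spatial = arrays["a"].copy()
    ro.feature = arrays["b"].copy()
    ro.bias = arrays["q"].copy()
    ro.alpha = arrays["alpha"].copy()


def _project(arrays: dict[str, np.ndarray], variant: str) -> None:
    for k in NONNEGATIVE & arrays.keys():
        np.maximum(arrays[k], 0.0, out=arrays[k])
    if variant == "dn_nonspecific" and "p" in arrays:
        arrays["p"][...] = nonspecific_project(arrays["p"])


def _flat_observations(responses: np.ndarray, mask: np.ndarray,
                       idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten (image, trial) pairs of a split into parallel index/count
    arrays; ``mask`` marks observed trials."""
    img_idx, trial_idx = np.nonzero(mask[idx])
    return idx[img_idx], responses[idx[img_idx], trial_idx]


def train(dataset, model: EncodingModel, loss_cfg: LossConfig,
          train_cfg: TrainConfig, freeze_filters: bool = False,
          trainable: set[str] | None = None,
          verbose: bool = False, eval_callback=None) -> FitResult:
    """Fit ``model`` in place on the dataset's train split, early-stopping
    on the validation split; returns the best-on-validation parameters.

    ``dataset`` must expose ``images`` (N, H, W), ``responses``
    (N, T, neurons), ``mask`` (N, T) and ``split`` (N,) with labels
    'train'/'val'/'test'. With ``freeze_filters`` the subunit stage is
    evaluated once (eval-mode statistics) and treated as a constant.
    ``trainable`` optionally restricts fitting to a named parameter
    subset (e.g. {"p"} for conditional-identifiability experiments);
    the rest stay at their current values.
    ``eval_callback(step, model, val_loss, val_corr)``, if given, runs at
    every validation evaluation with the current (not best) parameters.
    """
    rng = np.random.default_rng(train_cfg.seed)
    variant = model.arch.variant
    frozen = _trainable_arrays(model, freeze_filters)
    arrays = ({k: v for k, v in frozen.items() if k in trainable}
              if trainable is not None else frozen)
    if not arrays:
        raise ValueError("no trainable parameters selected")
    _project(arrays, variant)
    opt = Adam(arrays, lr=train_cfg.learning_rate)

    tr_idx = np.flatnonzero(dataset.split == "train")
    va_idx = np.flatnonzero(dataset.split == "val")
    if tr_idx.size == 0 or va_idx.size == 0:
        raise ValueError("dataset must contain train and validation partitions")

    driving_all = None
    log_driving_all = None
    if freeze_filters:
        chunks = [subunit_forward(dataset.images[i:i + 512], model.subunit,
                                  mode="eval").data.astype(np.float32)
                  for i in range(0, dataset.images.shape[0], 512)]
        driving_all = np.concatenate(chunks, axis=0)
        if variant in ("dn", "dn_nonspecific"):
            from .core import POW_EPS
            log_driving_all = np.log(driving_all + np.float32(POW_EPS))

    if (model.subunit.use_bn and model.subunit.bn_mean is None
            and not freeze_filters):
        # warm up the BN running statistics so the pre-training
        # validation pass has eval-mode statistics to standardize with
        warm = dataset.images[tr_idx[:train_cfg.batch_size]]
        subunit_forward(warm, model.subunit, mode="train")

    obs_img, obs_r = _flat_observations(dataset.responses, dataset.mask, tr_idx)
    va_img, va_r = _flat_observations(dataset.responses, dataset.mask, va_idx)
    va_mean = _masked_mean(dataset.responses[va_idx], dataset.mask[va_idx])

    def build_loss(img_ids: np.ndarray, counts: np.ndarray,
                   mode: str) -> tuple[Tensor, dict[str, Tensor]]:
        # graphs run in float32 for speed; the float64 master parameters
        # live in ``arrays`` and are updated by Adam
        tensors = {k: Tensor(v.astype(np.float32), requires_grad=True)
                   for k, v in arrays.items()}
        driving = log_driving = None
        images = dataset.images[img_ids]
        if log_driving_all is not None:
            log_driving = Tensor(log_driving_all[img_ids])
        elif driving_all is not None:
            driving = Tensor(driving_all[img_ids])
        rhat = model.forward(images, mode=mode, tensors=tensors,
                             driving=driving, log_driving=log_driving)
        loss = total_loss(rhat, counts, loss_cfg,
                          filters=tensors.get("w"), a=tensors.get("a"),
                          b=tensors.get("b"), alpha=tensors.get("alpha"))
        return loss, tensors

    def sync_model() -> None:
        full = dict(frozen)
        full.update(arrays)
        _write_back(model, full)

    def validation_metrics() -> tuple[float, float]:
        sync_model()
        if driving_all is not None:
            rhat = np.concatenate(
                [model.forward(None, driving=Tensor(driving_all[va_idx[i:i + 512]])).data
                 for i in range(0, va_idx.size, 512)])
        else:
            rhat = model.predict(dataset.images[va_idx], batch_size=512)
        obs = np.maximum(rhat[np.searchsorted(va_idx, va_img)], 1e-8)
        vloss = float(np.sum(obs - va_r * np.log(obs)) / va_r.shape[0])
        vcorr = avg_correlation(va_mean, rhat)
        return vloss, vcorr

    best = {k: v.copy() for k, v in arrays.items()}
    best_vloss, best_vcorr = validation_metrics()
    trace = [(0, np.nan, best_vloss, best_vcorr)]
    bad_evals = 0
    decays = 0
    step = 0
    max_steps = train_cfg.max_steps or 10 ** 9

    while step < max_steps:
        batch = rng.integers(0, obs_img.size, size=train_cfg.batch_size)
        loss, tensors = build_loss(obs_img[batch], obs_r[batch], mode="train")
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"training diverged at step {step}: loss={float(loss.data)}")
        loss.backward()
        opt.step({k: t.grad for k, t in tensors.items() if t.grad is not None})
        _project(arrays, variant)
        step += 1

        if step % train_cfg.eval_every == 0:
            vloss, vcorr = validation_metrics()
            trace.append((step, float(loss.data), vloss, vcorr))
            if eval_callback is not None:
                eval_callback(step, model, vloss, vcorr)
            if verbose:
                print(f"step {step:6d}  train {float(loss.data):10.3f}  "
                      f"val {vloss:8.4f}  corr {vcorr:6.3f}  lr {opt.lr:.2e}")
            if vloss < best_vloss:
                best_vloss, best_vcorr = vloss, vcorr
                best = {k: v.copy() for k, v in arrays.items()}
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= train_cfg.patience:
                    # patience exhausted: stop after the final decay,
                    # otherwise rewind to the best weights and decay lr
                    if decays >= train_cfg.num_decays:
                        break
                    decays += 1
                    for k in arrays:
                        arrays[k][...] = best[k]
                    opt.lr /= train_cfg.decay_factor
                    bad_evals = 0

    for k in arrays:
        arrays[k][...] = best[k]
    sync_model()
    return FitResult(model=model, trace=trace, validation_loss=best_vloss,
                     validation_score=best_vcorr, loss_config=loss_cfg,
                     steps_run=step)


def _masked_mean(responses: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-image mean spike count over observed trials: (N, neurons)."""
    counts = mask.sum(axis=1)[:, None]
    return (responses * mask[..., None]).sum(axis=1) / np.maximum(counts, 1)


# ---------------------------------------------------------------------------
# hyperparameter search and model selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperparameterSpace:
    """log10 intervals for the three regularizer weights."""

    smooth: tuple[float, float] = (-9.0, -3.5)
    sparse: tuple[float, float] = (-9.0, -4.5)
    out: tuple[float, float] = (-8.0, 2.0)

    @classmethod
    def for_variant(cls, variant: str) -> "HyperparameterSpace":
        """Search intervals per model class: the nonspecific and extended
        variants use the narrowed output-nonlinearity interval."""
        if variant in ("dn_nonspecific", "dn_extended"):
            return cls(out=(-5.0, 0.0))
        return cls()

    def __post_init__(self):
        for lo, hi in (self.smooth, self.sparse, self.out):
            if hi <= lo:
                raise ValueError("empty hyperparameter interval")


def sample_hyperparameters(space: HyperparameterSpace,
                           rng: np.random.Generator) -> LossConfig:
    """Draw each weight log-uniformly from its interval."""
    draw = lambda b: float(10.0 ** rng.uniform(*b))
    return LossConfig(lambda_smooth=draw(space.smooth),
                      lambda_sparse=draw(space.sparse),
                      lambda_out=draw(space.out))


def select_top_models(fits: list[FitResult], k: int = 10) -> dict:
    """Rank fits by validation score and summarize the top-k test scores
    with a normal-approximation 95% confidence interval."""
    import warnings

    if len(fits) < k:
        warnings.warn(f"only {len(fits)} fits available; using all", stacklevel=2)
        k = len(fits)
    ranked = sorted(fits, key=lambda f: f.validation_score, reverse=True)[:k]
    scores = np.array([f.test_score if f.test_score is not None
                       else f.validation_score for f in ranked], dtype=float)
    mean = float(scores.mean())
    sem = float(scores.std(ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return {"k": k, "mean": mean, "sem": sem,
            "ci95": (mean - 1.96 * sem, mean + 1.96 * sem),
            "scores": scores.tolist(), "fits": ranked}
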