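# Methods

This note documents the model this package implements, the choices made
where the published description leaves room, and what the synthetic-data
experiments do and do not establish.

## The encoding model

The model predicts trial-averaged spike counts of V1 neurons in response
to normalized grayscale images (40 × 40 px, 1.14° of visual field at
35 px/°). It is split into a *core*, shared by all neurons, and a
per-neuron *readout*.

**Subunit stage.** The image is convolved (valid, no padding) with C = 32
filters of 13 × 13 px (0.37°), passed through batch normalization without
re-scaling (BN\*: standardize to unit variance, add a learned per-channel
bias, no learned scale) and rectified:

    y_l = ReLU(BN*(w_l * x)),        y_l ∈ R^(28×28), y_l ≥ 0.

Because a learned scale would be redundant with the normalization weights
and readout (scaling y by β while scaling σ and the readout by the
matching factors leaves the prediction unchanged), BN\* omits it.

**Divisive normalization (DN) stage.** Each channel's exponentiated drive
is divided by a semi-saturation constant and a *learned* weighted sum of
all channels' locally pooled drives:

    z_l = y_l^{n_l} / (σ_l^{n_l} + Σ_k p_kl ⟨y_k^{n_k}⟩),

where ⟨·⟩ is 5 × 5 average pooling (stride 1), which makes the
normalizing input approximately phase-invariant without requiring many
phase-shifted filters. All of n_l, σ_l ≥ 0 and p_kl ≥ 0 are learned. The
matrix p is the object of scientific interest: which features normalize
which.

Variants: the *subunit* model replaces the DN stage with the identity
(an LN-LN baseline); the *nonspecific* control constrains each target's
incoming weights to be equal across source channels (C free weights
instead of C²); the *spatially extended* model replaces the weighted sum
by a dilated valid convolution (dilation 5, kernel k ∈ {1,3,5,7}) over
the pooled drives, with the kernel factorized into two non-negative
spatial pools per target and per-pool feature weights, so the
normalization pool can reach 0.49°–1.34° of the input image. With k = 1
the extended model reduces exactly to the center model.

**Readout.** Non-negative, factorized: g_i = Σ a_uv,i b_l,i z_uvl + q_i
(a spatial mask and a feature vector per neuron), followed by
r̂_i = h_i(g_i)·ELU\*(g_i) with ELU\*(g) = g for g ≥ 1, exp(g−1) below,
and h_i a positive per-neuron modulation expanded in a tent basis
(51 points on [−3, 6], spacing 0.18) with coefficients exp(α_ji). With
α = 0, h ≡ 1 on the grid interior and the output nonlinearity is ELU\*.

**Objective.** Poisson loss Σ(r̂ − r ln r̂) plus three penalties: Laplace
smoothness of the filters, the separable L1 norm of the factorized
readout, and squared first/second finite differences of α (per-neuron
mean). Optimization uses Adam (lr 10⁻³, batches of 256 observations),
evaluating validation Poisson loss every 100 steps; after 10 evaluations
without improvement the weights rewind to the best checkpoint and the
learning rate is divided by 3, four times in total. Non-negativity is
enforced by projection (clipping at zero) after every step, which
preserves exact zeros. Regularizer weights are drawn log-uniformly from
per-variant intervals when searching.

## Decisions where the description is open

- **Pooling boundary.** The 5 × 5 denominator pooling is stride-1 and
  zero-padded to "same" size so the denominator matches the 28 × 28
  numerator; border windows are under-pooled (divisor always 25).
  Interior pixels are exact; oracle tests compare interior pixels.
- **BN\***: variance epsilon 10⁻⁴, running statistics by exponential
  moving average with momentum 0.9, bias applied after standardization.
- **Numerical stability of y^n**: computed as exp(n·ln(y + ε)) with
  ε = 10⁻⁶ so gradients stay finite at y = 0; predictions are floored at
  10⁻⁸ inside the Poisson loss (floored entries are counted).
- **Output nonlinearity outside the grid**: the tents vanish outside
  [−3, 6], which would zero the prediction; g is clamped to the grid
  range before evaluating h. α is initialized at 0.
- **Finite differences of α**: first differences run over adjacent
  pairs, second differences over interior points; both vanish for
  constant α.
- **Early stopping quantity**: validation Poisson loss (the quantity the
  schedule monitors); the average correlation is reported alongside and
  used for cross-fit model selection. These two roles are deliberately
  distinct in the training loop.
- **Eq-29-style orientation estimate**: kernels are windowed with a
  centered Gaussian (std 3 px), mean-subtracted, scaled to unit L2 norm,
  zero-padded to 64 × 64; the power spectral density in the annulus
  0.3 < r < 0.7 (Nyquist units, strict inequalities) is summarized by
  the circular mean resultant m = Σ F e^{2iφ} / Σ F. The normalization
  by Σ F makes |m| a unit-free resultant length in [0, 1], comparable
  across filters, which the 0.125 oriented/unoriented threshold assumes.
  θ = arg(m)/2 mod π.
- **Normalization-input matrix**: averages the *pooled* quantity
  p_kl⟨y_k^{n_k}⟩ (what actually enters the denominator); the unpooled
  variant is available behind a flag.
- **Gabor phase/orientation convention**: orientation is the carrier
  wave-vector angle, counterclockwise from the positive row axis, pixels
  sampled at integer centers, origin top-left. Under this convention
  reversing the wave vector (φ → φ + π) together with negating the
  phase is the identity.
- **Size-tuning phase**: gratings use the optimal Gabor's single phase
  (no phase averaging); COI plaids average over the 8 mask phases.

## Automatic differentiation

No tensor-autodiff framework is part of the package's dependency set;
gradients are computed by a small reverse-mode tape (`dnv1.autodiff`)
providing exactly the primitives the model needs. Every primitive and
the full objective are tested against central finite differences. The
convolution and contraction primitives are expressed as BLAS matrix
products; the 5 × 5 pooling is a pair of banded matrix products, whose
operator is symmetric, making the backward pass the same operator.
Training runs in single precision with float64 master parameters.

## Synthetic data: what it emulates

The generator emulates the statistics the model was designed around, not
natural-image content:

- **Images**: 1/f-amplitude noise, optionally mixed with oriented Gabor
  texture patches (so stimuli carry oriented energy), an optional soft
  cosine aperture of 1° inner diameter, standardized to pooled zero mean
  and unit variance. A preprocessing path (2× block-mean downsampling,
  central 40 × 40 crop, standardization) handles raw 140 × 140 input.
- **Ground truth**: a DN model with a quadrature Gabor filter bank
  spanning 8 orientations, planted normalization weights
  p_kl ∝ exp(κ cos 2Δθ_kl) column-normalized so denominators stay O(1)
  (κ = 0 gives the nonspecific control), one-hot spatial readouts and
  quadrature-pair feature readouts. Per-neuron gain and bias are
  calibrated by bisection so the mean count is 2 spikes/trial and the
  explainable-to-total variance ratio under Poisson noise is ≈ 0.285,
  the regime of the recordings the model class targets (each neuron
  lands in roughly [0.15, 0.4]).
- **Responses**: independent Poisson counts per trial, 2–4 repeats per
  image, image-level 64/16/20 train/validation/test splits.

Passing tests on these populations shows the estimators and the training
loop are correct and that normalization structure is identifiable under
the model's own assumptions. It does not show that real V1 responses are
fit well, that over-dispersed (non-Poisson) noise is handled optimally,
or anything about stimulus statistics beyond second order.

## Problem sizes used in the test suite

Desk-scale defaults keep the suite tractable on one CPU: 16 channels,
2 000–4 000 synthetic images, step caps of a few thousand, and reduced
Gabor search grids (the full 73.7-million-stimulus grid is available via
configuration). The parameter-recovery experiment freezes the subunit
filters at the ground truth (the identifiability claim concerns the
normalization weights, and a 16-filter bank is recoverable only up to
rotations of its overcomplete basis otherwise) and fits n, σ, p and the
readout jointly.

## Identifiability of the normalization weights

Two facts emerged from the synthetic recovery experiments and are worth
stating precisely.

First, the normalization weights are *conditionally* identifiable: with
the subunit filters, exponents, semi-saturation constants and readout
held at the generating values, maximizing the Poisson likelihood over p
alone recovers the planted weights essentially exactly (Pearson ≈ 0.9
within ~1000 optimizer steps at 4000 images × 2 trials). The data
contain the information.

Second, the *joint* fit (DN stage and readout learned together, filters
frozen) reliably recovers the planted structure — the similar-to-
dissimilar fold ratio of normalizing input separates the κ = 1 and κ = 0
ground truths — but recovers the weight matrix itself only partially
(Pearson ≈ 0.5 at the full early-stopping schedule). The cause is an
optimization plateau, not a likelihood degeneracy: from the small
uniform spatial-readout initialization, gradient descent settles with
spatially diffuse readout masks (the shared feature maps are spatially
correlated under naturalistic stimuli, so a spread mask predicts almost
as well at first), and in that basin the conditionally optimal p differs
from the planted one. The diffuse basin's validation loss remains
clearly worse than the true-readout basin's, and sharpening happens, but
on a timescale far beyond desk-scale step budgets; regularizer weights
chosen by validation loss within the search intervals do not change
this. Interpreting fitted p matrices therefore warrants the same caution
the readout-contribution control applies: aggregate summaries (fold
ratios, binned profiles) are robust; entry-level weights inherit
readout-localization error.

## Known limitations

- Single time bin; no temporal dynamics or adaptation.
- Poisson likelihood only (over-dispersion available in the simulator as
  a robustness option but not in the objective).
- The extended model's crop bookkeeping supports the printed kernel
  sizes {1, 3, 5, 7}; other odd sizes work if the cropped numerator
  stays positive-sized.
- The exhaustive Gabor search is O(grid × units) model evaluations;
  gradient-based stimulus optimization is out of scope by design.
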