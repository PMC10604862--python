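# Methods

## Signal model and feature extraction

Epoching cuts continuous multichannel EEG into consecutive fixed-length
windows (default 5 s); trailing partial windows are discarded, never
padded, and labels/block identifiers are replicated onto every window of
their segment. Band decomposition uses a zero-phase 4th-order Butterworth
band-pass applied forward–backward (`sosfiltfilt`), standard EEG practice
that preserves phase; mains interference is removed with a 2nd-order IIR
notch of quality factor 30.

Differential entropy (DE) is computed per epoch/channel/band. The default
estimator band-pass filters the epoch and plugs its unbiased (n−1) sample
variance into the Gaussian closed form ½ ln(2πeσ²). Natural logarithms are
used throughout, consistent with the Gaussian density from which the closed
form derives; DE values are therefore in nats. An alternative estimator
takes half the log of the mean in-band power from a Hann-windowed
periodogram — the log-energy-spectrum equivalent. The two differ by
additive per-band constants, which are irrelevant downstream because every
classifier standardizes features per column; the variance estimator is the
default because its Gaussian calibration is exact. Constant (zero-variance)
epochs are rejected with the epoch/channel named rather than silently
producing −∞.

## Regularized CCA

For standardized views X (n × d₁) and Y (n × d₂) the implementation forms
sample covariances (n−1 denominator, matching the standardization), adds an
optional ridge ε·mean(diag(S))·I to each view, computes inverse square
roots by symmetric eigendecomposition, and takes the thin SVD of
M = S_XX^{-1/2} S_XY S_YY^{-1/2}. Projections are A = S_XX^{-1/2}U,
B = S_YY^{-1/2}V; canonical correlations are the singular values,
descending.

Numerical choices:

* **Ridge default 10⁻⁶** (relative to the mean covariance diagonal). With
  60–62 channels and a few hundred training epochs per fold the covariance
  can be ill-conditioned; this ridge stabilizes whitening without
  measurably shrinking ρ. The unregularized path is available and is the
  one compared against the independent eigen-oracle in tests.
* **Eigenvalue floor 10⁻¹²·λ_max** in the inverse square root. On the
  ridge-free path, clipping triggers a warning because it silently
  regularizes a singular covariance.
* **Sign convention.** SVD signs are arbitrary; each (uᵢ, vᵢ) pair is
  flipped jointly so the largest-magnitude element of uᵢ is positive. Joint
  flips preserve ρᵢ ≥ 0 and make fitted models reproducible.
* **Leakage-free application.** Standardization offsets/scales and the
  projection matrices are estimated on training data only and applied
  frozen to held-out epochs. The alternative — fitting on the pooled data —
  would inflate held-out accuracy and is deliberately not offered.

## IBC construction

Each of the 10 unordered band pairs (ordered δθ, δα, δβ, δγ, θα, θβ, θγ,
αβ, αγ, βγ) contributes X_F = α₁X′ + α₂Y′ with α₁ = α₂ = 0.5 by default
(the weights must sum to 1 and are exposed for sensitivity analyses).
Within a pair, columns follow descending canonical correlation, so "top-k"
always selects the most strongly coupled directions; the default
k = ⌊channels/2⌋ (31 for 62 channels, 30 for 60). The split-half analysis
uses the trailing ⌊channels/2⌋ components of the *same* fitted models, not
a refit.

## Classification and fusion

Both classifiers are linear-kernel SVMs (C = 1 default; the margin penalty
is exposed) with per-feature standardization stored in the model. Class
probabilities come from Platt sigmoid calibration fitted by internal
stratified cross-validation on the training fold (scikit-learn's
`CalibratedClassifierCV(SVC(kernel="linear"), ensemble=False)`); the CV
split is the only source of randomness and is seeded. Decision fusion sums
the two probability rows (optionally weighted, default (1, 1)) and takes
the argmax; exact ties resolve to the lowest class index for determinism.

## Evaluation protocol

Block-wise cross-validation defines one fold per stimulus block; the entire
pipeline — standardization, every per-pair CCA, and the classifiers — is
refitted per fold. A fold whose test block contains a class absent from
training is scored with a warning rather than dropped. The validity
protocol comprises the split-half comparison (paired t-test over fold
accuracies; a degenerate zero-variance difference yields p = NaN), the
top-k accuracy curve (monotonicity is *not* asserted — only the
rise-then-flatten envelope is a property of the method), and ICC/DCC:
ICC[k] is the mean over pairs of |Pearson r| between the pair's k-th IBC
column and integer-coded labels 0..c−1, DCC[k] the mean k-th canonical
correlation, CC their Pearson correlation over k. The absolute-Pearson-on-
integer-codes choice for categorical labels is isolated in one helper so a
correlation ratio or one-hot variant can be swapped in. No multiple-testing
correction is applied to the paired-test p-values; they are reported raw.

## Synthetic data

The generator plants r shared latent factors: band b's factor scores are
F_b = √γ·Z + √(1−γ)·E_b, and its DE matrix is
X_b = baseline + loading_scale·F_b L_bᵀ + class shift + noise. With
orthonormal loadings the population canonical correlation between coupled
bands is γ·g²/(g² + σ²) per factor, so γ is solved from the requested
`latent_corr`; targets beyond the attainable bound g²/(g² + σ²) raise an
error stating that bound. Ground truth (loadings, γ, population ρ) is
returned alongside the sample and is verified in tests against an
independent closed-form computation on the analytic covariance matrices.

Class structure enters as mean shifts: along the shared factors
(leading-canonical placement), along per-band directions orthogonal to the
factor subspace (trailing-canonical), restricted to one pair's factors
(specific-pair), or absent. A complementary scenario generates two
containers over one epoch layout — one separating only class 0 (trailing
directions, for the raw-DE classifier), one separating only the last class
(leading directions, for the IBC features) — so that decision fusion can
demonstrably recover what neither classifier resolves alone. Trailing
placement necessarily induces a small class-driven cross-band covariance
(any class-dependent mean in two bands correlates them); with the default
effect sizes this stays well below the planted factor coupling and the
shifted directions remain in the trailing half of the spectrum.

The raw-EEG generator re-expresses the latent DE targets as random-phase
sinusoids at random frequencies inside each band (variance set to
exp(2·DE)/(2πe)) plus a weak 1/f background, so that band-pass filtering
and variance-based DE recover the planted structure to within filter edge
effects.

**What the generator does not emulate:** volume conduction and electrode
geometry, non-Gaussian and non-stationary dynamics, phase–amplitude
coupling, artifacts, and between-subject variability. Passing tests
demonstrate that the pipeline recovers planted linear cross-band structure
and class effects under Gaussian noise; they do not certify accuracy levels
on real recordings.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| epoch length | 5 s | analysis window, no overlap |
| bands | δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz | canonical EEG bands |
| α₁, α₂ | 0.5, 0.5 | canonical-variate fusion weights |
| k | ⌊channels/2⌋ | components kept per band pair |
| ridge ε | 10⁻⁶ | relative covariance regularization |
| SVM C | 1.0 | margin penalty |
| fusion weights | (1, 1) | probability sum rule |
| generator geometry | 62 ch, 5 bands, 5 blocks, 3 classes, 135 epochs/block | mirrors a 62-channel study in which each block holds one ~4-min clip per class, cut into 5-s epochs |
| loading_scale / noise_sd | 3.0 / 1.0 | factor-signal fraction 0.9, so planted correlations up to 0.9 are attainable |
| class_effect | 1.0 | norm of the per-class factor-space mean shift |

## Study geometry for the reproductions

The Monte-Carlo studies behind `scripts/acceptance.py` run at 10 channels,
5 bands, 5 blocks × 135 epochs, 3 classes, k = 5. This keeps the shape of
the problem (signal in 3 of K leading components; feature-to-sample ratio
at k = K comparable to a 310-feature / ~2700-epoch recording) while each
block-wise CV completes in about a second. Parameter-recovery studies use
12 channels × 2000 epochs; the null threshold for "no planted coupling" is
the 97.5th percentile of the leading canonical correlation over 200
independent-Gaussian datasets of the same size, computed on the fly.

## Known limitations

* CCA is linear and two-view; kernel/sparse variants and joint analysis of
  more than two bands are out of scope.
* Probability calibration on small folds (few hundred epochs) is noisy;
  fused decisions inherit that noise.
* ICC for categorical labels via integer codes imposes an ordering on the
  classes; for unordered class sets a correlation ratio would be more
  principled (the hook exists, the default mirrors common practice).
* The EDF reader ingests one continuous recording as a single block/label;
  multi-condition recordings should be segmented upstream or loaded into
  the epoched HDF5 container directly.
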