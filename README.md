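# ibceeg — inter-band correlation features for EEG emotion recognition

Emotional states modulate EEG rhythms in several frequency bands at once,
and the bands do not act independently: delta, theta, alpha, beta and gamma
activity co-vary. `ibceeg` implements a feature-extraction pipeline that
turns that cross-band coupling itself into classification features, for
researchers working on affective computing and multichannel EEG decoding.

## Method

1. **Band-wise differential entropy (DE).** Each 5-s epoch is band-pass
   filtered into the five canonical bands (δ 1–4, θ 4–8, α 8–13, β 13–30,
   γ 30–50 Hz) and each epoch/channel/band is summarized by its differential
   entropy; for a Gaussian signal, DE = ½ ln(2πeσ²) nats, equivalent (up to a
   constant) to log band power. A 62-channel montage yields 310 DE features
   per epoch (62 × 5), a 60-channel montage 300.
2. **Canonical correlation analysis (CCA) per band pair.** For each of the
   10 unordered band pairs, the two per-channel DE matrices X, Y are
   standardized and CCA is solved by SVD of the whitened cross-covariance
   M = S_XX^{-1/2} S_XY S_YY^{-1/2} = UΣVᵀ, giving projection matrices
   A = S_XX^{-1/2}U, B = S_YY^{-1/2}V and canonical correlations ρ = diag(Σ).
   A small ridge (default 10⁻⁶ × mean covariance diagonal) stabilizes the
   whitening when channels outnumber what the training epochs support.
3. **IBC features.** The pair's canonical variates are fused by a convex
   weighted sum X_F = α₁X′ + α₂Y′ (α₁ = α₂ = ½ by default, α₁ + α₂ = 1),
   keeping the k components with the largest ρ (k = half the channel count
   by convention); the 10 per-pair blocks are concatenated into X_IBC.
4. **Decision-level fusion.** Linear-kernel SVMs with Platt-calibrated
   probabilities are trained on the raw DE features and on X_IBC; the fused
   prediction is argmax_k [p(ω_k | y_DE) + p(ω_k | y_IBC)].
5. **Evaluation.** Block-wise cross-validation (each stimulus block held out
   in turn, everything refit per fold) plus a validity protocol: split-half
   comparison (top-k vs bottom-k canonical components), top-k accuracy
   curves, and the correlation (CC) between per-component feature–label
   correlations (ICC) and canonical correlations (DCC).

A seeded synthetic-data module plants known cross-band canonical structure
and class effects, so the whole pipeline is testable without EEG recordings.

## Worked example

```python
import numpy as np
from ibceeg import (SynthSpec, simulate_de_features, fit_cca, IBCConfig,
                    build_ibc, blockwise_cv, de_fold_builder,
                    ibc_fold_builder, fused_fold_builder,
                    split_half_comparison, icc_dcc)

spec = SynthSpec(n_channels=10, n_epochs_per_block=135, latent_corr=0.8, seed=1)
de, labels, blocks, truth = simulate_de_features(spec)

model = fit_cca(de.band_matrix("delta"), de.band_matrix("theta"))
print("leading canonical correlations:", np.round(model.rho[:4], 3))

cfg = IBCConfig(k=5)
fset = build_ibc(de, cfg)
print("X_IBC shape:", fset.concatenated.shape)

for name, fb in [("DE", de_fold_builder(de, seed=1)),
                 ("IBC", ibc_fold_builder(de, cfg, seed=1)),
                 ("fused", fused_fold_builder(de, cfg, seed=1))]:
    print(name, round(blockwise_cv(fb, labels, blocks).mean_accuracy, 3))

top, bottom, p = split_half_comparison(de, cfg, seed=1)
print(f"split-half top={top:.3f} bottom={bottom:.3f} p={p:.2e}")
icc, dcc, cc = icc_dcc(de, cfg)
print(f"ICC-DCC correlation CC = {cc:.3f}")
```

Output:

```
leading canonical correlations: [0.887 0.842 0.802 0.178]
X_IBC shape: (675, 50)
DE 0.604
IBC 0.612
fused 0.615
split-half top=0.612 bottom=0.538 p=2.27e-02
ICC-DCC correlation CC = 0.515
```

The generator planted three shared latent factors with canonical
correlation 0.8 between every band pair; the fitted spectrum recovers them
(0.89/0.84/0.80) and then drops to the noise floor. Class information was
planted along the leading canonical directions, so the top-half IBC
components classify better than the bottom half (0.61 vs 0.54), decision
fusion edges out either single classifier, and the per-component
feature–label correlations track the canonical-correlation spectrum
(CC > 0.5).

## Command line

```bash
ibc simulate --spec spec.yaml --out synth.h5
ibc extract-de --input recording.edf --epoch-seconds 5 --out de.h5
ibc fit --de de.h5 --k 31 --alpha 0.5 --out ibc_model.h5
ibc transform --model ibc_model.h5 --de new_de.h5 --out ibc.csv
ibc evaluate --de de.h5 --report report.json
ibc validity --de de.h5 --k 5 --report validity.json
ibc run --config run.yaml
```

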