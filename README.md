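# pcgkit

Heart-disease screening from **phonocardiograms** (PCG) — audio
recordings of heart sounds. Each cardiac cycle contains two valve-closure
transients, S1 (≈30–100 Hz, start of systole) and S2 (≥100 Hz, end of
systole); valvular disease adds a *murmur*, band-limited noise between
the heart sounds whose frequency band is characteristic of the lesion
(aortic stenosis 100–450 Hz, mitral regurgitation 45–160 Hz, mitral
stenosis 40–95 Hz, mitral valve prolapse 45–90 Hz; the normal range is
100–180 Hz). `pcgkit` implements an end-to-end classification pipeline
for the five classes {NHF, AS, MR, MS, MVP}, exercisable entirely on
synthetic signals, aimed at researchers prototyping heart-sound
classifiers without access to clinical recordings.

The pipeline:

1. **Synthetic PCG generation** (`synthio`) — periodic S1/S2 bursts at a
   configurable heart rate plus disease-specific band-passed murmur
   noise (systolic for AS/MR/MVP, diastolic for MS) and white noise at a
   chosen SNR; WAV + manifest I/O.
2. **EEMD adaptive-filter denoising** (`eemdaf`) — ensemble empirical
   mode decomposition `x = Σₖ IMFₖ + r`; noise-dominated modes are
   identified with a white-noise IMF-energy model and removed, and an
   adaptive LMS canceller `w(n+1) = w(n) + μ e(n) u(n)` (stable for
   `μ < 2/(3 L P_in)`) mops up residual noise correlated with the
   rejected modes.
3. **SMOTE** (`smote`) — minority-class oversampling by segment
   interpolation `x_new = x + α (x_nn − x)`, α ~ U(0,1).
4. **Feature extraction** (`features`) — murmur-band power fractions,
   Shannon-envelope delta/theta modulation power, systolic/diastolic
   timing statistics from S1/S2 segmentation, global spectral stats.
5. **Impact-rate feature scoring** (`s2cir`) — soft-margin hyperplane
   `min ½‖s‖² + C Σ ξᵢ  s.t.  yᵢ(s·xᵢ + v) ≥ 1 − ξᵢ`, solved by a
   deterministic dual coordinate-ascent; the per-feature impact is
   `|sⱼ|·sd(Xⱼ)`.
6. **LV-PSO feature selection** (`lvpso`) — particle swarm over soft
   feature masks whose fitness is LVQ1 classification error with
   information-gain-weighted distance; acceleration coefficients
   e₁,e₂ ~ U(0,2) are classed low/medium/high and select the inertia
   weight (both low → 0.9, both high → 0.4, otherwise 0.65).
7. **Fuzzy inference × separable-conv classifier** (`fisxcnn`) — a
   five-layer first-order Sugeno system (product T-norm, normalized
   firing strengths, linear consequents, hybrid least-squares +
   gradient learning) produces a normal-vs-disease risk score that is
   fused into a 1-D Xception-style network: conv(32, k=5) → batchnorm →
   ReLU → maxpool → depthwise-separable conv(64, k=3) → batchnorm →
   ReLU → maxpool → global-average-pool → concat(risk) → dropout →
   dense → softmax, trained with categorical cross-entropy and Adam
   (lr 10⁻³). All layers are numpy with hand-derived backprop,
   validated against finite differences.
8. **Evaluation** (`evaluate`) — precision/recall/F1/accuracy, Cohen's
   κ, the polygon area metric (normalized hexagon area over precision,
   recall, F1, accuracy, AUC, Jaccard), and leakage-free stratified
   k-fold cross-validation (oversampling/selection/training refitted
   inside every training fold).

## Worked example

```python
from pcgkit import (SimConfig, simulate_recording, denoise_pcg,
                    EEMDConfig, LMSConfig, snr_db)

cfg = SimConfig(fs=4000.0, duration_s=5.0, snr_db=0.0, seed=0)
rec = simulate_recording("AS", cfg)          # aortic stenosis at 0 dB SNR
den = denoise_pcg(rec, EEMDConfig(n_trials=4, noise_sd=0.2, max_imfs=8),
                  LMSConfig(n_taps=8))
print(f"input SNR  {snr_db(rec.clean, rec.samples):5.2f} dB")
print(f"output SNR {snr_db(rec.clean, den.samples):5.2f} dB")
```

prints

```
input SNR  -0.08 dB
output SNR  6.33 dB
```

i.e. the denoiser recovers ≈6.4 dB of signal-to-noise ratio on this
recording (the mean gain over 20 seeds is ≈6.3 dB). The full study —
250 recordings at 15 dB SNR, denoised, featurized and classified under
stratified 5-fold CV — runs from the command line:

```bash
pcgkit run -c configs/default.yaml -o out/
```

and reports per-class precision/recall/F1 together with accuracy,
macro-F1, κ and the polygon area metric (all 1.000 at these generator
settings; the classes are fully separable at 15 dB).

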