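# Methods

## The synthetic heart-sound model

A phonocardiogram is modelled as a periodic train of cardiac cycles at a
configurable heart rate (default 60 bpm). Each cycle carries a
Gaussian-windowed S1 tone burst (centre ≈60 Hz, width 18 ms) at cycle
onset and an S2 burst (≈150 Hz, 12 ms) at the end of systole, with mild
beat-to-beat jitter (5 % frequency, 10 % amplitude) so consecutive
cycles are not identical. Systole occupies the first 35 % of the cycle,
diastole the remainder. Disease labels inject a murmur — white noise
band-passed (4th-order Butterworth, zero-phase) to the label's
characteristic band — into the systolic interval for AS, MR and MVP and
into the diastolic interval for MS, at an amplitude calibrated to
≈0.55 of the heart-sound RMS within the murmur interval. Finally white
Gaussian noise is added so the clean-composite-to-noise power ratio
equals the configured SNR. The default study conditions are 50
recordings per class, 4 kHz sampling, 5 s duration, 15 dB SNR.

What the generator does *not* emulate: S3/S4 gallops, respiration and
friction artifacts, sensor transfer functions, heart-rate variability
beyond per-burst jitter, murmur shapes (crescendo/decrescendo), and the
severe class imbalance and label noise of clinical corpora. Passing
the test suite therefore demonstrates that the pipeline's machinery is
correct and that it recovers planted, band-separable structure; it does
not certify clinical performance. In particular, the MS and MVP murmur
bands (40–95 vs 45–90 Hz) are nearly identical in frequency and are
separated mainly by murmur *timing* (diastolic vs systolic), which is
exactly the cue the filter-bank envelope input preserves.

## Denoising: EEMD plus adaptive noise cancellation

Empirical mode decomposition sifts the signal into intrinsic mode
functions: upper/lower extrema envelopes are cubic splines with two
extrema mirror-extended past each boundary (suppresses end swings);
sifting stops when the extrema/zero-crossing counts differ by at most
one **and** the Cauchy criterion `Σ(h_prev−h)²/Σh_prev² < 0.2` holds
(at most 50 sift iterations). Decomposition stops when the residual has
fewer than three extrema or `max_imfs` is reached, so the reconstruction
identity `x = Σ IMF + r` holds to machine precision by construction.
The ensemble variant decomposes `n_trials` noise-perturbed copies
(relative noise sd 0.2) and averages IMFs index-wise; with one trial and
zero noise it reduces bit-exactly to plain EMD.

IMF selection uses the white-noise energy model: EMD acts as a dyadic
filter bank on white noise, with IMF1 taking roughly half the noise
power and `E_k ≈ (E_1/0.719)·2.01^−k` beyond. The noise floor `E_1` is
estimated from IMF1 as the smaller of its energy and a MAD-based robust
variance, so sparse heart-sound bursts leaking into IMF1 do not inflate
it. An IMF whose energy is within a factor 2.5 of the model prediction
is classed noise-dominated and rejected; the factor was calibrated on
synthetic PCG at 0 dB, where the murmur-bearing mode sits near an
energy ratio of 3 and a looser factor systematically discards it. On a
clean signal the MAD estimate collapses and everything is kept
(pass-through). A correlation-threshold rule (drop IMFs with
|Pearson r| < 0.1 against the input) is available via
`select="correlation"`, but at 0 dB input every noise IMF correlates
≈0.5 with the input, so that rule degenerates to pass-through and the
energy model is the default.

The rejected modes form the reference of a final LMS cancellation pass
on the partial reconstruction. The textbook step bound
`μ_max = 2/(3 L P_in)` uses the *mean* reference power; murmur-gated
references are bursty, and a step sized on the mean power diverges
catastrophically inside bursts. The pipeline therefore sizes
`μ = 0.1·2/(3 L P_peak)` with `P_peak` the 0.999 power quantile, and
skips the stage entirely when the rejected energy is below 0.1 % of the
kept energy. A diverging LMS run (deliberately provoked in tests at
3×`μ_max`) is saturated at |e| = 1e50 rather than allowed to overflow,
so the divergence remains visible in the error history.

Measured on the synthetic conditions: mean SNR gain ≈6.3 dB at 0 dB
input (20 seeds, minimum ≈4.8), positive mean gain up to 10 dB input,
near pass-through on clean input.

## Oversampling and features

SMOTE interpolates uniformly on segments toward one of the k = 5
nearest same-class neighbours (Euclidean; ties broken by row index), so
synthetic points stay inside the minority convex hull. It operates on
the feature table (interpolating raw waveforms is meaningless), after
feature extraction and before selection; synthetic rows carry no
waveform, so the convolutional classifier trains on real rows only
while the balanced table drives ranking, selection and the fuzzy risk
model. Under the default balanced generator SMOTE is a no-op.

Features per recording: fractional Welch power (1 s windows, 50 %
overlap) in the eleven murmur bands; delta (0.5–4 Hz) and theta
(4–8 Hz) power of the Shannon-energy envelope spectrum — these are
envelope-*modulation* bands capturing rhythm-rate structure, since
audio-frequency delta/theta would be meaningless for heart sounds;
systolic/diastolic duration statistics from S1/S2 peak-picking on the
envelope (minimum peak distance 0.2 s, S1/S2 assigned by
systole < diastole); and RMS, zero-crossing rate, spectral centroid.
Segmentation failures fall back to zeroed timing features rather than
dropping the recording.

## Impact scoring and feature selection

The soft-margin hyperplane is solved in the dual by maximal-violating-
pair coordinate ascent (two multipliers per step, KKT tolerance 1e-8),
which is deterministic; the bias is then recovered *exactly* by
scanning the hinge breakpoints, where the objective is piecewise linear
in v. The objective agrees with an independent SLSQP primal QP to
≈1e-8 relative on random small instances. The impact rate is the
optimal objective; per-feature impacts `|s_j|·sd(X_j)` are aggregated
one-vs-rest by maximum for multi-class data. C defaults to 1.

LV-PSO fitness is the LVQ1 error of the weight-masked features,
averaged over a seeded stratified 3-fold split — a single 70/30 split
proved too noisy (error quantum 1/36 at n = 120) for the swarm to
resolve single-feature contributions. LVQ1 uses one prototype per
class (initialized at class means), winner by information-gain-weighted
squared distance, pull/push updates with a linearly decaying rate
(α₀ = 0.3, 10 epochs). Information gain is equal-width-binned mutual
information in bits (10 bins, scale-invariant). The swarm (15
particles, 25 iterations by default) is warm-started with two informed
positions — the all-ones mask and the normalized gain profile — which
measurably improves recovery of planted feature sets without biasing
the search away from sparse optima (velocities are random). Velocities
clamp at ±0.5/dimension, positions at [0, 1]; the final mask is
`gbest > 0.5` with the top-weight feature force-kept if empty.

## Fuzzy inference and the convolutional classifier

The Sugeno system uses Gaussian memberships (2 per input, centres
spanning the input range), the full rule grid (capped at 6 inputs; the
pipeline uses the top 4 impact-ranked features within the selected
mask, 16 rules), product T-norm, firing-strength normalization and
linear consequents. Hybrid training alternates a global least-squares
solve of all consequents (minimum-norm solution on rank deficiency,
which cannot increase the loss) with one analytic gradient step on
centres and widths (validated against central finite differences to
1e-5 relative); widths are floored at 1e-3 of the input range to keep
rule coverage. Trained on the binary target normal = 0 / disease = 1,
the clipped output is the fuzzy risk score.

The classifier input is a 6-channel *filter-bank envelope*: the
broadband Shannon envelope plus smoothed magnitude envelopes of the
signal band-passed to the five class bands, each resampled to 512
points and z-scored per recording. A single broadband envelope would
discard the murmur's spectral placement entirely (AS, MR and MVP are
indistinguishable by timing alone); the filter bank is the coarsest
representation that preserves both the band and the timing of the
murmur. 512 points suffice because every channel is 20 Hz band-limited
(≈5× oversampled at 5 s); the segment length is configurable.

The network is the layer stack given in the README with dropout
(p = 0.5) on the dense layer's input — dropout directly on the logits
destroys training. Weights are He-initialized from the model seed;
optimization is Adam (lr 1e-3, batch 32, 30 epochs default). Batch
normalization uses batch statistics in training and running averages
(momentum 0.9) at inference; inference is fully deterministic. Every
layer's backward pass is checked against finite differences at 1e-4
relative tolerance.

## Evaluation protocol

Stratified seeded k-fold (k = 5) with the entire preprocessing/model
stack refitted inside each training fold; synthetic SMOTE rows are
created from training rows only and never scored. Reported metrics:
per-class and macro precision/recall/F1, accuracy, Cohen's κ, and the
polygon area metric — the shoelace area of the hexagon whose radii at
60° spacing are macro precision, macro recall, macro F1, accuracy,
macro one-vs-rest AUC (rank-sum estimator with tie handling) and macro
Jaccard, normalized by the regular unit hexagon area `3√3/2`, so six
perfect metrics give exactly 1 and uniform radii r give r².

At the default study conditions (250 recordings, 15 dB, seed 11) the
cross-validated pipeline attains macro-F1 / accuracy / κ / PAM of
1.000: the five classes are fully separable at that SNR with this
generator, which is the intended regime for verifying the machinery.
Harder regimes (lower SNR, shorter recordings) degrade gracefully and
can be explored through `configs/default.yaml`.

## Problem sizes and runtime

Defaults are sized for a single CPU core: the full study (simulation,
EEMD denoising with 3 trials, feature extraction, 5-fold CV with
12-particle/15-iteration selection and 30-epoch network training) runs
in ≈5–6 minutes; the acceptance script adds the denoising benchmark
(20 recordings) and the LMS/EMD checks for ≈8 minutes total.

## Known limitations

* EMD sifting has no convergence guarantee; pathological signals may
  exhaust the 50-iteration cap with a slightly asymmetric mode (the
  reconstruction identity still holds exactly).
* The ensemble mean of EEMD is not an exact decomposition of the input
  (residual ensemble noise of order `noise_sd/√n_trials`).
* The LVQ fitness is a point estimate; feature selection on near-tied
  subsets is seed-dependent (by design — the swarm is seeded).
* The rule grid of the fuzzy system grows exponentially in its inputs;
  the 6-input cap is structural, not tunable.
* Multi-class impact scores use one-vs-rest maxima, which can over-rank
  features informative for a single easy class.
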