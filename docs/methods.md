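# Methods

This note documents the models, estimators and design choices behind
`eegfp`, in the order data flow through the pipeline.

## Synthetic cohort model

Each subject is a stationary vector-autoregressive process of order 2 on
the 32 montage channels,

x(n) = Σₖ Aₖ x(n−k) + e(n),   e(n) ~ N(0, Σ),

with three coefficient layers:

1. **Backbone** (shared by all subjects, drawn from a backbone seed):
   channel-wise AR dynamics — lag-1 diagonal U(0.25, 0.45), lag-2 diagonal
   U(−0.2, −0.1), giving oscillation-free decaying autocorrelation of
   roughly EEG-like bandwidth at the default 250 Hz — plus 32 weak shared
   off-diagonal couplings of magnitude `base_coupling` (default 0.1, random
   sign). Σ is diagonal with variances U(0.9, 1.1), in arbitrary µV-like
   units.
2. **Planted fingerprint** (per subject): `n_planted` = 12 directed lag-1
   couplings with magnitude `planted_strength` = 0.35 (±20% jitter, random
   sign), drawn by default among the 11 frontal electrodes so frontal
   enrichment of subject-specific connectivity has a recoverable ground
   truth (`plant_within` overrides this; 12 of the 110 possible ordered
   frontal pairs keeps fingerprints distinct between subjects almost
   surely). 0.35 puts the per-edge GC (~0.1 nats) roughly an order of
   magnitude above the finite-sample GC noise floor of a 2-s epoch, i.e.
   clearly detectable per epoch but far from deterministic coupling.
3. **Session drift**: for a session with nominal day d, coefficients are
   perturbed once per subject-session as A′ = A + s·σ_A·Z with Z standard
   normal, σ_A the RMS of the nonzero coefficients, and
   s = c·ln(d) (c = `drift_coeff` = 0.06). Day 1 (session A) is exactly
   drift-free; day 180 perturbs coefficients by ~31% RMS. The log law is
   the minimal monotone structure needed for a declining permanence curve;
   no claim is made that human inter-session variability follows it.

Stability is enforced by rescaling lag-k blocks by sᵏ (which scales every
companion-matrix eigenvalue by s) until the spectral radius is ≤ 0.95; the
same rescaling is applied to drifted models. Simulation discards a burn-in
of max(500, 10·order) samples, then adds independent white sensor noise of
standard deviation `noise_scale` = 0.2 (a modest measurement-noise floor,
~15–20% of signal RMS). A cohort is a pure function of its master seed.

**What the generator does and does not emulate.** It produces the
statistical structure the analysis assumes — subject-specific directed
coupling, monotone session drift, measurement noise — but not volume
conduction, 1/f spectra, alpha rhythms, eye/muscle artifacts, line noise,
or eyes-open/closed differences. Passing tests therefore demonstrate that
the pipeline recovers fingerprints *when they exist in this form*, not that
human EEG carries them; the filtering and Laplacian stages are still
exercised for real-data parity. Default sampling is 250 Hz rather than a
hardware-typical 1000 Hz so full-protocol runs stay desk-scale; a 2-s epoch
at 250 Hz (500 samples) still supports order-15 bivariate fits with ~440
residual degrees of freedom.

## Preprocessing

Fixed order: temporal filter → spatial Laplacian → segmentation.

- **Filter**: zero-phase (forward–backward) 4th-order Butterworth band-pass
  1–40 Hz plus a 2nd-order IIR notch at 50 Hz, Q = 30. Applied per channel;
  the notch is skipped automatically when it lies at or above Nyquist.
- **Surface Laplacian**: the Hjorth nearest-neighbour form — each channel
  minus the mean of its adjacent electrodes, with the adjacency shipped as
  a plain-text YAML table (`eegfp/data/montage_1020_32.yaml`). This is a
  deliberate, documented substitute for spherical-spline current-source-
  density estimation: it needs no head model and gives the same qualitative
  volume-conduction reduction, but is *not* numerically equivalent to CSD.
  The operator is linear and not idempotent; it is applied exactly once, to
  the continuous recording (before segmentation).
- **Segmentation**: consecutive non-overlapping 2-s epochs;
  floor(duration/2 s) per recording, trailing partial segment dropped. A
  4-minute recording yields 120 epochs.
- **Region map**: the five scalp regions are assigned by 10/20 name prefix
  (frontal: Fp*/F*/FC*, 11 electrodes; central: C*/CP*, 7; temporal:
  T7/T8/A1/A2, 4; parietal: P*/PO*, 7; occipital: O1/Oz/O2, 3). A1/A2 are
  grouped temporal by proximity. The whole montage (order, regions,
  positions, adjacency) is overridable via a YAML file.
- ICA artifact rejection is intentionally absent (synthetic data are
  artifact-free); real data are expected to be cleaned upstream, and the
  EDF/BrainVision reader matches channels case-insensitively against the
  montage.

## Granger causality

Strictly bivariate (pairwise), not conditioned on the other 30 channels:
each ordered pair gets its own order-15 BVAR. Conventions that the
literature leaves open, fixed here:

- the restricted model is a univariate OLS autoregression of the same order
  over the same sample window (n = p+1 … N) as the full model;
- residual variance is the mean squared residual with the population 1/M
  normaliser (no mean re-centering; band-passed signals are zero-mean);
- both variances are floored at ε = 10⁻¹² before the log ratio, and values
  in [−10⁻⁹, 0) from round-off are clipped to 0 — genuine negativity is
  impossible because the restricted regressors are nested in the full ones,
  so anything below −10⁻⁹ raises an error naming the channel pair;
- the diagonal of the GC matrix is fixed at 0 but retained in the
  1024-length row-major feature vector, keeping the 32 × 32 layout;
- order 15 for the 32-channel pipeline; desk-scale tests use order 8 at
  125 Hz (same lag span in milliseconds, half the parameters).

The full-matrix path computes the epoch's lag-matrix Gram matrix once and
solves all 32 restricted and 496 pairwise normal systems from its
sub-blocks, batched; a test pins it to the per-pair `lstsq` route. A
rank-deficient design (constant channel, duplicated channels) raises a
singular-fit error rather than returning a number.

## Mutual information

Plug-in histogram estimator: equal-width bins (default B = 16) over each
series' observed range, joint counts via 2-D binning, MI in bits
(log base 2; base e available). Zero cells contribute nothing. Summing the
cell terms in sorted order makes MI(x, y) and MI(y, x) bit-identical, and
computing marginals from integer counts keeps them exact. Constant inputs
give MI = 0 with a warning. The estimator has the usual upward plug-in bias
of roughly (B−1)²/(2N ln 2) nats for independent series — about 0.16 bits
at the 500-sample epochs of the default pipeline — which is immaterial for
identification (all epochs share the bias) but means absolute MI values
should not be over-interpreted. Equal-count binning is not provided;
equal-width binning makes MI exactly invariant to per-series affine maps.

## Identification

One-against-one RBF-SVM (one binary classifier per subject pair, majority
vote) on per-feature z-scored data. Defaults C = 1,
kernel width γ = 1/(n_features · Var) ("scale"); an optional small grid
search over C ∈ {0.1, 1, 10} runs strictly inside training folds.
Standardisation is fitted on training rows only — a canary test injects an
extreme-valued test row and checks predictions of other rows are unmoved.

- *Intra-session*: stratified (subject-balanced) ten-fold CV with a fixed
  shuffling seed; reported accuracy is pooled over held-out epochs
  (correct/total), i.e. epoch-level, not subject-level.
- *Cross-session*: one model fitted on all of session A; each later session
  scored in nominal-day order with all of its epochs.

z-scoring is an addition relative to a bare SVM pipeline: RBF kernels on
heterogeneous-scale connectivity features otherwise collapse onto the
highest-variance features.

## Connection weights and region attribution

An RBF-SVM has no primal feature weights, so contribution scores come from
one of two clearly-labelled surrogates: (a) default — linear one-against-one
SVMs on the standardised features, score = mean |coefficient| over all
subject-pair classifiers; (b) permutation importance of the RBF model
(column shuffle, accuracy drop, averaged over repeats, clipped at 0).
Method (a) is deterministic and fast; (b) is model-faithful but noisy at
small n. GC self-pairs carry weight 0 and are excluded from selection, so
the top-10% cut selects round(0.10 · 992) = 99 directed GC pairs (or
round(0.10 · 496) = 50 MI pairs); ties break toward the lower feature
index. Directed pairs (i→j) and (j→i) are scored and counted separately.
Region attribution is a 5 × 5 count matrix (source region × target region
for GC; canonical upper-triangle cell for MI) whose total equals the number
of major connections; the intra-frontal fraction is compared against the
uniform-selection baseline 11·10/(32·31) ≈ 0.111.

## Problem sizes in tests and the acceptance script

The full-protocol profile — 15 subjects × 120 epochs at 250 Hz, order-15
GC, ten-fold CV — is used where the headline identification regime is
checked (one drift-free session; ~1 minute). Multi-seed property checks
(permanence monotonicity, chance-level control, frontal-recovery majority)
run a reduced profile the package also exposes (`CI_PROFILE`): 4–6
subjects, 40–60 s recordings at 125 Hz, order-8 GC — chosen as the smallest
sizes at which the effects are comfortably larger than their seed-to-seed
spread. The chance-level control uses 15 label-distinct copies of a single
generator and checks accuracy against the binomial 95% band around 1/15.

## Known limitations

- Pairwise GC cannot distinguish direct from mediated influence; a common
  driver produces spurious edges. This matches the bivariate formulation
  the pipeline implements, by design.
- The Hjorth Laplacian is a coarse CSD approximation; region attribution
  near the montage boundary (A1/A2, Oz) inherits its adjacency choices.
- Broadband (1–40 Hz) analysis only; no per-band decomposition, no
  spectral GC, no phase-based indices.
- The MI bin count and the SVM hyperparameters are conventions, not fitted
  quantities; numerical parity with other toolboxes' MI values is not
  expected.
- Closed-set identification only: no verification-style (impostor/EER)
  evaluation.
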