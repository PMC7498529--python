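# Methods

## The decoding problem

`eegvote` decodes a binary affective state (high vs. low valence, or high
vs. low arousal, thresholded from self-report ratings) from multichannel
scalp EEG, one prediction per trial.  The design assumes recordings of the
DEAP type — 32 channels in the 10-20 montage, 128 Hz, 8064 samples
(63 s) per trial — but nothing in the code requires that geometry.

The method is deliberately simple and interpretable: classical rhythm
band-limiting, a small fixed feature set per channel, a KNN classifier, and
two rounds of majority voting that aggregate first over channels within a
rhythm and then over rhythms.

## Pipeline

1. **Denoising low-pass.**  Equiripple FIR, passband 45 Hz / stopband
   50 Hz, 1 dB passband ripple, 60 dB stopband attenuation, applied
   forward-backward (zero phase).  The design is verified against its
   ripple/attenuation spec on a 4096-point frequency grid at design time.
   Two alternative readings of the published sub-Hz edge figures
   (0.15/0.2, literal Hz or Nyquist fractions) are selectable for
   comparison; the literal variant falls back to a minimum-order elliptic
   IIR because its transition band is far too narrow for a practical FIR.
2. **Rhythm extraction.**  Four bands: delta 0-4 Hz (retaining DC), theta
   4-8, alpha 8-12, beta 12-30.  Gamma 30-45 Hz exists behind a flag for
   display but takes no part in classification.  The default extractor is
   an exact spectral projection (Fourier components outside `[low, high)`
   zeroed), which is zero-phase, linear, exactly idempotent, and tiles
   0-30 Hz exactly.  A 4th-order Butterworth band-pass (forward-backward)
   is available as `method="butter"`.

   The spectral default is a deliberate choice, not a convenience.  Two of
   the downstream features are effectively logarithmic readouts
   (log-energy entropy, and the fractal dimensions through their shape
   sensitivity), so a −60 dB stopband residue of a strong out-of-band
   oscillation is still perfectly legible to them: with IIR band-passes,
   a class effect planted purely at 8-12 Hz was decoded at accuracy 1.0
   from every rhythm's filtrate.  Per-rhythm attribution — the point of the
   analysis — requires out-of-band gain that is exactly zero.
3. **Features.**  Per channel and rhythm, a 2-level wavelet packet
   transform (Daubechies-4, symmetric half-point extension) keeps all six
   nodes: (1,0),(1,1),(2,0),(2,1),(2,2),(2,3), children of node *j* being
   *2j* (low-pass) and *2j+1* (high-pass).  Each node's coefficient
   sequence *d* yields, in fixed order:

   | feature | definition | parameter |
   |---|---|---|
   | SE  | −Σ d² ln d² | — |
   | LEE | −Σ ln d² | — |
   | NE  | Σ \|d\|^p | p = 1.1 |
   | TE  | #{ \|d\| > T } | T = 0.2 |
   | SUE | Σ min(d², ε²) | ε = 3.0 |
   | HFD | Higuchi slope, k = 1..k_max | k_max = 8 |
   | KFD | ln(L/a) / ln(d/a) | — |

   6 nodes × 7 features = 42 features per (channel, rhythm).
4. **Per-channel KNN.**  k = 3, Minkowski distance with exponent 2,
   features z-scored with training-fold statistics only, stratified
   10-fold cross-validation.  Each trial's label is predicted by a model
   that never saw its fold (out-of-fold prediction).
5. **First vote (channels).**  Channels are ranked by out-of-fold
   accuracy (ties: sensitivity, then recording order); the top five
   channels' out-of-fold prediction vectors are majority-voted into the
   rhythm's prediction.
6. **Second vote (rhythms).**  The four rhythm predictions are voted
   again; because four voters can tie, the rhythm with the highest
   first-step voted accuracy is duplicated once (ties: earlier band in
   standard order), making five voters.  The duplicate is placed first so
   a residual tie resolves toward the best rhythm.

## Conventions and numerical choices

- Natural logarithms everywhere.  `0·ln 0 = 0` and `ln 0 → 0` at the
  *energy* level (so squared coefficients that underflow to zero also drop
  out); silent nodes therefore produce finite entropies.
- The SURE entropy is the literal capped-energy sum over *all*
  coefficients — the min() already caps large ones, making a separate
  `|d| ≤ ε` side condition redundant.  MATLAB-`wentropy`-compatible
  variants of SURE and the (signed) log-energy entropy are available via
  `variant="toolbox"`.
- HFD is the least-squares slope of ln L(k) on ln(1/k) over k = 1..k_max
  (the classical estimator).  A per-k ratio form is degenerate at k = 1
  and biased by its ln(N−1) intercept, so it is not used.  On band-limited
  EEG-like waveforms the estimate stays in [1, 2]; on arbitrary rough
  sequences (e.g. near-silent high-band nodes) it may exceed 2, which is a
  property of the estimator, not an error.
- KFD embeds the series as a planar curve with unit abscissa spacing:
  L = Σ√(1+Δx²), a = L/(N−1), d = farthest Euclidean distance from the
  first vertex.  This makes KFD exactly 1 for any affine sequence and
  well-defined for a 1-D series.
- Constant (flat) signals: KFD raises a degenerate-input error at the
  function level; inside feature assembly both fractal dimensions
  substitute the sentinel 1.0 with a warning, because a silent filtered
  node is a legitimate occurrence that must not abort a pipeline run.
- Tie-breaking is deterministic everywhere: KNN distance ties prefer the
  lower training index and tied class votes follow the nearest neighbor;
  ranking ties fall back to sensitivity then channel order; even vote
  splits go to the highest-ranked voter; rhythm-duplication ties go to the
  earlier band.
- One master seed drives stratified fold assignment; synthetic datasets
  carry their own seed.  Identical (data, config, seeds) reproduce every
  output bit-for-bit.
- The batch feature path computes elementwise work in the input precision
  (float32 for generated datasets) with double-precision accumulation, in
  16-trial blocks (a cache-residency measure; results are independent of
  the chunking and match the scalar double-precision path to ~1e-6
  relative, which is far below any decision boundary the KNN sees).

## Selection optimism, and the nested mode

Channel selection uses the same out-of-fold predictions that are then
voted and scored.  On data with no class signal this inflates the voted
accuracy well above chance: per-channel null accuracies are ≈
Binomial(n, ½) draws, the top-5-of-32 order statistics sit near 0.6, and
two voting stages amplify that to ≈ 0.75 observed final accuracy on null
data (n = 80).  This optimism is intrinsic to the evaluation scheme the
pipeline mirrors, and the package reports it as-is by default.

`two_step_pipeline(..., nested_selection=True)` instead re-ranks channels
inside each training fold (using an inner cross-validation) before
predicting the held-out fold.  On the same null data this mode scores ≈
0.5, confirming that the gap is selection optimism rather than leakage:
an out-of-fold-discipline test verifies that corrupting one trial's
features cannot move predictions of other trials in its fold, and
label-permutation tests stay at chance for single channels.

## The synthetic generator

Real affective-EEG data of the DEAP type is access-restricted, so the
package carries a generator that emulates the *structure* the pipeline is
designed to exploit:

- **Background**: per-channel 1/f (pink) spectral noise, s.d. 10 µV —
  EEG-like relative band powers rather than white noise.
- **Oscillatory component**: random-phase spectral noise confined to the
  interior of the effect band (inset 12.5% of the bandwidth per side),
  s.d. 5 µV, a fresh draw per trial and channel.  Keeping the carrier
  strictly inside its nominal band ensures no class information sits on a
  band edge where even the analysis filters' finite resolution would
  smear it into a neighboring rhythm; using many random components rather
  than a pure sine avoids trivially separable line spectra.
- **Effect**: on HIGH trials the oscillation amplitude on a chosen channel
  subset is multiplied by `effect_gain` (default 4, i.e. a 16x band-power
  ratio).  The default effect channels are Fp1, FC1, T7, O1, T8.
- **Sensor noise**: white, s.d. 1 µV.  Labels are assigned to match the
  class balance exactly and shuffled by the seed.

What the generator does *not* emulate: volume conduction and inter-channel
correlation, artifacts (EOG/EMG), non-stationarity within trials, and any
genuine physiology of emotion.  Passing tests therefore demonstrate that
the pipeline recovers planted band-and-channel-specific amplitude effects
and is statistically sane — not that published accuracies on real
affective EEG are reproduced (those require the restricted dataset and are
out of scope).

## Problem sizes used in tests and the acceptance script

Statistical tests run the full study geometry (80 trials × 32 channels ×
8064 samples at 128 Hz): 20 seeded replicates each for null calibration
and for parameter recovery in the test suite; the acceptance script uses
5 replicates per condition (plus 2 nested-selection null runs) and
re-derives all formula-oracle quantities from scratch at 1000 random
vectors per oracle.  Unit and property tests use reduced geometries
(4-8 channels, 1-2k samples) where only correctness, not statistics, is at
stake.

## Known limitations

- The published accuracies on the DEAP dataset are not reproducible here
  (restricted data, and the evaluated 80-trial subset is unspecified);
  nothing in this package claims them.
- The default null behavior is optimistic by design (see above); use
  nested selection when an unbiased ensemble accuracy estimate matters.
- EDF output uses a minimal single-record writer (int16 quantization, one
  uniform sampling rate); it is read back by MNE and by this package, but
  exotic EDF consumers may expect multi-record layouts.
- Channel names are opaque case-insensitive keys; no montage geometry is
  used anywhere.
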