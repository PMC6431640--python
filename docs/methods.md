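# Methods

## The scoring model

`somnoscore` treats sleep staging as per-recording supervised
classification on a fixed epoch grid. Epochs are 0-based, half-open
intervals `[i·L, (i+1)·L)` of length `L` seconds; a trailing partial
epoch is dropped. The model assumes that (i) the manual reference
labels sampled for training are correct, (ii) stage-conditional signal
statistics are stationary enough within a recording for a
within-recording classifier to generalize from a few dozen epochs per
stage, and (iii) ARTIFACT/UNDETERMINED epochs carry no usable label
(they are excluded from training and evaluation but still receive a
prediction).

**Features.** Each epoch becomes a fixed-length vector. EEG and EOG
channels contribute absolute and relative band powers (delta 0.5–4,
theta 4–8, alpha 8–12, sigma 12–16, beta 16–30 Hz), a delta/theta
log-ratio, the 95% spectral edge frequency and the zero-crossing rate;
EMG channels log-RMS amplitude and >30 Hz log power; EOG pairs a
zero-lag cross-correlation; accelerometers log variance and log mean
absolute derivative; temperature channels mean and slope; ECG/OTHER
channels log-RMS only. Spectra come from an averaged modified
periodogram (Welch, Hamming window, 50% overlap) with 2 s segments, or
1 s segments at 4 s epochs so each epoch still averages ≥ 3 segments
while resolving the delta band. Band edges are clipped to each
channel's Nyquist frequency; bands entirely above Nyquist are dropped
with a warning. Powers are floored at 1e-12 before log10, and log-power
/ amplitude features are z-scored per recording (training and
prediction are within-recording by design, so per-recording scaling is
the natural normalization; the scaling parameters are stored on the
feature matrix). Non-finite values are imputed to 0 after scaling. The
battery is a standard sleep-staging repertoire behind a replaceable
interface — the package makes no claim that it matches any commercial
scorer's internal features.

**Training sets.** Uniform sampling without replacement per stage from
eligible (non-artifact) epochs; the defaults of 100/50/40 epochs per
stage at 4/10/30 s epochs correspond to 6.67/8.33/20 minutes of manual
scoring per stage. A stage rarer than the requested size is taken in
full with a warning rather than failing, which keeps short recordings
usable; a stage with no eligible epochs is an error. Paired
baseline/treatment designs support longitudinal training (per-stage
quota split evenly across the two recordings, odd remainder to
baseline) and baseline-only training.

**Classifier.** A random forest (200 trees, class-balanced weights,
fixed seed, single-threaded) fitted to the training epochs' feature
rows. Rationale: tolerant of mixed-scale features, stable with tens of
training examples per class, and provides per-class scores, which the
consistency rules need. Prediction is the score argmax with ties broken
toward the earlier vocabulary label. The classifier family is an
implementation decision of this package.

**Consistency rules.** Minimum bout durations per stage in seconds,
converted to epochs by ceiling division (floor 1). The smoothing is
iterative: the shortest violating bout (ties: earliest) is relabelled
to the neighbouring stage with the higher mean class score over the
bout; edge bouts take their single neighbour; iteration ends when no
bout is below its minimum. Each merge reduces the bout count, so the
procedure terminates; it never introduces a stage absent from its
input. Presets: `rodent()` (4 s W, 8 s NREM/REM), `mouse()` (12 s all
stages, i.e. three consecutive 4 s epochs). No stage-sequence grammar
is imposed (REM directly after wake is allowed). The default is no
smoothing.

## Agreement evaluation

Per-stage TP/FP/FN are counted over evaluated epochs (not excluded, not
ARTIFACT/UNDETERMINED in the reference). Conventions:

- any 0/0 ratio (sensitivity, precision or F of an absent stage) is 0;
- "overall" F is micro-averaged: counts are pooled across stages before
  applying the formula — on single-label data this equals epoch
  accuracy; the macro average (unweighted stage mean) is reported
  alongside so both aggregations are inspectable;
- rating bands are inclusive at their lower edge;
- training epochs are excluded from evaluation by default, since the
  claim under test is generalization to the *remaining* recording
  (a diagnostics switch re-includes them);
- transition-epoch exclusion removes the first and last epoch of every
  bout of the **predicted** hypnogram and ignores the corresponding
  reference epochs (a `transitions_from="reference"` option exists but
  is off by default);
- reclassification (N1→W, N1→N2, W1NREM23, NREM123) remaps both
  hypnograms — and shrinks the vocabulary — before any counting; when
  combined with transition exclusion the mask is computed from the
  reclassified predicted hypnogram, i.e. the evaluation operates
  entirely in the reclassified label space;
- Hedges' g uses the plain pooled-SD formula; the small-sample
  correction factor `1 − 3/(4(n1+n2) − 9)` is available behind a flag
  but off by default. |g| < 0.2 is "miniscule", then small/medium/large
  at 0.2/0.5/0.8. Zero pooled SD with equal means gives g = 0; with
  unequal means g is undefined (NaN, flagged);
- group comparisons are two-sided Student's t-tests (paired or
  independent); a Bonferroni-adjusted alpha (0.05/m) is applied only
  when the caller declares m > 1 planned comparisons. Zero-variance
  paired differences are flagged degenerate rather than raising.

The validation harnesses mirror how such a scorer is validated:
`training_size_curve` refits at each size × replicate with fresh seeded
training draws and aggregates mean ± SEM per stage;
`channel_ablation` samples the training epoch indices once and reuses
them across channel presets, so only the features differ between
configurations.

## Synthetic polysomnography

The generator exists so every pipeline stage is testable with known
ground truth; it emulates the statistical structure that matters to a
spectral-feature classifier and nothing more.

**Hypnograms** follow a semi-Markov model: stage-to-stage transition
weights (zero self-transitions) and geometric bout durations with
stage-specific means (minimum one epoch; a dispersion knob switches to
negative-binomial). **Signals** are synthesized per epoch: EEG as a sum
of band-limited Gaussian noise components (FFT-masked white noise)
mixed to the stage's relative band-power profile; EMG/ACC as broadband
noise scaled by a stage level (wake > NREM > REM muscle tone); EOG as
slow-band (0.3–3 Hz) noise with a component shared across the pair so
zero-lag correlation rises with eye activity; a small white noise floor
(0.05 relative amplitude) everywhere. All draws are seeded and
bit-reproducible.

Preset parameters (in `presets.yaml`, versioned) were chosen once as
field-realistic values: human 30 s epochs with five stages, long N2/N3/
REM bouts and brief N1; rodent 4 s epochs with ~2 min wake, ~2.7 min
NREM and ~1 min REM bouts; avian 4 s epochs with a 6.4 s mean REM bout,
which places the 95th percentile of geometric REM bout durations at
16 s — birds' REM episodes rarely exceed that.

What passing tests on this material do show: the pipeline's arithmetic
and bookkeeping are correct, the classifier recovers stages when
stage-conditional contrast exists, exclusion and ablation analyses move
in the directions their constructions force. What they do not show:
performance on real PSG, which has artifacts, non-stationarity,
spindles/K-complexes, scorer disagreement and class imbalance patterns
the generator does not emulate. Synthetic F-measures here are close to
1 and should be read as correctness checks, not performance claims.

A note on spectral estimation at 4 s epochs: with 1 s Welch segments a
band-power estimate has on the order of 20% relative standard
deviation, so per-epoch relative band powers scatter visibly around the
generating profiles even though stage means order exactly as specified.
Classification is robust to this because it pools many features.

## Problem sizes used in the shipped validation

The validation suite and `scripts/acceptance.py` run the end-to-end
rodent check at the scale the protocol arithmetic implies — twenty
replicates of 24 h recordings (21600 four-second epochs) with the
guideline 100 training epochs per stage — plus a 2 h ablation fixture
in which REM differs from NREM only in the EEG (REM muscle tone raised
to the NREM level), and an 11 h human-preset recording for the
training-size response curve over 5/20/40/60 epochs per stage with
three replicates per size.

## Known limitations

- EDF support covers continuous 16-bit EDF only (no EDF+ annotations or
  discontinuous records); physical ranges are symmetric about zero and
  chosen per file from the data.
- Uniform epoch grids only; sub-epoch (e.g. 1 s sliding-window) manual
  scoring must be resampled to a grid upstream.
- No artifact *detection* — artifact handling is by labels supplied in
  the reference hypnogram.
- No cross-recording transfer: a model is fitted per recording (or per
  baseline/treatment pair) by design.
- N1 in the human preset is rare and hard (its profile deliberately
  neighbours REM's); at larger training sizes N1 sampling may cap at
  the available epochs, mirroring the practical difficulty of N1.
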