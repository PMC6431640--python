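# somnoscore

Per-recording supervised wake–sleep stage scoring of polysomnography
(PSG), for sleep researchers who score EEG/EMG/EOG recordings from
humans, rodents or birds and want a brief session of manual scoring to
drive automated classification of the rest of the recording — together
with the full statistical apparatus needed to validate such a scorer.

## What it does

Manual sleep staging assigns one vigilance stage per fixed-length epoch
(4, 10 or 30 s): W, N1, N2, N3, REM for human recordings; W, NREM, REM
for animal recordings. `somnoscore` samples a small training set from a
manually scored hypnogram (by default 100 epochs per stage at 4 s
epochs, 50 at 10 s, 40 at 30 s — about 7–20 minutes of manual scoring
per stage), extracts per-epoch spectral and amplitude features from the
configured channels, fits a class-balanced random-forest classifier,
scores every epoch of the recording, and smooths the result with
minimum bout-duration consistency rules (e.g. 4 s wake / 8 s NREM and
REM).

Agreement between an automated and a manual hypnogram is quantified per
stage by the F-measure,

    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F           = 2 · sensitivity · precision / (sensitivity + precision)

with the overall score micro-averaged over pooled per-stage counts, and
qualitative ratings (intra-scorer ≥ 0.90, excellent ≥ 0.85, strong
≥ 0.80, average ≥ 0.70, inadequate < 0.70). The evaluation layer also
provides transition-epoch exclusion (dropping the first and last epoch
of each predicted bout), simplified-staging reclassification (N1→W,
N1→N2, W1NREM23, NREM123), input-channel ablation, training-size
response curves, Student's t group comparisons and Hedges' g effect
sizes with the pooled standard deviation.

Because deposited recordings are rarely available, the package ships a
synthetic PSG generator: semi-Markov hypnograms (geometric bout
durations, stage transition weights) with stage-conditional signals —
EEG band-power profiles, EMG tone ordering wake > NREM > REM,
eye-movement and accelerometer activity — for human, rodent and avian
presets, so the entire pipeline is testable against known ground truth.

## Worked example

```python
import somnoscore as sc

rec, hyp = sc.generate_recording("rodent", hours=1.0, seed=42)
stager = sc.SleepStager(rec, hyp, rules=sc.ConsistencyRules.rodent())
res = stager.fit(seed=0)          # default: 100 training epochs per stage
print(res.summary())
```

```
SleepStager results — recording 'synthetic-rodent-1944468666'
epoch length 4 s, 900 epochs, channels=ALL
training sizes {'W': 100, 'NREM': 100, 'REM': 100} (seed 0)
stage         sens    prec       F  rating
W            1.000   1.000   1.000  intra-scorer
NREM         1.000   0.997   0.999  intra-scorer
REM          0.967   1.000   0.983  intra-scorer
overall                      0.998  intra-scorer
evaluated 600/900 epochs (excluded fraction 0.333)
```

One hour of synthetic rodent PSG (900 four-second epochs) was scored
after training on 100 randomly sampled epochs per stage; the 300
training epochs are excluded from evaluation (hence 600 evaluated).
Each row gives the stage's sensitivity, precision, F-measure and its
qualitative rating; REM's F of 0.983 means both REM sensitivity (0.967)
and precision (1.000) are high. `res.evaluate(exclude_transitions=True)`
repeats the evaluation with the first/last epoch of every predicted
bout removed (overall F 0.998 here).

The same workflow is available from the shell:

```
somnoscore simulate --preset rodent --hours 24 --seed 1 --out run/
somnoscore score --recording run/recording.edf --hypnogram run/hypnogram.csv \
    --epoch-length 4 --rules rodent --out run/scored/
somnoscore evaluate --predicted run/scored/predicted.csv \
    --reference run/hypnogram.csv --epoch-length 4 --out run/eval/
```

Recordings are read and written as 16-bit EDF (or a one-column-per-
channel CSV dialect); hypnograms as `epoch_index,onset_s,stage` CSV or
one label per line.

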