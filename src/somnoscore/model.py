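"""Per-recording supervised sleep-stage scoring.

The workflow mirrors how a scorer uses assisted-scoring software: a
brief manually scored training set is sampled from the recording's
reference hypnogram, a classifier is fitted to the training epochs'
feature vectors, every epoch of the recording is scored, and minimum
bout-duration consistency rules smooth the result (e.g. 4 s for wake
and 8 s for NREM/REM in rat protocols; 12 s — three consecutive 4 s
epochs — in mouse protocols).

:class:`SleepStager` is the model object (recording + reference +
configuration); :meth:`SleepStager.fit` returns a
:class:`StagingResults` carrying the predicted hypnogram, per-epoch
class scores, the training set used, and evaluation / summary methods.

The classifier family is a random forest with class-balanced weighting:
it copes with mixed-scale features and very small training sets, and
provides the per-class scores the consistency rules need.  It is an
implementation choice of this package, not a reproduction of any
commercial scorer's (undisclosed) internal model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import evaluation as ev
from .bouts import segment_bouts
from .features import ChannelConfig, FeatureMatrix, extract_features
from .io import (
    EpochGrid,
    Hypnogram,
    Recording,
    StageVocabulary,
    make_epoch_grid,
    read_edf,
    read_hypnogram,
)
from .training import TrainingConfig, TrainingMode, TrainingSet, sample_training_set

__all__ = ["ConsistencyRules", "StageModel", "SleepStager", "StagingResults",
           "apply_consistency_rules", "save_model", "load_model"]

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ConsistencyRules:
    """Per-stage minimum bout durations in seconds.

    Stages absent from the mapping have no minimum (1 epoch).  Seconds
    convert to epochs by ceiling division, with a floor of 1 epoch.
    """

    min_bout_s: dict[str, float] = field(default_factory=dict)

    def min_epochs(self, epoch_length: float) -> dict[str, int]:
        out = {}
        for stage, seconds in self.min_bout_s.items():
            if seconds < 0:
                raise ValueError(f"negative minimum bout for {stage}")
            out[stage] = max(1, math.ceil(seconds / epoch_length - 1e-9))
        return out

    @classmethod
    def rodent(cls) -> "ConsistencyRules":
        """Rat-protocol rules: 4 s wake, 8 s NREM/REM."""
        return cls({"W": 4.0, "NREM": 8.0, "REM": 8.0})

    @classmethod
    def mouse(cls) -> "ConsistencyRules":
        """Mouse microstructure threshold: 12 s for every stage."""
        return cls({"W": 12.0, "NREM": 12.0, "REM": 12.0})

    @classmethod
    def none(cls) -> "ConsistencyRules":
        return cls({})


def apply_consistency_rules(hypnogram: Hypnogram, rules: ConsistencyRules,
                            scores: np.ndarray) -> Hypnogram:
    """Enforce minimum bout durations on a predicted hypnogram.

    Iteratively the shortest bout violating its stage minimum (ties:
    earliest) is relabelled to the neighbouring stage with the higher
    mean class score over that bout; bouts at the recording edges take
    their single neighbour.  Repeats until no violations remain, so the
    output has no sub-minimum bouts.  Never introduces a stage absent
    from the input.  ``scores`` is the (n_epochs, n_stages) class-score
    matrix in vocabulary order.
    """
    minima = rules.min_epochs(hypnogram.grid.epoch_length)
    if not minima or max(minima.values()) <= 1:
        return hypnogram
    labels = np.asarray(hypnogram.labels, dtype=object).copy()
    vocab = hypnogram.vocabulary
    stage_col = {s: j for j, s in enumerate(vocab.labels)}

    while True:
        bouts = segment_bouts(labels)
        if len(bouts) == 1:
            break  # a single bout has no neighbour to merge into
        violating = [b for b in bouts if b.length < minima.get(b.stage, 1)]
        if not violating:
            break
        worst = min(violating, key=lambda b: (b.length, b.start))
        i = bouts.index(worst)
        left = bouts[i - 1].stage if i > 0 else None
        right = bouts[i + 1].stage if i < len(bouts) - 1 else None
        sl = worst.start
        sr = worst.end + 1
        if left is None:
            target = right
        elif right is None or left == right:
            target = left
        else:
            mean_left = scores[sl:sr, stage_col[left]].mean()
            mean_right = scores[sl:sr, stage_col[right]].mean()
            target = left if mean_left >= mean_right else right
        labels[sl:sr] = target
    return hypnogram.replace(labels)


class StageModel:
    """Fitted classifier state: expected feature names, vocabulary, seed."""

    def __init__(self, classifier: RandomForestClassifier, feature_names: list[str],
                 vocabulary: StageVocabulary, seed: int):
        self.classifier = classifier
        self.feature_names = list(feature_names)
        self.vocabulary = vocabulary
        self.seed = seed

    def predict_scores(self, features: FeatureMatrix) -> np.ndarray:
        """Per-epoch class scores, columns in vocabulary order, rows sum to 1."""
        if features.names != self.feature_names:
            raise ValueError(
                "feature names/order differ from those seen at training time"
            )
        proba = self.classifier.predict_proba(features.values)
        scores = np.zeros((features.n_epochs, len(self.vocabulary.labels)))
        for k, cls in enumerate(self.classifier.classes_):
            scores[:, self.vocabulary.index(cls)] = proba[:, k]
        return scores


def fit_stage_model(features: FeatureMatrix, training: TrainingSet,
                    recording_id: str, vocabulary: StageVocabulary,
                    seed: int = 0, n_estimators: int = 200) -> StageModel:
    """Fit the classifier on the training set's feature rows.

    Deterministic given the seed.  Raises on single-class training sets,
    out-of-range epoch indices and non-finite features.
    """
    rows, targets = [], []
    for stage, pairs in training.epochs.items():
        for rid, idx in pairs:
            if rid != recording_id:
                continue
            if not 0 <= idx < features.n_epochs:
                raise ValueError(
                    f"training epoch {idx} outside feature matrix of "
                    f"{features.n_epochs} rows"
                )
            rows.append(idx)
            targets.append(stage)
    if len(set(targets)) < 2:
        raise ValueError("training set must span at least two stages")
    X = features.values[rows]
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite training features")
    clf = RandomForestClassifier(
        n_estimators=n_estimators,
        class_weight="balanced",
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    clf.fit(X, targets)
    return StageModel(clf, features.names, vocabulary, seed)


def predict_hypnogram(model: StageModel, features: FeatureMatrix,
                      grid: EpochGrid) -> tuple[Hypnogram, np.ndarray]:
    """Score every epoch: argmax of class scores, ties to the earlier
    vocabulary label.  Returns (hypnogram, scores)."""
    scores = model.predict_scores(features)
    # np.argmax takes the first maximum, i.e. the earlier vocabulary label
    idx = np.argmax(scores, axis=1)
    labels = np.array([model.vocabulary.labels[i] for i in idx], dtype=object)
    return Hypnogram(grid=grid, vocabulary=model.vocabulary, labels=labels), scores


def save_model(model: StageModel, path) -> None:
    joblib.dump({
        "format_version": _MODEL_FORMAT_VERSION,
        "classifier": model.classifier,
        "feature_names": model.feature_names,
        "vocabulary_labels": model.vocabulary.labels,
        "vocabulary_aliases": dict(model.vocabulary.aliases),
        "seed": model.seed,
    }, path)


def load_model(path) -> StageModel:
    d = joblib.load(path)
    if d.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {d.get('format_version')}")
    vocab = StageVocabulary(labels=tuple(d["vocabulary_labels"]),
                            aliases=d["vocabulary_aliases"])
    return StageModel(d["classifier"], d["feature_names"], vocab, d["seed"])


class SleepStager:
    """Model object: a recording, its reference hypnogram and configuration.

    Parameters
    ----------
    recording : Recording
        The multichannel PSG recording to score.
    reference : Hypnogram
        The manually scored hypnogram (full or partial; ARTIFACT /
        UNDETERMINED epochs are never sampled for training and never
        evaluated).
    epoch_length : float, optional
        Defaults to the reference hypnogram's epoch length.
    channels : ChannelConfig or preset name
        Input-channel configuration (default ``"ALL"``).
    rules : ConsistencyRules, optional
        Minimum bout-duration smoothing applied after prediction
        (default: none).
    window_s : float, optional
        Welch segment length override for feature extraction.

    Examples
    --------
    >>> stager = SleepStager(recording, reference, rules=ConsistencyRules.rodent())
    >>> res = stager.fit(seed=7)
    >>> print(res.evaluate().summary())
    """

    def __init__(self, recording: Recording, reference: Hypnogram,
                 epoch_length: float | None = None,
                 channels: ChannelConfig | str = "ALL",
                 rules: ConsistencyRules | None = None,
                 window_s: float | None = None):
        self.recording = recording
        self.reference = reference
        self.epoch_length = float(epoch_length or reference.grid.epoch_length)
        if abs(self.epoch_length - reference.grid.epoch_length) > 1e-9:
            raise ValueError("epoch_length disagrees with the reference hypnogram")
        self.grid = make_epoch_grid(recording, self.epoch_length)
        if self.grid.n_epochs < reference.grid.n_epochs:
            raise ValueError(
                f"recording holds {self.grid.n_epochs} epochs but the reference "
                f"hypnogram has {reference.grid.n_epochs}"
            )
        if self.grid.n_epochs > reference.grid.n_epochs:
            # recording slightly longer than the scored portion: trim
            self.grid = EpochGrid(self.epoch_length, reference.grid.n_epochs)
        self.channels = (channels if isinstance(channels, ChannelConfig)
                         else ChannelConfig.from_name(channels))
        self.rules = rules or ConsistencyRules.none()
        self.window_s = window_s
        self._features: FeatureMatrix | None = None

    @classmethod
    def from_files(cls, recording_path, hypnogram_path, epoch_length: float,
                   vocabulary: StageVocabulary, **kwargs) -> "SleepStager":
        """Build from an EDF recording and a hypnogram CSV."""
        rec = read_edf(recording_path)
        hyp = read_hypnogram(hypnogram_path, vocabulary, epoch_length)
        return cls(rec, hyp, epoch_length=epoch_length, **kwargs)

    @property
    def features(self) -> FeatureMatrix:
        """Per-epoch features (extracted lazily, cached)."""
        if self._features is None:
            self._features = extract_features(
                self.recording, self.grid, self.channels, window_s=self.window_s
            )
        return self._features

    def fit(self, size_per_stage: int | None = None, seed: int = 0,
            training_set: TrainingSet | None = None) -> "StagingResults":
        """Sample a training set (unless given), fit and score the recording.

        ``size_per_stage=None`` uses the epoch-length default (100 for
        4 s, 50 for 10 s, 40 for 30 s epochs).
        """
        if training_set is None:
            cfg = TrainingConfig(size_per_stage=size_per_stage, seed=seed,
                                 mode=TrainingMode.WITHIN_RECORDING)
            training_set = sample_training_set(self.reference, cfg,
                                               recording_id=self.recording.id)
        model = fit_stage_model(self.features, training_set, self.recording.id,
                                self.reference.vocabulary, seed=seed)
        raw, scores = predict_hypnogram(model, self.features, self.grid)
        final = apply_consistency_rules(raw, self.rules, scores)
        return StagingResults(stager=self, stage_model=model, hypnogram=final,
                              raw_hypnogram=raw, scores=scores,
                              training_set=training_set, seed=seed)


class StagingResults:
    """Results of a fitted :class:`SleepStager`.

    Attributes
    ----------
    hypnogram : Hypnogram
        Final prediction after consistency-rule smoothing.
    raw_hypnogram : Hypnogram
        Prediction before smoothing.
    scores : ndarray
        (n_epochs, n_stages) class scores in vocabulary order.
    training_set : TrainingSet
        The epochs the classifier was fitted on.
    """

    def __init__(self, stager: SleepStager, stage_model: StageModel,
                 hypnogram: Hypnogram, raw_hypnogram: Hypnogram,
                 scores: np.ndarray, training_set: TrainingSet, seed: int):
        self.stager = stager
        self.stage_model = stage_model
        self.hypnogram = hypnogram
        self.raw_hypnogram = raw_hypnogram
        self.scores = scores
        self.training_set = training_set
        self.seed = seed

    def evaluate(self, exclude_transitions: bool = False,
                 scheme: ev.ReclassScheme = ev.ReclassScheme.NONE,
                 include_training: bool = False, **kwargs) -> ev.AgreementReport:
        """Agreement with the reference hypnogram.

        Training epochs are excluded by default (scoring is assessed on
        the *remaining* recording); ``include_training=True`` keeps them
        for diagnostics.  Reference ARTIFACT/UNDETERMINED epochs are
        always excluded.
        """
        exclude: set[int] = set()
        if not include_training:
            exclude |= set(self.training_set.all_indices(self.stager.recording.id).tolist())
        report = ev.evaluate(
            self.hypnogram, self.stager.reference,
            exclude_transitions=exclude_transitions,
            exclude=exclude, scheme=scheme,
            provenance={
                "recording": self.stager.recording.id,
                "channels": self.stager.channels.name,
                "training_sizes": self.training_set.sizes,
                "training_seed": self.training_set.seed,
                "fit_seed": self.seed,
                "rules_s": dict(self.stager.rules.min_bout_s),
                "include_training": include_training,
            },
            **kwargs,
        )
        return report

    def summary(self) -> str:
        """Text summary: configuration, training composition, agreement."""
        rep = self.evaluate()
        head = [
            f"SleepStager results — recording {self.stager.recording.id!r}",
            f"epoch length {self.stager.grid.epoch_length:g} s, "
            f"{self.stager.grid.n_epochs} epochs, channels={self.stager.channels.name}",
            f"training sizes {self.training_set.sizes} (seed {self.training_set.seed})",
            "",
        ]
        return "\n".join(head) + rep.summary()

    def plot(self, ax=None):
        """Step plot of predicted vs reference hypnograms (stage index vs time)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        vocab = self.hypnogram.vocabulary.labels
        idx_of = {s: i for i, s in enumerate(vocab)}
        t = np.arange(self.hypnogram.n_epochs) * self.stager.grid.epoch_length / 3600.0
        ref = [idx_of.get(l, np.nan) for l in self.stager.reference.labels]
        pred = [idx_of.get(l, np.nan) for l in self.hypnogram.labels]
        ax.step(t, ref, where="post", lw=0.8, label="reference", alpha=0.7)
        ax.step(t, pred, where="post", lw=0.8, label="predicted", alpha=0.7)
        ax.set_yticks(range(len(vocab)), vocab)
        ax.set_xlabel("time (h)")
        ax.legend(loc="upper right")
        ax.invert_yaxis()
        return ax
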