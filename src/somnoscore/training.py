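"""Training-set construction by random epoch sampling.

Training sets are built per recording by uniform sampling without
replacement from the manually scored hypnogram, a fixed number of epochs
per stage.  The default sizes follow the per-epoch-length scoring
guideline: 100 epochs/stage at 4 s epochs (6.67 min of manual scoring
per state), 50 at 10 s (8.33 min) and 40 at 30 s (20 min).

For paired baseline/treatment designs two variants exist:
``LONGITUDINAL`` splits each stage's quota as evenly as possible across
the two recordings (odd remainder to baseline), ``BASELINE_ONLY`` draws
everything from the baseline recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .io import Hypnogram, excluded_epochs

__all__ = [
    "TrainingMode",
    "TrainingConfig",
    "TrainingSet",
    "StageSamplingError",
    "default_training_size",
    "sample_training_set",
    "build_paired_training_sets",
]

_DEFAULT_SIZES = {4: 100, 10: 50, 30: 40}


class StageSamplingError(ValueError):
    """A stage has no eligible epochs to sample from."""


class TrainingMode(str, Enum):
    WITHIN_RECORDING = "within"
    LONGITUDINAL = "longitudinal"
    BASELINE_ONLY = "baseline-only"


def default_training_size(epoch_length: float) -> int:
    """Guideline training-set size per stage for a given epoch length."""
    key = int(round(epoch_length))
    if abs(epoch_length - key) > 1e-9 or key not in _DEFAULT_SIZES:
        raise ValueError(
            f"no default training size for {epoch_length} s epochs "
            f"(defaults exist for {sorted(_DEFAULT_SIZES)}); pass size_per_stage explicitly"
        )
    return _DEFAULT_SIZES[key]


@dataclass(frozen=True)
class TrainingConfig:
    size_per_stage: int | None = None  # None: default for the epoch length
    seed: int = 0
    mode: TrainingMode = TrainingMode.WITHIN_RECORDING

    def __post_init__(self) -> None:
        if self.size_per_stage is not None and self.size_per_stage < 1:
            raise ValueError("size_per_stage must be >= 1")

    def resolved_size(self, epoch_length: float) -> int:
        if self.size_per_stage is not None:
            return self.size_per_stage
        return default_training_size(epoch_length)


@dataclass
class TrainingSet:
    """Sampled training epochs: per stage, (recording id, epoch index) pairs."""

    epochs: dict[str, list[tuple[str, int]]]
    seed: int

    def __post_init__(self) -> None:
        for stage, pairs in self.epochs.items():
            if len(set(pairs)) != len(pairs):
                raise ValueError(f"duplicate training epochs for stage {stage}")

    @property
    def sizes(self) -> dict[str, int]:
        return {s: len(p) for s, p in self.epochs.items()}

    @property
    def stages(self) -> list[str]:
        return [s for s, p in self.epochs.items() if p]

    def indices_for(self, recording_id: str) -> dict[str, np.ndarray]:
        """Epoch indices per stage restricted to one recording."""
        return {
            s: np.array([i for rid, i in pairs if rid == recording_id], dtype=int)
            for s, pairs in self.epochs.items()
        }

    def all_indices(self, recording_id: str) -> np.ndarray:
        """All training epoch indices in one recording, sorted."""
        out = [i for pairs in self.epochs.values() for rid, i in pairs if rid == recording_id]
        return np.array(sorted(out), dtype=int)


def _eligible_by_stage(hypnogram: Hypnogram) -> dict[str, np.ndarray]:
    labels = np.asarray(hypnogram.labels)
    excluded = excluded_epochs(hypnogram)
    keep = np.ones(len(labels), dtype=bool)
    if excluded:
        keep[list(excluded)] = False
    return {
        stage: np.flatnonzero((labels == stage) & keep)
        for stage in hypnogram.vocabulary
    }


def _sample_stage(eligible: np.ndarray, size: int, stage: str,
                  rng: np.random.Generator, recording_id: str) -> list[tuple[str, int]]:
    if eligible.size == 0:
        raise StageSamplingError(
            f"stage {stage!r} has no eligible epochs in recording {recording_id!r}"
        )
    if eligible.size < size:
        warnings.warn(
            f"stage {stage!r} has only {eligible.size} eligible epochs in "
            f"{recording_id!r} (requested {size}); taking all"
        )
        chosen = eligible
    else:
        chosen = rng.choice(eligible, size=size, replace=False)
    return [(recording_id, int(i)) for i in np.sort(chosen)]


def sample_training_set(hypnogram: Hypnogram, config: TrainingConfig,
                        recording_id: str = "recording") -> TrainingSet:
    """Uniform per-stage sampling without replacement from eligible epochs.

    Eligible epochs are those matching the stage and not ARTIFACT /
    UNDETERMINED.  When a stage has fewer eligible epochs than requested
    all of them are taken with a warning.  Reproducible given the seed.
    """
    size = config.resolved_size(hypnogram.grid.epoch_length)
    rng = np.random.default_rng(config.seed)
    eligible = _eligible_by_stage(hypnogram)
    epochs = {
        stage: _sample_stage(eligible[stage], size, stage, rng, recording_id)
        for stage in hypnogram.vocabulary
    }
    return TrainingSet(epochs=epochs, seed=config.seed)


def build_paired_training_sets(baseline: Hypnogram, treatment: Hypnogram,
                               config: TrainingConfig,
                               baseline_id: str = "baseline",
                               treatment_id: str = "treatment") -> TrainingSet:
    """Training set for a baseline/treatment pair.

    ``LONGITUDINAL``: each stage's quota is split as evenly as possible
    across the two recordings, the odd epoch going to baseline.
    ``BASELINE_ONLY``: everything from the baseline recording.
    Provenance (which recording each epoch came from) is kept per epoch.
    """
    if baseline.vocabulary.labels != treatment.vocabulary.labels:
        raise ValueError("baseline and treatment hypnograms use different vocabularies")
    if abs(baseline.grid.epoch_length - treatment.grid.epoch_length) > 1e-9:
        raise ValueError("baseline and treatment hypnograms use different epoch lengths")

    size = config.resolved_size(baseline.grid.epoch_length)
    if config.mode is TrainingMode.BASELINE_ONLY:
        ts = sample_training_set(baseline, config, recording_id=baseline_id)
        return ts
    if config.mode is not TrainingMode.LONGITUDINAL:
        raise ValueError(f"paired training sets need LONGITUDINAL or BASELINE_ONLY mode, "
                         f"got {config.mode}")

    n_base = (size + 1) // 2  # odd remainder to baseline
    n_treat = size // 2
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_treat = (np.random.default_rng(s) for s in ss.spawn(2))
    elig_base = _eligible_by_stage(baseline)
    elig_treat = _eligible_by_stage(treatment)
    epochs: dict[str, list[tuple[str, int]]] = {}
    for stage in baseline.vocabulary:
        pairs = _sample_stage(elig_base[stage], n_base, stage, rng_base, baseline_id)
        if n_treat > 0:
            pairs += _sample_stage(elig_treat[stage], n_treat, stage, rng_treat, treatment_id)
        epochs[stage] = pairs
    return TrainingSet(epochs=epochs, seed=config.seed)
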