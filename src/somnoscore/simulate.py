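"""Synthetic polysomnography with known ground truth.

Hypnograms are drawn from a semi-Markov model: the stage sequence
follows a transition-weight matrix with zero self-transitions, and each
bout's duration (in epochs) is geometric with the stage's mean (minimum
one epoch; a dispersion knob switches to negative-binomial).  Signals
are synthesized per epoch as band-limited Gaussian noise mixed to the
stage's relative EEG band-power profile, plus amplitude-modulated
broadband noise for EMG/EOG/ACC with stage-dependent levels (muscle
tone wake > NREM > REM).  This is deliberately not biophysical
modelling: only the stage-conditional spectral/amplitude contrast
matters to the classifier under test.

Three presets ship in ``presets.yaml``: ``human`` (30 s epochs, five
stages), ``rodent`` (4 s epochs, three stages) and ``avian`` (4 s
epochs, three stages with very short REM bouts — the REM bout-duration
95th percentile is at most 16 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import fft as sfft

from .features import BANDS
from .io import (
    ARTIFACT,
    EpochGrid,
    Hypnogram,
    Modality,
    Recording,
    SignalChannel,
    StageVocabulary,
    ANIMAL_VOCABULARY,
    HUMAN_VOCABULARY,
)

__all__ = ["SyntheticSpec", "load_preset", "available_presets",
           "generate_hypnogram", "generate_signals", "generate_recording"]

_EOG_BAND = (0.3, 3.0)  # slow eye-movement band, Hz
_EEG_SCALE = 30.0       # nominal amplitude scale, arbitrary physical units
_EMG_SCALE = 20.0
_EOG_SCALE = 40.0
_ACC_SCALE = 1.0


@dataclass
class SyntheticSpec:
    """Stage-conditional generative parameters for one species preset."""

    name: str
    epoch_length: float
    stages: tuple[str, ...]
    mean_bout_s: dict[str, float]
    transitions: dict[str, dict[str, float]]
    band_profile: dict[str, tuple[float, ...]]  # (delta, theta, alpha, sigma, beta)
    emg_level: dict[str, float]
    eog_level: dict[str, float]
    acc_level: dict[str, float]
    channels: list[dict]
    noise_floor: float = 0.05
    dispersion: float | None = None  # None: geometric bouts; else neg-binomial r

    def __post_init__(self) -> None:
        for stage in self.stages:
            row = self.transitions.get(stage, {})
            if stage in row and row[stage] != 0:
                raise ValueError(f"self-transition weight for {stage} must be zero")
            if sum(w for s, w in row.items() if s != stage) <= 0:
                raise ValueError(f"stage {stage} has no outgoing transition weight")
            prof = self.band_profile[stage]
            if abs(sum(prof) - 1.0) > 1e-6:
                raise ValueError(f"band profile for {stage} must sum to 1")
            if self.mean_bout_s[stage] <= 0:
                raise ValueError(f"mean bout for {stage} must be positive")

    @property
    def vocabulary(self) -> StageVocabulary:
        if self.stages == HUMAN_VOCABULARY.labels:
            return HUMAN_VOCABULARY
        if self.stages == ANIMAL_VOCABULARY.labels:
            return ANIMAL_VOCABULARY
        return StageVocabulary(labels=self.stages)

    def transition_matrix(self) -> np.ndarray:
        """Row-normalized embedded-chain transition probabilities."""
        k = len(self.stages)
        P = np.zeros((k, k))
        for i, s in enumerate(self.stages):
            for j, t in enumerate(self.stages):
                P[i, j] = self.transitions.get(s, {}).get(t, 0.0)
        return P / P.sum(axis=1, keepdims=True)

    def mean_bout_epochs(self, stage: str) -> float:
        return max(1.0, self.mean_bout_s[stage] / self.epoch_length)


def _presets_dict() -> dict:
    text = resources.files("somnoscore").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> list[str]:
    return sorted(_presets_dict()["presets"])


def load_preset(name: str) -> SyntheticSpec:
    """Load a named species preset from the versioned presets file."""
    data = _presets_dict()
    try:
        p = data["presets"][name.lower()]
    except KeyError as e:
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}") from e
    return SyntheticSpec(
        name=name.lower(),
        epoch_length=float(p["epoch_length"]),
        stages=tuple(p["stages"]),
        mean_bout_s={k: float(v) for k, v in p["mean_bout_s"].items()},
        transitions={k: dict(v) for k, v in p["transitions"].items()},
        band_profile={k: tuple(v) for k, v in p["band_profile"].items()},
        emg_level=dict(p.get("emg_level") or {}),
        eog_level=dict(p.get("eog_level") or {}),
        acc_level=dict(p.get("acc_level") or {}),
        channels=[dict(c) for c in p["channels"]],
        noise_floor=float(p.get("noise_floor", 0.05)),
    )


def _draw_bout_length(rng: np.random.Generator, mean_epochs: float,
                      dispersion: float | None) -> int:
    if mean_epochs <= 1.0:
        return 1
    if dispersion is None:
        return int(rng.geometric(1.0 / mean_epochs))
    # negative binomial shifted to support >= 1, mean preserved
    r = dispersion
    p = r / (r + mean_epochs - 1.0)
    return 1 + int(rng.negative_binomial(r, p))


def generate_hypnogram(spec: SyntheticSpec, n_epochs: int, seed: int,
                       artifact_fraction: float = 0.0) -> Hypnogram:
    """Semi-Markov hypnogram draw, truncated at ``n_epochs``.

    The initial stage is drawn with probability proportional to mean
    bout length.  ``artifact_fraction`` > 0 relabels that fraction of
    epochs (chosen uniformly) as ARTIFACT, for exercising exclusion
    plumbing.  Reproducible given the seed.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    P = spec.transition_matrix()
    means = np.array([spec.mean_bout_epochs(s) for s in spec.stages])
    state = int(rng.choice(len(spec.stages), p=means / means.sum()))

    labels = np.empty(n_epochs, dtype=object)
    pos = 0
    while pos < n_epochs:
        length = min(_draw_bout_length(rng, means[state], spec.dispersion),
                     n_epochs - pos)
        labels[pos : pos + length] = spec.stages[state]
        pos += length
        state = int(rng.choice(len(spec.stages), p=P[state]))

    if artifact_fraction > 0:
        n_art = int(round(artifact_fraction * n_epochs))
        idx = rng.choice(n_epochs, size=n_art, replace=False)
        labels[idx] = ARTIFACT

    grid = EpochGrid(epoch_length=spec.epoch_length, n_epochs=n_epochs)
    return Hypnogram(grid=grid, vocabulary=spec.vocabulary, labels=labels)


def _band_components(rng: np.random.Generator, n: int, fs: float,
                     bands: list[tuple[float, float]]) -> list[np.ndarray]:
    """Unit-variance Gaussian noise restricted to each band (FFT masking)."""
    white = rng.standard_normal(n).astype(np.float32)
    ft = sfft.rfft(white)
    freqs = sfft.rfftfreq(n, d=1.0 / fs)
    comps = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < min(hi, fs / 2.0))
        comp = sfft.irfft(ft * mask, n)
        sd = comp.std()
        comps.append(comp / (sd if sd > 0 else 1.0))
    return comps


def _stage_levels(hypnogram: Hypnogram, levels: dict[str, float],
                  floor: float) -> np.ndarray:
    """Per-epoch amplitude level; special labels reuse the floor level."""
    return np.array([levels.get(l, floor) for l in hypnogram.labels]) + floor


def generate_signals(hypnogram: Hypnogram, spec: SyntheticSpec, seed: int) -> Recording:
    """Synthesize the preset's channels conditioned on the hypnogram.

    EEG: per epoch, the five canonical band components are mixed with
    weights equal to the stage's band-power profile, so NREM epochs have
    high relative delta power, REM high theta, etc.  EMG/EOG/ACC:
    broadband (EMG/ACC) or slow-band (EOG) noise scaled by the stage's
    level; the two first EOG channels share a common slow component so
    their zero-lag correlation rises with eye activity.  Deterministic
    and bit-identical given the seed.
    """
    if hypnogram.vocabulary.labels != spec.vocabulary.labels:
        raise ValueError(
            f"hypnogram vocabulary {hypnogram.vocabulary.labels} does not match "
            f"preset {spec.name!r} ({spec.vocabulary.labels})"
        )
    n_epochs = hypnogram.n_epochs
    L = spec.epoch_length
    band_edges = list(BANDS.values())
    stage_idx = np.array(
        [spec.stages.index(l) if l in spec.stages else 0 for l in hypnogram.labels]
    )
    profiles = np.array([spec.band_profile[s] for s in spec.stages])  # (k, 5)

    ss = np.random.SeedSequence(seed)
    channel_seeds = ss.spawn(len(spec.channels) + 1)
    eog_shared_rng = np.random.default_rng(channel_seeds[-1])
    eog_shared: dict[float, np.ndarray] = {}

    channels: list[SignalChannel] = []
    for ch_spec, ch_seed in zip(spec.channels, channel_seeds):
        rng = np.random.default_rng(ch_seed)
        fs = float(ch_spec["rate"])
        modality = Modality(ch_spec["modality"])
        spe = int(round(fs * L))
        n = n_epochs * spe

        if modality is Modality.EEG:
            comps = _band_components(rng, n, fs, band_edges)
            w = np.sqrt(profiles[stage_idx]).astype(np.float32)
            x = np.zeros(n, dtype=np.float32)
            for b, comp in enumerate(comps):
                x += (comp.reshape(n_epochs, spe) * w[:, b : b + 1]).reshape(n)
            x += spec.noise_floor * rng.standard_normal(n).astype(np.float32)
            x *= _EEG_SCALE
        elif modality is Modality.EMG:
            level = _stage_levels(hypnogram, spec.emg_level, spec.noise_floor)
            x = rng.standard_normal(n).reshape(n_epochs, spe)
            x = (x * level[:, None]).reshape(n) * _EMG_SCALE
        elif modality is Modality.EOG:
            if fs not in eog_shared:
                (shared,) = _band_components(eog_shared_rng, n, fs, [_EOG_BAND])
                eog_shared[fs] = shared
            (own,) = _band_components(rng, n, fs, [_EOG_BAND])
            mix = 0.8 * eog_shared[fs] + 0.6 * own  # correlated across the pair
            level = _stage_levels(hypnogram, spec.eog_level, spec.noise_floor)
            x = (mix.reshape(n_epochs, spe) * level[:, None]).reshape(n)
            x += spec.noise_floor * rng.standard_normal(n)
            x *= _EOG_SCALE
        elif modality is Modality.ACC:
            level = _stage_levels(hypnogram, spec.acc_level, spec.noise_floor)
            x = rng.standard_normal(n).reshape(n_epochs, spe)
            x = (x * level[:, None]).reshape(n) * _ACC_SCALE
        else:
            x = rng.standard_normal(n)
        channels.append(
            SignalChannel(label=ch_spec["label"], sampling_rate=fs, samples=x,
                          modality=modality)
        )
    return Recording(id=f"synthetic-{spec.name}-{seed}", channels=channels)


def generate_recording(spec: SyntheticSpec | str, hours: float, seed: int,
                       artifact_fraction: float = 0.0) -> tuple[Recording, Hypnogram]:
    """Convenience wrapper: hypnogram plus signals for ``hours`` of recording.

    A 24 h rodent recording at 4 s epochs yields 21600 epochs.  Seeds
    for the hypnogram and the signals are derived from ``seed``.
    """
    if isinstance(spec, str):
        spec = load_preset(spec)
    n_epochs = int(hours * 3600.0 / spec.epoch_length + 1e-9)
    ss = np.random.SeedSequence(seed)
    s_hyp, s_sig = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    hyp = generate_hypnogram(spec, n_epochs, s_hyp, artifact_fraction=artifact_fraction)
    rec = generate_signals(hyp, spec, s_sig)
    return rec, hyp
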