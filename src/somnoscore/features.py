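"""Per-epoch feature extraction from multichannel recordings.

Each epoch becomes a fixed-length numeric vector.  The descriptor
battery is the standard sleep-staging repertoire and is deliberately a
replaceable interface, not an attempt to mirror any particular
commercial scorer's internals:

* EEG / EOG channels: absolute and relative band powers (delta 0.5-4,
  theta 4-8, alpha 8-12, sigma 12-16, beta 16-30 Hz) from an averaged
  modified periodogram (Welch, Hamming window), delta/theta log-ratio,
  spectral edge frequency (95% of total power) and zero-crossing rate;
* EMG channels: log RMS amplitude plus log power above 30 Hz where the
  sampling rate permits;
* EOG pairs: zero-lag cross-correlation per epoch;
* ACC channels: log variance and log mean absolute derivative;
* TEMP channels: epoch mean and linear slope;
* ECG / OTHER channels: log RMS amplitude only.

Absolute powers and amplitude features are log10-transformed (floor
1e-12) and z-scored per recording; relative powers, correlations and
rates are left on their natural scales.  Band edges are clipped to each
channel's Nyquist frequency; a band lying entirely above Nyquist is
dropped for that channel with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EpochGrid, Modality, Recording, SignalChannel

__all__ = ["BANDS", "ChannelConfig", "FeatureMatrix", "extract_features", "ConfigError"]

#: canonical EEG frequency bands in Hz (low edge inclusive, high exclusive)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 30.0),
}

LOG_FLOOR = 1e-12  # power floor applied before log10


class ConfigError(ValueError):
    """A channel configuration cannot be resolved against a recording."""


@dataclass(frozen=True)
class ChannelConfig:
    """Which channels feed the classifier.

    Either an explicit ``include`` list of channel labels, or a named
    preset resolved against the recording's modalities.  Presets mirror
    the input-channel configurations used in validation studies:
    ``ALL``, ``ONE_EEG``, ``EOG_ONLY``, ``EEG_EMG``, ``EEG_ONLY``,
    ``EMG_ONLY``, ``EEG_ACC``, ``ACC_ONLY``.
    """

    preset: str = "ALL"
    include: tuple[str, ...] = ()
    eeg_channel: str | None = None  # which EEG lead ONE_EEG uses

    _PRESET_MODALITIES = {
        "ALL": None,
        "ONE_EEG": (Modality.EEG,),
        "EOG_ONLY": (Modality.EOG,),
        "EEG_EMG": (Modality.EEG, Modality.EMG),
        "EEG_ONLY": (Modality.EEG,),
        "EMG_ONLY": (Modality.EMG,),
        "EEG_ACC": (Modality.EEG, Modality.ACC),
        "ACC_ONLY": (Modality.ACC,),
    }

    @classmethod
    def from_name(cls, name: str, eeg_channel: str | None = None) -> "ChannelConfig":
        name = name.strip().upper()
        if name not in cls._PRESET_MODALITIES:
            raise ConfigError(
                f"unknown preset {name!r}; choose from {sorted(cls._PRESET_MODALITIES)}"
            )
        return cls(preset=name, eeg_channel=eeg_channel)

    def resolve(self, recording: Recording) -> list[SignalChannel]:
        """Resolve to concrete channels, preserving recording order."""
        if self.include:
            try:
                return [recording.channel(lab) for lab in self.include]
            except KeyError as e:
                raise ConfigError(str(e)) from e
        if self.preset not in self._PRESET_MODALITIES:
            raise ConfigError(f"unknown preset {self.preset!r}")
        wanted = self._PRESET_MODALITIES[self.preset]
        if wanted is None:
            chans = list(recording.channels)
        else:
            chans = [c for c in recording.channels if c.modality in wanted]
        if self.preset == "ONE_EEG":
            if self.eeg_channel is not None:
                chans = [c for c in chans if c.label == self.eeg_channel]
            else:
                chans = chans[:1]
        if not chans:
            raise ConfigError(
                f"preset {self.preset!r} resolves to no channels in recording "
                f"{recording.id!r} (channels: {recording.labels})"
            )
        return chans

    @property
    def name(self) -> str:
        return self.preset if not self.include else "+".join(self.include)


@dataclass
class FeatureMatrix:
    """n_epochs x n_features matrix with names and the z-scaling used."""

    values: np.ndarray
    names: list[str]
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names):
            raise ValueError("feature count does not match name count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _welch_psd(epochs: np.ndarray, fs: float, window_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram per epoch row (Hamming, 50% overlap)."""
    nper = int(round(window_s * fs))
    nper = min(nper, epochs.shape[1])
    if nper < 8:
        raise ValueError(
            f"epoch of {epochs.shape[1]} samples too short for a {window_s} s "
            f"spectral window at {fs} Hz"
        )
    freqs, psd = sps.welch(
        epochs, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2, axis=1
    )
    return freqs, psd


def _band_powers(freqs: np.ndarray, psd: np.ndarray, fs: float,
                 label: str) -> dict[str, np.ndarray]:
    """Integrate PSD over each band; clip to Nyquist, drop empty bands."""
    nyq = fs / 2.0
    df = freqs[1] - freqs[0]
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in BANDS.items():
        if lo >= nyq:
            warnings.warn(
                f"band {name} ({lo}-{hi} Hz) above Nyquist ({nyq} Hz) for "
                f"channel {label!r}; dropped"
            )
            continue
        hi_c = min(hi, nyq)
        sel = (freqs >= lo) & (freqs < hi_c)
        out[name] = psd[:, sel].sum(axis=1) * df
    if not out:
        raise ValueError(f"no frequency band below Nyquist for channel {label!r}")
    return out


def _spectral_edge(freqs: np.ndarray, psd: np.ndarray, q: float = 0.95) -> np.ndarray:
    cum = np.cumsum(psd, axis=1)
    tot = cum[:, -1:]
    tot = np.where(tot > 0, tot, 1.0)
    idx = np.argmax(cum / tot >= q, axis=1)
    return freqs[idx]


def _zero_crossing_rate(epochs: np.ndarray, fs: float) -> np.ndarray:
    sign = np.signbit(epochs)
    return np.count_nonzero(sign[:, 1:] != sign[:, :-1], axis=1) * fs / epochs.shape[1]


def _log(x: np.ndarray) -> np.ndarray:
    return np.log10(np.maximum(x, LOG_FLOOR))


def _epoch_view(channel: SignalChannel, grid: EpochGrid) -> np.ndarray:
    spe = int(round(channel.sampling_rate * grid.epoch_length))
    need = spe * grid.n_epochs
    if channel.n_samples < need:
        raise ValueError(
            f"channel {channel.label!r} has {channel.n_samples} samples but the "
            f"grid needs {need}"
        )
    return channel.samples[:need].reshape(grid.n_epochs, spe)


def extract_features(recording: Recording, grid: EpochGrid,
                     config: ChannelConfig | str = "ALL",
                     window_s: float | None = None) -> FeatureMatrix:
    """Extract the per-epoch descriptor battery for the configured channels.

    ``window_s`` is the Welch segment length: default 2 s, shortened to
    1 s for 4 s epochs so each epoch still averages several segments.
    Deterministic; z-scoring is per recording and the scaling parameters
    are recorded on the returned matrix.
    """
    if isinstance(config, str):
        config = ChannelConfig.from_name(config)
    channels = config.resolve(recording)
    if window_s is None:
        window_s = 1.0 if grid.epoch_length <= 4 else 2.0

    cols: list[np.ndarray] = []
    names: list[str] = []
    zscored: list[bool] = []

    def add(name: str, values: np.ndarray, z: bool) -> None:
        names.append(name)
        cols.append(np.asarray(values, dtype=np.float64))
        zscored.append(z)

    seen: dict[str, int] = {}
    eog_epochs: list[tuple[str, np.ndarray]] = []
    for ch in channels:
        base = ch.label
        if base in seen:  # duplicate labels: disambiguate
            seen[base] += 1
            base = f"{base}#{seen[base]}"
        else:
            seen[base] = 0
        x = _epoch_view(ch, grid)

        if ch.modality in (Modality.EEG, Modality.EOG):
            freqs, psd = _welch_psd(x, ch.sampling_rate, window_s)
            bp = _band_powers(freqs, psd, ch.sampling_rate, ch.label)
            total = np.sum(list(bp.values()), axis=0)
            total = np.where(total > 0, total, LOG_FLOOR)
            for bname, p in bp.items():
                add(f"{base}:{bname}_logpow", _log(p), z=True)
            for bname, p in bp.items():
                add(f"{base}:{bname}_rel", p / total, z=False)
            if "delta" in bp and "theta" in bp:
                add(f"{base}:delta_theta_logratio", _log(bp["delta"]) - _log(bp["theta"]), z=True)
            add(f"{base}:sef95_hz", _spectral_edge(freqs, psd), z=False)
            add(f"{base}:zcr_hz", _zero_crossing_rate(x, ch.sampling_rate), z=False)
            if ch.modality is Modality.EOG:
                eog_epochs.append((base, x))
        elif ch.modality is Modality.EMG:
            rms = np.sqrt(np.mean(x**2, axis=1))
            add(f"{base}:log_rms", _log(rms), z=True)
            nyq = ch.sampling_rate / 2.0
            if nyq > 30.0:
                freqs, psd = _welch_psd(x, ch.sampling_rate, window_s)
                df = freqs[1] - freqs[0]
                sel = freqs >= 30.0
                add(f"{base}:high_logpow", _log(psd[:, sel].sum(axis=1) * df), z=True)
        elif ch.modality is Modality.ACC:
            add(f"{base}:log_var", _log(np.var(x, axis=1)), z=True)
            deriv = np.mean(np.abs(np.diff(x, axis=1)), axis=1)
            add(f"{base}:log_mad", _log(deriv), z=True)
        elif ch.modality is Modality.TEMP:
            add(f"{base}:mean", np.mean(x, axis=1), z=True)
            t = np.arange(x.shape[1]) / ch.sampling_rate
            tc = t - t.mean()
            slope = (x - x.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
            add(f"{base}:slope", slope, z=True)
        else:  # ECG / OTHER: minimal amplitude descriptor
            rms = np.sqrt(np.mean(x**2, axis=1))
            add(f"{base}:log_rms", _log(rms), z=True)

    # EOG pair: zero-lag cross-correlation per epoch
    if len(eog_epochs) >= 2:
        (la, xa), (lb, xb) = eog_epochs[0], eog_epochs[1]
        a = xa - xa.mean(axis=1, keepdims=True)
        b = xb - xb.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        denom = np.where(denom > 0, denom, 1.0)
        add(f"{la}~{lb}:xcorr0", (a * b).sum(axis=1) / denom, z=False)

    values = np.column_stack(cols)
    scaling: dict[str, tuple[float, float]] = {}
    for j, (name, z) in enumerate(zip(names, zscored)):
        if not z:
            continue
        mu = float(np.mean(values[:, j]))
        sd = float(np.std(values[:, j]))
        sd = sd if sd > 1e-12 else 1.0
        values[:, j] = (values[:, j] - mu) / sd
        scaling[name] = (mu, sd)
    values[~np.isfinite(values)] = 0.0  # imputation: all values finite
    return FeatureMatrix(values=values, names=names, scaling=scaling)
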