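"""Recording and hypnogram I/O, epoch grids, and stage vocabularies.

Everything downstream — feature extraction, training-set sampling,
classification, agreement scoring — is aligned to the epoch grid
established here.  Epochs are 0-based, half-open time intervals
``[i*L, (i+1)*L)`` of length ``L`` seconds; a trailing partial epoch is
dropped, never padded.

Signals are read and written in 16-bit EDF (European Data Format) or a
plain one-column-per-channel CSV dialect.  Hypnograms are one stage label
per epoch, either headerless one-label-per-line or CSV with columns
``epoch_index,onset_s,stage``.
"""

from __future__ import annotations

import io as _stdio
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Modality",
    "SignalChannel",
    "Recording",
    "EpochGrid",
    "StageVocabulary",
    "HUMAN_VOCABULARY",
    "ANIMAL_VOCABULARY",
    "Hypnogram",
    "FormatError",
    "read_edf",
    "write_edf",
    "read_text_recording",
    "write_text_recording",
    "read_hypnogram",
    "write_hypnogram",
    "make_epoch_grid",
    "excluded_epochs",
]

ARTIFACT = "ARTIFACT"
UNDETERMINED = "UNDETERMINED"
SPECIAL_LABELS = (ARTIFACT, UNDETERMINED)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class Modality(str, Enum):
    EEG = "EEG"
    EMG = "EMG"
    EOG = "EOG"
    ECG = "ECG"
    ACC = "ACC"
    TEMP = "TEMP"
    OTHER = "OTHER"


#: label prefixes used to infer a channel's modality (case-insensitive)
_MODALITY_PREFIXES = (
    ("EEG", Modality.EEG),
    ("EMG", Modality.EMG),
    ("EOG", Modality.EOG),
    ("ECG", Modality.ECG),
    ("EKG", Modality.ECG),
    ("ACCEL", Modality.ACC),
    ("ACC", Modality.ACC),
    ("TEMP", Modality.TEMP),
    ("T_", Modality.TEMP),
)


def infer_modality(label: str, overrides: Mapping[str, Modality] | None = None) -> Modality:
    """Infer a channel modality from its label prefix.

    ``overrides`` maps exact labels to modalities and wins over the
    prefix rule; montage naming varies between laboratories.
    """
    if overrides and label in overrides:
        return Modality(overrides[label])
    upper = label.strip().upper()
    for prefix, modality in _MODALITY_PREFIXES:
        if upper.startswith(prefix):
            return modality
    return Modality.OTHER


@dataclass
class SignalChannel:
    """A single physiological signal.

    Parameters
    ----------
    label : str
        Channel name, e.g. ``"EEG C3:A2"`` or ``"EMG nuchal"``.
    sampling_rate : float
        Samples per second, > 0.
    samples : ndarray
        Real-valued signal in physical units.
    modality : Modality, optional
        Inferred from the label prefix when not given.
    passband : (float, float), optional
        Acquisition filter metadata in Hz; informational only.
    units : str
        Physical dimension label stored in EDF headers.
    """

    label: str
    sampling_rate: float
    samples: np.ndarray
    modality: Modality | None = None
    passband: tuple[float, float] | None = None
    units: str = "uV"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")
        if self.modality is None:
            self.modality = infer_modality(self.label)
        else:
            self.modality = Modality(self.modality)

    @property
    def duration(self) -> float:
        """Channel duration in seconds."""
        return len(self.samples) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class Recording:
    """A multichannel polysomnography recording."""

    id: str
    channels: list[SignalChannel]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a Recording needs at least one channel")
        durations = [c.duration for c in self.channels]
        ref = durations[0]
        for c, d in zip(self.channels, durations):
            # channels must span the same time, give or take one sample period
            if abs(d - ref) > 1.0 / c.sampling_rate + 1e-9:
                raise ValueError(
                    f"channel {c.label!r} spans {d:.3f} s but {self.channels[0].label!r} "
                    f"spans {ref:.3f} s"
                )

    @property
    def duration(self) -> float:
        """Recording duration in seconds (shortest channel governs)."""
        return min(c.duration for c in self.channels)

    def channel(self, label: str) -> SignalChannel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(f"no channel labelled {label!r} in recording {self.id!r}")

    def by_modality(self, modality: Modality | str) -> list[SignalChannel]:
        modality = Modality(modality)
        return [c for c in self.channels if c.modality == modality]

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]


@dataclass(frozen=True)
class EpochGrid:
    """Uniform epoch grid: 0-based indices, half-open intervals."""

    epoch_length: float
    n_epochs: int

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be > 0")
        if self.n_epochs < 1:
            raise ValueError("grid needs at least one epoch")

    @property
    def duration(self) -> float:
        return self.epoch_length * self.n_epochs

    def onset(self, i: int) -> float:
        return i * self.epoch_length


def make_epoch_grid(recording: Recording | float, epoch_length: float) -> EpochGrid:
    """Build the epoch grid for a recording (or a bare duration in seconds).

    ``n_epochs = floor(duration / epoch_length)``; a trailing partial
    epoch is dropped.  A 30 h recording at 4 s epochs yields 27000
    epochs, a 24 h recording 21600.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be > 0")
    duration = recording.duration if isinstance(recording, Recording) else float(recording)
    n = int(math.floor(duration / epoch_length + 1e-9))
    if n < 1:
        raise ValueError(
            f"recording of {duration:.1f} s is shorter than one {epoch_length:.0f} s epoch"
        )
    return EpochGrid(epoch_length=float(epoch_length), n_epochs=n)


@dataclass(frozen=True)
class StageVocabulary:
    """Ordered set of stage labels plus token aliases.

    The special labels ARTIFACT and UNDETERMINED are always accepted in
    hypnograms but are never counted as stages.
    """

    labels: tuple[str, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("stage labels must be unique")
        for s in SPECIAL_LABELS:
            if s in self.labels:
                raise ValueError(f"{s} is reserved and cannot be a stage label")

    def __contains__(self, label: str) -> bool:
        return label in self.labels or label in SPECIAL_LABELS

    def __iter__(self):
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def normalize(self, token: str) -> str:
        """Map a file token to a canonical label; raise on unknown tokens."""
        token = token.strip()
        if token in self.aliases:
            token = self.aliases[token]
        if token in self.labels or token in SPECIAL_LABELS:
            return token
        raise ValueError(f"unknown stage token {token!r}")


_COMMON_ALIASES = {
    "R": "REM",
    "ART": ARTIFACT,
    "A": ARTIFACT,
    "MT": ARTIFACT,
    "UND": UNDETERMINED,
    "U": UNDETERMINED,
    "?": UNDETERMINED,
}

#: AASM human staging: wake, three NREM depths, REM
HUMAN_VOCABULARY = StageVocabulary(
    labels=("W", "N1", "N2", "N3", "REM"),
    aliases={**_COMMON_ALIASES, "WAKE": "W", "S1": "N1", "S2": "N2", "S3": "N3", "S4": "N3"},
)

#: rodent / avian three-state staging
ANIMAL_VOCABULARY = StageVocabulary(
    labels=("W", "NREM", "REM"),
    aliases={**_COMMON_ALIASES, "WAKE": "W", "N": "NREM", "NR": "NREM", "SWS": "NREM"},
)


@dataclass
class Hypnogram:
    """One stage label per epoch on an epoch grid."""

    grid: EpochGrid
    vocabulary: StageVocabulary
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.grid.n_epochs:
            raise ValueError(
                f"{len(self.labels)} labels for a grid of {self.grid.n_epochs} epochs"
            )
        bad = [l for l in np.unique(self.labels) if l not in self.vocabulary]
        if bad:
            raise ValueError(f"labels {bad} not in vocabulary {self.vocabulary.labels}")

    def __len__(self) -> int:
        return self.grid.n_epochs

    @property
    def n_epochs(self) -> int:
        return self.grid.n_epochs

    def counts(self) -> dict[str, int]:
        """Number of epochs per stage (special labels included)."""
        uniq, n = np.unique(self.labels, return_counts=True)
        return dict(zip(uniq.tolist(), n.tolist()))

    def replace(self, labels: np.ndarray, vocabulary: StageVocabulary | None = None) -> "Hypnogram":
        return Hypnogram(self.grid, vocabulary or self.vocabulary, labels)


def excluded_epochs(hypnogram: Hypnogram) -> set[int]:
    """Indices labelled ARTIFACT or UNDETERMINED.

    These epochs are excluded from training-set sampling and from
    agreement evaluation; the classifier still predicts a stage for
    them.  Idempotent and always a subset of ``[0, n_epochs)``.
    """
    mask = np.isin(np.asarray(hypnogram.labels), SPECIAL_LABELS)
    return set(np.flatnonzero(mask).tolist())


# ---------------------------------------------------------------------------
# EDF (European Data Format, 16-bit, continuous records)
# ---------------------------------------------------------------------------

_EDF_HEADER = 256  # bytes, fixed part
_EDF_PER_SIGNAL = 256  # bytes of header per signal


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _edf_number(x: float, width: int) -> bytes:
    """Format a number into EDF's fixed-width ascii fields."""
    for fmt in (f"{x:.10g}", f"{x:.4f}", f"{x:.1f}", f"{x:.0f}"):
        if len(fmt) <= width:
            return _pad(fmt, width)
    raise ValueError(f"cannot encode {x} in {width} chars")


def _choose_record_duration(rates: Sequence[float]) -> float:
    """Pick a data-record duration giving a whole number of samples per record."""
    for dur in (1.0, 2.0, 4.0, 5.0, 10.0):
        if all(abs(r * dur - round(r * dur)) < 1e-9 for r in rates):
            return dur
    raise ValueError(f"no EDF record duration fits sampling rates {rates}")


def write_edf(recording: Recording, path: str | Path, *, patient_id: str = "X",
              start: str = "01.01.0001.01.00.00") -> None:
    """Write a recording as 16-bit EDF.

    Physical min/max per signal are taken from the data (symmetric about
    zero) so quantization error is at most one digital step of the
    16-bit encoding.
    """
    path = Path(path)
    rates = [c.sampling_rate for c in recording.channels]
    rec_dur = _choose_record_duration(rates)
    spr = [int(round(c.sampling_rate * rec_dur)) for c in recording.channels]
    n_records = min(int(c.n_samples // s) for c, s in zip(recording.channels, spr))
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record")
    ns = len(recording.channels)

    phys_max, dig = [], []
    for c, s in zip(recording.channels, spr):
        x = c.samples[: n_records * s]
        m = float(np.max(np.abs(x)))
        m = m if m > 0 else 1.0
        # physical max must survive the 8-char ascii header exactly, or the
        # reader's linear map will not invert the writer's: round up to a
        # 5-significant-digit value >= max|x|
        pm = float(f"{m * 1.000001:.5g}")
        while pm < m:
            pm = float(f"{pm * 1.0001:.5g}")
        q = np.clip(np.round(x / pm * 32767.0), -32767, 32767).astype("<i2")
        phys_max.append(pm)
        dig.append(q)

    buf = _stdio.BytesIO()
    day, mo = start.split(".")[0:2]
    buf.write(_pad("0", 8))
    buf.write(_pad(patient_id, 80))
    buf.write(_pad(recording.id, 80))
    buf.write(_pad(f"{day}.{mo}.{start.split('.')[2][-2:]}", 8))
    buf.write(_pad(".".join(start.split(".")[3:6]), 8))
    buf.write(_pad(str(_EDF_HEADER + _EDF_PER_SIGNAL * ns), 8))
    buf.write(_pad("", 44))
    buf.write(_pad(str(n_records), 8))
    buf.write(_edf_number(rec_dur, 8))
    buf.write(_pad(str(ns), 4))

    def field_block(values: Iterable[bytes]) -> None:
        for v in values:
            buf.write(v)

    field_block(_pad(c.label, 16) for c in recording.channels)
    field_block(_pad("", 80) for _ in recording.channels)  # transducer
    field_block(_pad(c.units, 8) for c in recording.channels)
    field_block(_edf_number(-pm, 8) for pm in phys_max)
    field_block(_edf_number(pm, 8) for pm in phys_max)
    field_block(_edf_number(-32767, 8) for _ in recording.channels)
    field_block(_edf_number(32767, 8) for _ in recording.channels)
    field_block(
        _pad(f"HP:{c.passband[0]}Hz LP:{c.passband[1]}Hz" if c.passband else "", 80)
        for c in recording.channels
    )
    field_block(_edf_number(s, 8) for s in spr)
    field_block(_pad("", 32) for _ in recording.channels)

    for r in range(n_records):
        for q, s in zip(dig, spr):
            buf.write(q[r * s : (r + 1) * s].tobytes())
    path.write_bytes(buf.getvalue())


def read_edf(path: str | Path,
             modality_overrides: Mapping[str, Modality] | None = None) -> Recording:
    """Read a 16-bit EDF file into a :class:`Recording`.

    Physical scaling from the header is applied; modality is inferred
    from each label's prefix unless overridden.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _EDF_HEADER:
        raise FormatError(f"{path}: truncated EDF header ({len(raw)} bytes)")
    head = raw[:_EDF_HEADER].decode("ascii", "replace")

    def intfield(lo: int, hi: int, name: str) -> int:
        try:
            return int(head[lo:hi].strip())
        except ValueError as e:
            raise FormatError(f"{path}: bad {name} field {head[lo:hi]!r}") from e

    rec_id = head[88:168].strip()
    header_bytes = intfield(184, 192, "header-bytes")
    n_records = intfield(236, 244, "record-count")
    try:
        rec_dur = float(head[244:252].strip())
    except ValueError as e:
        raise FormatError(f"{path}: bad record-duration field") from e
    ns = intfield(252, 256, "signal-count")
    if ns < 1:
        raise FormatError(f"{path}: EDF declares zero signals")
    if len(raw) < header_bytes:
        raise FormatError(f"{path}: truncated signal headers")

    sig = raw[_EDF_HEADER:header_bytes].decode("ascii", "replace")

    # signal header is column-major blocks: ns*16 labels, ns*80 transducers, ...
    def block(width: int, start: int) -> tuple[list[str], int]:
        out = [sig[start + i * width : start + (i + 1) * width].strip() for i in range(ns)]
        return out, start + ns * width

    pos = 0
    labels, pos = block(16, pos)
    _, pos = block(80, pos)  # transducer
    units, pos = block(8, pos)
    pmin_s, pos = block(8, pos)
    pmax_s, pos = block(8, pos)
    dmin_s, pos = block(8, pos)
    dmax_s, pos = block(8, pos)
    prefilt, pos = block(80, pos)
    spr_s, pos = block(8, pos)

    try:
        pmin = [float(x) for x in pmin_s]
        pmax = [float(x) for x in pmax_s]
        dmin = [float(x) for x in dmin_s]
        dmax = [float(x) for x in dmax_s]
        spr = [int(x) for x in spr_s]
    except ValueError as e:
        raise FormatError(f"{path}: malformed numeric signal-header field") from e

    rec_bytes = 2 * sum(spr)
    avail = (len(raw) - header_bytes) // rec_bytes if rec_bytes else 0
    if n_records == -1:
        n_records = avail
    if n_records > avail:
        raise FormatError(
            f"{path}: header declares {n_records} records but file holds {avail}"
        )
    if n_records < 1:
        raise FormatError(f"{path}: no data records")

    data = np.frombuffer(
        raw, dtype="<i2", count=n_records * rec_bytes // 2, offset=header_bytes
    ).reshape(n_records, rec_bytes // 2)

    channels = []
    offset = 0
    for i in range(ns):
        dig = data[:, offset : offset + spr[i]].reshape(-1).astype(np.float64)
        offset += spr[i]
        dspan = dmax[i] - dmin[i]
        gain = (pmax[i] - pmin[i]) / dspan if dspan else 1.0
        phys = (dig - dmin[i]) * gain + pmin[i]
        pb = None
        m = re.search(r"HP:([\d.]+)\s*Hz\s+LP:([\d.]+)\s*Hz", prefilt[i])
        if m:
            pb = (float(m.group(1)), float(m.group(2)))
        channels.append(
            SignalChannel(
                label=labels[i],
                sampling_rate=spr[i] / rec_dur,
                samples=phys,
                modality=infer_modality(labels[i], modality_overrides),
                passband=pb,
                units=units[i] or "uV",
            )
        )
    return Recording(id=rec_id or path.stem, channels=channels)


# ---------------------------------------------------------------------------
# Plain-text recording dialect: one column per channel
# ---------------------------------------------------------------------------

def write_text_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as CSV: a sampling-rate header line, a label line,
    then one sample row per time point.  All channels must share one rate."""
    rates = {c.sampling_rate for c in recording.channels}
    if len(rates) != 1:
        raise ValueError("text recording dialect requires a single sampling rate")
    rate = rates.pop()
    n = min(c.n_samples for c in recording.channels)
    mat = np.column_stack([c.samples[:n] for c in recording.channels])
    header = f"# sampling_rate_hz={rate:g}\n" + ",".join(recording.labels)
    np.savetxt(path, mat, fmt="%.6g", delimiter=",", header=header, comments="")


def read_text_recording(path: str | Path,
                        modality_overrides: Mapping[str, Modality] | None = None) -> Recording:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        m = re.match(r"#\s*sampling_rate_hz\s*=\s*([\d.eE+-]+)", first)
        if not m:
            raise FormatError(
                f"{path}: first line must be '# sampling_rate_hz=<rate>', got {first!r}"
            )
        rate = float(m.group(1))
        labels = [t.strip() for t in fh.readline().strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != len(labels):
        raise FormatError(f"{path}: {len(labels)} labels but {data.shape[1]} columns")
    channels = [
        SignalChannel(label=lab, sampling_rate=rate, samples=data[:, i],
                      modality=infer_modality(lab, modality_overrides))
        for i, lab in enumerate(labels)
    ]
    return Recording(id=path.stem, channels=channels)


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path, vocabulary: StageVocabulary,
                   epoch_length: float) -> Hypnogram:
    """Read a hypnogram file.

    Two dialects are accepted: CSV with header ``epoch_index,onset_s,stage``
    (extra columns ignored), or headerless one-label-per-line.  Unknown
    stage tokens raise a :class:`ValueError` naming the offending line.
    """
    path = Path(path)
    raw_lines = path.read_text(encoding="utf-8").splitlines()
    # (original line number, content); '#' comment lines and blanks skipped
    lines = [(ln, l.strip()) for ln, l in enumerate(raw_lines, start=1)
             if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty hypnogram file")

    tokens: list[tuple[int, str]] = []  # (line number, token)
    header = [t.strip().lower() for t in lines[0][1].split(",")]
    if "stage" in header:
        i_stage = header.index("stage")
        i_idx = header.index("epoch_index") if "epoch_index" in header else None
        rows = []
        for ln, line in lines[1:]:
            parts = [t.strip() for t in line.split(",")]
            if len(parts) <= i_stage:
                raise ValueError(f"{path}:{ln}: too few columns")
            idx = int(parts[i_idx]) if i_idx is not None else len(rows)
            rows.append((idx, ln, parts[i_stage]))
        rows.sort(key=lambda r: r[0])
        tokens = [(ln, tok) for _, ln, tok in rows]
    else:
        tokens = lines

    labels = []
    for ln, tok in tokens:
        try:
            labels.append(vocabulary.normalize(tok))
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from e
    grid = EpochGrid(epoch_length=float(epoch_length), n_epochs=len(labels))
    return Hypnogram(grid=grid, vocabulary=vocabulary, labels=np.array(labels, dtype=object))


def write_hypnogram(hypnogram: Hypnogram, path: str | Path, *,
                    transitions: np.ndarray | None = None,
                    header_comment: str | None = None) -> None:
    """Write a hypnogram as ``epoch_index,onset_s,stage`` CSV.

    ``transitions`` adds a 0/1 ``transition`` column; ``header_comment``
    (e.g. a config hash) is written as a leading ``#`` line.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cols = "epoch_index,onset_s,stage"
        if transitions is not None:
            cols += ",transition"
        fh.write(cols + "\n")
        for i, lab in enumerate(hypnogram.labels):
            row = f"{i},{hypnogram.grid.onset(i):g},{lab}"
            if transitions is not None:
                row += f",{int(transitions[i])}"
            fh.write(row + "\n")
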