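"""Agreement between predicted and reference hypnograms.

The agreement metric throughout is the F-measure, the harmonic mean of
sensitivity (recall) and precision, computed per stage from per-epoch
TP/FP/FN counts and pooled (micro-averaged) for an overall score.
Conventions:

* any 0/0 ratio is defined as 0, so an absent stage scores 0, not NaN;
* "overall" is the micro average (pool TP/FP/FN across stages, then
  apply the formula); the macro average is reported alongside;
* F ratings use half-open bands, lower edge inclusive:
  intra-scorer >= 0.90, excellent >= 0.85, strong >= 0.80,
  average >= 0.70, inadequate < 0.70;
* effect sizes are Hedges' g with the plain pooled standard deviation
  (no small-sample correction by default), classified on |g| as
  miniscule < 0.2 <= small < 0.5 <= medium < 0.8 <= large.

Transition-epoch exclusion removes the first and last epoch of each
bout *of the predicted hypnogram* from evaluation; the corresponding
reference epochs are simply not analysed.  Simplified-staging schemes
(N1->W, N1->N2, W1NREM23, NREM123) remap both hypnograms before any
counting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bouts import tag_transition_epochs
from .io import (
    SPECIAL_LABELS,
    Hypnogram,
    StageVocabulary,
)

__all__ = [
    "StageCounts",
    "AgreementReport",
    "GroupSummary",
    "ReclassScheme",
    "ComparisonResult",
    "confusion_counts",
    "f_measure",
    "overall_f",
    "macro_f",
    "rate_f",
    "hedges_g",
    "reclassify",
    "evaluate",
    "compare_groups",
    "training_size_curve",
    "channel_ablation",
]


# ---------------------------------------------------------------------------
# Counts and F-measure
# ---------------------------------------------------------------------------

@dataclass
class StageCounts:
    """Per-stage TP/FP/FN over the evaluated epochs."""

    counts: dict[str, tuple[int, int, int]]  # stage -> (TP, FP, FN)
    n_evaluated: int

    def tp(self, stage: str) -> int:
        return self.counts[stage][0]

    def pooled(self) -> tuple[int, int, int]:
        tp = sum(c[0] for c in self.counts.values())
        fp = sum(c[1] for c in self.counts.values())
        fn = sum(c[2] for c in self.counts.values())
        return tp, fp, fn


def confusion_counts(predicted: Hypnogram, reference: Hypnogram,
                     exclusions: set[int] | frozenset[int] = frozenset()) -> StageCounts:
    """TP/FP/FN per stage over epochs not excluded and not ARTIFACT /
    UNDETERMINED in the reference.

    TP are epochs the prediction classified into the stage and the
    reference agrees; FP (type I) are epochs flagged as the stage that
    the reference puts elsewhere; FN (type II) are reference epochs of
    the stage that the prediction missed.
    """
    if predicted.grid != reference.grid:
        raise ValueError("predicted and reference hypnograms are on different grids")
    if predicted.vocabulary.labels != reference.vocabulary.labels:
        raise ValueError("predicted and reference hypnograms use different vocabularies")
    n = reference.n_epochs
    if exclusions and (min(exclusions) < 0 or max(exclusions) >= n):
        raise ValueError("exclusions outside [0, n_epochs)")

    pred = np.asarray(predicted.labels)
    ref = np.asarray(reference.labels)
    keep = ~np.isin(ref, SPECIAL_LABELS)
    if exclusions:
        keep[list(exclusions)] = False
    pred, ref = pred[keep], ref[keep]

    counts: dict[str, tuple[int, int, int]] = {}
    for stage in reference.vocabulary:
        p = pred == stage
        r = ref == stage
        tp = int(np.count_nonzero(p & r))
        fp = int(np.count_nonzero(p & ~r))
        fn = int(np.count_nonzero(~p & r))
        counts[stage] = (tp, fp, fn)
    return StageCounts(counts=counts, n_evaluated=int(keep.sum()))


def f_measure(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(sensitivity, precision, F) from per-stage counts.

    sensitivity = TP/(TP+FN); precision = TP/(TP+FP);
    F = 2*s*p/(s+p).  Any 0/0 ratio is defined as 0.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    s = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f = 2 * s * p / (s + p) if (s + p) > 0 else 0.0
    return s, p, f


def overall_f(counts: StageCounts) -> float:
    """Micro-averaged F: pool TP/FP/FN across stages, then apply the formula.

    On single-label-per-epoch data this equals epoch accuracy.
    """
    if counts.n_evaluated < 1:
        raise ValueError("no evaluated epochs")
    tp, fp, fn = counts.pooled()
    return f_measure(tp, fp, fn)[2]


def macro_f(counts: StageCounts) -> float:
    """Unweighted mean of per-stage F values."""
    return float(np.mean([f_measure(*c)[2] for c in counts.counts.values()]))


_RATINGS = (
    (0.90, "intra-scorer"),
    (0.85, "excellent"),
    (0.80, "strong"),
    (0.70, "average"),
)


def rate_f(f: float) -> str:
    """Qualitative generalization rating for an F score (bounds inclusive
    upward): intra-scorer >=0.9, excellent >=0.85, strong >=0.8,
    average >=0.7, inadequate <0.7."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"F must lie in [0, 1], got {f}")
    for bound, label in _RATINGS:
        if f >= bound:
            return label
    return "inadequate"


# ---------------------------------------------------------------------------
# Effect sizes and group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group comparisons need n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")

    @classmethod
    def from_scores(cls, scores) -> "GroupSummary":
        a = np.asarray(scores, dtype=float)
        return cls(mean=float(a.mean()), sd=float(a.std(ddof=1)), n=len(a))


_G_MAGNITUDES = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def hedges_g(a: GroupSummary, b: GroupSummary,
             small_sample_correction: bool = False) -> tuple[float, str]:
    """Hedges' g = (M1 - M2) / SD_pooled, with
    SD_pooled = sqrt(((n1-1)SD1^2 + (n2-1)SD2^2) / (n1+n2-2)).

    Magnitude is classified on |g|: miniscule < 0.2 <= small < 0.5 <=
    medium < 0.8 <= large.  When both SDs are zero: g = 0 for equal
    means, otherwise undefined (NaN, magnitude "undefined").  The
    optional small-sample correction multiplies g by
    1 - 3/(4(n1+n2) - 9); it is off by default.
    """
    sd_pooled = np.sqrt(((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2))
    if sd_pooled == 0:
        if a.mean == b.mean:
            return 0.0, "miniscule"
        return float("nan"), "undefined"
    g = (a.mean - b.mean) / sd_pooled
    if small_sample_correction:
        g *= 1.0 - 3.0 / (4.0 * (a.n + b.n) - 9.0)
    mag = "miniscule"
    for bound, label in _G_MAGNITUDES:
        if abs(g) >= bound:
            mag = label
            break
    return float(g), mag


@dataclass(frozen=True)
class ComparisonResult:
    t: float
    p: float
    g: float
    magnitude: str
    alpha: float
    significant: bool
    degenerate: bool = False


def compare_groups(a, b, paired: bool = False,
                   n_comparisons: int = 1) -> ComparisonResult:
    """Two-sided Student's t-test plus Hedges' g.

    ``paired`` selects the paired test (equal lengths, shared subjects).
    ``n_comparisons`` > 1 applies a Bonferroni-adjusted alpha
    (0.05 / m, e.g. 0.025 for two planned tests); the comparison itself
    is unchanged.  Zero variance in the paired differences is flagged
    degenerate rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and len(a) != len(b):
        raise ValueError("paired comparison needs equal-length groups")
    if min(len(a), len(b)) < 2:
        raise ValueError("group comparisons need n >= 2")
    alpha = 0.05 / max(1, n_comparisons)
    g, mag = hedges_g(GroupSummary.from_scores(a), GroupSummary.from_scores(b))

    degenerate = False
    if paired:
        if np.std(a - b) == 0:
            degenerate = True
            t, p = (0.0, 1.0) if np.allclose(a, b) else (float("nan"), float("nan"))
        else:
            t, p = sstats.ttest_rel(a, b)
    else:
        if np.std(a) == 0 and np.std(b) == 0:
            degenerate = True
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (float("nan"), float("nan"))
        else:
            t, p = sstats.ttest_ind(a, b)
    sig = bool(np.isfinite(p) and p < alpha and not degenerate)
    return ComparisonResult(t=float(t), p=float(p), g=g, magnitude=mag,
                            alpha=alpha, significant=sig, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Stage reclassification
# ---------------------------------------------------------------------------

class ReclassScheme(str, Enum):
    """Simplified human staging schemes applied identically to both
    hypnograms before evaluation."""

    NONE = "none"
    N1_TO_WAKE = "n1w"
    N1_TO_N2 = "n1n2"
    W1NREM23 = "w1nrem23"   # N1 -> W; N2, N3 -> NREM
    NREM123 = "nrem123"     # N1, N2, N3 -> NREM


_RECLASS_MAPS: dict[ReclassScheme, dict[str, str]] = {
    ReclassScheme.N1_TO_WAKE: {"N1": "W"},
    ReclassScheme.N1_TO_N2: {"N1": "N2"},
    ReclassScheme.W1NREM23: {"N1": "W", "N2": "NREM", "N3": "NREM"},
    ReclassScheme.NREM123: {"N1": "NREM", "N2": "NREM", "N3": "NREM"},
}


def reclassify(hypnogram: Hypnogram, scheme: ReclassScheme) -> Hypnogram:
    """Remap stage labels per the scheme; ARTIFACT/UNDETERMINED pass through.

    The vocabulary shrinks accordingly (e.g. NREM123 yields W, NREM, REM).
    Requires the human five-stage vocabulary for any scheme but NONE.
    """
    scheme = ReclassScheme(scheme)
    if scheme is ReclassScheme.NONE:
        return hypnogram
    mapping = _RECLASS_MAPS[scheme]
    missing = [s for s in mapping if s not in hypnogram.vocabulary.labels]
    if missing:
        raise ValueError(
            f"scheme {scheme.value} undefined for vocabulary "
            f"{hypnogram.vocabulary.labels} (missing {missing})"
        )
    new_labels_order: list[str] = []
    for lab in hypnogram.vocabulary.labels:
        new = mapping.get(lab, lab)
        if new not in new_labels_order:
            new_labels_order.append(new)
    vocab = StageVocabulary(labels=tuple(new_labels_order),
                            aliases=dict(hypnogram.vocabulary.aliases))
    labels = np.array(
        [mapping.get(l, l) for l in hypnogram.labels], dtype=object
    )
    return Hypnogram(grid=hypnogram.grid, vocabulary=vocab, labels=labels)


# ---------------------------------------------------------------------------
# The full agreement report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-stage and overall agreement with full configuration provenance."""

    per_stage: dict[str, dict[str, float | str | int]]
    overall_f: float
    overall_rating: str
    macro_f: float
    n_evaluated: int
    n_epochs: int
    excluded_fraction: float
    provenance: dict = field(default_factory=dict)

    def stage_f(self, stage: str) -> float:
        return float(self.per_stage[stage]["f"])

    def to_frame(self) -> pd.DataFrame:
        """One row per stage plus an overall row."""
        rows = []
        for stage, d in self.per_stage.items():
            rows.append({"stage": stage, **d})
        rows.append({
            "stage": "overall", "sensitivity": np.nan, "precision": np.nan,
            "f": self.overall_f, "rating": self.overall_rating,
            "tp": sum(d["tp"] for d in self.per_stage.values()),
            "fp": sum(d["fp"] for d in self.per_stage.values()),
            "fn": sum(d["fn"] for d in self.per_stage.values()),
        })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "per_stage": self.per_stage,
            "overall_f": self.overall_f,
            "overall_rating": self.overall_rating,
            "macro_f": self.macro_f,
            "n_evaluated": self.n_evaluated,
            "n_epochs": self.n_epochs,
            "excluded_fraction": self.excluded_fraction,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"{'stage':<10}{'sens':>8}{'prec':>8}{'F':>8}  rating"]
        for stage, d in self.per_stage.items():
            lines.append(
                f"{stage:<10}{d['sensitivity']:>8.3f}{d['precision']:>8.3f}"
                f"{d['f']:>8.3f}  {d['rating']}"
            )
        lines.append(
            f"{'overall':<10}{'':>8}{'':>8}{self.overall_f:>8.3f}  {self.overall_rating}"
        )
        lines.append(
            f"evaluated {self.n_evaluated}/{self.n_epochs} epochs "
            f"(excluded fraction {self.excluded_fraction:.3f})"
        )
        return "\n".join(lines)


def evaluate(predicted: Hypnogram, reference: Hypnogram, *,
             exclude_transitions: bool = False,
             exclude: set[int] | frozenset[int] = frozenset(),
             scheme: ReclassScheme = ReclassScheme.NONE,
             transitions_from: str = "predicted",
             provenance: dict | None = None) -> AgreementReport:
    """Full agreement evaluation.

    With ``exclude_transitions``, the first and last epoch of each bout
    of the *predicted* hypnogram (after any reclassification) are
    removed from evaluation and the corresponding reference epochs are
    not analysed.  ``exclude`` adds caller-supplied indices, typically
    the training epochs.  ``scheme`` remaps both hypnograms first.
    """
    scheme = ReclassScheme(scheme)
    if scheme is not ReclassScheme.NONE:
        predicted = reclassify(predicted, scheme)
        reference = reclassify(reference, scheme)

    exclusions: set[int] = set(int(i) for i in exclude)
    if exclude_transitions:
        if transitions_from not in ("predicted", "reference"):
            raise ValueError("transitions_from must be 'predicted' or 'reference'")
        src = predicted if transitions_from == "predicted" else reference
        exclusions |= set(np.flatnonzero(tag_transition_epochs(src)).tolist())

    counts = confusion_counts(predicted, reference, exclusions)
    per_stage: dict[str, dict] = {}
    for stage, (tp, fp, fn) in counts.counts.items():
        s, p, f = f_measure(tp, fp, fn)
        per_stage[stage] = {
            "sensitivity": s, "precision": p, "f": f, "rating": rate_f(f),
            "tp": tp, "fp": fp, "fn": fn,
        }
    ov = overall_f(counts)
    prov = dict(provenance or {})
    prov.update({
        "scheme": scheme.value,
        "exclude_transitions": exclude_transitions,
        "transitions_from": transitions_from if exclude_transitions else None,
        "n_excluded_supplied": len(set(int(i) for i in exclude)),
    })
    return AgreementReport(
        per_stage=per_stage,
        overall_f=ov,
        overall_rating=rate_f(ov),
        macro_f=macro_f(counts),
        n_evaluated=counts.n_evaluated,
        n_epochs=reference.n_epochs,
        excluded_fraction=1.0 - counts.n_evaluated / reference.n_epochs,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Validation harnesses: training-size curves and channel ablation
# ---------------------------------------------------------------------------

def training_size_curve(stager, sizes, replicates: int = 3, seed: int = 0,
                        **evaluate_kwargs) -> pd.DataFrame:
    """Training-set-size to F-measure response curve.

    For each size and replicate a fresh seeded training set is drawn,
    the model refitted and the recording rescored; results are
    aggregated as mean +/- SEM per stage and overall.  ``stager`` is a
    fitted-or-not :class:`~somnoscore.model.SleepStager`; its features
    are extracted once and reused.

    Returns a tidy frame with columns
    ``size, stage, mean_f, sem_f, replicates``.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for size in sizes:
        scores: dict[str, list[float]] = {}
        for child in ss.spawn(replicates):
            rep_seed = int(child.generate_state(1)[0] % (2**31))
            res = stager.fit(size_per_stage=size, seed=rep_seed)
            report = res.evaluate(**evaluate_kwargs)
            for stage in report.per_stage:
                scores.setdefault(stage, []).append(report.stage_f(stage))
            scores.setdefault("overall", []).append(report.overall_f)
        for stage, vals in scores.items():
            arr = np.asarray(vals)
            sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            rows.append({"size": size, "stage": stage,
                         "mean_f": float(arr.mean()), "sem_f": sem,
                         "replicates": len(arr)})
    return pd.DataFrame(rows)


def channel_ablation(recording, reference: Hypnogram, presets,
                     size_per_stage: int | None = None, seed: int = 0,
                     rules=None, **evaluate_kwargs) -> dict[str, AgreementReport]:
    """Score the same recording under several input-channel configurations.

    The training epoch *indices* are sampled once and reused across
    presets, so only the features differ between runs.
    """
    from .features import ChannelConfig
    from .model import SleepStager
    from .training import TrainingConfig, sample_training_set

    cfg = TrainingConfig(size_per_stage=size_per_stage, seed=seed)
    shared_training = sample_training_set(reference, cfg, recording_id=recording.id)

    out: dict[str, AgreementReport] = {}
    for preset in presets:
        config = preset if isinstance(preset, ChannelConfig) else ChannelConfig.from_name(preset)
        stager = SleepStager(recording, reference,
                             epoch_length=reference.grid.epoch_length,
                             channels=config, rules=rules)
        res = stager.fit(training_set=shared_training, seed=seed)
        report = res.evaluate(**evaluate_kwargs)
        report.provenance["channels"] = config.name
        out[config.name] = report
    return out
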