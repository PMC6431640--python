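"""Bout segmentation and transition-epoch tagging.

A bout is a maximal run of consecutive epochs sharing one label.  A
transition epoch is the first or last epoch of a bout (a length-1 bout
is both, and is tagged once).  ARTIFACT/UNDETERMINED runs count as
segments of their own, so a stage run interrupted by an artifact is two
bouts: an artifact breaks the continuity of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Hypnogram

__all__ = ["BoutSegment", "segment_bouts", "tag_transition_epochs"]


@dataclass(frozen=True)
class BoutSegment:
    """A maximal run of one label: epochs ``start`` .. ``end`` inclusive."""

    stage: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _labels_of(hypnogram: Hypnogram | np.ndarray) -> np.ndarray:
    if isinstance(hypnogram, Hypnogram):
        return np.asarray(hypnogram.labels, dtype=object)
    return np.asarray(hypnogram, dtype=object)


def segment_bouts(hypnogram: Hypnogram | np.ndarray) -> list[BoutSegment]:
    """Run-length segmentation: consecutive bouts have different labels
    and together tile ``[0, n_epochs)`` exactly."""
    labels = _labels_of(hypnogram)
    if labels.size == 0:
        raise ValueError("cannot segment an empty hypnogram")
    change = np.flatnonzero(labels[1:] != labels[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [labels.size - 1]))
    return [BoutSegment(stage=labels[s], start=int(s), end=int(e))
            for s, e in zip(starts, ends)]


def tag_transition_epochs(hypnogram: Hypnogram | np.ndarray) -> np.ndarray:
    """Boolean mask marking the first and last epoch of every bout.

    Bouts at the recording edges are treated like interior bouts, so the
    tagged count is exactly ``sum(min(2, bout_length))`` over bouts.
    """
    labels = _labels_of(hypnogram)
    mask = np.zeros(labels.size, dtype=bool)
    for b in segment_bouts(labels):
        mask[b.start] = True
        mask[b.end] = True
    return mask
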