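"""Label-sequence processing: smoothing, metrics, transition matrices.

A recording's behavioral flow is summarized by its transition matrix:
consecutive repeats are collapsed into an occurrence vector (run-length
compression) and lag-1 pairs of that vector are counted into an NC x NC
table with a structurally zero diagonal.  Stabilized matrices are the
difference to the mean matrix of an experiment's control recordings, so
the control group averages to exactly zero — the common reference that
makes recordings comparable across experiments.

The alphabet (cluster-id set) is declared per analysis so matrices from
different recordings stay conformable even when some clusters are never
visited.  Labels may come from any segmentation method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


class AlphabetError(ValueError):
    pass


@dataclass
class LabelSequence:
    """Per-frame behavioral-cluster assignment over a fixed alphabet."""

    recording_id: str
    labels: np.ndarray
    alphabet: np.ndarray
    fps: float = 25.0
    frame_offset: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.alphabet = np.asarray(sorted(np.unique(self.alphabet)))
        if len(self.labels) == 0:
            raise ValueError("empty label sequence")
        if not np.isin(self.labels, self.alphabet).all():
            bad = np.setdiff1d(np.unique(self.labels), self.alphabet)
            raise AlphabetError(f"labels outside alphabet: {bad.tolist()}")

    def __len__(self) -> int:
        return len(self.labels)

    def _indices(self) -> np.ndarray:
        """Labels as positions in the sorted alphabet."""
        return np.searchsorted(self.alphabet, self.labels)


@dataclass
class TransitionMatrix:
    """NC x NC counts of run-to-run transitions of one recording."""

    counts: np.ndarray
    alphabet: np.ndarray
    recording_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.alphabet = np.asarray(self.alphabet)
        nc = len(self.alphabet)
        if self.counts.shape != (nc, nc):
            raise AlphabetError("counts shape does not match alphabet size")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("transition matrix diagonal must be zero")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class StabilizedTransitionMatrix:
    """A recording's matrix minus the mean matrix of the control group."""

    values: np.ndarray
    alphabet: np.ndarray
    recording_id: str = ""
    control_reference: list[str] = field(default_factory=list)


@dataclass
class ClusterMetrics:
    """Per-cluster usage: run counts, frames/seconds, run boundaries."""

    occurrences: dict  # cluster -> number of runs
    frames: dict  # cluster -> frames spent
    seconds: dict  # cluster -> seconds spent
    onsets: dict  # cluster -> list of run-start frame indices
    offsets: dict  # cluster -> list of run-end frame indices (inclusive)


def _runs(labels: np.ndarray):
    """Run-length encoding: (values, start indices, run lengths)."""
    change = np.r_[True, labels[1:] != labels[:-1]]
    starts = np.flatnonzero(change)
    values = labels[starts]
    lengths = np.diff(np.r_[starts, len(labels)])
    return values, starts, lengths


def smooth_labels(seq: LabelSequence, halfwidth: int = 5) -> LabelSequence:
    """Modal smoothing over a sliding window of ±halfwidth frames.

    Each frame is replaced by the most frequent label within its window;
    windows shrink at sequence edges.  Ties break to the smallest cluster
    id, deterministically.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if halfwidth == 0:
        return replace(seq, labels=seq.labels.copy())
    idx = seq._indices()
    n, k = len(idx), len(seq.alphabet)
    onehot_csum = np.zeros((n + 1, k), dtype=np.int32)
    onehot_csum[np.arange(1, n + 1), idx] = 1
    np.cumsum(onehot_csum, axis=0, out=onehot_csum)
    lo = np.clip(np.arange(n) - halfwidth, 0, n)
    hi = np.clip(np.arange(n) + halfwidth + 1, 0, n)
    counts = onehot_csum[hi] - onehot_csum[lo]
    smoothed = seq.alphabet[np.argmax(counts, axis=1)]  # argmax ties -> lowest
    return replace(seq, labels=smoothed)


def transition_matrix(seq: LabelSequence) -> TransitionMatrix:
    """Count run-to-run transitions of a label sequence.

    Repeating labels are collapsed first (occurrence vector); cell (a, b)
    counts how often a run of a is immediately followed by a run of b.
    The diagonal is structurally zero and the counts sum to
    (number of runs) - 1.
    """
    idx = seq._indices()
    values, _, _ = _runs(idx)
    nc = len(seq.alphabet)
    counts = np.zeros((nc, nc), dtype=np.int64)
    if len(values) > 1:
        np.add.at(counts, (values[:-1], values[1:]), 1)
    return TransitionMatrix(counts=counts, alphabet=seq.alphabet,
                            recording_id=seq.recording_id)


def compute_metrics(seq: LabelSequence) -> ClusterMetrics:
    """Per-cluster occurrences, time spent and run on/offsets."""
    values, starts, lengths = _runs(np.asarray(seq.labels))
    ends = starts + lengths - 1
    occurrences: dict = {}
    frames: dict = {}
    onsets: dict = {}
    offsets: dict = {}
    for c in seq.alphabet.tolist():
        sel = values == c
        occurrences[c] = int(sel.sum())
        frames[c] = int(lengths[sel].sum())
        onsets[c] = (starts[sel] + seq.frame_offset).tolist()
        offsets[c] = (ends[sel] + seq.frame_offset).tolist()
    seconds = {c: frames[c] / seq.fps for c in frames}
    return ClusterMetrics(occurrences=occurrences, frames=frames,
                          seconds=seconds, onsets=onsets, offsets=offsets)


def stabilize(T: TransitionMatrix,
              controls: list[TransitionMatrix]) -> StabilizedTransitionMatrix:
    """Subtract the elementwise mean of the control matrices from T."""
    if not controls:
        raise ValueError("controls must be nonempty")
    for c in controls:
        if not np.array_equal(c.alphabet, T.alphabet):
            raise AlphabetError("control matrix alphabet mismatch")
    mean = np.mean([c.counts for c in controls], axis=0)
    return StabilizedTransitionMatrix(
        values=T.counts - mean, alphabet=T.alphabet,
        recording_id=T.recording_id,
        control_reference=[c.recording_id for c in controls])


def cross_tabulate(seqA: LabelSequence, seqB: LabelSequence) -> np.ndarray:
    """Frame-by-frame contingency table between two labelings.

    Cell (a, b) counts frames labeled ``a`` by the source sequence and
    ``b`` by the target; rows index seqA's alphabet, columns seqB's.
    """
    if len(seqA) != len(seqB):
        raise ValueError(
            f"length mismatch: {len(seqA)} vs {len(seqB)} frames")
    ia, ib = seqA._indices(), seqB._indices()
    table = np.zeros((len(seqA.alphabet), len(seqB.alphabet)), dtype=np.int64)
    np.add.at(table, (ia, ib), 1)
    return table


def bin_labels(seq: LabelSequence, bin_length_s: float) -> list[LabelSequence]:
    """Split a sequence into contiguous time bins of ``bin_length_s`` seconds.

    Each bin is an independent sequence: metrics and transition matrices
    computed per bin never count a transition across a bin boundary.  A
    short trailing remainder forms a final (shorter) bin.
    """
    if bin_length_s <= 0:
        raise ValueError("bin length must be positive")
    per_bin = int(round(bin_length_s * seq.fps))
    if per_bin >= len(seq):
        warnings.warn("bin longer than recording; returning a single bin",
                      stacklevel=2)
        return [replace(seq, labels=seq.labels.copy())]
    out = []
    for b, start in enumerate(range(0, len(seq), per_bin)):
        chunk = seq.labels[start:start + per_bin]
        out.append(LabelSequence(
            recording_id=f"{seq.recording_id}#bin{b}", labels=chunk,
            alphabet=seq.alphabet, fps=seq.fps,
            frame_offset=seq.frame_offset + start))
    return out
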