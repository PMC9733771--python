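"""Backfitting microstate prototypes to EEG epochs.

Each sample is labeled with the prototype minimizing the polarity-
invariant global map dissimilarity

    GMD = || EEG(t)/GFP(t) - A_k/GFP(A_k) || / sqrt(C),

equivalent to maximizing the squared spatial correlation (for
average-referenced maps, GMD^2 = 2 (1 - corr)). Short segments are then
smoothed away, and per-state occurrence / duration / coverage, mean GFP,
mean spatial correlation, per-state GEV and the between-state transition
matrix are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MsfusionError
from .microstates import MicrostateModel, compute_gev, spatial_corr


@dataclass
class SegmentationResult:
    """Per-sample state labels for one epoch."""

    labels: np.ndarray
    fs: float
    k: int
    corr: np.ndarray | None = None       # (L, K) signed spatial correlations
    epoch_kind: str = ""
    min_segment_ms: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        if self.labels.size and not (0 <= self.labels.min()
                                     and self.labels.max() < self.k):
            raise MsfusionError("labels out of range")

    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start indices, labels) of maximal constant-label runs."""
        return _runs(self.labels)


def _runs(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if labels.size == 0:
        return np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    return starts, labels[starts]


@dataclass
class MicrostateStats:
    """Per-state temporal statistics of a set of segmentations."""

    table: pd.DataFrame  # one row per state

    @property
    def coverage(self) -> np.ndarray:
        return self.table["coverage"].to_numpy()

    @property
    def duration_ms(self) -> np.ndarray:
        return self.table["duration_ms"].to_numpy()

    @property
    def occurrence(self) -> np.ndarray:
        return self.table["occurrence"].to_numpy()


@dataclass
class TransitionMatrix:
    """First-order transition probabilities between distinct segments."""

    probs: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.probs.shape != self.counts.shape:
            raise MsfusionError("shape mismatch")


# ---------------------------------------------------------------------------

def topo_similarity(map_a: np.ndarray, map_b: np.ndarray
                    ) -> tuple[float, float]:
    """Spatial correlation and GMD between two maps.

    Maps are average-referenced and GFP-normalized; for such maps
    gmd^2 = 2 (1 - corr) holds exactly.
    """
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise MsfusionError("channel count mismatch")
    c = a.size
    a = a - a.mean()
    b = b - b.mean()
    gfp_a = a.std(ddof=0)
    gfp_b = b.std(ddof=0)
    if gfp_a == 0 or gfp_b == 0:
        raise MsfusionError("zero-GFP map")
    gmd = float(np.linalg.norm(a / gfp_a - b / gfp_b) / np.sqrt(c))
    corr = float((a / (gfp_a * np.sqrt(c))) @ (b / (gfp_b * np.sqrt(c))))
    return corr, gmd


def backfit_labels(epoch: np.ndarray, model: MicrostateModel,
                   epoch_kind: str = "", fs: float = 250.0
                   ) -> SegmentationResult:
    """Label every sample with the most similar prototype.

    ``epoch`` is (C, L). Assignment maximizes corr^2 (minimizes the
    polarity-invariant GMD); exact ties break to the lowest state index.
    """
    epoch = np.asarray(epoch, float)
    if epoch.shape[0] != model.prototypes.shape[1]:
        raise MsfusionError("channel count does not match the model")
    corr = spatial_corr(epoch, model.prototypes)   # (L, K)
    labels = np.argmax(corr ** 2, axis=1)          # argmax -> first max
    return SegmentationResult(labels=labels, fs=fs, k=model.k, corr=corr,
                              epoch_kind=epoch_kind)


def temporal_smooth(seg: SegmentationResult, min_segment_ms: float = 30.0
                    ) -> SegmentationResult:
    """Remove segments shorter than ``min_segment_ms``.

    The shortest sub-threshold segment is dissolved into its neighbours:
    a split point inside the segment is chosen maximizing the summed
    corr^2 of reassigning the left part to the left neighbour's label and
    the right part to the right's. The segment count strictly decreases
    each step, so the procedure terminates with all segments at or above
    threshold (or a single segment).
    """
    min_len = int(round(min_segment_ms / 1000.0 * seg.fs))
    n = seg.labels.size
    if min_len > n:
        raise MsfusionError("min_segment_ms longer than the epoch")
    if seg.corr is None:
        raise MsfusionError("smoothing needs per-sample correlations")
    labels = seg.labels.copy()
    corr2 = seg.corr ** 2
    while True:
        starts, seg_labels = _runs(labels)
        if starts.size <= 1:
            break
        ends = np.append(starts[1:], n)
        lengths = ends - starts
        short = np.flatnonzero(lengths < min_len)
        if short.size == 0:
            break
        i = short[np.argmin(lengths[short])]
        s, e = starts[i], ends[i]
        left = seg_labels[i - 1] if i > 0 else None
        right = seg_labels[i + 1] if i < seg_labels.size - 1 else None
        if left is None:
            labels[s:e] = right
        elif right is None:
            labels[s:e] = left
        else:
            span = np.arange(s, e + 1)
            left_cum = np.concatenate([[0.0], np.cumsum(corr2[s:e, left])])
            right_cum = np.concatenate(
                [[0.0], np.cumsum(corr2[s:e, right][::-1])])[::-1]
            split = span[np.argmax(left_cum + right_cum)]
            labels[s:split] = left
            labels[split:e] = right
    return SegmentationResult(labels=labels, fs=seg.fs, k=seg.k,
                              corr=seg.corr, epoch_kind=seg.epoch_kind,
                              min_segment_ms=min_segment_ms)


def segment_stats(segs, epochs=None, model: MicrostateModel | None = None
                  ) -> MicrostateStats:
    """Pooled per-state statistics over one or more segmentations.

    occurrence = segments per second, duration = mean segment length (ms),
    coverage = fraction of labeled samples. When epochs and a model are
    given, mean GFP, mean |spatial correlation| and the per-state GEV
    partition are included. Absent states carry occurrence/duration/
    coverage 0 and NaN for the map-based metrics.
    """
    if isinstance(segs, SegmentationResult):
        segs = [segs]
    if epochs is not None and not isinstance(epochs, (list, tuple)):
        epochs = [epochs]
    k = segs[0].k
    n_total = sum(s.labels.size for s in segs)
    total_s = sum(s.labels.size / s.fs for s in segs)
    seg_counts = np.zeros(k)
    seg_samples = np.zeros(k)
    sample_counts = np.zeros(k)
    for s in segs:
        starts, labs = _runs(s.labels)
        ends = np.append(starts[1:], s.labels.size)
        for lab, st, en in zip(labs, starts, ends):
            seg_counts[lab] += 1
            seg_samples[lab] += (en - st) / s.fs
        sample_counts += np.bincount(s.labels, minlength=k)

    present = seg_counts > 0
    occurrence = seg_counts / total_s
    duration_ms = np.where(present, seg_samples / np.maximum(seg_counts, 1)
                           * 1000.0, 0.0)
    coverage = sample_counts / n_total

    mean_gfp = np.full(k, np.nan)
    mean_corr = np.full(k, np.nan)
    gev_per_state = np.full(k, np.nan)
    if epochs is not None and model is not None:
        all_maps = np.concatenate([np.asarray(e, float) for e in epochs],
                                  axis=1)
        all_labels = np.concatenate([s.labels for s in segs])
        gfp = all_maps.std(axis=0, ddof=0)
        corr = spatial_corr(all_maps, model.prototypes)
        corr_assigned = np.abs(corr[np.arange(all_labels.size), all_labels])
        for j in range(k):
            mask = all_labels == j
            if mask.any():
                mean_gfp[j] = gfp[mask].mean()
                mean_corr[j] = corr_assigned[mask].mean()
        _, gev_states = compute_gev(all_maps, all_labels, model.prototypes)
        gev_per_state = np.where(present, gev_states, np.nan)

    table = pd.DataFrame({
        "state": np.arange(1, k + 1),
        "present": present,
        "occurrence": occurrence,
        "duration_ms": duration_ms,
        "coverage": coverage,
        "mean_gfp": mean_gfp,
        "mean_spatial_corr": mean_corr,
        "gev": gev_per_state,
    })
    return MicrostateStats(table=table)


def transition_matrix(segs) -> TransitionMatrix:
    """Pool transitions between consecutive distinct segments.

    Rows are 'from', columns 'to'; the diagonal is structurally zero and
    each row with outgoing transitions is normalized to sum to 1.
    """
    if isinstance(segs, SegmentationResult):
        segs = [segs]
    k = segs[0].k
    counts = np.zeros((k, k))
    for s in segs:
        _, labs = _runs(s.labels)
        for a, b in zip(labs[:-1], labs[1:]):
            counts[a, b] += 1
    if counts.sum() == 0:
        warnings.warn("no transitions observed; returning a zero matrix")
        return TransitionMatrix(probs=np.zeros((k, k)), counts=counts)
    row_sums = counts.sum(axis=1, keepdims=True)
    probs = np.divide(counts, row_sums, out=np.zeros_like(counts),
                      where=row_sums > 0)
    return TransitionMatrix(probs=probs, counts=counts)
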