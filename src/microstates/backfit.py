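"""Back-fitting and temporal microstate parameters.

Every sample of the epoched recording is assigned to the microstate map
with the highest absolute spatial (Pearson) correlation — polarity is
ignored, as is standard for spontaneous EEG.  From the resulting label
series, per-class mean duration (ms), occurrence (/s) and time coverage
(%) and the 12 jointly-normalized ordered transition percentages are
computed.  Runs never span epoch boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochedRecording
from .templates import CLASS_LABELS

__all__ = [
    "LabelSeries",
    "backfit",
    "smooth_labels",
    "compute_parameters",
    "compute_transitions",
    "TRANSITION_PAIRS",
]

TRANSITION_PAIRS: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(4) if i != j
)


@dataclass(frozen=True)
class LabelSeries:
    """Per-sample class indices over concatenated epochs."""

    labels: np.ndarray = field(repr=False)
    epoch_boundaries: np.ndarray = field(repr=False)  # includes 0 and n
    fs: float = 500.0
    n_classes: int = 4

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        b = np.asarray(self.epoch_boundaries, dtype=np.int64)
        if lab.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if lab.size and (lab.min() < 0 or lab.max() >= self.n_classes):
            raise ValueError("labels out of class range")
        if b.ndim != 1 or b[0] != 0 or b[-1] != lab.size or np.any(np.diff(b) <= 0):
            raise ValueError("epoch_boundaries must be sorted, spanning the series")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "epoch_boundaries", b)

    def epoch_slices(self) -> list[slice]:
        b = self.epoch_boundaries
        return [slice(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]

    def runs(self) -> list[tuple[int, int]]:
        """(class, length) run-length encoding, restarted at each epoch."""
        out: list[tuple[int, int]] = []
        for sl in self.epoch_slices():
            seg = self.labels[sl]
            if seg.size == 0:
                continue
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [seg.size]])
            out.extend((int(seg[s]), int(e - s)) for s, e in zip(starts, ends))
        return out


def _correlation_labels(maps: np.ndarray, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """argmax_k |corr| labels and the full |corr| matrix for samples (C, T)."""
    v = data - data.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(v, axis=0)
    m = maps - maps.mean(axis=1, keepdims=True)
    m = m / np.linalg.norm(m, axis=1, keepdims=True)
    corr = np.abs(m @ v)  # (k, T), unnormalized by sample norms
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(norms > 0, corr / norms, 0.0)
    return np.argmax(corr, axis=0), corr


def _absorb_singletons(
    labels: np.ndarray, boundaries: np.ndarray, corr: np.ndarray
) -> np.ndarray:
    """Merge single-sample runs into the flanking class with higher |corr|.

    One-sample microstates are below the temporal resolution of the
    analysis (the generator itself refuses dynamics finer than two
    samples), so they are treated as assignment noise, not as segments.
    Iterates until no singleton remains (cascades are bounded).
    """
    labels = labels.copy()
    for lo, hi in zip(boundaries[:-1], boundaries[1:]):
        seg = labels[lo:hi]
        for _ in range(int(hi - lo)):
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [seg.size]])
            singles = np.flatnonzero(ends - starts == 1)
            if singles.size == 0 or len(starts) == 1:
                break
            changed = False
            for r in singles:
                cand = []
                if r > 0:
                    cand.append(int(seg[starts[r - 1]]))
                if r < len(starts) - 1:
                    cand.append(int(seg[starts[r + 1]]))
                t = int(starts[r])
                new = max(cand, key=lambda k: (corr[k, lo + t], -k))
                if new != seg[t]:
                    seg[t] = new
                    changed = True
            if not changed:
                break
    return labels


def backfit(epochs: EpochedRecording, maps: np.ndarray) -> LabelSeries:
    """Label every sample by max |spatial correlation| with the maps.

    Zero-variance samples inherit the previous sample's label (leading ones
    get class 0); ties resolve to the lowest class index via argmax.
    Single-sample runs are then absorbed into the better-correlated
    flanking class — they are below the two-sample resolvability floor of
    the segment dynamics and arise only where the instantaneous field is
    noise-dominated (GFP troughs).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[1] != epochs.n_channels:
        raise ValueError("map channel count does not match epochs")
    data = epochs.concatenated()
    labels, corr = _correlation_labels(maps, data)
    flat = np.linalg.norm(data - data.mean(axis=0, keepdims=True), axis=0) == 0
    if np.any(flat):
        labels = labels.copy()
        prev = 0
        for t in range(labels.size):
            if flat[t]:
                labels[t] = prev
            else:
                prev = labels[t]
    boundaries = epochs.epoch_boundaries()
    labels = _absorb_singletons(labels, boundaries, corr)
    return LabelSeries(labels, boundaries, fs=epochs.fs, n_classes=maps.shape[0])


def smooth_labels(
    series: LabelSeries,
    min_duration_ms: float,
    epochs: EpochedRecording | None = None,
    maps: np.ndarray | None = None,
) -> LabelSeries:
    """Absorb runs shorter than ``min_duration_ms``.

    Each sample of an offending run is reassigned to whichever flanking
    run's class has the higher |correlation| with that sample (falling back
    to the longer flank when no data/maps are supplied); repeats until no
    run violates the threshold.  A zero threshold is the identity.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration_ms must be >= 0")
    min_samples = int(np.ceil(min_duration_ms * series.fs / 1000.0))
    max_epoch = int(np.max(np.diff(series.epoch_boundaries)))
    if min_samples > max_epoch:
        raise ValueError("smoothing threshold exceeds the epoch length")
    if min_samples <= 1:
        return series

    corr = None
    if epochs is not None and maps is not None:
        _, corr = _correlation_labels(np.asarray(maps, float), epochs.concatenated())

    labels = series.labels.copy()
    for sl in series.epoch_slices():
        seg = labels[sl]
        offset = sl.start
        for _ in range(seg.size):  # bounded number of absorption passes
            change = np.flatnonzero(np.diff(seg)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [seg.size]])
            lengths = ends - starts
            if len(starts) <= 1:
                break
            short = np.flatnonzero(lengths < min_samples)
            if short.size == 0:
                break
            # absorb the shortest offending run first (ties: earliest)
            r = int(short[np.argmin(lengths[short])])
            cand = []
            if r > 0:
                cand.append(int(seg[starts[r - 1]]))
            if r < len(starts) - 1:
                cand.append(int(seg[starts[r + 1]]))
            for t in range(starts[r], ends[r]):
                if corr is not None:
                    pick = max(cand, key=lambda k: corr[k, offset + t])
                else:
                    flank_len = {
                        k: (lengths[r - 1] if r > 0 and seg[starts[r - 1]] == k else 0)
                        + (
                            lengths[r + 1]
                            if r < len(starts) - 1 and seg[starts[r + 1]] == k
                            else 0
                        )
                        for k in cand
                    }
                    pick = max(cand, key=lambda k: (flank_len[k], -k))
                seg[t] = pick
    return LabelSeries(labels, series.epoch_boundaries, fs=series.fs,
                       n_classes=series.n_classes)


def compute_parameters(
    series: LabelSeries, exclude_truncated: bool = False
) -> pd.DataFrame:
    """Mean duration (ms), occurrence (/s) and coverage (%) per class.

    With ``exclude_truncated`` the runs touching an epoch boundary are
    dropped from duration and occurrence (coverage always uses all
    samples).  With the default (all runs included) the identity
    occurrence * duration(s) = coverage/100 holds exactly.
    """
    if series.labels.size == 0:
        raise ValueError("empty label series")
    k = series.n_classes
    total_samples = series.labels.size
    total_seconds = total_samples / series.fs

    run_lengths: dict[int, list[int]] = {c: [] for c in range(k)}
    for sl in series.epoch_slices():
        seg = series.labels[sl]
        change = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [seg.size]])
        for i, (s, e) in enumerate(zip(starts, ends)):
            if exclude_truncated and (i == 0 or i == len(starts) - 1):
                continue
            run_lengths[int(seg[s])].append(int(e - s))

    rows = []
    for c in range(k):
        n_samples_c = int(np.sum(series.labels == c))
        runs = run_lengths[c]
        rows.append(
            {
                "class": CLASS_LABELS[c] if k == 4 else str(c),
                "duration_ms": (
                    float(np.mean(runs)) * 1000.0 / series.fs if runs else np.nan
                ),
                "occurrence_hz": len(runs) / total_seconds,
                "coverage_pct": 100.0 * n_samples_c / total_samples,
            }
        )
    return pd.DataFrame(rows)


def compute_transitions(series: LabelSeries) -> pd.DataFrame:
    """Jointly-normalized ordered transition percentages (12 cells sum to 100).

    Transitions are counted between consecutive runs within an epoch;
    nothing is counted across epoch boundaries.
    """
    k = series.n_classes
    counts = np.zeros((k, k))
    for sl in series.epoch_slices():
        seg = series.labels[sl]
        change = np.flatnonzero(np.diff(seg))
        np.add.at(counts, (seg[change], seg[change + 1]), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no transitions in the label series")
    pct = 100.0 * counts / total
    rows = [
        {
            "transition": f"{CLASS_LABELS[i]}->{CLASS_LABELS[j]}",
            "from": CLASS_LABELS[i],
            "to": CLASS_LABELS[j],
            "percent": float(pct[i, j]),
        }
        for i, j in TRANSITION_PAIRS
    ]
    return pd.DataFrame(rows)
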