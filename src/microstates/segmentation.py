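"""GFP-peak extraction, polarity-invariant modified K-means, GEV, group-map
aggregation, canonical A-D labeling, and TANOVA.

The modified K-means treats a topography and its sign flip as identical:
samples are assigned by maximal squared spatial (Pearson) correlation and
each cluster map is updated to the dominant eigenvector of the outer-product
sum of its members, so cluster centroids are defined only up to sign.  The
objective maximized is the global explained variance (GEV), the GFP-weighted
fraction of topographic variance captured by the assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from .preprocess import EpochedRecording
from .templates import CLASS_LABELS, TemplateSet

__all__ = [
    "GFPSeries",
    "PeakTopographies",
    "SegmentationResult",
    "TanovaResult",
    "compute_gfp",
    "find_gfp_peaks",
    "modified_kmeans",
    "compute_gev",
    "aggregate_group_maps",
    "label_maps",
    "tanova",
]


@dataclass(frozen=True)
class GFPSeries:
    """Global field power (spatial SD across channels) per sample."""

    values: np.ndarray = field(repr=False)
    fs: float = 500.0
    epoch_boundaries: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("GFP must be a finite non-negative 1-D series")
        object.__setattr__(self, "values", v)
        if self.epoch_boundaries is not None:
            object.__setattr__(
                self, "epoch_boundaries", np.asarray(self.epoch_boundaries, np.int64)
            )


@dataclass(frozen=True)
class PeakTopographies:
    """Average-referenced topographies at GFP peaks."""

    topographies: np.ndarray = field(repr=False)  # (P, C)
    peak_gfp: np.ndarray = field(repr=False)
    peak_indices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        topo = np.asarray(self.topographies, dtype=float)
        gfp = np.asarray(self.peak_gfp, dtype=float)
        idx = np.asarray(self.peak_indices, dtype=np.int64)
        if topo.ndim != 2 or gfp.shape != (topo.shape[0],) or idx.shape != gfp.shape:
            raise ValueError("inconsistent peak arrays")
        if np.any(gfp <= 0):
            raise ValueError("peak GFP must be positive")
        if np.max(np.abs(topo.mean(axis=1))) > 1e-8 * max(1.0, np.abs(topo).max()):
            raise ValueError("peak topographies must be average-referenced")
        object.__setattr__(self, "topographies", topo)
        object.__setattr__(self, "peak_gfp", gfp)
        object.__setattr__(self, "peak_indices", idx)

    @property
    def n_peaks(self) -> int:
        return self.topographies.shape[0]


@dataclass(frozen=True)
class SegmentationResult:
    """Unit-norm cluster maps, per-peak labels and the achieved GEV."""

    maps: np.ndarray = field(repr=False)  # (k, C)
    peak_labels: np.ndarray = field(repr=False)
    gev: float = 0.0
    label_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if not (0.0 <= self.gev <= 1.0 + 1e-12):
            raise ValueError("GEV must lie in [0, 1]")
        if np.max(np.abs(np.linalg.norm(maps, axis=1) - 1.0)) > 1e-6:
            raise ValueError("maps must be unit-norm")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "peak_labels", np.asarray(self.peak_labels, np.int64))


@dataclass(frozen=True)
class TanovaResult:
    """Randomization test on topographies: one effect, one p-value."""

    effect: str
    observed_stat: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """Mean-remove and L2-normalize rows (spatial-correlation coordinates)."""
    x = x - x.mean(axis=1, keepdims=True)
    n = np.linalg.norm(x, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return x / n


def compute_gfp(epochs: EpochedRecording) -> GFPSeries:
    """GFP(t) = spatial standard deviation across channels, per sample."""
    data = epochs.concatenated()
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite input")
    gfp = data.std(axis=0)
    return GFPSeries(gfp, fs=epochs.fs, epoch_boundaries=epochs.epoch_boundaries())


def find_gfp_peaks(
    gfp: GFPSeries, epochs: EpochedRecording, min_separation_ms: float = 10.0
) -> PeakTopographies:
    """Strict local GFP maxima within each epoch, >= 10 ms apart.

    Candidates are strict interior maxima; when two candidates fall closer
    than the separation, the higher one wins (earlier on ties).  Raises if
    no peak is found anywhere.
    """
    if gfp.epoch_boundaries is None:
        raise ValueError("GFP series lacks epoch boundaries")
    x = gfp.values
    min_gap = max(1, int(round(min_separation_ms * gfp.fs / 1000.0)))
    keep: list[int] = []
    for lo, hi in zip(gfp.epoch_boundaries[:-1], gfp.epoch_boundaries[1:]):
        seg = x[lo:hi]
        if seg.size < 3:
            raise ValueError("epochs must contain at least 3 samples")
        cand = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] > seg[2:])) + 1
        if cand.size == 0:
            continue
        order = cand[np.lexsort((cand, -seg[cand]))]  # high GFP first, then early
        chosen: list[int] = []
        for c in order:
            if all(abs(c - o) >= min_gap for o in chosen):
                chosen.append(int(c))
        keep.extend(int(lo) + c for c in sorted(chosen))
    if not keep:
        raise ValueError("no GFP peaks found")
    idx = np.asarray(sorted(keep), dtype=np.int64)
    data = epochs.concatenated()
    return PeakTopographies(data[:, idx].T, x[idx], idx)


def compute_gev(
    peaks: PeakTopographies, maps: np.ndarray, labels: np.ndarray
) -> float:
    """Global explained variance of an assignment.

    GEV = sum_p (GFP_p * r(v_p, m_{l_p}))^2 / sum_p GFP_p^2 with r the
    spatial Pearson correlation; polarity-invariant since r enters squared.
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != peaks.n_peaks or maps.shape[1] != peaks.topographies.shape[1]:
        raise ValueError("inconsistent dimensions")
    denom = float(np.sum(peaks.peak_gfp**2))
    if denom == 0:
        raise ValueError("zero total GFP")
    v = _unit_rows(peaks.topographies)
    m = _unit_rows(maps)
    r = np.einsum("pc,pc->p", v, m[labels])
    return float(np.sum((peaks.peak_gfp * r) ** 2) / denom)


def _dominant_eigvec(members: np.ndarray) -> np.ndarray:
    """Dominant right-singular vector of a members-by-channels matrix."""
    # polarity-blind centroid: maximizes sum of squared projections
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    v = vt[0]
    # deterministic sign: largest-|.| component positive
    v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
    return v / np.linalg.norm(v)


def modified_kmeans(
    peaks: PeakTopographies,
    k: int = 4,
    restarts: int = 50,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | np.random.Generator = 0,
    return_history: bool = False,
) -> SegmentationResult | tuple[SegmentationResult, list[np.ndarray]]:
    """Polarity-invariant modified K-means on GFP-peak topographies.

    Assignment: maximal squared spatial correlation with the k maps.
    Update: dominant eigenvector of the members' outer-product sum.
    Objective: GEV; iterations stop when its relative change drops below
    ``tol`` (or after ``max_iter``); the best of ``restarts`` random
    initializations (k distinct peak topographies) is returned.  With
    ``return_history`` the per-iteration GEV trajectory of every restart
    is returned as well.
    """
    P = peaks.n_peaks
    if k > P:
        raise ValueError("more clusters than peak topographies")
    if np.any(np.linalg.norm(peaks.topographies, axis=1) == 0):
        raise ValueError("all-zero topography among peaks")
    v_unit = _unit_rows(peaks.topographies)
    # raw (mean-removed, unnormalized) rows: the eigenvector update on these
    # maximizes sum((v.m)^2) = C * sum((GFP * r)^2), i.e. the GEV numerator,
    # which makes the iteration monotone in GEV
    v_raw = peaks.topographies - peaks.topographies.mean(axis=1, keepdims=True)
    gfp2 = peaks.peak_gfp**2
    denom = float(gfp2.sum())
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    histories: list[np.ndarray] = []
    for _ in range(max(1, restarts)):
        maps = _unit_rows(peaks.topographies[rng.choice(P, size=k, replace=False)])
        prev_gev = -np.inf
        history: list[float] = []
        for _it in range(max_iter):
            corr = v_unit @ maps.T  # (P, k)
            labels = np.argmax(corr**2, axis=1)
            # re-seed empty clusters with the worst-explained topography
            for c in range(k):
                if not np.any(labels == c):
                    worst = int(np.argmin(np.max(corr**2, axis=1)))
                    labels[worst] = c
            new_maps = np.empty_like(maps)
            for c in range(k):
                new_maps[c] = _dominant_eigvec(v_raw[labels == c])
            maps = new_maps
            corr = v_unit @ maps.T
            labels = np.argmax(corr**2, axis=1)
            gev = float(
                np.sum(gfp2 * np.take_along_axis(corr, labels[:, None], 1)[:, 0] ** 2)
                / denom
            )
            history.append(gev)
            if gev - prev_gev <= tol * max(prev_gev, tol):
                prev_gev = gev
                break
            prev_gev = gev
        histories.append(np.asarray(history))
        if best is None or prev_gev > best[0]:
            best = (prev_gev, maps, labels)
    gev, maps, labels = best
    result = SegmentationResult(
        maps=maps, peak_labels=labels, gev=min(max(gev, 0.0), 1.0)
    )
    if return_history:
        return result, histories
    return result


def aggregate_group_maps(
    subject_results: list[SegmentationResult] | list[np.ndarray],
    seed: int | np.random.Generator = 0,
    max_iter: int = 100,
) -> np.ndarray:
    """Across-subject alignment of per-subject maps into group maps.

    Iteratively permutes each subject's k maps to maximize the summed
    squared spatial correlation with the running group maps (polarity
    ignored), recomputing every slot's group map as the dominant
    eigenvector across subjects, until the common-variance criterion stops
    improving.  The alternating search is restarted from every subject's
    own maps (plus a few seeded random reference permutations) and the
    best-criterion solution kept, since a single initialization can stall
    in a local alignment optimum.  Returns unit-norm (k, C) group maps.
    """
    arrs = [
        np.asarray(s.maps if isinstance(s, SegmentationResult) else s, dtype=float)
        for s in subject_results
    ]
    if len(arrs) < 2:
        raise ValueError("need at least 2 subjects")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("subjects must share channel and map counts")
    k = shape[0]
    subj = np.stack([_unit_rows(a) for a in arrs])  # (N, k, C)
    n = subj.shape[0]
    perms = list(permutations(range(k)))
    rng = np.random.default_rng(seed)

    def refine(group: np.ndarray) -> tuple[float, np.ndarray]:
        crit_prev = -np.inf
        for _ in range(max_iter):
            corr2 = np.einsum("nkc,mc->nkm", subj, group) ** 2  # (N, subj-map, slot)
            assign = []
            for i in range(n):
                scores = [sum(corr2[i, p[s], s] for s in range(k)) for p in perms]
                assign.append(perms[int(np.argmax(scores))])
            aligned = np.stack([subj[i, list(p), :] for i, p in enumerate(assign)])
            group = np.stack([_dominant_eigvec(aligned[:, s, :]) for s in range(k)])
            crit = float(np.mean(np.einsum("nsc,sc->ns", aligned, group) ** 2))
            if crit - crit_prev <= 1e-12:
                return crit, group
            crit_prev = crit
        return crit_prev, group

    starts = [subj[i] for i in range(n)]
    for _ in range(8):
        starts.append(subj[rng.integers(n)][rng.permutation(k)])
    best_crit, best_group = -np.inf, None
    for start in starts:
        crit, group = refine(start)
        if crit > best_crit + 1e-15:
            best_crit, best_group = crit, group
    return best_group


def label_maps(
    maps: np.ndarray, canonical: TemplateSet
) -> tuple[tuple[str, ...], np.ndarray]:
    """Assign canonical A-D labels to maps by total |spatial correlation|.

    Searches all k! assignments for the one maximizing the summed absolute
    correlation with the canonical templates (ties: lexicographically
    smallest permutation).  Returns the labels in input-map order plus the
    maps reordered A-D and sign-aligned to the canonical templates.
    """
    maps = np.asarray(maps, dtype=float)
    k = canonical.k
    if maps.shape != canonical.maps.shape:
        raise ValueError("maps and canonical templates differ in shape")
    corr = _unit_rows(maps) @ _unit_rows(canonical.maps).T  # (map, template)
    best_perm = None
    best_score = -np.inf
    for p in permutations(range(k)):  # p[m] = template slot of map m
        score = sum(abs(corr[m, p[m]]) for m in range(k))
        if score > best_score + 1e-12:
            best_score, best_perm = score, p
    labels = tuple(canonical.labels[best_perm[m]] for m in range(k))
    ordered = np.empty_like(maps)
    for m in range(k):
        sign = 1.0 if corr[m, best_perm[m]] >= 0 else -1.0
        row = maps[m] * sign
        ordered[best_perm[m]] = row / np.linalg.norm(row)
    return labels, ordered


def _tanova_stats(subj_class_maps: np.ndarray, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group-effect and interaction statistics for many group assignments.

    ``subj_class_maps``: (N, k, C) L2-normalized maps; ``membership``:
    (n_assignments, N) boolean, True = group 1.  Returns two
    (n_assignments,) arrays of dissimilarity statistics (GFP of difference
    maps; mean over classes for the interaction).
    """
    n, k, c = subj_class_maps.shape
    m_subj = subj_class_maps.mean(axis=1)  # (N, C) subject-mean maps
    flat = subj_class_maps.reshape(n, k * c)
    z = membership.astype(float)
    n1 = z.sum(axis=1, keepdims=True)
    n2 = (1.0 - z).sum(axis=1, keepdims=True)
    g1_subj = z @ m_subj / n1
    g2_subj = (1.0 - z) @ m_subj / n2
    diff_subj = g1_subj - g2_subj  # (n_assignments, C)
    group_stat = diff_subj.std(axis=1)  # GFP of the grand-difference map

    g1_cls = (z @ flat / n1).reshape(-1, k, c)
    g2_cls = ((1.0 - z) @ flat / n2).reshape(-1, k, c)
    d = (g1_cls - g1_subj[:, None, :]) - (g2_cls - g2_subj[:, None, :])
    inter_stat = d.std(axis=2).mean(axis=1)
    return group_stat, inter_stat


def tanova(
    group1_maps: np.ndarray,
    group2_maps: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> list[TanovaResult]:
    """Topographic randomization test between two groups of labeled maps.

    Each subject's per-class maps (already labeled/sign-aligned) are
    L2-normalized; the group main effect is the GFP of the difference of
    the groups' grand-mean (class-averaged) maps, the interaction the mean
    over classes of the GFP of class-wise group differences after removing
    the group main effect.  The null reassigns subjects to groups.
    """
    g1 = np.asarray(group1_maps, dtype=float)
    g2 = np.asarray(group2_maps, dtype=float)
    if g1.ndim != 3 or g2.ndim != 3 or g1.shape[1:] != g2.shape[1:]:
        raise ValueError("groups must be (n_subjects, k, C) with matching (k, C)")
    if min(g1.shape[0], g2.shape[0]) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    allm = np.concatenate([g1, g2])
    allm = allm / np.linalg.norm(allm, axis=2, keepdims=True)
    n1, n = g1.shape[0], allm.shape[0]

    obs_membership = np.zeros((1, n), dtype=bool)
    obs_membership[0, :n1] = True
    obs_group, obs_inter = _tanova_stats(allm, obs_membership)

    rng = np.random.default_rng(seed)
    perm_membership = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        perm_membership[i, rng.choice(n, size=n1, replace=False)] = True
    perm_group, perm_inter = _tanova_stats(allm, perm_membership)

    out = []
    for effect, obs, perm in (
        ("group", float(obs_group[0]), perm_group),
        ("interaction", float(obs_inter[0]), perm_inter),
    ):
        p = (1.0 + np.sum(perm >= obs - 1e-15)) / (1.0 + n_perm)
        out.append(TanovaResult(effect=effect, observed_stat=obs, p=float(p), n_perm=n_perm))
    return out
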