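"""End-to-end drivers: recording -> maps -> labels -> parameter tables.

Per subject, the pipeline band-passes 2-20 Hz, selects the first N 2-s
average-referenced epochs, extracts GFP-peak topographies and clusters them
with the polarity-invariant modified K-means (k=4).  Subject maps are
aggregated into group maps (per group), labeled A-D against the canonical
templates, and back-fitted onto each subject's broadband epochs to yield
duration / occurrence / coverage and the 12 transition percentages.

Back-fitting deliberately uses the epochs *before* the 2-20 Hz filter: an
18 Hz-wide filter has an impulse response of the same order as a microstate
segment (60-120 ms), so narrow-band filtering blurs segment boundaries and
fragments the label series at GFP troughs; the narrow band is used only
where it belongs, to select clean high-SNR topographies for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backfit import backfit, compute_parameters, compute_transitions, smooth_labels
from .preprocess import epoch_and_reference, filter_recording, resample_recording
from .segmentation import (
    SegmentationResult,
    aggregate_group_maps,
    compute_gfp,
    find_gfp_peaks,
    label_maps,
    modified_kmeans,
)
from .synth import SyntheticRecording
from .templates import TemplateSet

__all__ = [
    "PipelineConfig",
    "segment_subject",
    "analyze_group",
    "analyze_group_lazy",
    "analyze_cohort",
]


@dataclass(frozen=True)
class PipelineConfig:
    band: tuple[float, float] = (2.0, 20.0)
    epoch_length_s: float = 2.0
    n_epochs: int = 60
    k: int = 4
    restarts: int = 50
    max_iter: int = 500
    tol: float = 1e-8
    min_peak_separation_ms: float = 10.0
    smoothing_ms: float = 0.0  # plugin-style short-segment rejection, off
    exclude_truncated: bool = False
    pooled_clustering: bool = False  # single-level K-means on pooled peaks
    # acquisition stage (applied only when a recording is above target_fs)
    acquisition_band: tuple[float, float] = (0.5, 70.0)
    notch_hz: float | None = 50.0
    target_fs: float = 500.0


def _conditioned(rec: SyntheticRecording, cfg: PipelineConfig) -> SyntheticRecording:
    """Acquisition-stage filtering + downsampling for high-rate recordings."""
    if rec.fs > cfg.target_fs:
        rec = filter_recording(rec, *cfg.acquisition_band, notch=cfg.notch_hz)
        rec = resample_recording(rec, cfg.target_fs)
    return rec


def segment_subject(
    rec: SyntheticRecording, cfg: PipelineConfig = PipelineConfig(), seed: int = 0
) -> SegmentationResult:
    """2-20 Hz filter -> epochs -> GFP peaks -> modified K-means."""
    rec = _conditioned(rec, cfg)
    narrow = filter_recording(rec, *cfg.band)
    ep = epoch_and_reference(narrow, cfg.epoch_length_s, cfg.n_epochs)
    gfp = compute_gfp(ep)
    peaks = find_gfp_peaks(gfp, ep, cfg.min_peak_separation_ms)
    return modified_kmeans(
        peaks, k=cfg.k, restarts=cfg.restarts, max_iter=cfg.max_iter,
        tol=cfg.tol, seed=seed,
    )


def analyze_group_lazy(
    make_recording,
    n_subjects: int,
    canonical: TemplateSet,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    group_name: str = "group",
    subject_ids: list[str] | None = None,
) -> dict:
    """Full pipeline for one group, materializing one recording at a time.

    ``make_recording(i)`` must deterministically rebuild subject ``i``'s
    recording; it is called twice per subject (clustering pass, then
    back-fitting pass) so that a 60+-subject cohort never has to be held in
    memory at once.  Returns a dict with the labeled group maps (rows
    ordered A-D), per-subject parameter and transition tables, per-subject
    GEV, and each subject's own canonical-aligned maps (TANOVA input).
    """
    if subject_ids is None:
        subject_ids = [f"{group_name}-{i + 1:03d}" for i in range(n_subjects)]
    seeds = np.random.SeedSequence(seed).generate_state(n_subjects) % (2**31)

    if cfg.pooled_clustering:
        # single-level variant: one K-means over all subjects' peaks
        topos, gfps = [], []
        for i in range(n_subjects):
            rec = _conditioned(make_recording(i), cfg)
            narrow = filter_recording(rec, *cfg.band)
            ep = epoch_and_reference(narrow, cfg.epoch_length_s, cfg.n_epochs)
            p = find_gfp_peaks(compute_gfp(ep), ep, cfg.min_peak_separation_ms)
            topos.append(p.topographies)
            gfps.append(p.peak_gfp)
        from .segmentation import PeakTopographies

        pooled = PeakTopographies(
            np.concatenate(topos), np.concatenate(gfps),
            np.arange(sum(len(g) for g in gfps)),
        )
        seg = modified_kmeans(
            pooled, k=cfg.k, restarts=cfg.restarts, max_iter=cfg.max_iter,
            tol=cfg.tol, seed=int(seeds[0]),
        )
        seg_results = [seg]
        group_maps_raw = seg.maps
        subject_maps = None
    else:
        seg_results = [
            segment_subject(make_recording(i), cfg, int(seeds[i]))
            for i in range(n_subjects)
        ]
        group_maps_raw = aggregate_group_maps(seg_results, seed=seed)
    _, group_maps = label_maps(group_maps_raw, canonical)
    if not cfg.pooled_clustering:
        subject_maps = np.stack(
            [label_maps(r.maps, canonical)[1] for r in seg_results]
        )

    params_rows, trans_rows = [], []
    for i, sid in enumerate(subject_ids):
        rec = _conditioned(make_recording(i), cfg)
        ep = epoch_and_reference(rec, cfg.epoch_length_s, cfg.n_epochs)
        series = backfit(ep, group_maps)
        if cfg.smoothing_ms > 0:
            series = smooth_labels(series, cfg.smoothing_ms, ep, group_maps)
        p = compute_parameters(series, exclude_truncated=cfg.exclude_truncated)
        p.insert(0, "subject_id", sid)
        p.insert(1, "group", group_name)
        params_rows.append(p)
        t = compute_transitions(series)
        t.insert(0, "subject_id", sid)
        t.insert(1, "group", group_name)
        trans_rows.append(t)

    return {
        "group_maps": group_maps,
        "segmentations": seg_results,
        "subject_maps": subject_maps,
        "gev": np.array([r.gev for r in seg_results]),
        "parameters": pd.concat(params_rows, ignore_index=True),
        "transitions": pd.concat(trans_rows, ignore_index=True),
    }


def analyze_group(
    recordings: list[SyntheticRecording],
    canonical: TemplateSet,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int = 0,
    group_name: str = "group",
    subject_ids: list[str] | None = None,
) -> dict:
    """Full pipeline for one in-memory group of recordings."""
    return analyze_group_lazy(
        recordings.__getitem__, len(recordings), canonical, cfg,
        seed=seed, group_name=group_name, subject_ids=subject_ids,
    )


def analyze_cohort(
    recordings: list[SyntheticRecording],
    clinical: pd.DataFrame,
    canonical: TemplateSet,
    cfg: PipelineConfig = PipelineConfig(),
    seed: int = 0,
) -> dict:
    """Run both groups of a generated cohort and merge the tables."""
    out = {"groups": {}}
    params, trans = [], []
    for g, name in enumerate(clinical["group"].unique()):
        sel = clinical["group"] == name
        recs = [recordings[i] for i in np.flatnonzero(sel.to_numpy())]
        res = analyze_group(
            recs, canonical, cfg, seed=seed + g,
            group_name=str(name),
            subject_ids=clinical.loc[sel, "subject_id"].tolist(),
        )
        out["groups"][name] = res
        params.append(res["parameters"])
        trans.append(res["transitions"])
    out["parameters"] = pd.concat(params, ignore_index=True)
    out["transitions"] = pd.concat(trans, ignore_index=True)
    out["clinical"] = clinical
    return out
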