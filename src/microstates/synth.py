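"""Synthetic resting-state EEG with planted microstate dynamics.

The generator realizes the standard microstate forward model: the scalp
field at every instant is one of four fixed template topographies, scaled
by a global waveform and corrupted by spatially white sensor noise,

    v(t) = a(t) * T_{L(t)} + eps(t),

where the label sequence ``L(t)`` is a semi-Markov chain (gamma-distributed
segment lengths with planted per-class means, an embedded zero-diagonal
transition matrix between segments) and ``a(t)`` is a rectified 10 Hz
sinusoid scaled to unit mean, so GFP peaks recur roughly every 50 ms as in
eyes-closed alpha-dominated EEG.  Because every planted quantity (mean
durations, segment weights, embedded transitions, SNR, the clinical
correlation) is known, each pipeline stage can be validated by parameter
recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import ElectrodeMontage
from .templates import CLASS_LABELS, TemplateSet

__all__ = [
    "SemiMarkovSpec",
    "CohortSpec",
    "SyntheticRecording",
    "sample_state_sequence",
    "render_eeg",
    "generate_clinical",
    "generate_cohort",
    "cohort_recording_factory",
    "stationary_distribution",
]

_AMPLITUDE_UV = 10.0  # overall scale of the rendered signal, microvolts
_GFP_FREQ_HZ = 10.0  # carrier of the rectified global waveform


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigvec)."""
    transitions = np.asarray(transitions, dtype=float)
    w, v = np.linalg.eig(transitions.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class SemiMarkovSpec:
    """Planted segment-level dynamics for one group.

    Parameters
    ----------
    mean_durations
        Per-class mean segment duration, ms (> 0).
    segment_weights
        Probability that a segment belongs to each class; must be the
        stationary distribution of ``embedded_transitions`` to within 0.02.
    embedded_transitions
        4x4 row-stochastic matrix with zero diagonal: probability of the
        next segment's class given the current one.
    duration_shape
        Gamma shape of the segment-length law (mean is kept planted).
    """

    mean_durations: np.ndarray
    segment_weights: np.ndarray
    embedded_transitions: np.ndarray = field(repr=False)
    duration_shape: float = 2.0

    def __post_init__(self) -> None:
        dur = np.asarray(self.mean_durations, dtype=float)
        w = np.asarray(self.segment_weights, dtype=float)
        P = np.asarray(self.embedded_transitions, dtype=float)
        k = dur.shape[0]
        if w.shape != (k,) or P.shape != (k, k):
            raise ValueError("inconsistent spec dimensions")
        if np.any(dur <= 0):
            raise ValueError("mean_durations must be positive")
        if np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("embedded_transitions must be row-stochastic")
        if np.max(np.abs(np.diag(P))) > 0:
            raise ValueError("embedded_transitions must have zero diagonal")
        if abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
            raise ValueError("segment_weights must be a distribution")
        if self.duration_shape <= 0:
            raise ValueError("duration_shape must be positive")
        pi = stationary_distribution(P)
        if np.max(np.abs(pi - w)) > 0.02:
            raise ValueError(
                "segment_weights must match the stationary distribution of "
                "embedded_transitions to within 0.02"
            )
        object.__setattr__(self, "mean_durations", dur)
        object.__setattr__(self, "segment_weights", w)
        object.__setattr__(self, "embedded_transitions", P)

    @property
    def k(self) -> int:
        return self.mean_durations.shape[0]

    def expected_coverage(self) -> np.ndarray:
        """Long-run fraction of time in each class (weights x durations)."""
        m = self.segment_weights * self.mean_durations
        return m / m.sum()

    def expected_occurrence(self) -> np.ndarray:
        """Long-run per-class segment rate, per second."""
        mean_seg_ms = float(np.sum(self.segment_weights * self.mean_durations))
        return self.segment_weights / (mean_seg_ms / 1000.0)

    def replace_duration(self, class_index: int, new_ms: float) -> "SemiMarkovSpec":
        dur = self.mean_durations.copy()
        dur[class_index] = new_ms
        return SemiMarkovSpec(
            dur, self.segment_weights, self.embedded_transitions, self.duration_shape
        )


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort description (recording geometry + clinical model)."""

    n_per_group: tuple[int, int]
    group_specs: tuple[SemiMarkovSpec, SemiMarkovSpec]
    group_names: tuple[str, str] = ("patient", "control")
    fs: float = 500.0
    length_s: float = 240.0
    snr: float = 5.0
    clinical_mean: float = 65.85  # HIT-6 scale
    clinical_sd: float = 6.91
    rho: float = -0.27  # target corr(class-C duration, HIT-6), patient group
    duration_sd_ms: float = 8.70  # between-subject SD of class-C duration
    sex_f_counts: tuple[int, int] = (50, 50)
    age_mean: tuple[float, float] = (32.79, 31.44)
    age_sd: tuple[float, float] = (6.83, 4.63)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.length_s <= 0 or self.snr <= 0:
            raise ValueError("fs, length_s and snr must be positive")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must not exceed 1")
        if abs(self.rho) == 1 and self.duration_sd_ms == 0:
            raise ValueError("|rho| = 1 requires nonzero duration variance")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")


@dataclass(frozen=True)
class SyntheticRecording:
    """Multichannel EEG matrix with montage and optional ground truth."""

    data: np.ndarray = field(repr=False)  # (n_channels, n_samples), microvolts
    fs: float = 500.0
    montage: ElectrodeMontage | None = None
    truth_labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.montage is not None and self.montage.n_channels != data.shape[0]:
            raise ValueError("montage channel count does not match data")
        if self.truth_labels is not None:
            lab = np.asarray(self.truth_labels)
            if lab.shape != (data.shape[1],):
                raise ValueError("truth_labels must have one entry per sample")
            if lab.min() < 0 or lab.max() >= len(CLASS_LABELS):
                raise ValueError("truth_labels out of class range")
            object.__setattr__(self, "truth_labels", lab.astype(np.int64))
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def sample_state_sequence(
    spec: SemiMarkovSpec, length_s: float, fs: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample a per-sample class-index sequence from the semi-Markov law.

    Segment classes follow the embedded chain (first segment from the
    stationary weights); segment lengths are gamma with the class's planted
    mean, rounded to at least one sample.
    """
    if fs * float(np.min(spec.mean_durations)) / 1000.0 < 2:
        raise ValueError("sampling rate too low to resolve the shortest class")
    rng = np.random.default_rng(seed)
    n = int(round(length_s * fs))
    mean_samples = spec.mean_durations * fs / 1000.0
    shape = spec.duration_shape

    labels = np.empty(n, dtype=np.int64)
    pos = 0
    state = int(rng.choice(spec.k, p=spec.segment_weights))
    while pos < n:
        run = max(1, int(round(rng.gamma(shape, mean_samples[state] / shape))))
        end = min(n, pos + run)
        labels[pos:end] = state
        pos = end
        state = int(rng.choice(spec.k, p=spec.embedded_transitions[state]))
    return labels


def render_eeg(
    labels: np.ndarray,
    templates: TemplateSet,
    fs: float,
    snr: float,
    seed: int | np.random.Generator,
    montage: ElectrodeMontage | None = None,
) -> SyntheticRecording:
    """Render a label sequence into multichannel EEG.

    The carrier is a signed 10 Hz sinusoid, phase-continuous across
    segments, scaled so the GFP waveform (its rectification) has unit
    mean; GFP peaks therefore recur every 50 ms.  A signed rather than
    rectified carrier keeps the signal inside the 2-20 Hz analysis band
    (a rectified carrier has its energy at DC/20/40 Hz, and the 2 Hz
    high-pass edge then smears each segment's topography over its
    neighbours); under the polarity-invariant analysis the two choices
    are indistinguishable except through linear filtering.  Noise is
    spatially white Gaussian, average-referenced, and scaled so that
    mean(signal GFP) / mean(noise GFP) = ``snr``.  ``snr=np.inf``
    disables noise entirely.
    """
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    if labels.min() < 0 or labels.max() >= templates.k:
        raise ValueError("labels out of range for the template set")
    if snr <= 0:
        raise ValueError("snr must be positive")
    if montage is not None and montage.n_channels != templates.n_channels:
        raise ValueError("montage channel count does not match templates")

    n = labels.shape[0]
    c = templates.n_channels
    t = np.arange(n) / fs
    a = np.sin(2 * np.pi * _GFP_FREQ_HZ * t)
    a *= np.pi / 2.0  # mean of |sin| is 2/pi -> unit-mean GFP waveform

    signal = templates.maps[labels].T * a  # (C, T); templates are avg-ref
    sig_gfp_mean = float(np.mean(np.std(signal, axis=0)))

    if np.isinf(snr):
        data = signal
    else:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((c, n))
        noise -= noise.mean(axis=0, keepdims=True)
        noise_gfp_mean = float(np.mean(np.std(noise, axis=0)))
        noise *= (sig_gfp_mean / snr) / noise_gfp_mean
        data = signal + noise
    return SyntheticRecording(
        data * _AMPLITUDE_UV, fs=fs, montage=montage, truth_labels=labels
    )


def _subject_seeds(seed: int, n: int) -> np.ndarray:
    """Fixed splitting of one master seed into per-subject child seeds."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_clinical(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Clinical/demographic table with planted class-C duration jitter.

    Per subject, the planted class-C mean duration is its group value plus
    Gaussian jitter (SD ``duration_sd_ms``); the HIT-6 score is drawn from
    the conditional Gaussian that yields population correlation ``rho``
    with that jittered duration (patients; controls get an independent
    score).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    c_idx = CLASS_LABELS.index("C")
    rows = []
    for g, (name, n, sm) in enumerate(
        zip(spec.group_names, spec.n_per_group, spec.group_specs)
    ):
        base_c = float(sm.mean_durations[c_idx])
        jitter = rng.normal(0.0, spec.duration_sd_ms, size=n)
        dur_c = base_c + jitter
        z = rng.standard_normal(n)
        hit6 = spec.clinical_mean + spec.clinical_sd * (
            spec.rho * jitter / spec.duration_sd_ms
            + np.sqrt(1.0 - spec.rho**2) * z
        )
        n_f = min(spec.sex_f_counts[g], n)
        sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
        age = rng.normal(spec.age_mean[g], spec.age_sd[g], size=n)
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{name}-{i + 1:03d}",
                    "group": name,
                    "sex": sex[i],
                    "age": round(float(age[i]), 2),
                    "HIT6": round(float(hit6[i]), 2),
                    "planted_duration_C_ms": round(float(dur_c[i]), 4),
                }
            )
    return pd.DataFrame(rows)


def cohort_recording_factory(
    spec: CohortSpec,
    clinical: pd.DataFrame,
    templates: TemplateSet,
    seed: int,
    montage: ElectrodeMontage | None = None,
):
    """Deterministic per-subject recording builder for a generated cohort.

    ``factory(i)`` rebuilds the recording of the i-th clinical-table row
    (rows are ordered by group) from the master seed, so cohorts can be
    streamed subject-by-subject instead of held in memory.  Each subject's
    semi-Markov spec is the group spec with its class-C mean duration
    replaced by the subject's jittered value (floored at 20 ms so the
    segment law stays resolvable).
    """
    n_total = len(clinical)
    seeds = _subject_seeds(seed, 2 * n_total)
    c_idx = CLASS_LABELS.index("C")
    group_of = dict(zip(spec.group_names, spec.group_specs))

    def factory(i: int) -> SyntheticRecording:
        row = clinical.iloc[i]
        sm = group_of[row["group"]]
        dur_c = max(20.0, float(row["planted_duration_C_ms"]))
        subj_spec = sm.replace_duration(c_idx, dur_c)
        labels = sample_state_sequence(
            subj_spec, spec.length_s, spec.fs, int(seeds[2 * i])
        )
        return render_eeg(
            labels, templates, spec.fs, spec.snr, int(seeds[2 * i + 1]), montage
        )

    return factory


def generate_cohort(
    spec: CohortSpec,
    templates: TemplateSet,
    seed: int,
    montage: ElectrodeMontage | None = None,
) -> tuple[list[SyntheticRecording], pd.DataFrame]:
    """Generate per-subject recordings plus the clinical table (in memory)."""
    clinical = generate_clinical(spec, seed)
    factory = cohort_recording_factory(spec, clinical, templates, seed, montage)
    recordings = [factory(i) for i in range(len(clinical))]
    return recordings, clinical
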