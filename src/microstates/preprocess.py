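"""Signal conditioning: band-pass/notch filtering, resampling, epoching and
common average referencing.

The study chain is: acquisition-stage 0.5-70 Hz band-pass + 50 Hz notch,
downsampling to 500 Hz, selection of 2-s epochs, common average reference,
then a 2-20 Hz band-pass before microstate segmentation.  All filters are
zero-phase (forward-backward IIR): 4th-order Butterworth band-pass, 2nd-order
notch with quality 30.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .synth import SyntheticRecording

__all__ = [
    "EpochedRecording",
    "filter_recording",
    "resample_recording",
    "epoch_and_reference",
    "average_reference",
    "flag_artifact_epochs",
]


@dataclass(frozen=True)
class EpochedRecording:
    """Average-referenced epochs, shape (n_epochs, n_channels, n_samples)."""

    epochs: np.ndarray = field(repr=False)
    fs: float = 500.0
    epoch_length_s: float = 2.0

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if ep.shape[2] != int(round(self.epoch_length_s * self.fs)):
            raise ValueError("sample count inconsistent with epoch length")
        if not np.all(np.isfinite(ep)):
            raise ValueError("epochs must be finite")
        if np.max(np.abs(ep.mean(axis=1))) > 1e-8:
            raise ValueError("epochs must be average-referenced")
        object.__setattr__(self, "epochs", ep)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def concatenated(self) -> np.ndarray:
        """Channels x samples matrix with epochs laid end to end."""
        return np.concatenate(list(self.epochs), axis=1)

    def epoch_boundaries(self) -> np.ndarray:
        s = self.n_samples_per_epoch
        return np.arange(0, (self.n_epochs + 1) * s, s)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean (idempotent)."""
    return data - data.mean(axis=0, keepdims=True)


def filter_recording(
    rec: SyntheticRecording,
    band_lo: float,
    band_hi: float,
    notch: float | None = None,
) -> SyntheticRecording:
    """Zero-phase band-pass (and optional notch) filter, length preserved."""
    nyq = rec.fs / 2.0
    if not (0 < band_lo < band_hi < nyq):
        raise ValueError(f"invalid band [{band_lo}, {band_hi}] Hz at fs={rec.fs}")
    sos = signal.butter(2, [band_lo, band_hi], btype="bandpass", fs=rec.fs, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    if notch is not None:
        if not (0 < notch < nyq):
            raise ValueError("notch frequency must be below Nyquist")
        b, a = signal.iirnotch(notch, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return SyntheticRecording(
        data, fs=rec.fs, montage=rec.montage, truth_labels=rec.truth_labels
    )


def resample_recording(rec: SyntheticRecording, target_fs: float) -> SyntheticRecording:
    """Anti-aliased polyphase downsampling to ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError("upsampling not supported")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    truth = None
    if rec.truth_labels is not None:
        # nearest-sample decimation of the ground-truth labels
        idx = np.round(np.arange(data.shape[1]) * rec.fs / target_fs).astype(int)
        truth = rec.truth_labels[np.clip(idx, 0, rec.n_samples - 1)]
    return SyntheticRecording(data, fs=target_fs, montage=rec.montage, truth_labels=truth)


def epoch_and_reference(
    rec: SyntheticRecording, epoch_length_s: float = 2.0, n_epochs: int = 60
) -> EpochedRecording:
    """First-N contiguous non-overlapping epochs, common-average referenced."""
    s = int(round(epoch_length_s * rec.fs))
    available = rec.n_samples // s
    if n_epochs > available:
        raise ValueError(
            f"requested {n_epochs} epochs but only {available} available"
        )
    ep = rec.data[:, : n_epochs * s].reshape(rec.n_channels, n_epochs, s)
    ep = np.moveaxis(ep, 0, 1)  # (E, C, S)
    ep = ep - ep.mean(axis=1, keepdims=True)
    return EpochedRecording(ep, fs=rec.fs, epoch_length_s=epoch_length_s)


def flag_artifact_epochs(
    epoched: EpochedRecording, threshold_uv: float | None = None
) -> np.ndarray:
    """Amplitude-threshold artifact hook (pass-through by default).

    Returns a boolean mask of epochs whose maximum absolute amplitude
    exceeds ``threshold_uv``; with the default ``None`` nothing is flagged
    (synthetic data are artifact-free, and ICA/visual rejection of real
    data is out of scope).
    """
    if threshold_uv is None:
        return np.zeros(epoched.n_epochs, dtype=bool)
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    return np.abs(epoched.epochs).max(axis=(1, 2)) > threshold_uv


def truth_label_epochs(rec: SyntheticRecording, epoched: EpochedRecording) -> np.ndarray:
    """Ground-truth labels aligned with the concatenated epochs."""
    if rec.truth_labels is None:
        raise ValueError("recording carries no ground-truth labels")
    s = epoched.n_samples_per_epoch
    return rec.truth_labels[: epoched.n_epochs * s]
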