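"""Canonical microstate template topographies (classes A-D).

The four canonical resting-state maps are modeled as dipolar scalp patterns:

* **A** - left-posterior positive / right-frontal negative diagonal,
* **B** - its mirror image (right-posterior / left-frontal),
* **C** - occipital positive vs. frontal negative (anterior-posterior axis),
* **D** - fronto-central maximum against the posterior rim.

Each map is the difference of two isotropic Gaussian bumps (sigma = 0.6 head
radii) evaluated at the electrode positions, then average-referenced and
normalized to unit Euclidean norm, the convention used throughout the
clustering code.  Because clustering and back-fitting are polarity
invariant, only the spatial configuration (not the sign) of these maps is
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import ElectrodeMontage

__all__ = ["TemplateSet", "make_canonical_templates", "CLASS_LABELS"]

CLASS_LABELS: tuple[str, ...] = ("A", "B", "C", "D")

_SIGMA = 0.6  # Gaussian bump width, head radii

# (positive bump center, negative bump center) in disk coordinates.
# D's negative bump sits far behind the head rim so that on the scalp it
# reads as a faint posterior ring around a fronto-central maximum; keeping
# it weak is what separates D from the anterior-posterior dipole of C under
# polarity-invariant matching.
_BUMP_CENTERS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "A": ((-0.60, -0.40), (0.60, 0.40)),
    "B": ((0.60, -0.40), (-0.60, 0.40)),
    "C": ((0.0, -0.80), (0.0, 0.80)),
    "D": ((0.0, 0.10), (0.0, -2.50)),
}


@dataclass(frozen=True)
class TemplateSet:
    """k unit-norm, average-referenced topographies with class labels."""

    maps: np.ndarray = field(repr=False)  # (k, n_channels)
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 2:
            raise ValueError("maps must be a (k, n_channels) matrix")
        if maps.shape[0] != len(self.labels):
            raise ValueError("one label per map required")
        if not np.all(np.isfinite(maps)):
            raise ValueError("maps must be finite")
        if np.max(np.abs(maps.mean(axis=1))) > 1e-8:
            raise ValueError("maps must be average-referenced")
        if np.max(np.abs(np.linalg.norm(maps, axis=1) - 1.0)) > 1e-8:
            raise ValueError("maps must have unit norm")
        object.__setattr__(self, "maps", maps)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def spatial_correlations(self) -> np.ndarray:
        """Pairwise Pearson correlations between the template maps."""
        m = self.maps - self.maps.mean(axis=1, keepdims=True)
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        return m @ m.T


def _gauss_bump(positions: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    d2 = np.sum((positions - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * _SIGMA**2))


def make_canonical_templates(montage: ElectrodeMontage) -> TemplateSet:
    """Build the four canonical class-A..D maps on a given montage.

    Raises
    ------
    ValueError
        If the montage has fewer than 8 channels (enforced by the montage
        itself) or if the resulting maps are too collinear to serve as
        distinct classes (|pairwise correlation| >= 0.95).
    """
    rows = []
    for label in CLASS_LABELS:
        pos_c, neg_c = _BUMP_CENTERS[label]
        m = _gauss_bump(montage.positions, pos_c) - _gauss_bump(montage.positions, neg_c)
        m = m - m.mean()
        norm = np.linalg.norm(m)
        if norm < 1e-12:
            raise ValueError(f"degenerate template for class {label}")
        rows.append(m / norm)
    tset = TemplateSet(np.array(rows), CLASS_LABELS)
    corr = tset.spatial_correlations()
    off = corr[~np.eye(tset.k, dtype=bool)]
    if np.max(np.abs(off)) >= 0.95:
        raise ValueError("montage yields near-collinear canonical templates")
    return tset
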