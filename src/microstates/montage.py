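"""Electrode montage: 10-20 / 10-10 channel names with 2-D scalp coordinates.

Coordinates live on the unit disk (azimuthal-equidistant view from above,
nose up, head radius 1).  The built-in 64-channel layout is an idealized
extended 10-20 cap generated from the standard ring/arc construction; it is
left-right symmetric by design, which the canonical template builder relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeMontage", "standard_64_montage"]


@dataclass(frozen=True)
class ElectrodeMontage:
    """Named electrodes with 2-D scalp-projection coordinates.

    Parameters
    ----------
    channel_names
        Unique 10-20/10-10 style labels, one per channel (>= 8 channels).
    positions
        ``(n_channels, 2)`` array of (x, y) coordinates, ``|pos| <= 1``
        (x to the right ear, y to the nasion).
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n_channels, 2) array")
        if len(names) != pos.shape[0]:
            raise ValueError("channel_names and positions length mismatch")
        if len(names) < 8:
            raise ValueError("montage needs at least 8 channels")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        r = np.linalg.norm(pos, axis=1)
        if np.any(r > 1.0 + 1e-9):
            raise ValueError("positions must lie within the unit head disk")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def reflected(self) -> "ElectrodeMontage":
        """Montage mirrored left<->right (x -> -x), same names."""
        pos = self.positions.copy()
        pos[:, 0] *= -1.0
        return ElectrodeMontage(self.channel_names, pos)


def _ring(radius: float, labels_deg: dict[str, float]) -> dict[str, np.ndarray]:
    out = {}
    for name, deg in labels_deg.items():
        a = np.deg2rad(deg)  # 0 deg = nasion, positive clockwise (right)
        out[name] = np.array([radius * np.sin(a), radius * np.cos(a)])
    return out


def standard_64_montage() -> ElectrodeMontage:
    """Idealized 64-channel extended 10-20 montage on the unit disk.

    Outer 10% ring at r = 0.82; midline electrodes equally spaced on the
    nasion-inion diameter; lateral electrodes interpolated between the
    midline point and the same-row ring electrode at 10-10 fractions.
    """
    ring_r = 0.82
    pos: dict[str, np.ndarray] = {}

    ring = {
        "Fpz": 0, "Fp2": 18, "AF8": 36, "F8": 54, "FT8": 72, "T8": 90,
        "TP8": 108, "P8": 126, "PO8": 144, "O2": 162, "Oz": 180,
        "O1": 198, "PO7": 216, "P7": 234, "TP7": 252, "T7": 270,
        "FT7": 288, "F7": 306, "AF7": 324, "Fp1": 342,
    }
    pos.update(_ring(ring_r, ring))

    midline_y = {
        "AFz": 0.75, "Fz": 0.5, "FCz": 0.25, "Cz": 0.0,
        "CPz": -0.25, "Pz": -0.5, "POz": -0.75,
    }
    for name, f in midline_y.items():
        pos[name] = np.array([0.0, ring_r * f])
    pos["Iz"] = np.array([0.0, -0.95])

    # row -> (midline anchor, right-ring anchor, electrodes at fractions
    # from midline toward the ring); left side mirrors with odd indices
    rows = {
        "AF": ("AFz", "AF8", {"AF4": 0.5}),
        "F": ("Fz", "F8", {"F2": 0.25, "F4": 0.5, "F6": 0.75}),
        "FC": ("FCz", "FT8", {"FC2": 0.25, "FC4": 0.5, "FC6": 0.75}),
        "C": ("Cz", "T8", {"C2": 0.25, "C4": 0.5, "C6": 0.75}),
        "CP": ("CPz", "TP8", {"CP2": 0.25, "CP4": 0.5, "CP6": 0.75}),
        "P": ("Pz", "P8", {"P2": 0.25, "P4": 0.5, "P6": 0.75}),
        "PO": ("POz", "PO8", {"PO4": 0.33, "PO6": 0.66}),
    }
    for _row, (mid, right, lat) in rows.items():
        m, r = pos[mid], pos[right]
        for name, frac in lat.items():
            p = (1 - frac) * m + frac * r
            pos[name] = p
            left_name = name[:-1] + str(int(name[-1]) - 1)
            pos[left_name] = np.array([-p[0], p[1]])

    names = tuple(pos)
    coords = np.array([pos[n] for n in names])
    montage = ElectrodeMontage(names, coords)
    assert montage.n_channels == 64
    return montage
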