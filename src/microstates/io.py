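"""Plain-text I/O: recordings as CSV matrices, tables as TSV, maps as CSV.

A recording travels as two files: ``<stem>.csv`` (rows = channels, first
column the channel name, remaining columns samples in microvolts) and an
optional ``<stem>_labels.tsv`` sidecar (columns: sample, class) carrying
synthetic ground truth.  The montage is a CSV of name,x,y rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ElectrodeMontage
from .synth import SyntheticRecording
from .templates import CLASS_LABELS

__all__ = [
    "write_montage_csv",
    "read_montage_csv",
    "write_recording_csv",
    "read_recording_csv",
    "write_maps_csv",
    "read_maps_csv",
    "write_run_report",
]


def write_montage_csv(montage: ElectrodeMontage, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": montage.channel_names,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_montage_csv(path: str | Path) -> ElectrodeMontage:
    df = pd.read_csv(path)
    return ElectrodeMontage(tuple(df["name"]), df[["x", "y"]].to_numpy(float))


def write_recording_csv(rec: SyntheticRecording, stem: str | Path) -> None:
    stem = Path(stem)
    names = (
        rec.montage.channel_names
        if rec.montage is not None
        else [f"ch{i:02d}" for i in range(rec.n_channels)]
    )
    with open(stem.with_suffix(".csv"), "w") as fh:
        fh.write(f"# fs_hz={rec.fs}\n")
        for name, row in zip(names, rec.data):
            fh.write(name + "," + ",".join(f"{v:.4f}" for v in row) + "\n")
    if rec.truth_labels is not None:
        pd.DataFrame(
            {
                "sample": np.arange(rec.n_samples),
                "class": [CLASS_LABELS[c] for c in rec.truth_labels],
            }
        ).to_csv(stem.parent / (stem.name + "_labels.tsv"), sep="\t", index=False)


def read_recording_csv(
    stem: str | Path, montage: ElectrodeMontage | None = None
) -> SyntheticRecording:
    stem = Path(stem)
    path = stem if stem.suffix == ".csv" else stem.with_suffix(".csv")
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs_hz="):
            raise ValueError("recording CSV lacks the fs header line")
        fs = float(header.split("=", 1)[1])
        names, rows = [], []
        for line in fh:
            name, _, rest = line.partition(",")
            names.append(name)
            rows.append(np.fromstring(rest, sep=","))
    data = np.vstack(rows)
    labels_path = path.parent / (path.stem + "_labels.tsv")
    truth = None
    if labels_path.exists():
        lab = pd.read_csv(labels_path, sep="\t")
        truth = np.array([CLASS_LABELS.index(c) for c in lab["class"]])
    return SyntheticRecording(data, fs=fs, montage=montage, truth_labels=truth)


def write_maps_csv(
    maps: np.ndarray, channel_names: list[str] | tuple[str, ...], path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(maps), index=list(CLASS_LABELS), columns=list(channel_names))
    df.index.name = "class"
    df.to_csv(path)


def read_maps_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, index_col="class").to_numpy(float)


def write_run_report(report: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
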