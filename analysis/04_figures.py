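#!/usr/bin/env python
"""Figures: group maps, temporal-parameter distributions, clinical scatter.

Reads the tables written by 01-03 and renders PNGs under results/figures/
(regenerable; not part of the text deliverable).
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from microstates import io

ROOT = Path(__file__).resolve().parents[1]


def plot_maps(montage, maps_by_group, path):
    fig, axes = plt.subplots(
        len(maps_by_group), 4, figsize=(10, 2.6 * len(maps_by_group))
    )
    axes = np.atleast_2d(axes)
    for r, (gname, maps) in enumerate(maps_by_group.items()):
        lim = np.abs(maps).max()
        for c, label in enumerate("ABCD"):
            ax = axes[r, c]
            ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, lw=1))
            sc = ax.scatter(
                montage.positions[:, 0], montage.positions[:, 1],
                c=maps[c], cmap="RdBu_r", vmin=-lim, vmax=lim, s=44,
            )
            ax.set_title(f"{gname}: {label}", fontsize=10)
            ax.set_xlim(-1.15, 1.15)
            ax.set_ylim(-1.15, 1.25)
            ax.set_aspect("equal")
            ax.axis("off")
    fig.colorbar(sc, ax=axes, shrink=0.7, label="map weight (a.u.)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_parameters(params, path):
    metrics = [
        ("duration_ms", "mean duration (ms)"),
        ("occurrence_hz", "occurrence (/s)"),
        ("coverage_pct", "time coverage (%)"),
    ]
    groups = params["group"].unique()
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    for ax, (metric, title) in zip(axes, metrics):
        data, positions, colors = [], [], []
        for c, cls in enumerate("ABCD"):
            for g, gname in enumerate(groups):
                sel = (params["class"] == cls) & (params["group"] == gname)
                data.append(params.loc[sel, metric].to_numpy())
                positions.append(c + (g - 0.5) * 0.35)
                colors.append(f"C{g}")
        parts = ax.violinplot(data, positions=positions, widths=0.3, showmeans=True)
        for body, color in zip(parts["bodies"], colors):
            body.set_facecolor(color)
        ax.set_xticks(range(4), list("ABCD"))
        ax.set_title(title)
    handles = [plt.Line2D([], [], color=f"C{g}", lw=5) for g in range(len(groups))]
    fig.legend(handles, list(groups), loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation(params, clinical, path):
    groups = clinical["group"].unique()
    pat_ids = clinical.loc[clinical["group"] == groups[0], "subject_id"]
    dur = (
        params[(params["class"] == "C") & params["subject_id"].isin(pat_ids)]
        .set_index("subject_id")["duration_ms"]
    )
    hit6 = clinical.set_index("subject_id").loc[dur.index, "HIT6"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(dur, hit6, s=20)
    b, a = np.polyfit(dur, hit6, 1)
    xs = np.linspace(dur.min(), dur.max(), 10)
    ax.plot(xs, a + b * xs, "k--", lw=1)
    r = np.corrcoef(dur, hit6)[0, 1]
    ax.set_xlabel("measured class-C mean duration (ms)")
    ax.set_ylabel("HIT-6")
    ax.set_title(f"patients: r = {r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def main() -> None:
    out = ROOT / "results"
    figs = out / "figures"
    figs.mkdir(exist_ok=True)
    montage = io.read_montage_csv(out / "montage.csv")
    params = pd.read_csv(out / "parameters.tsv", sep="\t")
    clinical = pd.read_csv(out / "clinical.tsv", sep="\t")
    maps_by_group = {
        p.stem.replace("maps_", ""): io.read_maps_csv(p)
        for p in sorted(out.glob("maps_*.csv"))
    }
    plot_maps(montage, maps_by_group, figs / "group_maps.png")
    plot_parameters(params, figs / "temporal_parameters.png")
    plot_correlation(params, clinical, figs / "duration_C_vs_hit6.png")
    print(f"wrote figures to {figs}")


if __name__ == "__main__":
    main()
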