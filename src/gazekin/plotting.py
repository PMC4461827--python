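"""Multi-panel figure rendering for the simulation drivers.

Display convention: positive azimuth maps to +y in the model frame; the
panels plot it on the positive horizontal axis without relabeling
left/right.  Torsion axes show rotation-vector x components (deg) for the
scatter ranges and trajectories.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_range_scan", "plot_fig4", "plot_trajectories"]

_COLORS = {"eye": "tab:red", "head": "tab:green", "gaze": "tab:blue"}


def plot_range_scan(table: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Two rows (vertical vs horizontal; torsion vs horizontal) by three
    columns (eye-in-head, head, gaze) of final-orientation scatter."""
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), constrained_layout=True)
    top = table[table["target_eta_deg"] == table["target_eta_deg"].max()]
    for j, which in enumerate(("eye", "head", "gaze")):
        c = _COLORS[which]
        axes[0, j].scatter(
            table[f"{which}_rz_deg"], table[f"{which}_ry_deg"], s=3, color=c
        )
        axes[0, j].set_title(which)
        axes[0, j].set_xlabel("horizontal r$_z$ (deg)")
        axes[0, j].set_ylabel("vertical r$_y$ (deg)")
        axes[1, j].scatter(
            table[f"{which}_rz_deg"], table[f"{which}_rx_deg"], s=3, color=c
        )
        axes[1, j].plot(top["gaze_rz_deg"], top["gaze_rx_deg"], color="black", lw=1)
        axes[1, j].set_xlabel("horizontal r$_z$ (deg)")
        axes[1, j].set_ylabel("torsion r$_x$ (deg)")
    if title:
        fig.suptitle(title)
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_fig4(shifts, path: str | Path, title: str = "") -> Path:
    """Screen paths, retinal paths, and angular gaze paths of an accuracy
    suite, one column of panels."""
    fig, axes = plt.subplots(3, 1, figsize=(5, 10), constrained_layout=True)
    for s in shifts:
        axes[0].plot(s.screen_path["screen_a_cm"], s.screen_path["screen_b_cm"])
        axes[0].plot(
            s.screen_path["screen_a_cm"].iloc[-1],
            s.screen_path["screen_b_cm"].iloc[-1],
            "kx",
        )
        axes[1].plot(s.retinal_path["re_gamma_deg"], s.retinal_path["re_eta_deg"])
        tr = s.trajectory
        axes[2].plot(tr["gaze_rz_deg"], tr["gaze_ry_deg"])
    axes[0].set_xlabel("screen horizontal (cm)")
    axes[0].set_ylabel("screen vertical (cm)")
    axes[1].set_xlabel("retinal azimuth (deg)")
    axes[1].set_ylabel("retinal elevation (deg)")
    axes[2].set_xlabel("gaze horizontal r$_z$ (deg)")
    axes[2].set_ylabel("gaze vertical r$_y$ (deg)")
    if title:
        fig.suptitle(title)
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_trajectories(results, path: str | Path, title: str = "") -> Path:
    """Torsion-vs-horizontal paths of eye, head, and gaze for a trajectory
    suite (one curve per shift)."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), constrained_layout=True)
    for res in results:
        tr = res["trajectory"]
        for j, which in enumerate(("eye", "head", "gaze")):
            axes[j].plot(
                tr[f"{which}_rz_deg"], tr[f"{which}_rx_deg"], color=_COLORS[which], lw=1
            )
    for j, which in enumerate(("eye", "head", "gaze")):
        axes[j].set_title(which)
        axes[j].set_xlabel("horizontal r$_z$ (deg)")
        axes[j].set_ylabel("torsion r$_x$ (deg)")
    if title:
        fig.suptitle(title)
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
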