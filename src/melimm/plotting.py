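"""Minimal plotting helpers for timeseries and grid snapshots."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_timeseries(timeseries: pd.DataFrame, out_path: str | Path, columns=("tumor_area_mm2",)):
    """Line plot of selected timeseries columns against day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for col in columns:
        ax.plot(timeseries["day"], timeseries[col], label=col)
    ax.set_xlabel("day post tumor injection")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_snapshot(grid: np.ndarray, out_path: str | Path, title: str = ""):
    """Heat map of a per-site count grid (tumor or T-cell snapshot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(grid, origin="lower", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8, label="count per site")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
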