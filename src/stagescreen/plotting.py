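"""Per-plate heatmaps of raw values and B-scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")  # headless screening servers
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_plate_heatmap"]


def plot_plate_heatmap(wells: pd.DataFrame, value_col: str = "value",
                       n_rows: int = 8, n_cols: int = 12, ax=None,
                       title: str | None = None):
    """Heatmap of one plate slice (single plate/channel/replicate).

    Useful for eyeballing row/column artifacts before and after B-scoring.
    Returns the matplotlib Axes.
    """
    mat = np.full((n_rows, n_cols), np.nan)
    mat[wells["row"].to_numpy(), wells["col"].to_numpy()] = wells[value_col].to_numpy()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(n_cols), [str(c + 1) for c in range(n_cols)])
    ax.set_yticks(range(n_rows), [chr(ord("A") + r) for r in range(n_rows)])
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label=value_col)
    return ax
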