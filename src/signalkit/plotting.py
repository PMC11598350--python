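"""Optional presentation layer: drug x event heatmaps of screen results."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

log = logging.getLogger(__name__)


def render_heatmap(
    signal_frame: pd.DataFrame,
    path: str | Path,
    metric: str = "ic025",
    annotate_signals: bool = True,
) -> Optional[Path]:
    """Render a drugs-by-events grid colored by ``metric``.

    Signal pairs are marked with an asterisk.  Returns the written path,
    or None (with a warning) for an empty table.  Purely presentational:
    the delimited tables are the contract.
    """
    if signal_frame.empty:
        log.warning("empty signal table: heatmap skipped")
        return None
    if metric not in signal_frame.columns:
        raise ValueError(f"metric column {metric!r} absent from signal table")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = signal_frame.pivot_table(
        index="drug", columns="event", values=metric, aggfunc="first"
    )
    sig = (
        signal_frame.pivot_table(
            index="drug", columns="event", values="signal", aggfunc="first"
        ).reindex_like(grid)
        if "signal" in signal_frame.columns
        else None
    )
    fig, ax = plt.subplots(
        figsize=(max(4, 0.45 * grid.shape[1] + 2), max(3, 0.35 * grid.shape[0] + 2))
    )
    mesh = ax.pcolormesh(grid.to_numpy(dtype=float), cmap="RdBu_r", shading="auto")
    fig.colorbar(mesh, ax=ax, label=metric)
    ax.set_xticks([i + 0.5 for i in range(grid.shape[1])])
    ax.set_xticklabels(grid.columns, rotation=90, fontsize=7)
    ax.set_yticks([i + 0.5 for i in range(grid.shape[0])])
    ax.set_yticklabels(grid.index, fontsize=8)
    if annotate_signals and sig is not None:
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                if bool(sig.iloc[i, j]) and pd.notna(sig.iloc[i, j]):
                    ax.text(
                        j + 0.5, i + 0.5, "*", ha="center", va="center", fontsize=9
                    )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
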