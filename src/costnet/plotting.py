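"""Simple metric-versus-cost line plots for the global curves."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_global_curves(metric_table: pd.DataFrame, phenotypes: pd.DataFrame,
                       metric: str, path: Path | str) -> None:
    """Group-mean curve of a global metric across the cost grid.

    One line per group with a shaded +/- 1 SD band, written to ``path``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = metric_table[metric_table["metric"] == metric]
    merged = table.merge(phenotypes[["subject_id", "group"]], on="subject_id")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for group, chunk in merged.groupby("group"):
        stats = chunk.groupby("cost")["value"].agg(["mean", "std"])
        ax.plot(stats.index, stats["mean"], label=group)
        ax.fill_between(stats.index, stats["mean"] - stats["std"],
                        stats["mean"] + stats["std"], alpha=0.2)
    ax.set_xlabel("cost (sparsity)")
    ax.set_ylabel(metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
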