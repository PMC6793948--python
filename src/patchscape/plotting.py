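"""Bar-chart rendering of variance-partitioning results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_variance_partition"]


def plot_variance_partition(partition: pd.DataFrame, path=None, floor_at_zero=True):
    """Grouped bars of unique block fractions + TVE per response × age class.

    Negative adjusted fractions may be floored at zero for display (the
    underlying table never is).  Returns the matplotlib figure.
    """
    cols = ["unique_abi", "unique_pre", "unique_his", "TVE"]
    labels = ["Abi", "Pre", "His", "Conjoint"]
    data = partition[cols].copy()
    if floor_at_zero:
        data = data.clip(lower=0)
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(data), 4))
    data.columns = labels
    data.plot.bar(ax=ax, color=["#444444", "#888888", "#bbbbbb", "#222266"])
    ax.set_ylabel("Adjusted explained variation (%)")
    ax.set_xlabel("response × age class")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
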