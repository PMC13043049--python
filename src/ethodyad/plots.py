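"""Plot helpers: group time-course curves and transition graphs.

Thin wrappers over matplotlib; every function returns the Axes so figures
can be composed.  Styling is deliberately minimal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_group_curves(
    long_df: pd.DataFrame,
    group: str,
    dv: str = "value",
    within: str = "bin",
    significant_bins=None,
    ax=None,
):
    """Mean ± SEM curves per group over time bins.

    ``significant_bins`` (iterable of bin indices) is drawn as a bar along
    the x axis, marking per-bin post-hoc differences.
    """
    import matplotlib.pyplot as plt

    from .timeseries import group_curves

    if ax is None:
        _, ax = plt.subplots()
    curves = group_curves(long_df, group, dv, within)
    for g, chunk in curves.groupby(group):
        ax.plot(chunk[within], chunk["mean"], label=str(g))
        ax.fill_between(
            chunk[within],
            chunk["mean"] - chunk["sem"],
            chunk["mean"] + chunk["sem"],
            alpha=0.25,
        )
    if significant_bins is not None and len(significant_bins):
        y = curves["mean"].min()
        ax.plot(
            np.asarray(list(significant_bins)),
            np.full(len(significant_bins), y),
            "k.",
            markersize=4,
        )
    ax.set_xlabel("time bin")
    ax.set_ylabel(dv)
    ax.legend()
    return ax


def plot_transition_graph(graph, ax=None, scale: float = 6.0):
    """Directed graph with edge width and grayscale coding the mean
    transition probability (darker and thicker = more likely)."""
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots()
    pos = nx.circular_layout(graph)
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)])
    wmax = weights.max() if weights.size else 1.0
    for (u, v, d) in graph.edges(data=True):
        w = d["weight"] / wmax if wmax > 0 else 0.0
        nx.draw_networkx_edges(
            graph,
            pos,
            edgelist=[(u, v)],
            width=0.5 + scale * w,
            edge_color=[(1 - w) * 0.85] * 3,
            connectionstyle="arc3,rad=0.15",
            ax=ax,
        )
    nx.draw_networkx_nodes(graph, pos, node_color="white", edgecolors="black", ax=ax)
    nx.draw_networkx_labels(graph, pos, font_size=8, ax=ax)
    ax.set_axis_off()
    return ax
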