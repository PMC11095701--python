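"""Optional matplotlib renderings of the report surfaces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import pandas as pd  # noqa: E402

from .community import CommunityPartition  # noqa: E402


def plot_hour_heatmap(heatmap: pd.DataFrame, path: str | Path) -> Path:
    """Hour-of-day × relationship heat map as a PNG."""
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(heatmap.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(heatmap.columns)), heatmap.columns)
    ax.set_yticks(range(0, 24, 2), range(0, 24, 2))
    ax.set_ylabel("hour of day")
    ax.set_title("Interaction frequency by hour and relationship")
    fig.colorbar(im, ax=ax, label="episodes")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_network(
    net: nx.Graph, partition: CommunityPartition | None, path: str | Path
) -> Path:
    """Spring layout with node size ∝ degree and colour = community."""
    pos = nx.spring_layout(net, seed=7, weight="weight")
    degrees = dict(net.degree())
    sizes = [30 + 12 * degrees[v] for v in net]
    colors = [partition.labels[v] if partition else 0 for v in net]
    widths = [0.3 + 0.05 * net[u][v].get("weight", 1) for u, v in net.edges()]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx_nodes(net, pos, node_size=sizes, node_color=colors,
                           cmap="tab10", ax=ax)
    nx.draw_networkx_edges(net, pos, width=widths, alpha=0.4, ax=ax)
    ax.set_axis_off()
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
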