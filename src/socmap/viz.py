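"""Static figure export for the connectivity graph.

One plot style: spring-layout graph where link thickness scales with the
group mean correlation, node diameter with degree, and node color with
community membership.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402

from .network import CommunityPartition, ConnectivityGraph  # noqa: E402


def plot_connectivity_graph(graph: ConnectivityGraph,
                            partition: CommunityPartition | None = None,
                            path=None, seed: int = 0):
    """Draw the thresholded ROI graph; returns the matplotlib figure."""
    g = graph.to_networkx()
    pos = nx.spring_layout(g, seed=seed, weight="weight")
    fig, ax = plt.subplots(figsize=(7, 6))

    widths = [6.0 * abs(g.edges[e]["r"]) for e in g.edges]
    styles = ["solid" if g.edges[e]["r"] >= 0 else "dashed" for e in g.edges]
    nx.draw_networkx_edges(g, pos, width=widths, style=styles,
                           edge_color="0.4", ax=ax)

    degrees = np.array([graph.degree.get(n, 0) for n in g.nodes])
    sizes = 300 + 160 * degrees
    if partition is not None:
        modules = [partition.assignment[n] for n in g.nodes]
        cmap = plt.get_cmap("tab10")
        colors = [cmap(m % 10) for m in modules]
    else:
        colors = "tab:blue"
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color=colors,
                           edgecolors="black", ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=8, ax=ax)
    ax.set_axis_off()
    ax.set_title("ROI functional connectivity "
                 f"(|r| > {graph.threshold:.3f}; solid +, dashed −)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
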