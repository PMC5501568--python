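"""Basic plot exports: U-matrix heatmap, cluster/site map, cluster means."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_umatrix(um, path=None, ax=None):
    """Heatmap of per-node mean neighbor distance."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(um.node_values, origin="lower", cmap="viridis")
    ax.set_title("U-matrix (mean neighbor distance)")
    ax.figure.colorbar(im, ax=ax, label="distance (normalized units)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_site_map(cluster_raster, design_frame, path=None, ax=None):
    """Cluster raster with the selected sampling sites overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    vals = np.ma.masked_invalid(cluster_raster.values)
    extent = [
        cluster_raster.origin_x - cluster_raster.cell_size / 2,
        cluster_raster.origin_x + cluster_raster.cell_size * (cluster_raster.shape[1] - 0.5),
        cluster_raster.origin_y - cluster_raster.cell_size / 2,
        cluster_raster.origin_y + cluster_raster.cell_size * (cluster_raster.shape[0] - 0.5),
    ]
    ax.imshow(vals, origin="lower", extent=extent, cmap="tab10", interpolation="nearest")
    bmu = design_frame[design_frame["role"] == "BMU"]
    extra = design_frame[design_frame["role"] != "BMU"]
    ax.scatter(extra["x"], extra["y"], c="white", edgecolors="k", s=25,
               label="additional site")
    ax.scatter(bmu["x"], bmu["y"], c="red", edgecolors="k", s=70, marker="*",
               label="BMU site")
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    ax.legend(loc="upper right")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_cluster_means(anova_results, path=None):
    """Bar chart of cluster means +- SE, one panel per indicator."""
    results = list(anova_results)
    fig, axes = plt.subplots(1, len(results), figsize=(3.2 * len(results), 3.5),
                             squeeze=False)
    for ax, res in zip(axes[0], results):
        g = res.group_stats
        ax.bar([str(c) for c in g["cluster"]], g["mean"], yerr=g["se"],
               capsize=4, color=["#4c72b0", "#c44e52", "#55a868"][: len(g)])
        for i, c in enumerate(g["cluster"]):
            ax.text(i, g["mean"].iloc[i], res.letters.get(c, ""),
                    ha="center", va="bottom")
        ax.set_title(f"{res.indicator}\nF={res.f_statistic:.2f}, p={res.p_value:.3g}")
        ax.set_xlabel("cluster")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
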