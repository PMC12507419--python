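"""Z-scoring, hierarchical clustering and heatmap-ready exports.

The selected gene set is standardized per gene (Z-score across samples)
and clustered agglomeratively with Euclidean distance; the tree is cut to
a user-chosen number of clusters with distinct expression patterns. The
heatmap itself is a thin export: Z-scored values in dendrogram leaf order
plus cluster labels, so any plotting front-end can draw it (an optional
matplotlib renderer is included as a convenience, not a contract).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "complete", "ward")


@dataclass
class ClusterAssignment:
    """A k-cluster partition of genes (or samples) with its merge tree.

    ``labels`` maps item id -> cluster index in 1..k; clusters partition
    the item set, so cluster sizes always sum to the number of items.
    """

    labels: pd.Series
    linkage: np.ndarray
    k: int

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Center each gene row to mean 0 and scale to (sample) SD 1.

    Zero-variance rows are set to all-zero with a warning.
    """
    values = expr.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sds.ravel() == 0) | ~np.isfinite(sds.ravel())
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) set to zero during Z-scoring",
            RuntimeWarning, stacklevel=2,
        )
    safe_sds = np.where(sds == 0, 1.0, sds)
    z = (values - means) / safe_sds
    z[flat, :] = 0.0
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def hierarchical_clusters(expr: pd.DataFrame, genes=None, k: int = 6,
                          axis: str = "genes",
                          method: str = "average") -> ClusterAssignment:
    """Agglomerative clustering of Z-scored expression.

    Parameters
    ----------
    expr : genes x samples expression matrix
    genes : optional gene subset (typically the optimal set)
    k : number of clusters the tree is cut into
    axis : {"genes", "samples"} what to cluster
    method : linkage method, one of {"average", "complete", "ward"}
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}, got {method!r}")
    if axis not in ("genes", "samples"):
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if genes is not None:
        expr = expr.loc[list(genes)]
    z = zscore_rows(expr)
    data = z if axis == "genes" else z.T
    n_items = data.shape[0]
    if not 1 <= k <= n_items:
        raise ValueError(f"k={k} must be in [1, {n_items}]")
    if n_items == 1:
        return ClusterAssignment(
            labels=pd.Series([1], index=data.index), linkage=np.empty((0, 4)),
            k=1,
        )
    tree = linkage(data.to_numpy(), method=method, metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # relabel clusters 1..k in order of first appearance (input-order stable)
    remap, labels = {}, []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return ClusterAssignment(
        labels=pd.Series(labels, index=data.index, name="cluster"),
        linkage=tree,
        k=k,
    )


def heatmap_table(expr: pd.DataFrame, assignment: ClusterAssignment,
                  genes=None) -> pd.DataFrame:
    """Z-scored values in dendrogram leaf order with a cluster column."""
    if genes is not None:
        expr = expr.loc[list(genes)]
    z = zscore_rows(expr)
    if assignment.linkage.shape[0] > 0:
        order = leaves_list(assignment.linkage)
        items = assignment.labels.index[order]
    else:
        items = assignment.labels.index
    if set(items) <= set(z.index):
        table = z.loc[items]
    else:  # sample-axis clustering: order columns instead
        table = z[items].T
    table = table.copy()
    table.insert(0, "cluster", assignment.labels.loc[items].to_numpy())
    return table


def render_heatmap(table: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a heatmap table (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = table.drop(columns=["cluster"])
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * values.shape[1]), max(4.0, 0.02 * len(values)))
    )
    im = ax.imshow(values.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-3, vmax=3, interpolation="nearest")
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels(values.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
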