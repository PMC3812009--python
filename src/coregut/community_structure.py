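"""Abundant-OTU selection and two-way hierarchical clustering.

The heatmap analysis restricts the normalised table to OTUs whose share of
the grand total is at least a threshold (default 0.1%), then clusters both
samples and OTUs agglomeratively on their abundance profiles.  Distances
are Bray–Curtis on relative abundances (default) or Euclidean on
log10(x+1) counts; linkage is average (UPGMA, default) or complete.  Both
dendrograms export to Newick with ultrametric branch lengths derived from
the merge heights.

Sequence-based phylogenies cannot be computed from a count table, so the
axis trees here are abundance-profile dendrograms — the nearest computable
structure to a cladogram annotation of a heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import OtuTable, ValidationError

__all__ = [
    "select_abundant_otus",
    "Dendrogram",
    "hierarchical_cluster",
    "HeatmapResult",
    "heatmap_analysis",
    "plot_heatmap",
]

_DISTANCES = ("bray_curtis", "euclidean_on_log")
_LINKAGES = ("average", "complete")


def select_abundant_otus(
    table: OtuTable, threshold: float = 0.001
) -> tuple[list[str], float]:
    """OTUs whose grand-total share is >= ``threshold``.

    Returns the selected ids (table column order) and the fraction of all
    sequences those OTUs cover.  Selection is monotone in the threshold.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    pooled = table.counts.sum(axis=0)
    total = pooled.sum()
    if total <= 0:
        raise ValidationError("table has no reads")
    share = pooled / total
    mask = share >= threshold
    selected = list(pooled.index[mask])
    return selected, float(share[mask].sum())


@dataclass
class Dendrogram:
    """Agglomerative tree over labelled units."""

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str
    metric: str

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels at ``k`` clusters."""
        flat = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def to_newick(self, path: str | Path | None = None) -> str:
        """Newick string with ultrametric branch lengths.

        Each edge length is the difference between the parent's and the
        child's merge height (leaves sit at height 0).
        """
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            inner = ",".join(
                render(child, node.dist) for child in (node.left, node.right)
            )
            return f"({inner}):{length:.10g}"

        if tree.is_leaf():  # single unit — degenerate, guarded upstream
            text = f"{self.labels[tree.id]};"
        else:
            inner = ",".join(
                render(child, tree.dist) for child in (tree.left, tree.right)
            )
            text = f"({inner});"
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _distance_matrix(matrix: np.ndarray, metric: str) -> np.ndarray:
    if metric == "bray_curtis":
        rowsums = matrix.sum(axis=1, keepdims=True)
        if np.any(rowsums == 0):
            raise ValidationError("cannot take Bray-Curtis of an all-zero unit")
        return pdist(matrix / rowsums, metric="braycurtis")
    if metric == "euclidean_on_log":
        return pdist(np.log10(matrix + 1.0), metric="euclidean")
    raise ValidationError(f"distance must be one of {_DISTANCES}")


def hierarchical_cluster(
    matrix: pd.DataFrame,
    axis: str = "samples",
    distance: str = "bray_curtis",
    linkage: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of samples (rows) or OTUs (columns).

    ``matrix`` is a samples x OTUs abundance frame (counts or relative
    abundances).  Bray–Curtis profiles are row-normalised along the chosen
    axis before the distance is taken.  The agglomeration is deterministic
    for a fixed input order.
    """
    if axis == "samples":
        data = matrix
    elif axis == "otus":
        data = matrix.T
    else:
        raise ValidationError("axis must be 'samples' or 'otus'")
    if data.shape[0] < 2:
        raise ValidationError(f"need >= 2 units on axis {axis!r} to cluster")
    if linkage not in _LINKAGES:
        raise ValidationError(f"linkage must be one of {_LINKAGES}")
    dvec = _distance_matrix(data.to_numpy(dtype=float), distance)
    Z = hierarchy.linkage(dvec, method=linkage)
    return Dendrogram(
        labels=[str(x) for x in data.index],
        linkage_matrix=Z,
        method=linkage,
        metric=distance,
    )


@dataclass
class HeatmapResult:
    """Selected OTUs, ordered abundance matrix and both axis trees."""

    otu_ids: list[str]
    covered_fraction: float
    matrix: pd.DataFrame  # samples x selected OTUs, display scale
    sample_tree: Dendrogram
    otu_tree: Dendrogram

    def ordered_matrix(self) -> pd.DataFrame:
        return self.matrix.loc[
            self.sample_tree.leaf_order, self.otu_tree.leaf_order
        ]


def heatmap_analysis(
    table: OtuTable,
    threshold: float = 0.001,
    distance: str = "bray_curtis",
    linkage: str = "average",
    log_scale: bool = True,
) -> HeatmapResult:
    """Select abundant OTUs and cluster both axes for heatmap rendering.

    The display matrix holds per-sample relative abundances of the selected
    OTUs (log10(x + 1e-5) if ``log_scale``); clustering runs on the selected
    raw counts with the requested distance.
    """
    selected, covered = select_abundant_otus(table, threshold)
    if len(selected) < 2:
        raise ValidationError(
            "fewer than 2 OTUs pass the abundance threshold; lower it"
        )
    sub = table.counts[selected]
    rel = sub.div(table.depths, axis=0)
    display = np.log10(rel + 1e-5) if log_scale else rel
    sample_tree = hierarchical_cluster(sub, "samples", distance, linkage)
    otu_tree = hierarchical_cluster(sub, "otus", distance, linkage)
    return HeatmapResult(
        otu_ids=selected,
        covered_fraction=covered,
        matrix=display,
        sample_tree=sample_tree,
        otu_tree=otu_tree,
    )


def plot_heatmap(result: HeatmapResult, path: str | Path) -> None:
    """Render the ordered matrix as a PNG/PDF heatmap (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = result.ordered_matrix()
    fig, ax = plt.subplots(
        figsize=(max(6, 0.08 * mat.shape[1]), max(4, 0.25 * mat.shape[0]))
    )
    im = ax.pcolormesh(mat.to_numpy(), cmap="viridis")
    ax.set_yticks(np.arange(mat.shape[0]) + 0.5, mat.index, fontsize=5)
    ax.set_xticks([])
    ax.set_xlabel(f"{mat.shape[1]} OTUs")
    fig.colorbar(im, ax=ax, label="abundance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
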