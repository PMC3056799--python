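"""Hierarchical clustering of arrays (UPGMA / average linkage).

Arrays are compared by 1 - Pearson correlation of their log2 signal
profiles over the present-filtered probe universe (Euclidean distance is
available by flag) and agglomerated with average linkage. Samples are
canonicalised by id before clustering, so the tree is deterministic and
invariant to the input sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, StatisticsError
from .differential import log_transform
from .io_formats import ExpressionExperiment


@dataclass
class Dendrogram:
    """A binary merge tree over sample ids with merge heights."""

    sample_ids: tuple
    linkage: np.ndarray  # scipy linkage matrix over sample_ids order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Serialise with branch lengths (leaf height 0, length = parent
        height minus child height)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def upgma(dissimilarity, labels) -> Dendrogram:
    """Average-linkage agglomeration of a square dissimilarity matrix."""
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigurationError("dissimilarity must be a square matrix")
    if len(labels) != D.shape[0]:
        raise ConfigurationError("labels must match the matrix dimension")
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return Dendrogram(sample_ids=tuple(labels), linkage=Z)


def cluster_arrays(
    exp: ExpressionExperiment,
    probe_subset=None,
    metric: str = "correlation",
    floor: float = 1.0,
) -> Dendrogram:
    """Average-linkage dendrogram of the experiment's arrays.

    ``probe_subset`` should normally be the present-filtered universe. A
    sample with a constant profile has no defined correlation and raises
    :class:`StatisticsError` naming the sample.
    """
    if len(exp.sample_ids) < 3:
        raise ConfigurationError("clustering needs at least 3 samples")
    log2 = log_transform(exp, floor=floor)
    if probe_subset is not None:
        log2 = log2.loc[list(probe_subset)]
    order = sorted(exp.sample_ids)
    X = log2[order].to_numpy().T  # samples x probes

    if metric == "correlation":
        sds = X.std(axis=1)
        if (sds == 0).any():
            bad = order[int(np.argmax(sds == 0))]
            raise StatisticsError(
                f"sample {bad!r} has a constant profile; correlation undefined"
            )
        D = pdist(X, metric="correlation")  # = 1 - Pearson r
    elif metric == "euclidean":
        D = pdist(X, metric="euclidean")
    else:
        raise ConfigurationError(f"unknown distance metric {metric!r}")
    return upgma(squareform(D), order)


def cut_tree(dend: Dendrogram, k: int) -> pd.Series:
    """Partition the samples into ``k`` groups by removing the k-1 highest
    merges. Returns a Series sample_id -> cluster label (1..k)."""
    n = len(dend.sample_ids)
    if not 1 <= k <= n:
        raise ConfigurationError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(dend.linkage, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(dend.sample_ids), name="cluster")
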