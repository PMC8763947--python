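"""Hierarchical clustering of samples and per-cluster resistance summaries.

Samples (matrix columns) are clustered agglomeratively with complete linkage
on Euclidean distances over the full gene space.  Cutting the tree at k = 2
separates the two main expression clusters; per cluster, the fraction of
therapy-resistant models is reported with nearest-integer percentages
recomputed from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from pdxnet.io import ExpressionMatrix


def round_percent(x: float) -> int:
    """Nearest-integer percentage, halves rounding up."""
    return int(np.floor(x + 0.5))


@dataclass
class ClusterAssignment:
    """Agglomeration tree over samples (scipy linkage encoding)."""

    linkage: np.ndarray          # (n-1, 4) merge table
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child1", "child2", "height", "size"]
        ).astype({"child1": int, "child2": int, "size": int})


def hierarchical_cluster(expr: ExpressionMatrix) -> ClusterAssignment:
    """Complete-linkage, Euclidean-distance tree over sample columns."""
    if expr.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    X = expr.data.to_numpy(dtype=float).T
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    return ClusterAssignment(linkage=Z, sample_ids=expr.sample_ids)


def cut_tree(tree: ClusterAssignment, k: int = 2) -> pd.Series:
    """Cluster labels from cutting the tree into exactly k groups.

    Labels are renumbered by decreasing cluster size (cluster 1 = largest;
    size ties keep the original dendrogram order).
    """
    n = tree.n_samples
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    return pd.Series(labels, index=tree.sample_ids, name="cluster")


def resistance_by_cluster(labels: pd.Series, resistant_flags) -> pd.DataFrame:
    """Per-cluster totals, resistant counts and rounded percentages."""
    flags = np.asarray(resistant_flags, dtype=bool)
    if len(flags) != len(labels):
        raise ValueError("labels and resistant flags must have equal length")
    rows = []
    for cluster in sorted(labels.unique()):
        mask = labels.to_numpy() == cluster
        n_total = int(mask.sum())
        n_resistant = int(flags[mask].sum())
        rows.append(
            {
                "cluster": int(cluster),
                "n_total": n_total,
                "n_resistant": n_resistant,
                "percent_resistant": round_percent(100.0 * n_resistant / n_total),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
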