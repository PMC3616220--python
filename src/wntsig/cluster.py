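"""Sample stratification by hierarchical clustering on signature probes.

Samples of the primary-tumour cohort are clustered on the Euclidean distance
over the signature-probe dimensions with complete-linkage agglomeration, and
the tree is cut into k = 2 groups.  Cluster labels are oriented by expression:
cluster 1 is the cluster with the higher mean expression over the
positive-sign signature probes (the poor-prognosis, signature-high group),
which makes labels invariant to input sample order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

__all__ = ["ClusterAssignment", "hierarchical_cluster", "adjusted_rand_index"]


@dataclass
class ClusterAssignment:
    """Sample -> {1,2,...} labels plus the linkage merge history."""

    labels: dict[str, int]
    linkage_tree: np.ndarray  # scipy linkage matrix (merges + heights)

    def group(self, label: int) -> list[str]:
        return [s for s, l in self.labels.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["sample_id", "cluster"]
        )


def hierarchical_cluster(
    matrix,
    signature_probes: list[str],
    k: int = 2,
    positive_probes: list[str] | None = None,
    min_probes: int = 3,
    row_scale: str | None = None,
) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering of samples on signature probes.

    Parameters
    ----------
    matrix
        ExpressionMatrix covering the cohort to stratify.
    signature_probes
        Probe ids defining the feature space; probes missing from the matrix
        below ``min_probes`` raise an error listing them.
    positive_probes
        Probes of the signature's positive arm, used for the orientation rule;
        defaults to all signature probes found.
    row_scale
        ``None`` (default, raw values) or ``'zscore'`` to standardize each
        probe row before computing distances.
    """
    present = [p for p in signature_probes if p in matrix.data.index]
    missing = [p for p in signature_probes if p not in matrix.data.index]
    if len(present) < min_probes:
        raise ValueError(
            f"only {len(present)} signature probes found (min {min_probes}); "
            f"missing: {missing}"
        )
    if matrix.n_samples < k:
        raise ValueError(f"need at least k={k} samples, got {matrix.n_samples}")

    # Sort samples lexicographically so agglomeration ties break identically
    # regardless of input column order.
    order = sorted(matrix.sample_ids)
    sub = matrix.data.loc[present, order]
    if row_scale == "zscore":
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError("zscore scaling undefined for constant probe rows")
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    elif row_scale is not None:
        raise ValueError(f"unknown row_scale: {row_scale!r}")

    X = sub.to_numpy().T  # samples x probes
    dists = pdist(X, metric="euclidean")
    if np.all(dists == 0):
        raise ValueError("all samples identical: distances degenerate")
    Z = linkage(dists, method="complete")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(set(raw)) < k:
        raise ValueError(f"could not separate {k} clusters (tied heights)")

    # Orientation: cluster 1 = higher mean expression over positive-arm probes.
    pos = [p for p in (positive_probes or present) if p in sub.index]
    if not pos:
        pos = present
    sample_means = matrix.data.loc[pos, order].mean(axis=0).to_numpy()
    cluster_means = {
        c: float(sample_means[raw == c].mean()) for c in np.unique(raw)
    }
    ranked = sorted(cluster_means, key=lambda c: (-cluster_means[c], c))
    relabel = {c: i + 1 for i, c in enumerate(ranked)}
    labels = {s: relabel[c] for s, c in zip(order, raw)}
    return ClusterAssignment(labels=labels, linkage_tree=Z)


def adjusted_rand_index(a: dict[str, int], b: dict[str, int]) -> float:
    """Permutation-model adjusted Rand index between two labelings.

    Both labelings must cover the same sample set.
    """
    if set(a) != set(b):
        raise ValueError("labelings cover different sample sets")
    keys = sorted(a)
    return float(adjusted_rand_score([a[k] for k in keys], [b[k] for k in keys]))
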