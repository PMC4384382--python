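"""Moderated log transform, variance filtering, hierarchical clustering, PCA.

The transform is ``log2(K / s + 1)``: a deterministic stand-in for a
regularized-log transform that likewise compresses between-sample
differences for low-count genes so they do not dominate Euclidean
distances.  Clustering is agglomerative with complete linkage on Euclidean
distances; PCA is a gene-centered SVD of the samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ValidationError


def rlog_surrogate(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Shifted-log transform of size-factor-normalized counts."""
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / s[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def top_variance_genes(matrix: pd.DataFrame, fraction: float = 0.5) -> pd.Index:
    """The top ``fraction`` of genes by across-sample variance (ddof=1).

    Ties are broken by gene identifier order, so the selection is
    deterministic regardless of row order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 samples to rank by variance")
    var = matrix.to_numpy(dtype=float).var(axis=1, ddof=1)
    k = math.ceil(fraction * len(var))
    order = np.lexsort((matrix.index.to_numpy(), -var))  # variance desc, then id
    return matrix.index[np.sort(order[:k])]


@dataclass
class Dendrogram:
    """Agglomerative clustering result (scipy linkage matrix + leaf labels)."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Cut into ``k`` flat clusters; returns label -> cluster id."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def cophenetic_nearest(self) -> dict[str, str]:
        """For each leaf, the leaf that joins it at the lowest merge height."""
        n = len(self.labels)
        coph = hierarchy.cophenet(self.linkage)
        d = np.zeros((n, n))
        d[np.triu_indices(n, 1)] = coph
        d += d.T
        np.fill_diagonal(d, np.inf)
        return {
            self.labels[i]: self.labels[int(np.argmin(d[i]))] for i in range(n)
        }

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def hierarchical_cluster(matrix: pd.DataFrame, axis: str = "samples") -> Dendrogram:
    """Complete-linkage agglomerative clustering on Euclidean distances.

    ``axis='samples'`` clusters columns, ``axis='genes'`` rows.  Ordering is
    deterministic given input order (scipy breaks distance ties by index).
    """
    if axis == "samples":
        data = matrix.to_numpy(dtype=float).T
        labels = [str(c) for c in matrix.columns]
    elif axis == "genes":
        data = matrix.to_numpy(dtype=float)
        labels = [str(i) for i in matrix.index]
    else:
        raise ValidationError(f"axis must be 'samples' or 'genes', got {axis!r}")
    if len(labels) < 2:
        raise ValidationError("need >= 2 items to cluster")
    link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    return Dendrogram(linkage=link, labels=labels)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained: np.ndarray  # variance fractions, non-increasing
    loadings: pd.DataFrame  # genes x components


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Gene-centered PCA of the samples.

    Sign convention: within each component the largest-magnitude gene
    loading is made positive.  Explained-variance fractions sum to 1 over
    all components.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need >= 2 samples for PCA")
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # fix signs: largest |loading| positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp),
        explained=explained,
        loadings=pd.DataFrame(vt.T, index=matrix.index, columns=comp),
    )
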