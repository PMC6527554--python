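"""Exploratory statistics: sample correlations, hierarchical clustering,
PCA and t-SNE embeddings of log2CPM profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .io import CountDataError
from .normalize import center_rows

__all__ = [
    "EmbeddingResult",
    "ClusterTree",
    "correlation_matrix",
    "hierarchical_cluster",
    "pca_embedding",
    "tsne_embedding",
]


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # samples x k
    method: str
    explained_variance: np.ndarray | None = None
    seed: int | None = None


@dataclass
class ClusterTree:
    """Dendrogram encoding: scipy-format merge matrix plus leaf labels."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def correlation_matrix(log2cpm: np.ndarray) -> np.ndarray:
    """Sample x sample Pearson correlations of expression columns."""
    m = np.asarray(log2cpm, dtype=float)
    if m.shape[1] < 2:
        raise CountDataError("correlation needs at least 2 samples")
    sd = m.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise CountDataError(
            f"zero-variance sample column(s) {bad}: correlation undefined"
        )
    return np.corrcoef(m, rowvar=False)


def hierarchical_cluster(
    matrix: np.ndarray,
    labels: list[str] | None = None,
    distance: str = "one-minus-correlation",
    linkage_method: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of columns (samples) or rows.

    ``distance`` is ``one-minus-correlation`` (1 - Pearson between
    columns) or ``euclidean`` (between columns).  Agglomeration is
    deterministic; equal distances resolve to the smallest index pair.
    """
    m = np.asarray(matrix, dtype=float)
    if linkage_method not in ("average", "complete"):
        raise CountDataError(f"unsupported linkage {linkage_method!r}")
    if distance == "one-minus-correlation":
        d = 1.0 - correlation_matrix(m)
        np.fill_diagonal(d, 0.0)
        d = np.maximum((d + d.T) / 2.0, 0.0)
        condensed = squareform(d, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(m.T, metric="euclidean")
    else:
        raise CountDataError(f"unsupported distance {distance!r}")
    if np.any(~np.isfinite(condensed)):
        raise CountDataError("non-finite distances: cannot cluster")
    Z = linkage(condensed, method=linkage_method)
    n = m.shape[1]
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    if len(labels) != n:
        raise CountDataError("labels length does not match the number of items")
    return ClusterTree(merges=Z, labels=list(labels))


def pca_embedding(matrix: np.ndarray, k: int) -> EmbeddingResult:
    """Project samples onto the top-k principal components of the
    gene-centered log2CPM matrix (genes x samples in, samples x k out)."""
    m = np.asarray(matrix, dtype=float)
    n_genes, n_samples = m.shape
    if k > min(n_samples - 1, n_genes):
        raise CountDataError(
            f"k={k} exceeds min(samples-1, genes) = {min(n_samples - 1, n_genes)}"
        )
    centered = center_rows(m)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(centered.T)
    return EmbeddingResult(
        coordinates=coords,
        method="pca",
        explained_variance=pca.explained_variance_ratio_,
    )


def tsne_embedding(
    matrix: np.ndarray, k: int = 2, perplexity: float = 5.0, seed: int = 0
) -> EmbeddingResult:
    """t-SNE embedding of samples; identical seed gives identical
    coordinates.  Requires perplexity < (samples - 1) / 3."""
    m = np.asarray(matrix, dtype=float)
    n_samples = m.shape[1]
    limit = (n_samples - 1) / 3.0
    if perplexity >= limit:
        raise CountDataError(
            f"perplexity {perplexity} too large for {n_samples} samples; "
            f"must be < (samples-1)/3 = {limit:.2f}"
        )
    ts = TSNE(
        n_components=k,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=500,
    )
    coords = ts.fit_transform(center_rows(m).T)
    return EmbeddingResult(coordinates=coords, method="tsne", seed=seed)
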