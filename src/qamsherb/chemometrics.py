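"""Batch classification: hierarchical clustering and correlation-matrix PCA.

PCA operates on the correlation matrix of the common-peak area matrix
(each peak z-scored), so eigenvalues sum to the number of peaks and the
percent variance of component k is 100 * lambda_k / p.  Clustering is
agglomerative on Euclidean distance (Ward linkage by default) with an
optional SPSS-style rescaling of merge heights to 0-25 so that cuts
quoted on that axis are interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring (mean 0, sample SD 1); constant columns are
    dropped with a warning since they carry no variance."""
    if len(matrix) < 2:
        raise ValueError("standardization needs at least 2 rows")
    sd = matrix.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    return (matrix - matrix.mean(axis=0)) / sd


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    percent_variance: np.ndarray  # 100 * lambda / p
    cumulative_percent: np.ndarray
    scores: pd.DataFrame  # batches x components
    loadings: pd.DataFrame  # peaks x components

    def report(self) -> pd.DataFrame:
        """Eigenvalue table: component, eigenvalue, % variance, cumulative %."""
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": np.round(self.eigenvalues, 3),
                "percent_variance": np.round(self.percent_variance, 3),
                "cumulative_percent": np.round(self.cumulative_percent, 3),
            }
        )


def pca_correlation(matrix: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of columns.

    Scores are the z-scored data projected on the eigenvectors; each
    loading vector's largest-magnitude element is made positive so the
    component signs are deterministic.  Rank-deficient input yields
    trailing (near-)zero eigenvalues, not an error.
    """
    if len(matrix) < 3:
        raise ValueError("correlation PCA needs at least 3 rows")
    z = standardize(matrix)
    corr = np.corrcoef(z.to_numpy(float), rowvar=False)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    p = corr.shape[0]
    percent = 100.0 * eigval / p
    comp_ids = [f"PC{k + 1}" for k in range(p)]
    scores = pd.DataFrame(z.to_numpy(float) @ eigvec, index=matrix.index, columns=comp_ids)
    loadings = pd.DataFrame(eigvec, index=z.columns, columns=comp_ids)
    return PCAResult(
        eigenvalues=eigval,
        percent_variance=percent,
        cumulative_percent=np.cumsum(percent),
        scores=scores,
        loadings=loadings,
    )


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    heights: np.ndarray  # merge heights, non-decreasing
    rescaled_heights: np.ndarray  # SPSS-style 0-25 axis
    labels: pd.Series  # cluster id per batch (1-based), or all 1 without a cut
    leaf_order: list  # dendrogram leaf order (row ids)


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "ward",
    cut_distance: float | None = None,
    standardize_first: bool = True,
    rescale: bool = False,
) -> ClusterResult:
    """Agglomerative clustering of batches on their peak-area vectors.

    ``cut_distance`` is interpreted on the raw merge heights, or on the
    0-25 rescaled axis when ``rescale`` is set (the convention of the
    statistics packages that print dendrograms on that axis).
    """
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 rows")
    if linkage not in ("ward", "average", "complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    data = standardize(matrix) if standardize_first else matrix
    dist = pdist(data.to_numpy(float), metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    heights = z[:, 2].copy()
    max_h = heights.max() if heights.max() > 0 else 1.0
    rescaled = 25.0 * heights / max_h

    if cut_distance is None:
        flat = np.ones(len(matrix), dtype=int)
    else:
        t = cut_distance * max_h / 25.0 if rescale else cut_distance
        flat = hierarchy.fcluster(z, t=t, criterion="distance")
    labels = pd.Series(flat, index=matrix.index, name="cluster")
    labels = _canonical_labels(labels)
    return ClusterResult(
        linkage_matrix=z,
        heights=heights,
        rescaled_heights=rescaled,
        labels=labels,
        leaf_order=_canonical_leaf_order(z, list(matrix.index)),
    )


def _canonical_labels(labels: pd.Series) -> pd.Series:
    """Renumber clusters so the cluster holding the lexically smallest
    row id is 1, the next 2, ...; makes labels row-order invariant."""
    firsts = {c: min(str(i) for i in labels.index[labels == c]) for c in labels.unique()}
    remap = {c: k + 1 for k, c in enumerate(sorted(firsts, key=firsts.get))}
    return labels.map(remap).rename("cluster")


def _canonical_leaf_order(z: np.ndarray, ids: list) -> list:
    """Dendrogram leaf order with children sorted by their subtree's
    lexically smallest row id; row-order invariant for labeled input."""
    n = len(ids)

    def walk(node: int) -> list:
        if node < n:
            return [ids[node]]
        left, right = int(z[node - n, 0]), int(z[node - n, 1])
        a, b = walk(left), walk(right)
        return a + b if min(map(str, a)) <= min(map(str, b)) else b + a

    return walk(2 * n - 2)


def heatmap_matrix(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    linkage: str = "ward",
) -> pd.DataFrame:
    """Column-z-scored matrix with rows and columns permuted into
    dendrogram leaf order, ready for heatmap rendering."""
    z = standardize(matrix)
    row_order = hierarchical_cluster(z, metric=metric, linkage=linkage, standardize_first=False).leaf_order
    col_order = hierarchical_cluster(z.T, metric=metric, linkage=linkage, standardize_first=False).leaf_order
    return z.loc[row_order, col_order]
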