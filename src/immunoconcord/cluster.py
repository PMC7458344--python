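"""Matrix preprocessing, SVD imputation, hierarchical clustering and PCA.

These reproduce the heatmap/ordination conventions of the study's figures:
unit-variance row scaling, iterative SVD imputation of missing values,
agglomerative clustering under euclidean/manhattan/correlation distances
with complete or average linkage, and principal components with 95%
prediction ellipses per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA as _SKPCA


class SVDImputer(TransformerMixin, BaseEstimator):
    """Iterative low-rank SVD imputation of missing matrix entries.

    Missing entries are initialized to row means, then the matrix is
    repeatedly truncated to ``rank`` singular values and the missing entries
    replaced by the reconstruction, until the largest absolute change in any
    imputed entry falls below ``tol`` or ``max_iter`` is reached.  Observed
    entries are never altered.

    Parameters
    ----------
    rank:
        Truncation rank; default ``min(matrix dims) - 1`` capped at 10.
    tol:
        Convergence threshold on the max absolute change of imputed entries.
    max_iter:
        Iteration cap; hitting it sets ``converged_ = False`` with a warning
        but still returns the current estimate.
    """

    def __init__(self, rank: Optional[int] = None, tol: float = 1e-6, max_iter: int = 100):
        self.rank = rank
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        index = columns = None
        if isinstance(X, pd.DataFrame):
            index, columns = X.index, X.columns
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        mask = np.isnan(X)
        if mask.all(axis=1).any():
            raise ValueError("matrix has an all-missing row")
        if mask.all(axis=0).any():
            raise ValueError("matrix has an all-missing column")
        rank = self.rank if self.rank is not None else min(10, min(X.shape) - 1)
        if not 1 <= rank < min(X.shape):
            raise ValueError(f"rank must satisfy 1 <= rank < min(dim); got {rank} for shape {X.shape}")

        self.n_iter_ = 0
        self.converged_ = True
        if not mask.any():
            out = X.copy()
        else:
            filled = X.copy()
            row_means = np.nanmean(X, axis=1)
            filled[mask] = np.broadcast_to(row_means[:, None], X.shape)[mask]
            self.converged_ = False
            for it in range(1, self.max_iter + 1):
                U, s, Vt = np.linalg.svd(filled, full_matrices=False)
                recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
                delta = np.max(np.abs(recon[mask] - filled[mask]))
                filled[mask] = recon[mask]
                self.n_iter_ = it
                if delta < self.tol:
                    self.converged_ = True
                    break
            if not self.converged_:
                warnings.warn(
                    f"SVD imputation did not converge in {self.max_iter} iterations (last change {delta:.3g})",
                    RuntimeWarning,
                    stacklevel=2,
                )
            out = filled
        if index is not None:
            return pd.DataFrame(out, index=index, columns=columns)
        return out

    def transform(self, X):
        # each matrix is imputed from its own structure; transform == fit_transform
        return self.fit_transform(X)


def svd_impute(matrix, rank: Optional[int] = None, tol: float = 1e-6, max_iter: int = 100):
    """Functional form of :class:`SVDImputer` (see its docstring)."""
    return SVDImputer(rank=rank, tol=tol, max_iter=max_iter).fit_transform(matrix)


def scale_rows(matrix: pd.DataFrame, mode: str = "unit_variance") -> pd.DataFrame:
    """Row scaling: ``none``, ``center`` (subtract row mean) or
    ``unit_variance`` (center then divide by the row standard deviation).

    Unit-variance scaling refuses zero-variance rows, naming the offender.
    """
    if mode == "none":
        return matrix.copy()
    if mode not in ("center", "unit_variance"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    if mode == "center":
        return centered
    sd = matrix.std(axis=1, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance rows cannot be unit-variance scaled: {list(zero)}")
    return centered.div(sd, axis=0)


@dataclass
class ClusterSpec:
    """Distance/linkage/scaling conventions for a clustered heatmap axis."""

    distance: str = "euclidean"
    linkage: str = "complete"
    row_scaling: str = "none"
    axis: str = "rows"

    def __post_init__(self) -> None:
        if self.distance not in ("euclidean", "manhattan", "correlation"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("complete", "average"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.row_scaling not in ("none", "center", "unit_variance"):
            raise ValueError(f"unknown row scaling {self.row_scaling!r}")
        if self.axis not in ("rows", "columns", "both"):
            raise ValueError(f"unknown axis {self.axis!r}")


def _distances(items: np.ndarray, distance: str) -> np.ndarray:
    if distance == "correlation":
        if items.shape[1] < 2:
            raise ValueError("correlation distance needs >= 2 features per item")
        if (items.std(axis=1) == 0).any():
            bad = int(np.argmax(items.std(axis=1) == 0))
            raise ValueError(f"constant item at position {bad} under correlation distance")
        return pdist(items, metric="correlation")  # 1 - Pearson r
    metric = "cityblock" if distance == "manhattan" else "euclidean"
    return pdist(items, metric=metric)


def hcluster(matrix: pd.DataFrame, spec: ClusterSpec, k: Optional[int] = None):
    """Agglomerative clustering of the rows of ``matrix`` under ``spec``.

    Returns ``(linkage_matrix, labels)`` where the linkage matrix is in
    scipy format (merge heights non-decreasing for complete/average linkage)
    and ``labels`` cuts the tree into ``k`` flat clusters (None -> no cut).
    Clustering columns is done by passing the transpose.  The agglomeration
    is deterministic for a fixed input; with distinct pairwise distances the
    merge order is independent of row order.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 items to cluster")
    data = scale_rows(matrix, spec.row_scaling)
    d = _distances(data.to_numpy(dtype=float), spec.distance)
    Z = hierarchy.linkage(d, method=spec.linkage)
    labels = None
    if k is not None:
        flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = pd.Series(flat, index=matrix.index, name="cluster")
    return Z, labels


def dendrogram_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: np.ndarray  # percent per component


def pca(matrix: pd.DataFrame, row_scaling: str = "unit_variance", impute: bool = True, n_components: Optional[int] = None) -> PCAResult:
    """Principal components of samples from a features x samples matrix.

    Missing entries are SVD-imputed first (when ``impute``), rows scaled per
    ``row_scaling``, then components computed by SVD of the centered sample
    cloud.  Components are ordered by decreasing explained variance, which is
    reported in percent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    data = matrix
    if impute and data.isna().to_numpy().any():
        data = svd_impute(data)
    data = scale_rows(data, row_scaling)
    X = data.to_numpy(dtype=float).T  # samples x features
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=matrix.index, columns=comp_names),
        variance_explained=model.explained_variance_ratio_ * 100.0,
    )


@dataclass
class Ellipse:
    """Prediction ellipse in a 2-D score plane: center, semi-axes, rotation."""

    center: np.ndarray
    semi_axes: np.ndarray  # major, minor
    angle: float  # radians, major axis vs x-axis
    probability: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (n, 2) array of points."""
        c, s = np.cos(self.angle), np.sin(self.angle)
        R = np.array([[c, s], [-s, c]])
        local = (np.asarray(points, dtype=float) - self.center) @ R.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + (local[:, 1] / self.semi_axes[1]) ** 2 <= 1.0


def prediction_ellipse(scores: np.ndarray, probability: float = 0.95) -> Ellipse:
    """Ellipse containing a new observation from the group with the given
    probability, assuming bivariate normality.

    The ellipse is the group mean offset by the chi-square(2 df) quantile
    scaling of the group's 2x2 covariance.  Requires >= 3 group members.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ValueError(f"prediction ellipse needs >= 3 group members, have {pts.shape[0]}")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(probability, df=2)
    semi = np.sqrt(np.clip(evals, 0, None) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle, probability=probability)


def distance_matrix(matrix: pd.DataFrame, distance: str) -> pd.DataFrame:
    """Square-form pairwise distance matrix between the rows of ``matrix``."""
    d = _distances(matrix.to_numpy(dtype=float), distance)
    return pd.DataFrame(squareform(d), index=matrix.index, columns=matrix.index)
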