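"""Scikit-learn style clusterers wrapping the linkage pipeline.

:class:`HCID` clusters interval-valued observations with the
overlapping-ratio distance; :class:`ConventionalHC` is the point-data
baseline using Euclidean distances on the interval centers (or on plain
points).  Both run agglomerative complete linkage on the resulting
precomputed distance matrix and cut the tree at ``n_clusters``.

Both estimators follow the scikit-learn contract (``get_params`` /
``set_params``, ``fit`` / ``fit_predict``, fitted attributes with a
trailing underscore) so they compose with ``sklearn.base.clone`` and
model-selection utilities.  One deliberate deviation: ``labels_`` are
``1..k`` with cluster 1 the largest, matching how flat cuts of a
dendrogram are reported here, rather than scikit-learn's 0-based labels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .hierarchy import complete_linkage, cut
from .intervals import IntervalMatrix, LabeledDataset
from .metrics import DistanceMatrix, euclidean_distance_matrix, or_distance_matrix

__all__ = ["HCID", "ConventionalHC"]


def as_interval_matrix(X) -> IntervalMatrix:
    """Coerce estimator input to an :class:`IntervalMatrix`.

    Accepts an :class:`IntervalMatrix`, a :class:`LabeledDataset`, a
    ``(centers, radii)`` pair, or a plain ``(n, 2J)`` array whose first J
    columns are centers and last J columns radii.
    """
    if isinstance(X, IntervalMatrix):
        return X
    if isinstance(X, LabeledDataset):
        return X.intervals
    if isinstance(X, tuple) and len(X) == 2:
        return IntervalMatrix(np.asarray(X[0]), np.asarray(X[1]))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] % 2:
        raise ValueError(
            "array input must have shape (n, 2J) with centers in the first J "
            f"columns and radii in the last J; got {arr.shape}"
        )
    j = arr.shape[1] // 2
    return IntervalMatrix(arr[:, :j], arr[:, j:])


class HCID(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of interval-valued data (HC-ID).

    Computes the pairwise overlapping-ratio distance of the interval
    observations, runs agglomerative complete linkage on it and cuts the
    dendrogram into ``n_clusters`` flat clusters.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of flat clusters to cut the tree into.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Cluster labels in ``1..n_clusters``, cluster 1 the largest.
    distance_matrix_ : DistanceMatrix
        The precomputed overlapping-ratio distances actually clustered.
    dendrogram_ : Dendrogram
        The full complete-linkage merge tree.
    n_features_in_ : int
        Number of interval features J.

    Examples
    --------
    >>> import numpy as np
    >>> from hcid import HCID
    >>> centers = np.array([[0.0], [0.1], [5.0]])
    >>> radii = np.array([[0.5], [0.5], [0.5]])
    >>> HCID(n_clusters=2).fit_predict((centers, radii))
    array([1, 1, 2])
    """

    def __init__(self, n_clusters: int = 2):
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        """Cluster interval data X (see :func:`as_interval_matrix` for forms)."""
        m = as_interval_matrix(X)
        if not 1 <= self.n_clusters <= m.n_obs:
            raise ValueError(
                f"n_clusters must be in 1..{m.n_obs}, got {self.n_clusters}"
            )
        self.interval_matrix_ = m
        self.distance_matrix_ = or_distance_matrix(m)
        self.dendrogram_ = complete_linkage(self.distance_matrix_)
        self.assignment_ = cut(self.dendrogram_, self.n_clusters)
        self.labels_ = self.assignment_.labels
        self.n_features_in_ = m.n_features
        return self


class ConventionalHC(ClusterMixin, BaseEstimator):
    """Conventional hierarchical clustering of point data (baseline).

    Euclidean distances on the observation points (for interval input,
    the centers), complete linkage, flat cut at ``n_clusters``.

    Parameters
    ----------
    n_clusters : int, default=2
    scale : bool, default=False
        Z-score features before computing distances.  Off by default: the
        baseline operates on raw feature scales.
    metric : {"euclidean", "precomputed"}, default="euclidean"
        With ``"precomputed"``, ``X`` is a square distance matrix (or
        :class:`DistanceMatrix`) and ``scale`` must be False.
    """

    def __init__(self, n_clusters: int = 2, scale: bool = False, metric: str = "euclidean"):
        self.n_clusters = n_clusters
        self.scale = scale
        self.metric = metric

    def fit(self, X, y=None):
        if self.metric not in ("euclidean", "precomputed"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric == "precomputed":
            if self.scale:
                raise ValueError("scale is meaningless with a precomputed matrix")
            if isinstance(X, DistanceMatrix):
                d = X
            else:
                d = DistanceMatrix(np.asarray(X, dtype=float), metric_tag="generic")
        else:
            if isinstance(X, (IntervalMatrix, LabeledDataset, tuple)):
                m = as_interval_matrix(X)
                points, ids = m.centers, m.obs_ids
            else:
                points = np.asarray(X, dtype=float)
                ids = None
            d = euclidean_distance_matrix(points, scale=self.scale, obs_ids=ids)
        if not 1 <= self.n_clusters <= d.n_obs:
            raise ValueError(f"n_clusters must be in 1..{d.n_obs}, got {self.n_clusters}")
        self.distance_matrix_ = d
        self.dendrogram_ = complete_linkage(d)
        self.assignment_ = cut(self.dendrogram_, self.n_clusters)
        self.labels_ = self.assignment_.labels
        if self.metric == "euclidean":
            self.n_features_in_ = points.shape[1]
        return self
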