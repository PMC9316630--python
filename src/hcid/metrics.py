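"""Overlapping-ratio similarity and distance for interval-valued data.

For one feature, the overlapping ratio of interval :math:`I` with respect
to interval :math:`I'` is the fraction of :math:`I` covered by their
intersection,

.. math:: OR(I, I') = |I \\cap I'| / |I|,

with :math:`|\\cdot|` the interval width.  It is asymmetric: a short
interval inside a long one is fully covered (OR = 1) while the long one is
only partly covered.  Averaging the two directions over all J features
gives the similarity

.. math:: S_{OR}^J(i, i') = \\frac{1}{2J} \\sum_j
          \\bigl[ OR(I_{ij}, I_{i'j}) + OR(I_{i'j}, I_{ij}) \\bigr]

and the dissimilarity :math:`D_{OR}^J = 1 - S_{OR}^J`, both in [0, 1].
:math:`D_{OR}^J` is symmetric with zero diagonal, and is invariant under
per-feature positive affine rescaling (widths and intersections scale
together), so no feature standardization is needed.

Degenerate (zero-width) intervals follow the width -> 0 limit: a point
covered by the other closed interval has OR = 1, otherwise 0; a
positive-width interval is never covered by a point (width-0
intersection, OR = 0).  Touching intervals such as [0,1] and [1,2]
intersect in a single point and therefore have OR = 0 in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .intervals import IntervalMatrix

__all__ = [
    "DistanceMatrix",
    "overlap_ratio",
    "pair_similarity",
    "pair_distance",
    "or_distance_matrix",
    "euclidean_distance_matrix",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric n x n dissimilarity matrix with zero diagonal.

    ``metric_tag`` records how it was computed (``"or_distance"`` entries
    are additionally bounded in [0, 1]).
    """

    values: np.ndarray
    metric_tag: str = "or_distance"
    obs_ids: tuple = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {v.shape}")
        if not np.allclose(v, v.T, rtol=0.0, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        if self.metric_tag == "or_distance" and (v > 1.0 + 1e-12).any():
            raise ValueError("or_distance entries must lie in [0, 1]")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        ids = self.obs_ids
        if ids is None:
            ids = tuple(str(i + 1) for i in range(v.shape[0]))
        else:
            ids = tuple(str(i) for i in ids)
            if len(ids) != v.shape[0]:
                raise ValueError(f"{len(ids)} obs ids for {v.shape[0]} observations")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "obs_ids", ids)

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.obs_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def to_csv(self, path) -> None:
        """Square CSV with observation ids as header and index."""
        self.to_frame().to_csv(path, index_label="obs_id")

    @classmethod
    def from_csv(cls, path, metric_tag: str = "or_distance") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0, comment="#", float_precision="round_trip")
        return cls(df.to_numpy(float), metric_tag=metric_tag, obs_ids=list(df.columns))

    def to_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style distance text for tree tools."""
        n = self.n_obs
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{n}\n")
            for i in range(n):
                row = " ".join(f"{self.values[i, j]:.10g}" for j in range(i))
                name = self.obs_ids[i][:10].ljust(10)
                fh.write(f"{name} {row}".rstrip() + "\n")


def _directed_or(lo_a, hi_a, lo_b, hi_b):
    """Elementwise OR(a, b) = |a n b| / |a| with the degenerate-width rules.

    Arguments broadcast; returns an array of the broadcast shape.
    """
    lo_a, hi_a, lo_b, hi_b = (
        np.asarray(x, dtype=float) for x in np.broadcast_arrays(lo_a, hi_a, lo_b, hi_b)
    )
    inter = np.clip(np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b), 0.0, None)
    width_a = hi_a - lo_a
    pos = width_a > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(pos, inter / np.where(pos, width_a, 1.0), 0.0)
    # width-0 "a": OR is 1 when the point lies inside closed [lo_b, hi_b]
    point_in = (lo_a >= lo_b) & (lo_a <= hi_b)
    return np.where(pos, ratio, point_in.astype(float))


def overlap_ratio(a, b) -> float:
    """OR(a, b) for two intervals given as (lower, upper) pairs."""
    lo_a, hi_a = (float(x) for x in a)
    lo_b, hi_b = (float(x) for x in b)
    if lo_a > hi_a or lo_b > hi_b:
        raise ValueError("interval lower bound exceeds upper bound")
    return float(_directed_or(lo_a, hi_a, lo_b, hi_b))


def _row_bounds(row_c, row_r):
    c = np.asarray(row_c, dtype=float)
    r = np.asarray(row_r, dtype=float)
    if c.ndim != 1 or c.shape != r.shape:
        raise ValueError("rows must be 1-d and of equal length")
    if c.size == 0:
        raise ValueError("rows must have at least one feature")
    if (r < 0).any():
        raise ValueError("negative radius in row")
    return c - r, c + r


def pair_similarity(x_centers, x_radii, y_centers, y_radii) -> float:
    """J-dimensional overlapping-ratio similarity of two interval rows."""
    lo_x, hi_x = _row_bounds(x_centers, x_radii)
    lo_y, hi_y = _row_bounds(y_centers, y_radii)
    if lo_x.shape != lo_y.shape:
        raise ValueError("rows have different numbers of features")
    fwd = _directed_or(lo_x, hi_x, lo_y, hi_y)
    bwd = _directed_or(lo_y, hi_y, lo_x, hi_x)
    return float((fwd + bwd).sum() / (2 * lo_x.size))


def pair_distance(x_centers, x_radii, y_centers, y_radii) -> float:
    """J-dimensional overlapping-ratio distance; equals 1 - similarity."""
    return 1.0 - pair_similarity(x_centers, x_radii, y_centers, y_radii)


def or_distance_matrix(m: IntervalMatrix) -> DistanceMatrix:
    """Pairwise overlapping-ratio distance matrix of an interval matrix.

    Vectorized over all ordered pairs; identical (to rounding) to looping
    :func:`pair_distance` over every pair.
    """
    if m.n_obs < 2:
        raise ValueError("need at least 2 observations for a distance matrix")
    lo = m.lower
    hi = m.upper
    # ordered-pair directed OR, shape (n, n, J): entry [i, k, j] = OR(row i, row k)
    fwd = _directed_or(lo[:, None, :], hi[:, None, :], lo[None, :, :], hi[None, :, :])
    sim = (fwd + fwd.transpose(1, 0, 2)).mean(axis=2) / 2.0
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, metric_tag="or_distance", obs_ids=m.obs_ids)


def euclidean_distance_matrix(points, scale: bool = False, obs_ids=None, feature_names=None) -> DistanceMatrix:
    """Euclidean distances between point observations (conventional baseline).

    With ``scale=True`` features are z-scored first; a zero-variance
    feature is then an error (it would divide by zero), reported by name.
    """
    x = np.asarray(points, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"points must be 2-dimensional, got shape {x.shape}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations for a distance matrix")
    if scale:
        sd = x.std(axis=0, ddof=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = feature_names or [f"f{j + 1}" for j in range(x.shape[1])]
            raise ValueError(
                f"cannot scale zero-variance feature {names[zero[0]]!r}"
            )
        x = (x - x.mean(axis=0)) / sd
    d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(d, metric_tag="euclidean", obs_ids=obs_ids)
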