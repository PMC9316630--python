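"""Interval-valued data matrices.

An interval-valued observation records each feature as a closed interval
``[lower, upper]`` — equivalently a center (midpoint) ``c`` and a
nonnegative radius ``r`` with ``lower = c - r`` and ``upper = c + r`` —
encoding the measurement uncertainty around a point value.  The two
parameterizations are exactly interconvertible and :class:`IntervalMatrix`
stores the center/radius form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntervalMatrix",
    "LabeledDataset",
    "from_bounds",
    "to_bounds",
    "wdbc_to_intervals",
    "read_interval_csv",
    "write_interval_csv",
    "WDBC_BASE_FEATURES",
]

logger = logging.getLogger(__name__)

#: The ten cell-nucleus features of the Wisconsin diagnostic breast-cancer
#: dataset, in the order the standard 32-column CSV lists them.
WDBC_BASE_FEATURES = (
    "radius",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave_points",
    "symmetry",
    "fractal_dimension",
)


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class IntervalMatrix:
    """An n x J matrix of intervals stored as centers and radii.

    Parameters
    ----------
    centers : (n, J) array
        Interval midpoints ``c_ij``.
    radii : (n, J) array
        Interval half-widths ``r_ij``; must be nonnegative.
    feature_names : sequence of str, optional
        J feature identifiers (defaults to ``f1..fJ``).
    obs_ids : sequence of str, optional
        n observation identifiers (defaults to ``1..n``).
    allow_nan : bool
        If False (default), any NaN in centers or radii is rejected.
    """

    centers: np.ndarray
    radii: np.ndarray
    feature_names: tuple = field(default=None)
    obs_ids: tuple = field(default=None)
    allow_nan: bool = False

    def __post_init__(self):
        centers = _as_2d_float(self.centers, "centers")
        radii = _as_2d_float(self.radii, "radii")
        if centers.shape != radii.shape:
            raise ValueError(
                f"centers {centers.shape} and radii {radii.shape} differ in shape"
            )
        if not self.allow_nan and (np.isnan(centers).any() or np.isnan(radii).any()):
            raise ValueError(
                "NaN values in interval data; pass allow_nan=True or use "
                "drop_incomplete() upstream"
            )
        with np.errstate(invalid="ignore"):
            neg = radii < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(f"negative radius {radii[i, j]} at cell ({i + 1}, {j + 1})")
        n, J = centers.shape
        names = self.feature_names
        if names is None:
            names = tuple(f"f{j + 1}" for j in range(J))
        else:
            names = tuple(str(f) for f in names)
        ids = self.obs_ids
        if ids is None:
            ids = tuple(str(i + 1) for i in range(n))
        else:
            ids = tuple(str(i) for i in ids)
        if len(names) != J:
            raise ValueError(f"{len(names)} feature names for {J} features")
        if len(ids) != n:
            raise ValueError(f"{len(ids)} obs ids for {n} observations")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "feature_names", names)
        object.__setattr__(self, "obs_ids", ids)

    @property
    def n_obs(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    @property
    def shape(self) -> tuple:
        return self.centers.shape

    @property
    def lower(self) -> np.ndarray:
        return self.centers - self.radii

    @property
    def upper(self) -> np.ndarray:
        return self.centers + self.radii

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalMatrix):
            return NotImplemented
        return (
            self.centers.shape == other.centers.shape
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.radii, other.radii)
            and self.feature_names == other.feature_names
            and self.obs_ids == other.obs_ids
        )

    def take(self, indices) -> "IntervalMatrix":
        """Row subset / reordering preserving ids."""
        indices = np.asarray(indices)
        return IntervalMatrix(
            self.centers[indices],
            self.radii[indices],
            feature_names=self.feature_names,
            obs_ids=tuple(self.obs_ids[i] for i in indices),
        )


@dataclass(frozen=True)
class LabeledDataset:
    """An interval matrix plus optional binary class labels.

    Labels are evaluation-only ground truth (e.g. ``M``/``B`` diagnoses);
    clustering never sees them.
    """

    intervals: IntervalMatrix
    labels: tuple = None

    def __post_init__(self):
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != self.intervals.n_obs:
                raise ValueError(
                    f"{len(labels)} labels for {self.intervals.n_obs} observations"
                )
            if len(set(labels)) != 2:
                raise ValueError(
                    f"labels must take exactly 2 distinct values, got {sorted(set(map(str, labels)))}"
                )
            object.__setattr__(self, "labels", labels)

    @property
    def has_labels(self) -> bool:
        return self.labels is not None


def from_bounds(lower, upper, feature_names=None, obs_ids=None) -> IntervalMatrix:
    """Build an :class:`IntervalMatrix` from lower/upper bound matrices.

    Centers are ``(lower + upper) / 2`` and radii ``(upper - lower) / 2``.
    Raises a :class:`ValueError` naming the first offending cell when any
    ``lower > upper``.
    """
    lower = _as_2d_float(lower, "lower")
    upper = _as_2d_float(upper, "upper")
    if lower.shape != upper.shape:
        raise ValueError(f"lower {lower.shape} and upper {upper.shape} differ in shape")
    bad = lower > upper
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"lower > upper at cell ({i + 1}, {j + 1}): "
            f"[{lower[i, j]}, {upper[i, j]}] is not a valid interval"
        )
    return IntervalMatrix(
        (lower + upper) / 2.0,
        (upper - lower) / 2.0,
        feature_names=feature_names,
        obs_ids=obs_ids,
    )


def to_bounds(m: IntervalMatrix):
    """Return ``(lower, upper)`` bound matrices; exact inverse of :func:`from_bounds`."""
    return m.lower, m.upper


def wdbc_to_intervals(table: pd.DataFrame) -> LabeledDataset:
    """Turn a Wisconsin diagnostic breast-cancer table into intervals.

    For each of the ten base features the ``*_worst`` column (mean of the
    three largest per-image cell values — the noisiest summary) becomes the
    interval center and the matching ``*_se`` column (its per-image
    dispersion) becomes the radius, so each patient is a 10-dimensional
    hyperrectangle ``worst ± se``.  A ``diagnosis`` column, when present,
    is carried along as evaluation-only labels.

    Accepts either already-suffixed column names (``radius_worst`` /
    ``radius_se``) or the standard 32-column layout
    ``id, diagnosis, <30 features in mean/se/worst blocks>``.
    """
    df = table.copy()
    cols = set(df.columns)
    worst_cols = [c for c in df.columns if str(c).endswith("_worst")]
    if not worst_cols:
        raise ValueError(
            "no *_worst columns found; expected WDBC columns like 'radius_worst'"
        )
    features, centers, radii = [], [], []
    for wc in worst_cols:
        base = str(wc)[: -len("_worst")]
        se_col = f"{base}_se"
        if se_col not in cols:
            raise ValueError(f"column {wc!r} has no matching {se_col!r} column")
        features.append(base)
        centers.append(pd.to_numeric(df[wc], errors="raise").to_numpy(float))
        radii.append(pd.to_numeric(df[se_col], errors="raise").to_numpy(float))
    centers = np.column_stack(centers)
    radii = np.column_stack(radii)
    if "id" in cols:
        obs_ids = tuple(str(v) for v in df["id"])
    else:
        obs_ids = None
    labels = tuple(df["diagnosis"]) if "diagnosis" in cols else None
    intervals = IntervalMatrix(
        centers, radii, feature_names=features, obs_ids=obs_ids
    )
    return LabeledDataset(intervals, labels)


def read_wdbc(path) -> LabeledDataset:
    """Read the standard 32-column WDBC diagnostic CSV (with or without header)."""
    head = pd.read_csv(path, nrows=1, header=None)
    has_header = str(head.iloc[0, 1]).strip().lower() == "diagnosis"
    if has_header:
        df = pd.read_csv(path)
        df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    else:
        names = ["id", "diagnosis"]
        for block in ("mean", "se", "worst"):
            names += [f"{f}_{block}" for f in WDBC_BASE_FEATURES]
        df = pd.read_csv(path, header=None, names=names)
    return wdbc_to_intervals(df)


_DIALECTS = ("center_radius", "lower_upper", "point")
_SUFFIXES = {"center_radius": ("_c", "_r"), "lower_upper": ("_lo", "_hi")}


def read_interval_csv(
    path, dialect: str = "center_radius", label_col: str = None, drop_incomplete: bool = False
) -> LabeledDataset:
    """Read a LabeledDataset from CSV.

    Dialects: ``center_radius`` pairs ``<feat>_c``/``<feat>_r`` columns,
    ``lower_upper`` pairs ``<feat>_lo``/``<feat>_hi``, ``point`` reads plain
    numeric columns with all radii set to zero.  Lines starting with ``#``
    are ignored (provenance headers).  ``drop_incomplete`` drops rows with
    missing cells (logged); by default missing cells are an error.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    labels = None
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in CSV header")
        labels = df[label_col]
        df = df.drop(columns=[label_col])
    obs_ids = None
    if "obs_id" in df.columns:
        obs_ids = tuple(str(v) for v in df["obs_id"])
        df = df.drop(columns=["obs_id"])

    for c in df.columns:
        if not pd.api.types.is_numeric_dtype(df[c]):
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric cell in column {c!r}: {exc}") from exc

    if df.isna().any().any():
        if not drop_incomplete:
            raise ValueError(
                "missing values in CSV; pass drop_incomplete=True to drop those rows"
            )
        keep = ~df.isna().any(axis=1)
        n_drop = int((~keep).sum())
        logger.info("dropping %d incomplete rows", n_drop)
        df = df[keep]
        if labels is not None:
            labels = labels[keep]
        if obs_ids is not None:
            obs_ids = tuple(i for i, k in zip(obs_ids, keep) if k)

    if dialect == "point":
        centers = df.to_numpy(float)
        m = IntervalMatrix(
            centers,
            np.zeros_like(centers),
            feature_names=list(df.columns),
            obs_ids=obs_ids,
        )
    else:
        sa, sb = _SUFFIXES[dialect]
        first = [c for c in df.columns if str(c).endswith(sa)]
        feats = [str(c)[: -len(sa)] for c in first]
        unpaired = [c for c in df.columns if c not in first and str(c)[: -len(sb)] not in feats]
        missing = [f + sb for f in feats if f + sb not in df.columns]
        if not feats or unpaired or missing:
            raise ValueError(
                f"unpaired columns for dialect {dialect!r}: "
                f"missing={missing} unexpected={unpaired}"
            )
        a = df[[f + sa for f in feats]].to_numpy(float)
        b = df[[f + sb for f in feats]].to_numpy(float)
        if dialect == "center_radius":
            m = IntervalMatrix(a, b, feature_names=feats, obs_ids=obs_ids)
        else:
            m = from_bounds(a, b, feature_names=feats, obs_ids=obs_ids)
    return LabeledDataset(m, None if labels is None else tuple(labels))


def write_interval_csv(
    data: LabeledDataset | IntervalMatrix,
    path,
    dialect: str = "center_radius",
    label_col: str = "label",
    header_comment: str = None,
) -> None:
    """Write a dataset to CSV; exact inverse of :func:`read_interval_csv`."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if isinstance(data, IntervalMatrix):
        data = LabeledDataset(data)
    m = data.intervals
    out = {"obs_id": list(m.obs_ids)}
    if dialect == "point":
        if (m.radii != 0).any():
            raise ValueError("point dialect cannot represent nonzero radii")
        for j, f in enumerate(m.feature_names):
            out[f] = m.centers[:, j]
    elif dialect == "center_radius":
        for j, f in enumerate(m.feature_names):
            out[f + "_c"] = m.centers[:, j]
            out[f + "_r"] = m.radii[:, j]
    else:
        lower, upper = to_bounds(m)
        for j, f in enumerate(m.feature_names):
            out[f + "_lo"] = lower[:, j]
            out[f + "_hi"] = upper[:, j]
    df = pd.DataFrame(out)
    if data.labels is not None:
        df[label_col] = list(data.labels)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # %.17g round-trips IEEE doubles exactly
        df.to_csv(fh, index=False, float_format="%.17g")
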