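"""Unsupervised interpretation of pooled feature tables.

One or several per-sample feature tables (CSV/XLSX, e.g. the tabular output
of the tracking/adhesion/occlusion workflows) are pooled into a standardized
feature matrix and partitioned with k-means.  A scree curve (within-cluster
sum of squares versus k) suggests a number of clusters via the elbow
(second-difference) criterion, the mean silhouette coefficient grades the
separation, and a per-sample × cluster frequency table is emitted in a
contingency layout ready for downstream Chi-squared testing.

Standardization (zero mean, unit s.d. per feature over the pooled points)
defaults to on: the features mix units (µm², µm/s, a.u.), so unscaled
Euclidean k-means would be dominated by whichever feature has the largest
numeric range.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_media import InputError

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "assemble_feature_matrix",
    "scree_analysis",
    "cluster_kmeans",
]

_N_RESTARTS = 10


@dataclass
class FeatureMatrix:
    """Pooled, optionally standardized points with per-point sample labels."""

    points: np.ndarray           # (n, p), standardized if requested
    feature_names: list[str]
    sample_labels: np.ndarray    # (n,) label of the file of origin
    means: np.ndarray | None     # per-feature standardization record
    stds: np.ndarray | None
    n_dropped: int = 0           # rows dropped for missing values

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class ClusterResult:
    labels: np.ndarray                   # cluster id per point, 0 = largest cluster
    n_clusters: int
    inertia: float
    silhouette: float | None             # undefined (None) for k < 2
    frequency_table: pd.DataFrame        # sample label × cluster counts
    centers: np.ndarray


def _read_table(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def assemble_feature_matrix(
    tables,
    selected_features: list[str],
    standardize: bool = True,
    sample_labels: list[str] | None = None,
) -> FeatureMatrix:
    """Pool per-sample tables into one feature matrix.

    ``tables`` is a list of file paths, DataFrames, or (label, DataFrame)
    pairs; file paths default to their stem as sample label.  Rows with
    missing values in the selected features are dropped (the count is
    recorded on the result).
    """
    if not selected_features:
        raise InputError("select at least one feature column")
    frames = []
    labels = []
    for i, item in enumerate(tables):
        if isinstance(item, tuple):
            label, df = item
        elif isinstance(item, pd.DataFrame):
            df = item
            label = sample_labels[i] if sample_labels else f"sample_{i}"
        else:
            path = Path(item)
            df = _read_table(path)
            label = sample_labels[i] if sample_labels else path.stem
        for col in selected_features:
            if col not in df.columns:
                raise InputError(f"feature column {col!r} missing from table {label!r}")
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise InputError(f"feature column {col!r} in table {label!r} is not numeric")
        frames.append(df[selected_features])
        labels.extend([label] * len(df))
    pooled = pd.concat(frames, ignore_index=True)
    labels = np.asarray(labels, dtype=object)
    keep = ~pooled.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    points = pooled[keep].to_numpy(dtype=float)
    labels = labels[keep.to_numpy()]
    if points.shape[0] == 0:
        raise InputError("no complete rows after dropping missing values")

    means = stds = None
    if standardize:
        means = points.mean(axis=0)
        stds = points.std(axis=0)
        safe = np.where(stds > 0, stds, 1.0)
        points = (points - means) / safe
    return FeatureMatrix(points=points, feature_names=list(selected_features),
                         sample_labels=labels, means=means, stds=stds,
                         n_dropped=n_dropped)


def scree_analysis(matrix: FeatureMatrix, k_max: int, seed: int = 0):
    """Within-cluster sum of squares for k = 1..k_max plus an elbow suggestion.

    The suggested k maximizes the second difference of the inertia curve —
    the point where adding another cluster stops paying.  The suggestion is
    advisory; a user-chosen k always wins.
    """
    n = matrix.n_points
    if k_max >= n:
        raise InputError(f"k_max ({k_max}) must be smaller than the number of points ({n})")
    if k_max < 1:
        raise InputError("k_max must be >= 1")
    inertia = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=_N_RESTARTS, random_state=seed)
        km.fit(matrix.points)
        inertia.append(float(km.inertia_))
    inertia = np.asarray(inertia)
    if k_max >= 3:
        second_diff = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]  # at k = 2..k_max-1
        suggested_k = int(np.argmax(second_diff)) + 2
    else:
        suggested_k = 1 if k_max == 1 else 2
    return inertia, suggested_k


def cluster_kmeans(matrix: FeatureMatrix, n_clusters: int, seed: int = 0) -> ClusterResult:
    """Partition the pooled points into ``n_clusters`` with seeded k-means.

    k-means++ seeding with 10 restarts and a fixed seed keeps runs
    deterministic; the best-inertia solution is kept.  Cluster ids are
    renumbered in descending cluster size so labels are stable across runs.
    The silhouette is the mean over points of (b − a)/max(a, b); it is
    undefined (None) for a single cluster.
    """
    n = matrix.n_points
    if n_clusters >= n:
        raise InputError(f"n_clusters ({n_clusters}) must be smaller than n points ({n})")
    if n_clusters < 1:
        raise InputError("n_clusters must be >= 1")
    km = KMeans(n_clusters=n_clusters, n_init=_N_RESTARTS, random_state=seed)
    raw = km.fit_predict(matrix.points)

    sizes = np.bincount(raw, minlength=n_clusters)
    order = np.argsort(-sizes, kind="stable")      # largest cluster -> id 0
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    labels = remap[raw]
    centers = km.cluster_centers_[order]

    sil = None
    if n_clusters >= 2:
        sil = float(silhouette_score(matrix.points, labels))

    freq = pd.crosstab(
        pd.Series(matrix.sample_labels, name="sample"),
        pd.Series(labels, name="cluster"),
    )
    freq = freq.reindex(columns=range(n_clusters), fill_value=0)
    return ClusterResult(labels=labels, n_clusters=n_clusters,
                         inertia=float(km.inertia_), silhouette=sil,
                         frequency_table=freq, centers=centers)
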