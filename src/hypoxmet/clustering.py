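"""Heat-map layout: control-centered change profiles, unsupervised column
ordering and k-means row clustering.

Each animal contributes one column per interval (hypoxia EA/SA, reoxygenation
ER/EA); every row (feature) is centered on the mean change of the sham
controls for the matching interval, so a zero cell means "changed like a
control".  Columns are reordered by complete-linkage agglomeration on
Euclidean distances; rows are grouped by seeded k-means (k = 5 by default).
Display values are clipped to +/-3 on the log2 scale (about an 8-fold
change); the unclipped matrix is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .datamodel import ChangeMatrix, ValidationError

log = logging.getLogger("hypoxmet")


def center_on_controls(changes_by_interval: dict, control_animals) -> pd.DataFrame:
    """Features x profiles matrix of control-centered changes.

    ``changes_by_interval`` maps interval name to a ChangeMatrix; columns of
    the result are labelled ``"<animal>:<interval>"``.  Per row, the mean
    change of the control animals within the same interval is subtracted.
    """
    control_animals = set(control_animals)
    blocks = []
    for interval, ch in changes_by_interval.items():
        ctrl = [a for a in ch.values.index if a in control_animals]
        if not ctrl:
            raise ValidationError(f"no control animals with {interval} changes")
        centered = ch.values.sub(ch.values.loc[ctrl].mean(axis=0), axis=1)
        centered.index = [f"{a}:{interval}" for a in centered.index]
        blocks.append(centered.T)  # features x profiles
    mat = pd.concat(blocks, axis=1)
    return mat


def order_columns(matrix: pd.DataFrame):
    """Complete-linkage agglomeration of columns on Euclidean distance.

    Returns (column_order, linkage_matrix); all-missing columns are excluded
    with a warning, remaining missing cells are treated as zero (a change
    equal to the control mean) for distance purposes.  Leaf order follows the
    deterministic recursive traversal of the merge tree (lower original index
    first on ties).
    """
    drop = matrix.columns[matrix.isna().all(axis=0)]
    if len(drop):
        log.warning("excluding %d all-missing columns from column clustering", len(drop))
        matrix = matrix.drop(columns=drop)
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 columns to cluster")
    X = matrix.fillna(0.0).to_numpy(dtype=float).T  # observations = columns
    Z = linkage(X, method="complete", metric="euclidean")
    order = [matrix.columns[i] for i in leaves_list(Z)]
    return order, Z


def cut_columns(Z: np.ndarray, columns, k: int) -> pd.Series:
    """Cut the column dendrogram into k flat clusters (labels per column)."""
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=list(columns), name="column_cluster")


def cluster_rows(matrix: pd.DataFrame, k: int = 5, seed: int = 0):
    """Seeded k-means over rows (10 restarts, best inertia kept).

    Returns (row_clusters: feature -> cluster id, row_order) with rows ordered
    cluster-by-cluster and, within a cluster, by distance to its centroid.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > matrix.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of rows ({matrix.shape[0]})")
    X = matrix.fillna(0.0).to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    dist = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    df = pd.DataFrame({"cluster": labels, "dist": dist, "pos": np.arange(len(labels))}, index=matrix.index)
    df = df.sort_values(["cluster", "dist", "pos"], kind="mergesort")
    return pd.Series(labels, index=matrix.index, name="row_cluster"), list(df.index)


@dataclass
class HeatmapLayout:
    """Everything needed to draw the change heat-map, rendering aside."""

    matrix: pd.DataFrame  # features x profiles, centered log2 changes (unclipped)
    display_matrix: pd.DataFrame  # clipped copy for rendering
    column_order: list
    column_linkage: np.ndarray
    row_clusters: pd.Series
    row_order: list
    clip: float = 3.0

    def ordered(self, clipped: bool = True) -> pd.DataFrame:
        src = self.display_matrix if clipped else self.matrix
        return src.loc[self.row_order, self.column_order]


def build_heatmap_layout(
    changes_by_interval: dict, control_animals, k: int = 5, seed: int = 0, clip: float = 3.0,
) -> HeatmapLayout:
    """Assemble the full heat-map layout from per-interval change matrices."""
    mat = center_on_controls(changes_by_interval, control_animals)
    column_order, Z = order_columns(mat)
    row_clusters, row_order = cluster_rows(mat, k=k, seed=seed)
    display = mat.clip(lower=-clip, upper=clip)
    return HeatmapLayout(mat, display, column_order, Z, row_clusters, row_order, clip)
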