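"""Spatial statistics on object centres of mass.

Distances between COMs use the straight-line (Euclidean) formula
``sqrt((x2-x1)^2 + (y2-y1)^2 + (z2-z1)^2)`` on physical nm coordinates.
Distance matrices and networks stay in nm; displacements and
nearest-neighbour distances are reported in μm.

Clustering: K-means with the cluster count chosen by the silhouette
method, and full-covariance Gaussian mixtures with the component count
chosen by BIC.  Both are seeded and deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .volio import NM_PER_UM, Point3D

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "com_distance",
    "displacement_from_center",
    "distance_matrix",
    "radial_ranking",
    "build_network",
    "kmeans_silhouette",
    "gmm_cluster",
    "nn_within_clusters",
]

DEFAULT_SEED = 1729
DEFAULT_NETWORK_K = 3


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs COM distance matrix in nm with zero diagonal."""

    object_ids: list[int]
    matrix: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.object_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match object id count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.object_ids, columns=self.object_ids)


@dataclass
class ClusterResult:
    """Clustering of COM points with model-selection trace.

    ``nn_within`` is each point's distance (μm) to its nearest neighbour in
    the same cluster; NaN for singleton clusters, which are flagged.
    """

    k: int
    labels: np.ndarray
    centers: list[Point3D]
    scores: dict[int, float]  # silhouette (K-means) or BIC (GMM) per candidate k
    nn_within: np.ndarray  # μm; NaN for singletons
    singleton_flags: np.ndarray
    method: str = "kmeans"


def _points_array(points) -> np.ndarray:
    if isinstance(points, np.ndarray):
        arr = np.asarray(points, dtype=float)
    else:
        arr = np.asarray([p.as_array() if isinstance(p, Point3D) else p for p in points], dtype=float)
    if arr.ndim != 2:
        raise ValueError("points must be an (n, d) array of coordinates")
    return arr


def com_distance(p1: Point3D, p2: Point3D) -> float:
    """Straight-line distance between two COMs, in nm."""
    return float(np.linalg.norm(p1.as_array() - p2.as_array()))


def displacement_from_center(object_com: Point3D, cell_com: Point3D) -> float:
    """Distance of an object's COM from the cell centre, reported in μm."""
    return com_distance(object_com, cell_com) / NM_PER_UM


def distance_matrix(objects: dict[int, Point3D] | list[tuple[int, Point3D]]) -> DistanceMatrix:
    """All-pairs COM distance matrix (nm); requires at least two objects."""
    items = sorted(objects.items()) if isinstance(objects, dict) else sorted(objects)
    if len(items) < 2:
        raise ValueError("need at least two objects for a distance matrix")
    ids = [i for i, _ in items]
    pts = np.asarray([p.as_array() for _, p in items])
    mat = cdist(pts, pts)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(object_ids=ids, matrix=mat)


def radial_ranking(
    chromosomes: pd.DataFrame,
    cell_com: Point3D,
) -> pd.DataFrame:
    """Rank chromosomes by descending volume and report centre distance.

    ``chromosomes`` needs columns ``object_id``, ``volume`` and
    ``com_x_nm/com_y_nm/com_z_nm``.  Row ``rank`` 1 is the largest
    chromosome; ``distance_um`` its COM distance from the cell centre.
    """
    if chromosomes.empty:
        return pd.DataFrame(columns=["rank", "object_id", "volume", "distance_um"])
    df = chromosomes.sort_values(
        ["volume", "object_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    dists = [
        displacement_from_center(Point3D(r.com_x_nm, r.com_y_nm, r.com_z_nm), cell_com)
        for r in df.itertuples()
    ]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(df) + 1),
            "object_id": df["object_id"].to_numpy(),
            "volume": df["volume"].to_numpy(),
            "distance_um": dists,
        }
    )


def build_network(
    dm: DistanceMatrix,
    rule: str = "mutual_knn",
    k: int = DEFAULT_NETWORK_K,
    threshold_nm: float | None = None,
    node_labels: dict[int, str] | None = None,
) -> nx.Graph:
    """Proximity network over a distance matrix.

    Default rule: mutual k-nearest-neighbours (k=3) — an undirected edge
    exists iff each node is among the other's k nearest.  Ties in distance
    break by lower index (stable argsort), making the graph deterministic.
    The alternative ``"threshold"`` rule connects all pairs closer than
    ``threshold_nm``.  Degree under mutual-kNN never exceeds k, and the
    edge set grows monotonically with k.
    """
    n = len(dm.object_ids)
    g = nx.Graph()
    g.add_nodes_from(dm.object_ids)
    if node_labels:
        nx.set_node_attributes(g, node_labels, "label")
    g.graph["rule"] = rule
    if rule == "mutual_knn":
        if k >= n:
            raise ValueError(f"k={k} must be below the number of objects ({n})")
        g.graph["k"] = k
        order = np.argsort(dm.matrix, axis=1, kind="stable")
        knn = [set(row[row != i][:k].tolist()) for i, row in enumerate(order)]
        for i in range(n):
            for j in knn[i]:
                if i < j and i in knn[j]:
                    g.add_edge(dm.object_ids[i], dm.object_ids[j], distance_nm=float(dm.matrix[i, j]))
    elif rule == "threshold":
        if threshold_nm is None:
            raise ValueError("threshold rule needs threshold_nm")
        g.graph["threshold_nm"] = threshold_nm
        for i in range(n):
            for j in range(i + 1, n):
                if dm.matrix[i, j] <= threshold_nm:
                    g.add_edge(dm.object_ids[i], dm.object_ids[j], distance_nm=float(dm.matrix[i, j]))
    else:
        raise ValueError(f"unknown network rule {rule!r}")
    return g


def nn_within_clusters(points, labels) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour distance within each point's own cluster, in μm.

    Returns ``(distances_um, singleton_flags)``; members of singleton
    clusters have no neighbour, get NaN and are flagged.
    """
    pts = _points_array(points)
    labels = np.asarray(labels)
    n = len(pts)
    out = np.full(n, np.nan)
    singleton = np.zeros(n, dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) == 1:
            singleton[idx] = True
            continue
        d = cdist(pts[idx], pts[idx])
        np.fill_diagonal(d, np.inf)
        out[idx] = d.min(axis=1) / NM_PER_UM
    return out, singleton


def _finish_cluster_result(pts, labels, centers, scores, k, method) -> ClusterResult:
    nn, singles = nn_within_clusters(pts, labels)
    center_pts = [Point3D(*c) for c in centers]
    return ClusterResult(
        k=int(k),
        labels=np.asarray(labels),
        centers=center_pts,
        scores={int(kk): float(v) for kk, v in scores.items()},
        nn_within=nn,
        singleton_flags=singles,
        method=method,
    )


def kmeans_silhouette(
    points,
    k_range=None,
    seed: int = DEFAULT_SEED,
    n_init: int = 10,
) -> ClusterResult:
    """K-means with the cluster count selected by the silhouette method.

    Runs K-means (``n_init`` restarts per candidate, seeded) for each k in
    ``k_range`` (default 2..min(10, n−1)) and keeps the k maximising the
    mean silhouette width on Euclidean nm coordinates; ties prefer the
    smaller k.  Degenerate input (all points identical) and n < 3 raise.
    """
    pts = _points_array(points)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points for silhouette-based K selection")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate configuration: all points identical")
    if k_range is None:
        k_range = range(2, min(10, n - 1) + 1)
    k_range = [int(k) for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    scores: dict[int, float] = {}
    fits = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(pts)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(pts, labels))
        fits[k] = km
    if not scores:
        raise ValueError("no candidate k produced a valid clustering")
    best = max(sorted(scores), key=lambda k: scores[k])
    km = fits[best]
    # cluster centres ordered to match label indices (x, y, z nm)
    return _finish_cluster_result(pts, km.labels_, km.cluster_centers_, scores, best, "kmeans")


def gmm_cluster(
    points,
    max_components: int = 5,
    seed: int = DEFAULT_SEED,
    sex_labels: dict[int, str] | None = None,
    object_ids: list[int] | None = None,
) -> ClusterResult:
    """Full-covariance Gaussian mixture with the component count picked by BIC.

    Fits 1..``max_components`` components; a k whose fit fails is skipped
    with a warning.  When ``sex_labels`` (object id -> 'X'/'Y') and
    ``object_ids`` are given, the result gains a ``sex_cluster_members``
    attribute listing co-members of the cluster(s) holding X and Y.
    """
    pts = _points_array(points)
    n = len(pts)
    if not (1 <= max_components <= n):
        raise ValueError("need n >= max_components >= 1")
    scores: dict[int, float] = {}
    fits = {}
    for k in range(1, max_components + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(n_components=k, covariance_type="full", random_state=seed, n_init=3)
                gm.fit(pts)
            if not gm.converged_ and k > 1:
                warnings.warn(f"GMM with k={k} did not converge; skipped")
                continue
            scores[k] = float(gm.bic(pts))
            fits[k] = gm
        except Exception as exc:  # singular covariance etc.
            warnings.warn(f"GMM with k={k} failed ({exc}); skipped")
    if not fits:
        raise ValueError("no GMM component count could be fitted")
    best = min(sorted(scores), key=lambda k: scores[k])
    gm = fits[best]
    labels = gm.predict(pts)
    result = _finish_cluster_result(pts, labels, gm.means_, scores, best, "gmm")
    if sex_labels and object_ids is not None:
        id_arr = np.asarray(object_ids)
        members: dict[str, list[int]] = {}
        for oid, sl in sex_labels.items():
            pos = np.flatnonzero(id_arr == oid)
            if len(pos):
                cl = labels[pos[0]]
                members[sl] = sorted(int(i) for i in id_arr[labels == cl])
        result.sex_cluster_members = members  # type: ignore[attr-defined]
    return result
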