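"""Zone delineation and sampling-site selection.

The trained SOM codebook is partitioned with K-means; every field location
then inherits the cluster of its winning node, which delineates the
management/sampling zones.  Within each zone the location closest to the
cluster centroid (the "best matching unit", BMU) is the critical sampling
site, and further sites are spread across the zone by greedy farthest-point
selection in geographic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .som import SOMCodebook, bmu_indices
from .terrain import FeatureMatrix

log = logging.getLogger(__name__)


@dataclass
class KMeansResult:
    labels: np.ndarray
    centers: np.ndarray
    sse: float
    n_iter: int


def _lloyd(X: np.ndarray, k: int, w: np.ndarray, rng: np.random.Generator,
           max_iter: int = 300):
    n = len(X)
    seedable = np.flatnonzero(w > 0)
    centers = X[rng.choice(seedable, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for it in range(max_iter):
        d2 = cdist(X, centers, "sqeuclidean")
        new_labels = np.argmin(d2, axis=1)
        # repair empty clusters by re-seeding at the farthest weighted point
        for c in range(k):
            if w[new_labels == c].sum() == 0:
                wd = w * d2[np.arange(n), new_labels]
                far = int(np.argmax(wd))
                centers[c] = X[far]
                d2[:, c] = ((X - centers[c]) ** 2).sum(axis=1)
                new_labels = np.argmin(d2, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            m = labels == c
            centers[c] = np.average(X[m], axis=0, weights=w[m])
    d2 = cdist(X, centers, "sqeuclidean")
    sse = float((w * d2[np.arange(n), labels]).sum())
    return labels, centers, sse, it + 1


def kmeans(
    vectors: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> KMeansResult:
    """Lloyd's K-means, best of ``n_restarts`` seeded starts by SSE.

    Iterates assignment/update until membership stops changing; empty
    clusters are re-seeded from the point farthest from its center.
    Optional non-negative ``weights`` turn the objective into the weighted
    within-cluster sum of squares (used to weight SOM nodes by how many
    field locations they win).
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be 2-D")
    if k < 1:
        raise ValueError("k must be >= 1")
    if weights is None:
        w = np.ones(len(X))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(X),) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, one per vector, not all zero")
    n_distinct = len(np.unique(X[w > 0], axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct (weighted) vectors")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(max(n_restarts, 1)):
        labels, centers, sse, n_iter = _lloyd(X, k, w, rng)
        if best is None or sse < best.sse - 1e-12:
            best = KMeansResult(labels, centers, sse, n_iter)
    return best


@dataclass
class ClusterModel:
    """Cluster labels over SOM nodes and field locations.

    Centroids live in the (normalized) input feature space and equal the
    mean of the member *location* vectors; cluster ids are renumbered by
    descending membership (cluster 0 is the largest).
    """

    k: int
    node_labels: np.ndarray
    location_labels: np.ndarray
    centroids: np.ndarray
    sse: float

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.location_labels == c)


def cluster_field(
    cb: SOMCodebook,
    fm: FeatureMatrix,
    k: int,
    seed: int | None = None,
    n_restarts: int = 10,
    node_weighting: str = "hits",
) -> ClusterModel:
    """K-means on the codebook nodes, labels propagated to locations.

    Each location inherits the cluster of its winning node; input-space
    centroids are then recomputed from the member locations.  With the
    default ``node_weighting="hits"`` each node enters the K-means
    objective weighted by the number of locations it wins, so the field
    data drive the partition rather than the lattice's sparsely hit
    interpolating prototypes; ``"none"`` clusters the nodes unweighted.
    """
    if k < 2:
        raise ValueError("k must be >= 2 for zone delineation")
    winners = bmu_indices(fm.data, cb)
    if node_weighting == "hits":
        weights = np.bincount(winners, minlength=cb.n_nodes).astype(float)
    elif node_weighting == "none":
        weights = None
    else:
        raise ValueError("node_weighting must be 'hits' or 'none'")
    km = kmeans(cb.vectors, k, n_restarts=n_restarts, seed=seed, weights=weights)
    loc_labels = km.labels[winners]
    counts = np.bincount(loc_labels, minlength=k)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(
            f"cluster(s) {empty} have no member locations; try a smaller k"
        )
    # stable renumbering: largest cluster first (ties by old id)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    node_labels = remap[km.labels]
    loc_labels = remap[loc_labels]
    centroids = np.vstack([
        fm.data[loc_labels == c].mean(axis=0) for c in range(k)
    ])
    sse = float(sum(
        ((fm.data[loc_labels == c] - centroids[c]) ** 2).sum() for c in range(k)
    ))
    return ClusterModel(k, node_labels, loc_labels, centroids, sse)


# ---------------------------------------------------------------------------
# Sampling design
# ---------------------------------------------------------------------------


@dataclass
class ClusterSites:
    cluster: int
    bmu_row: int
    bmu_distance: float  # normalized-feature distance to the centroid
    site_rows: list[int] = field(default_factory=list)  # includes the BMU first

    @property
    def additional_rows(self) -> list[int]:
        return self.site_rows[1:]


@dataclass
class SamplingDesign:
    clusters: list[ClusterSites]
    shortfalls: dict[int, int] = field(default_factory=dict)

    @property
    def sites_total(self) -> int:
        return sum(len(c.site_rows) for c in self.clusters)

    def all_rows(self) -> list[int]:
        return [r for c in self.clusters for r in c.site_rows]

    def to_frame(self, fm: FeatureMatrix):
        import pandas as pd

        x, y = fm.coords()
        recs = []
        for cs in self.clusters:
            for j, row in enumerate(cs.site_rows):
                recs.append({
                    "cluster": cs.cluster,
                    "role": "BMU" if j == 0 else "additional",
                    "row_index": row,
                    "x": x[row],
                    "y": y[row],
                })
        return pd.DataFrame(recs)


def select_bmu_location(cm: ClusterModel, fm: FeatureMatrix) -> SamplingDesign:
    """Per cluster, the member location nearest its centroid (ties: lowest row)."""
    out = []
    for c in range(cm.k):
        rows = cm.members(c)
        if len(rows) == 0:
            raise ValueError(f"cluster {c} is empty")
        d = np.linalg.norm(fm.data[rows] - cm.centroids[c], axis=1)
        j = int(np.argmin(d))  # argmin returns the first (lowest-row) minimum
        out.append(ClusterSites(c, int(rows[j]), float(d[j]), [int(rows[j])]))
    return SamplingDesign(out)


def select_additional_sites(
    cm: ClusterModel,
    fm: FeatureMatrix,
    n_per_cluster: int = 11,
    seed: int | None = None,
) -> SamplingDesign:
    """BMU plus ``n_per_cluster`` spatially spread sites per cluster.

    Greedy farthest-point selection in geographic (x, y) space, seeded at
    the BMU: repeatedly add the member maximizing its minimum distance to
    the sites already chosen (ties: lowest row index).  Deterministic; the
    ``seed`` argument is accepted for interface symmetry but unused.

    A cluster smaller than ``1 + n_per_cluster`` contributes all of its
    members, and the shortfall is logged and recorded on the design.
    """
    if n_per_cluster < 0:
        raise ValueError("n_per_cluster must be >= 0")
    design = select_bmu_location(cm, fm)
    x, y = fm.coords()
    for cs in design.clusters:
        rows = cm.members(cs.cluster)
        want = 1 + n_per_cluster
        if len(rows) < want:
            design.shortfalls[cs.cluster] = want - len(rows)
            log.warning(
                "cluster %d has only %d members; selecting all (short %d sites)",
                cs.cluster, len(rows), want - len(rows),
            )
        pts = np.column_stack([x[rows], y[rows]])
        start = int(np.flatnonzero(rows == cs.bmu_row)[0])
        chosen = [start]
        chosen_mask = np.zeros(len(rows), dtype=bool)
        chosen_mask[start] = True
        mind = np.linalg.norm(pts - pts[start], axis=1)
        while len(chosen) < min(want, len(rows)):
            mind_masked = np.where(chosen_mask, -np.inf, mind)
            j = int(np.argmax(mind_masked))  # first max -> lowest row on ties
            chosen.append(j)
            chosen_mask[j] = True
            mind = np.minimum(mind, np.linalg.norm(pts - pts[j], axis=1))
        cs.site_rows = [int(rows[j]) for j in chosen]
    return design
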