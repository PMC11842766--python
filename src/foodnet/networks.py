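"""Second-level ROI clustering into representational sub-networks.

Group-average RDMs are compared across ROIs (Pearson correlation of their
upper-triangle vectors) to form an ROI similarity matrix; outlier ROIs —
regions whose representational profile sits far from every other region —
are screened out by a multi-metric distance z-score; the remaining ROIs are
partitioned into sub-networks either by silhouette-validated k-means on the
similarity-matrix rows or by maximum-modularity community detection on the
weighted ROI graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import mahalanobis, pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .rdm import RDM, upper_tri

__all__ = [
    "ROISimilarityMatrix",
    "OutlierReport",
    "NetworkPartition",
    "roi_similarity_matrix",
    "detect_outlier_rois",
    "cluster_rois",
    "silhouette_mean",
    "max_modularity_exhaustive",
]


@dataclass
class ROISimilarityMatrix:
    """Pearson correlations of RDM upper-triangle vectors across ROI pairs."""

    roi_ids: list[str]
    s: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        m = len(self.roi_ids)
        if self.s.shape != (m, m):
            raise ValueError("similarity matrix shape does not match roi_ids")

    @property
    def m(self) -> int:
        return len(self.roi_ids)

    def subset(self, keep: list[str]) -> "ROISimilarityMatrix":
        idx = [self.roi_ids.index(r) for r in keep]
        return ROISimilarityMatrix(roi_ids=list(keep), s=self.s[np.ix_(idx, idx)])


def roi_similarity_matrix(group_rdms: dict[str, RDM]) -> ROISimilarityMatrix:
    """Second-level similarity matrix across ROIs' group-average RDMs."""
    roi_ids = list(group_rdms.keys())
    if len(roi_ids) < 3:
        raise ValueError("need at least 3 ROIs")
    labels = group_rdms[roi_ids[0]].labels
    vecs = []
    for r in roi_ids:
        if group_rdms[r].labels != labels:
            raise ValueError("all RDMs must share condition labels")
        v = upper_tri(group_rdms[r])
        if np.std(v) == 0:
            raise ValueError(f"constant upper-triangle vector for ROI {r}")
        vecs.append(v)
    s = np.corrcoef(np.array(vecs))
    np.fill_diagonal(s, 1.0)
    return ROISimilarityMatrix(roi_ids=roi_ids, s=s)


@dataclass
class OutlierReport:
    """Per-ROI mean distances to other ROIs, their z-scores, exclusion flags.

    ``distances``/``zscores`` are DataFrames indexed by ROI with one column
    per metric (correlation, euclidean, mahalanobis).  An ROI is excluded
    when its correlation-metric z-score reaches ``z_threshold``; the other
    metrics are reported for context.
    """

    distances: pd.DataFrame
    zscores: pd.DataFrame
    excluded: list[str]
    z_threshold: float

    def kept(self) -> list[str]:
        return [r for r in self.distances.index if r not in self.excluded]


def detect_outlier_rois(
    rdm_vectors: dict[str, np.ndarray],
    z_threshold: float = 2.0,
    mahalanobis_components: int | None = None,
) -> OutlierReport:
    """Screen ROIs whose representational profile is far from all others.

    For each of three metrics — correlation distance, Euclidean distance,
    and Mahalanobis distance in a PCA-reduced space (at most m - 2
    components, since the full vector covariance over a handful of ROIs is
    singular) — the mean distance of each ROI to the others is z-scored
    across ROIs.  Exclusion keys on the correlation metric at
    ``z >= z_threshold``.
    """
    roi_ids = list(rdm_vectors.keys())
    m = len(roi_ids)
    if m < 4:
        raise ValueError("need at least 4 ROIs for outlier screening")
    x = np.array([np.asarray(rdm_vectors[r], dtype=float) for r in roi_ids])

    dist = {
        "correlation": squareform(pdist(x, metric="correlation")),
        "euclidean": squareform(pdist(x, metric="euclidean")),
    }
    n_comp = mahalanobis_components if mahalanobis_components is not None else m - 2
    n_comp = max(1, min(n_comp, m - 2, x.shape[1]))
    xc = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    red = xc @ vt[:n_comp].T
    cov = np.cov(red, rowvar=False)
    cov = np.atleast_2d(cov)
    vi = np.linalg.pinv(cov)
    dmah = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dmah[i, j] = dmah[j, i] = mahalanobis(red[i], red[j], vi)
    dist["mahalanobis"] = dmah

    mean_d = {k: d.sum(axis=1) / (m - 1) for k, d in dist.items()}
    z = {}
    for k, v in mean_d.items():
        sd = v.std()  # population sd, so z-scores have mean 0, sd 1
        if sd == 0:
            raise ValueError(f"degenerate ROI set: zero spread of {k} mean distances")
        z[k] = (v - v.mean()) / sd
    distances = pd.DataFrame(mean_d, index=roi_ids)
    zscores = pd.DataFrame(z, index=roi_ids)
    excluded = [r for r in roi_ids if zscores.loc[r, "correlation"] >= z_threshold]
    return OutlierReport(
        distances=distances, zscores=zscores, excluded=excluded, z_threshold=z_threshold
    )


@dataclass
class NetworkPartition:
    """Assignment of ROIs to sub-networks with its validation curve."""

    labels: dict[str, int]  # ROI id -> community in 1..chosen_k
    silhouette_by_k: dict[int, float]
    chosen_k: int
    modularity_q: float | None = None
    method: str = "kmeans"

    def rois_in(self, community: int) -> list[str]:
        return [r for r, c in self.labels.items() if c == community]


def silhouette_mean(distance: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient of a labelled distance matrix.

    Standard definition ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with a
    the mean within-cluster distance and b the mean distance to the nearest
    other cluster; items in singleton clusters score 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return float(silhouette_score(np.asarray(distance, float), labels, metric="precomputed"))


def _partition_weight(s: np.ndarray) -> np.ndarray:
    """Edge weights (s + 1)/2 for the graph path (modularity needs >= 0)."""
    w = (s + 1.0) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


def _modularity_q(w: np.ndarray, labels: np.ndarray) -> float:
    """Weighted-graph modularity of a labelling (closed form)."""
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += w[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
    return float(q)


def _set_partitions(n: int):
    """All set partitions of range(n) as restricted-growth label arrays."""
    labels = np.zeros(n, dtype=int)
    mx = np.zeros(n, dtype=int)

    def rec(i: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(mx[i - 1] + 2 if i > 0 else 1):
            labels[i] = c
            mx[i] = max(mx[i - 1], c) if i > 0 else 0
            yield from rec(i + 1)

    yield from rec(0)


def max_modularity_exhaustive(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Globally maximum-modularity partition by enumerating all partitions."""
    best_q, best = -np.inf, None
    for labels in _set_partitions(w.shape[0]):
        q = _modularity_q(w, labels)
        if q > best_q:
            best_q, best = q, labels
    return best, best_q


def _greedy_modularity(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Greedy agglomeration (CNM) with single-node local refinement."""
    g = nx.from_numpy_array(w)
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    labels = np.zeros(w.shape[0], dtype=int)
    for c, nodes in enumerate(comms):
        for i in nodes:
            labels[i] = c
    q = _modularity_q(w, labels)
    improved = True
    while improved:
        improved = False
        for i in range(len(labels)):
            current = labels[i]
            for c in np.unique(labels):
                if c == current:
                    continue
                labels[i] = c
                q_new = _modularity_q(w, labels)
                if q_new > q + 1e-12:
                    q = q_new
                    current = c
                    improved = True
                else:
                    labels[i] = current
    return labels, q


def cluster_rois(
    sim: ROISimilarityMatrix,
    method: str = "kmeans",
    k_range: range = range(2, 9),
    n_init: int = 50,
    seed: int | None = 0,
    exhaustive_max_m: int = 12,
) -> NetworkPartition:
    """Partition ROIs into sub-networks.

    kmeans path (default): rows of the similarity matrix are the feature
    vectors; for each k the best of ``n_init`` initializations is scored by
    the mean silhouette under distance ``1 - s``, and the silhouette-argmax
    k is chosen.  modularity path: community detection on the weighted
    graph with edge weights ``(s + 1)/2`` — exact exhaustive search up to
    ``exhaustive_max_m`` nodes, greedy agglomeration with local refinement
    above that; the modularity Q of the partition is reported.
    """
    m = sim.m
    if m < 4:
        raise ValueError("need at least 4 ROIs to cluster")
    dist = 1.0 - sim.s
    np.fill_diagonal(dist, 0.0)

    if method == "kmeans":
        ks = [k for k in k_range if k <= m - 1]
        if not ks:
            raise ValueError("empty k_range")
        sil: dict[int, float] = {}
        labels_by_k: dict[int, np.ndarray] = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
            lab = km.fit_predict(sim.s)
            sil[k] = silhouette_mean(dist, lab)
            labels_by_k[k] = lab
        chosen = max(sil, key=lambda k: (sil[k], -k))
        labels = _canonical_labels(labels_by_k[chosen])
        q = _modularity_q(_partition_weight(sim.s), labels)
        return NetworkPartition(
            labels=dict(zip(sim.roi_ids, (labels + 1).tolist())),
            silhouette_by_k=sil,
            chosen_k=chosen,
            modularity_q=q,
            method="kmeans",
        )
    elif method == "modularity":
        w = _partition_weight(sim.s)
        if m <= exhaustive_max_m:
            labels, q = max_modularity_exhaustive(w)
        else:
            labels, q = _greedy_modularity(w)
        labels = _canonical_labels(labels)
        k = len(np.unique(labels))
        sil = {k: silhouette_mean(dist, labels)} if k >= 2 else {}
        return NetworkPartition(
            labels=dict(zip(sim.roi_ids, (labels + 1).tolist())),
            silhouette_by_k=sil,
            chosen_k=k,
            modularity_q=q,
            method="modularity",
        )
    raise ValueError(f"unknown method: {method!r}")


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out
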