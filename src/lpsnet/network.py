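"""Sub-network identification and weighted graph metrics.

Sub-networks are read off an average-linkage (UPGMA) dendrogram built on
a node-to-node distance.  Two distances are offered: the default
profile-correlation distance ``1 - corr(row_i, row_j)`` (nodes are close
when they connect to the rest of the brain in the same way), and the
direct ``1 - connectivity`` distance.  On clean block-structured
connectivity both recover the same partition.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import (
    ConnectivityMatrix,
    Dendrogram,
    GroupConnectivityStats,
    NetworkPartition,
)

logger = logging.getLogger(__name__)

__all__ = [
    "node_distance_matrix",
    "average_linkage",
    "cut_to_groups",
    "group_connectivity",
    "weighted_clustering_coefficient",
    "event_related_clustering",
]


def _as_matrix(conn: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    m = conn.values if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("connectivity must be symmetric")
    return m


def node_distance_matrix(
    conn: ConnectivityMatrix | np.ndarray,
    method: str = "profile_correlation",
) -> np.ndarray:
    """Pairwise node distances for dendrogram clustering.

    ``profile_correlation``: ``d_ij = 1 - r(row_i, row_j)`` with the
    Pearson correlation computed over the remaining columns (i and j
    excluded, so a pair's own edge does not drive its similarity).
    ``one_minus_connectivity``: ``d_ij = 1 - conn_ij``.  A node with a
    constant connection profile has undefined correlation; its distances
    default to 1 and a warning is logged.
    """
    m = _as_matrix(conn)
    n = m.shape[0]
    if method == "one_minus_connectivity":
        d = 1.0 - m
    elif method == "profile_correlation":
        d = np.zeros((n, n))
        mask = ~np.eye(n, dtype=bool)
        flagged = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                cols = mask[i] & mask[j]
                cols[i] = cols[j] = False
                xi, xj = m[i, cols], m[j, cols]
                si, sj = xi.std(), xj.std()
                if si == 0 or sj == 0:
                    d[i, j] = d[j, i] = 1.0
                    flagged = True
                    continue
                r = np.dot(xi - xi.mean(), xj - xj.mean()) / (len(xi) * si * sj)
                d[i, j] = d[j, i] = 1.0 - r
        if flagged:
            logger.warning("constant connection profile: distance defaulted to 1")
    else:
        raise ValueError(f"unknown distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    return d


def average_linkage(
    dist: np.ndarray,
    labels: list[str] | None = None,
    metric_name: str = "custom",
) -> Dendrogram:
    """UPGMA merge tree: cluster-pair distance is the unweighted mean of
    member-pair distances."""
    d = np.asarray(dist, dtype=float)
    if np.any(np.isnan(d)):
        raise ValueError("distance matrix contains NaN")
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    condensed = squareform(np.maximum(d, 0.0), checks=False)
    Z = linkage(condensed, method="average")
    labels = labels or [f"S{i}" for i in range(n)]
    return Dendrogram(linkage=Z, labels=list(labels), metric=metric_name)


def cut_to_groups(dendrogram: Dendrogram, K: int) -> NetworkPartition:
    """Cut the K-1 highest merges, yielding K groups (deterministic)."""
    n = len(dendrogram.labels)
    if not (1 <= K <= n):
        raise ValueError(f"K must lie in [1, {n}]")
    raw = fcluster(dendrogram.linkage, t=K, criterion="maxclust")
    # relabel groups 0..K-1 in order of first appearance
    _, labels = np.unique(raw, return_inverse=True)
    order = {}
    remapped = np.empty_like(labels)
    for idx, g in enumerate(labels):
        if g not in order:
            order[g] = len(order)
        remapped[idx] = order[g]
    return NetworkPartition(
        labels=remapped, K=len(order), dendrogram=dendrogram, cut_rule=f"maxclust({K})"
    )


def group_connectivity(
    conn: ConnectivityMatrix | np.ndarray, partition: NetworkPartition
) -> GroupConnectivityStats:
    """Intra-group and inter-group-pair sums of unique pairwise values.

    ``intra(g)`` sums the upper triangle within group g; ``inter(g, h)``
    sums every cross edge between groups g and h.  Together they
    partition the upper triangle of the matrix, so
    ``sum(intra) + sum(inter) == total upper-triangle sum`` exactly.
    """
    m = _as_matrix(conn)
    if len(partition.labels) != m.shape[0]:
        raise ValueError("partition does not cover this matrix")
    groups = partition.groups()
    intra = {}
    inter = {}
    for g, members in enumerate(groups):
        sub = m[np.ix_(members, members)]
        intra[g] = float(np.triu(sub, 1).sum())
    for g in range(len(groups)):
        for h in range(g + 1, len(groups)):
            inter[(g, h)] = float(m[np.ix_(groups[g], groups[h])].sum())
    return GroupConnectivityStats(intra=intra, inter=inter)


def weighted_clustering_coefficient(
    conn: ConnectivityMatrix | np.ndarray,
) -> np.ndarray:
    """Fully weighted clustering coefficient per node (no thresholding).

    Geometric-mean triangle form: with weights rescaled by the global
    maximum, ``C_i = sum_{j != h} (w_ij w_ih w_jh)^(1/3) / (k_i (k_i-1))``
    where ``k_i`` counts node i's nonzero-weight neighbors.  Values lie
    in [0, 1]; invariant under global positive rescaling of the weights.
    """
    m = _as_matrix(conn)
    if np.any(m < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.diagonal(m) != 0):
        raise ValueError("diagonal must be zero")
    wmax = m.max()
    if wmax == 0:
        logger.warning("all-zero connectivity: clustering coefficients are zero")
        return np.zeros(m.shape[0])
    w = m / wmax
    a = np.cbrt(w)
    triangles = np.einsum("ij,jh,hi->i", a, a, a)  # 2x the triangle sum per node
    k = (m > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return c


def event_related_clustering(
    event_coeffs: np.ndarray, baseline_coeffs: np.ndarray, eps: float = 1e-6
) -> np.ndarray:
    """Baseline-normalized clustering coefficients: (event - base) / base."""
    ev = np.asarray(event_coeffs, dtype=float)
    ba = np.asarray(baseline_coeffs, dtype=float)
    if ev.shape != ba.shape:
        raise ValueError("event and baseline coefficient vectors must match")
    return (ev - ba) / np.maximum(ba, eps)
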