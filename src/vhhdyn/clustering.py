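"""Clustering of domains by their dynamics profiles.

The pairwise distance between two domains is the MSA-guided mean absolute
difference of their column-projected RMSF profiles,

    d(v, w) = 1/(n - m) * Σ_i |v_i - w_i|,

where the sum runs over the n alignment columns and n - m counts the
columns at which *both* domains have a residue (pairwise deletion; a
column with a gap in either sequence contributes nothing).  An alternative
distance averages the per-column ΔPB between the two domains' Protein
Block frequency profiles.  Domains are then grouped by agglomerative
hierarchical clustering with complete linkage, and two flat clusterings
can be compared through a contingency table plus the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.cluster import contingency_matrix

from .metrics import FrequencyVector, delta_pb

__all__ = [
    "DistanceMatrix",
    "ClusterResult",
    "rmsf_distance",
    "avg_deltapb_distance",
    "profile_distance_matrix",
    "deltapb_distance_matrix",
    "hcluster",
    "confusion",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between domains."""

    domain_ids: list[str]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.domain_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match domain count")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite distances")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise ValueError("matrix not symmetric")
        if np.abs(np.diag(self.values)).max() > 1e-12:
            raise ValueError("nonzero diagonal")


@dataclass
class ClusterResult:
    """Flat labels plus the dendrogram that produced them.

    ``labels`` are positive integers numbered by first appearance in the
    domain list; ``singleton`` flags clusters smaller than the configured
    minimum size.
    """

    domain_ids: list[str]
    labels: np.ndarray
    merges: np.ndarray            # scipy linkage matrix
    singleton: np.ndarray
    params: dict = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [d for d, l in zip(self.domain_ids, self.labels)
                if l == label]


def rmsf_distance(v: np.ndarray, w: np.ndarray,
                  squared: bool = False) -> float:
    """MSA-guided mean absolute difference between two column profiles.

    ``v`` and ``w`` are column-indexed vectors with NaN at gap columns;
    only columns where both values are present contribute, and the sum is
    divided by the number of such columns.  ``squared=True`` switches to
    the root-mean-square variant (sensitivity checks only).
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("profiles live in different column spaces")
    both = ~np.isnan(v) & ~np.isnan(w)
    if not both.any():
        raise ValueError("no shared occupied columns between profiles")
    diff = v[both] - w[both]
    if squared:
        return float(np.sqrt(np.mean(diff ** 2)))
    return float(np.mean(np.abs(diff)))


def avg_deltapb_distance(p1: dict[int, FrequencyVector],
                         p2: dict[int, FrequencyVector]) -> float:
    """Mean per-column ΔPB over columns defined in both domains.

    ``p1`` and ``p2`` map 1-based MSA columns to PB frequency vectors;
    undefined vectors and absent columns are skipped pairwise.
    """
    shared = [c for c in p1 if c in p2
              and p1[c].defined and p2[c].defined]
    if not shared:
        raise ValueError("no shared defined columns between PB profiles")
    return float(np.mean([delta_pb(p1[c], p2[c]) for c in shared]))


def profile_distance_matrix(profiles: dict[str, np.ndarray],
                            squared: bool = False) -> DistanceMatrix:
    """All-pairs :func:`rmsf_distance` over column-projected profiles."""
    ids = list(profiles)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = rmsf_distance(
                profiles[ids[i]], profiles[ids[j]], squared=squared)
    return DistanceMatrix(ids, d, metric="rmsf_msa_mad")


def deltapb_distance_matrix(
        profiles: dict[str, dict[int, FrequencyVector]]) -> DistanceMatrix:
    """All-pairs :func:`avg_deltapb_distance`."""
    ids = list(profiles)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = avg_deltapb_distance(
                profiles[ids[i]], profiles[ids[j]])
    return DistanceMatrix(ids, d, metric="avg_deltapb")


def _relabel_by_first_appearance(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, l in enumerate(labels):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return out


def hcluster(dm: DistanceMatrix, k: int | None = 4,
             height: float | None = None, min_size: int = 2,
             method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of a distance matrix, complete linkage.

    With ``k`` given, the dendrogram is scanned from ``k`` flat clusters
    upward until at least ``k`` clusters of size >= ``min_size`` exist (or
    the scan is exhausted), so that small outlying domains are split off
    as flagged singletons rather than absorbed into the dense clusters.
    With ``height`` given, the tree is simply cut at that height.
    Cluster numbers are assigned by first appearance in the domain list.
    """
    n = len(dm.domain_ids)
    if height is None:
        if k is None:
            raise ValueError("either k or height is required")
        if not 1 <= k <= n:
            raise ValueError(f"k={k} invalid for {n} domains")
    Z = linkage(squareform(dm.values, checks=False), method=method)
    if height is not None:
        flat = fcluster(Z, t=height, criterion="distance")
        params = {"method": method, "height": height, "min_size": min_size}
    else:
        flat = fcluster(Z, t=k, criterion="maxclust")
        for k_total in range(k, n + 1):
            flat = fcluster(Z, t=k_total, criterion="maxclust")
            _, sizes = np.unique(flat, return_counts=True)
            if (sizes >= min_size).sum() >= k:
                break
        params = {"method": method, "k": k, "min_size": min_size}
    flat = _relabel_by_first_appearance(flat)
    _, inv, sizes = np.unique(flat, return_inverse=True, return_counts=True)
    singleton = sizes[inv] < min_size
    return ClusterResult(list(dm.domain_ids), flat, Z, singleton, params)


def confusion(a, b, domain_ids_a=None, domain_ids_b=None
              ) -> tuple[np.ndarray, float]:
    """Contingency table and adjusted Rand index of two flat clusterings.

    ``a`` and ``b`` must label the same domains in the same order (pass
    ``domain_ids_*`` to enforce the identity).  The table's rows follow the
    sorted labels of ``a`` and its columns those of ``b``; the ARI is
    invariant to label permutation and lies in [-1, 1].
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("clusterings cover different numbers of domains")
    if domain_ids_a is not None and domain_ids_b is not None:
        if list(domain_ids_a) != list(domain_ids_b):
            raise ValueError("clusterings cover different domain sets")
    table = contingency_matrix(a, b)
    return table, float(adjusted_rand_score(a, b))
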