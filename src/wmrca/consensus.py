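"""Resampling consensus clustering with CDF / delta-area diagnostics.

For a fixed cluster number K, samples are repeatedly subsampled without
replacement, clustered with a base algorithm, and the fraction of runs in
which each pair is co-clustered among the runs where it was co-sampled is
recorded in an N × N consensus matrix M.  A stable K yields a near-binary
M; the empirical CDF of its upper-triangular entries and the change of the
area under that CDF across K are the classic diagnostics for choosing K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.cluster import KMeans

from .preprocess import FeatureMatrix

log = logging.getLogger("wmrca")

Distance = Literal["pearson", "spearman", "euclidean", "jaccard"]
BaseAlgorithm = Literal["hierarchical", "kmeans", "pam"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ConsensusMatrix:
    """Co-clustering frequencies from resampled clustering at one K."""

    M: np.ndarray
    K: int
    n_reps: int
    sample_ids: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n = len(self.sample_ids)
        if self.M.shape != (n, n):
            raise ValueError("consensus matrix shape does not match sample_ids")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(self.M), 1.0):
            raise ValueError("consensus matrix diagonal must be 1")
        if self.M.min() < -1e-12 or self.M.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def pair_values(self) -> np.ndarray:
        """Upper-triangular consensus values, one per sample pair."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.M[iu]


@dataclass
class ClusterAssignment:
    """Hard sample labels in 1..K with every class non-empty."""

    labels: dict[str, int]
    K: int

    def __post_init__(self) -> None:
        present = set(self.labels.values())
        if present != set(range(1, self.K + 1)):
            raise ValueError(f"labels must cover exactly 1..{self.K}, got {sorted(present)}")

    def to_array(self, sample_ids: list[str] | None = None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else list(self.labels)
        return np.array([self.labels[s] for s in ids], dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)


@dataclass
class CdfCurve:
    """Empirical CDF of consensus pair values on a uniform [0, 1] grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("CDF values must be non-decreasing")
        if abs(self.values[-1] - 1.0) > 1e-12:
            raise ValueError("CDF must reach 1 at the end of the grid")

    def area(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


# ---------------------------------------------------------------------------
# Distances and base clusterers
# ---------------------------------------------------------------------------

def sample_dissimilarity(X: np.ndarray, distance: Distance) -> np.ndarray:
    """N × N dissimilarity between sample columns of a features × samples array."""
    if distance == "euclidean":
        D = squareform(pdist(X.T, metric="euclidean"))
    elif distance == "jaccard":  # for binary membership profiles
        D = squareform(pdist(X.T.astype(bool), metric="jaccard"))
    elif distance in ("pearson", "spearman"):
        if X.shape[0] < 2:
            raise ValueError("correlation distance needs at least 2 features")
        if distance == "pearson":
            C = np.corrcoef(X.T)
        else:
            C, _ = spearmanr(X)
            C = np.atleast_2d(C)
        if np.isnan(C).any():
            log.warning("constant sample profile: undefined correlations set to 0")
            C = np.nan_to_num(C, nan=0.0)
        D = 1.0 - C
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return D


def _cut_to_labels(Z: np.ndarray, K: int) -> np.ndarray:
    """Cut a linkage tree into exactly K clusters, labels 0..K-1."""
    return cut_tree(Z, n_clusters=K).ravel()


def _kmedoids(D: np.ndarray, K: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """Voronoi-iteration k-medoids on a precomputed dissimilarity."""
    n = D.shape[0]
    medoids = np.sort(rng.choice(n, size=K, replace=False))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        # keep empty clusters alive by retaining their medoid
        new_medoids = medoids.copy()
        for k in range(K):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[k] = members[np.argmin(costs)]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _cluster_once(
    X_sub: np.ndarray,
    K: int,
    base_algorithm: BaseAlgorithm,
    distance: Distance,
    linkage_name: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster the sample columns of X_sub into K groups; labels 0..K-1."""
    if base_algorithm == "hierarchical":
        D = sample_dissimilarity(X_sub, distance)
        Z = scipy_linkage(squareform(D, checks=False), method=linkage_name)
        return _cut_to_labels(Z, K)
    if base_algorithm == "kmeans":
        seed = int(rng.integers(2**31))
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        return km.fit_predict(X_sub.T)
    if base_algorithm == "pam":
        D = sample_dissimilarity(X_sub, distance)
        return _kmedoids(D, K, rng)
    raise ValueError(f"unknown base algorithm {base_algorithm!r}")


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def build_consensus_matrix(
    m: FeatureMatrix,
    K: int,
    n_reps: int = 250,
    subsample_fraction: float = 0.8,
    base_algorithm: BaseAlgorithm = "hierarchical",
    distance: Distance = "pearson",
    linkage: str = "complete",
    seed: int = 0,
) -> ConsensusMatrix:
    """Resample, cluster, and accumulate co-clustering frequencies at one K.

    Each repetition draws ``round(subsample_fraction * N)`` samples without
    replacement, clusters them into K groups, and increments co-cluster and
    co-sampling counts; M is their elementwise ratio.  A fixed seed makes M
    bit-identical across runs.
    """
    if np.isnan(m.values).any():
        raise ValueError("consensus clustering requires a complete matrix; impute first")
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    N = m.n_samples
    n_sub = int(round(subsample_fraction * N))
    if K > n_sub:
        raise ValueError(f"K={K} exceeds the subsample size {n_sub}")
    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((N, N))
    co_sampled = np.zeros((N, N))
    for _ in range(n_reps):
        idx = np.sort(rng.choice(N, size=n_sub, replace=False))
        labels = _cluster_once(m.values[:, idx], K, base_algorithm, distance, linkage, rng)
        co_sampled[np.ix_(idx, idx)] += 1
        for k in range(labels.max() + 1):
            members = idx[labels == k]
            co_cluster[np.ix_(members, members)] += 1
    never = (co_sampled == 0) & ~np.eye(N, dtype=bool)
    if never.any():
        log.warning("%d sample pairs never co-sampled; their consensus is set to 0 "
                    "(increase n_reps or subsample_fraction)", int(never.sum()) // 2)
    M = np.divide(co_cluster, co_sampled, out=np.zeros((N, N)), where=co_sampled > 0)
    np.fill_diagonal(M, 1.0)
    return ConsensusMatrix(
        M=M, K=K, n_reps=n_reps, sample_ids=list(m.sample_ids),
        params=dict(subsample_fraction=subsample_fraction, base_algorithm=base_algorithm,
                    distance_name=distance, linkage_name=linkage, seed=seed),
    )


def consensus_dissimilarity(cm: ConsensusMatrix) -> np.ndarray:
    """1 - M with exact zero diagonal, clipped to [0, 1]."""
    D = np.clip(1.0 - cm.M, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def assign_consensus_labels(cm: ConsensusMatrix, linkage: str = "complete") -> ClusterAssignment:
    """Final labels: agglomerative clustering of 1 - M cut into K groups.

    Cluster ids are renumbered 1..K in order of first appearance so the
    labelling is deterministic.
    """
    D = consensus_dissimilarity(cm)
    off = D[~np.eye(cm.n_samples, dtype=bool)]
    if off.size and np.ptp(off) < 1e-12:
        raise ValueError(
            "degenerate consensus matrix (all pairs equally similar); "
            "try a different K or more repetitions"
        )
    Z = scipy_linkage(squareform(D, checks=False), method=linkage)
    raw = _cut_to_labels(Z, cm.K)
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    labels = {s: relabel[r] for s, r in zip(cm.sample_ids, raw)}
    return ClusterAssignment(labels=labels, K=cm.K)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def consensus_cdf(cm: ConsensusMatrix, grid_size: int = 101) -> CdfCurve:
    """Empirical CDF of the N(N-1)/2 pairwise consensus values."""
    if cm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    vals = cm.pair_values()
    grid = np.linspace(0.0, 1.0, grid_size)
    values = (vals[None, :] <= grid[:, None]).mean(axis=1)
    return CdfCurve(grid=grid, values=values)


def delta_area_curve(cdfs: dict[int, CdfCurve]) -> dict[int, float]:
    """Relative change in the area under the CDF across consecutive K.

    The K=2 entry is the total area under its CDF; for K > 2 the entry is
    (A(K) - A(K-1)) / A(K-1).
    """
    ks = sorted(cdfs)
    if not ks or ks[0] != 2 or ks != list(range(2, 2 + len(ks))):
        raise ValueError("K grid must be contiguous and start at 2")
    areas = {k: cdfs[k].area() for k in ks}
    delta = {2: areas[2]}
    for k in ks[1:]:
        delta[k] = (areas[k] - areas[k - 1]) / areas[k - 1]
    return delta


def _best_match_changes(a: np.ndarray, b: np.ndarray) -> int:
    """Samples whose group changes between two partitions, after optimally
    matching labels (Hungarian on the contingency table, padded square)."""
    la = np.unique(a)
    lb = np.unique(b)
    cont = np.zeros((la.size, lb.size), dtype=int)
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            cont[i, j] = int(np.sum((a == x) & (b == y)))
    size = max(la.size, lb.size)
    padded = np.zeros((size, size), dtype=int)
    padded[: la.size, : lb.size] = cont
    rows, cols = linear_sum_assignment(-padded)
    agree = padded[rows, cols].sum()
    return int(a.size - agree)


def tracking_table(
    assignments: dict[int, ClusterAssignment],
) -> tuple[pd.DataFrame, dict[tuple[int, int], int]]:
    """Long-format (sample, K, label) table plus per-K-step instability.

    For each consecutive pair of K values the second element counts the
    samples whose cluster membership changes once labels are optimally
    matched (so a pure relabelling counts as zero changes).
    """
    ks = sorted(assignments)
    sample_sets = {k: set(assignments[k].labels) for k in ks}
    base = sample_sets[ks[0]]
    if any(s != base for s in sample_sets.values()):
        raise ValueError("all assignments must share the same sample set")
    samples = list(assignments[ks[0]].labels)
    rows = [(s, k, assignments[k].labels[s]) for k in ks for s in samples]
    table = pd.DataFrame(rows, columns=["sample_id", "K", "cluster"])
    changes: dict[tuple[int, int], int] = {}
    for k1, k2 in zip(ks, ks[1:]):
        a = assignments[k1].to_array(samples)
        b = assignments[k2].to_array(samples)
        changes[(k1, k2)] = _best_match_changes(a, b)
    return table, changes
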