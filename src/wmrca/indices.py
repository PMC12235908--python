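"""Internal cluster-validation indices and per-index best-K decisions.

Ten indices score a clustering over a grid of candidate K: the proportion
of ambiguous clustering (PAC) and the cophenetic index, both computed from
the consensus matrix; seven partition indices (mean silhouette,
Calinski–Harabasz, entropy, Dunn, Dunn 2, within/between ratio, Pearson
gamma) computed from the clustering dissimilarity and labels; and the gap
statistic computed from the raw data against a uniform reference.  Each
index profile is reduced to a one-hot vote for its preferred K, and the
votes are stacked into a binary decision matrix for weighted voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import calinski_harabasz_score

from .consensus import (
    ClusterAssignment,
    ConsensusMatrix,
    consensus_dissimilarity,
    _cut_to_labels,
)
from .preprocess import FeatureMatrix

log = logging.getLogger("wmrca")

#: canonical index order (rows of the decision matrix)
INDEX_NAMES: tuple[str, ...] = (
    "pac", "cophenetic", "silhouette", "calinski_harabasz", "entropy",
    "dunn", "dunn2", "wb_ratio", "pearson_gamma", "gap",
)

INDEX_DIRECTIONS: dict[str, str] = {
    "pac": "minimize",
    "cophenetic": "maximize",
    "silhouette": "maximize",
    "calinski_harabasz": "maximize",
    "entropy": "maximize",
    "dunn": "maximize",
    "dunn2": "maximize",
    "wb_ratio": "minimize",
    "pearson_gamma": "maximize",
    "gap": "special",
}


@dataclass
class IndexProfile:
    """One index evaluated over the K grid (NaN where undefined)."""

    index_name: str
    k_grid: list[int]
    values: np.ndarray
    direction: Literal["minimize", "maximize", "special"]
    se: np.ndarray | None = None  # standard errors (gap statistic only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.k_grid),):
            raise ValueError("values length must match k_grid")
        expected = INDEX_DIRECTIONS.get(self.index_name)
        if expected is not None and expected != self.direction:
            raise ValueError(
                f"{self.index_name} must have direction {expected!r}, got {self.direction!r}")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se length must match k_grid")


@dataclass
class DecisionMatrix:
    """Binary T × |k_grid| matrix of one-hot per-index votes."""

    d: np.ndarray
    index_names: list[str]
    k_grid: list[int]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=int)
        if self.d.shape != (len(self.index_names), len(self.k_grid)):
            raise ValueError("decision matrix shape mismatch")
        if not np.isin(self.d, (0, 1)).all():
            raise ValueError("decision matrix entries must be 0/1")
        if not (self.d.sum(axis=1) == 1).all():
            raise ValueError("every index row must vote for exactly one K")

    @property
    def T(self) -> int:
        return len(self.index_names)


# ---------------------------------------------------------------------------
# Consensus-matrix indices
# ---------------------------------------------------------------------------

def pac(cm: ConsensusMatrix, x1: float = 0.1, x2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: CDF(x2) - CDF(x1), exact counts.

    The fraction of sample pairs whose consensus value lies in (x1, x2] —
    pairs neither clearly together nor clearly apart.  Lower is better.
    """
    if not 0 <= x1 < x2 <= 1:
        raise ValueError("need 0 <= x1 < x2 <= 1")
    vals = cm.pair_values()
    return float(np.mean(vals <= x2) - np.mean(vals <= x1))


def cophenetic_index(cm: ConsensusMatrix, linkage: str = "complete") -> tuple[float, float]:
    """(cophenetic correlation, mean cophenetic distance) of the consensus tree.

    The dendrogram is built on 1 - M; the correlation between the original
    dissimilarities and the dendrogram's cophenetic distances measures how
    faithfully a hierarchical structure fits the consensus (closer to 1 is
    more stable; this is the voting statistic).  The plain mean of all
    pairwise cophenetic distances is returned as a secondary diagnostic.
    """
    if cm.n_samples < 3:
        raise ValueError("cophenetic index needs at least 3 samples")
    y = squareform(consensus_dissimilarity(cm), checks=False)
    Z = scipy_linkage(y, method=linkage)
    coph_d = cophenet(Z)
    mean_coph = float(np.mean(coph_d))
    if np.ptp(y) < 1e-15 or np.ptp(coph_d) < 1e-15:
        log.warning("cophenetic correlation undefined (constant dissimilarities)")
        return float("nan"), mean_coph
    corr = float(np.corrcoef(y, coph_d)[0, 1])
    return corr, mean_coph


# ---------------------------------------------------------------------------
# Partition indices on a dissimilarity + labels
# ---------------------------------------------------------------------------

def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed dissimilarity.

    Singleton clusters score 0 (and so does a sample with a(i)=b(i)=0).
    """
    n = D.shape[0]
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i])
        n_same = same.sum()
        if n_same <= 1:
            continue  # singleton -> 0
        a = D[i, same].sum() / (n_same - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def partition_indices(
    dist: np.ndarray,
    X: np.ndarray | None,
    labels: ClusterAssignment | np.ndarray,
) -> dict[str, float]:
    """Seven partition-quality indices for one clustering.

    Parameters
    ----------
    dist
        Symmetric N × N dissimilarity with zero diagonal (the clustering
        geometry, e.g. 1 - Pearson).
    X
        Optional N × d coordinate matrix (samples as rows) used only for
        the Calinski–Harabasz index; NaN is returned for it when absent.
    labels
        Cluster assignment with >= 2 non-empty clusters.

    Statistics that are undefined for the given partition (e.g. no
    within-cluster pair anywhere) come back as NaN.
    """
    lab = labels.to_array() if isinstance(labels, ClusterAssignment) else np.asarray(labels)
    n = dist.shape[0]
    if dist.shape != (n, n) or lab.shape != (n,):
        raise ValueError("dist must be N x N and labels length N")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("dist must be symmetric with zero diagonal")
    uniq = np.unique(lab)
    K = uniq.size
    if K < 2:
        raise ValueError("need at least 2 non-empty clusters")

    out: dict[str, float] = {}
    same = lab[:, None] == lab[None, :]
    iu = np.triu_indices(n, k=1)
    d_vec = dist[iu]
    same_vec = same[iu]

    out["silhouette"] = _mean_silhouette(dist, lab)

    if X is not None and K < n:
        out["calinski_harabasz"] = float(calinski_harabasz_score(X, lab))
    else:
        out["calinski_harabasz"] = float("nan")

    sizes = np.array([(lab == c).sum() for c in uniq], dtype=float)
    p = sizes / n
    out["entropy"] = float(-(p * np.log(p)).sum())

    within = d_vec[same_vec]
    between = d_vec[~same_vec]
    if within.size == 0:  # all-singleton partition
        out["dunn"] = float("nan")
        out["dunn2"] = float("nan")
        out["wb_ratio"] = float("nan")
    else:
        max_diam = float(within.max())
        min_sep = float(between.min())
        # zero diameter with positive separation = perfectly tight clusters
        if max_diam > 0:
            out["dunn"] = min_sep / max_diam
        else:
            out["dunn"] = float("inf") if min_sep > 0 else float("nan")
        # dunn2: min average between-cluster / max average within-cluster
        avg_within = [dist[np.ix_(lab == c, lab == c)][np.triu_indices(int(s), k=1)].mean()
                      for c, s in zip(uniq, sizes) if s >= 2]
        avg_between = [dist[np.ix_(lab == c1, lab == c2)].mean()
                       for i, c1 in enumerate(uniq) for c2 in uniq[i + 1:]]
        max_avg_within = max(avg_within)
        min_avg_between = min(avg_between)
        if max_avg_within > 0:
            out["dunn2"] = min_avg_between / max_avg_within
        else:
            out["dunn2"] = float("inf") if min_avg_between > 0 else float("nan")
        out["wb_ratio"] = float(within.mean() / between.mean()) if between.mean() > 0 else float("nan")

    if np.ptp(d_vec) < 1e-15 or same_vec.all() or (~same_vec).all():
        out["pearson_gamma"] = float("nan")
    else:
        out["pearson_gamma"] = float(np.corrcoef(d_vec, (~same_vec).astype(float))[0, 1])
    return out


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------

def _pooled_within_dispersion(X: np.ndarray, labels: np.ndarray) -> float:
    """W = sum over clusters of (sum of within pairwise squared distances) / (2 n_k)."""
    W = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        if members.shape[0] < 2:
            continue
        W += float(np.sum(pdist(members, metric="sqeuclidean")) / (2 * members.shape[0]))
        # equals the within-cluster sum of squared deviations from the centroid
    return W


def gap_statistic(
    X: FeatureMatrix | np.ndarray,
    assignments: dict[int, ClusterAssignment],
    B: int = 50,
    seed: int = 0,
) -> IndexProfile:
    """Gap statistic profile over the K grid of the given assignments.

    Gap(K) = mean_b log W*_Kb - log W_K, with W the pooled within-cluster
    dispersion, and B reference datasets drawn uniformly over the
    per-feature range box of the observed samples.  Reference datasets are
    clustered hierarchically (complete linkage, Euclidean) at each K.  The
    returned profile carries s_K = sd_b(log W*) * sqrt(1 + 1/B) for the
    one-standard-error selection rule.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    if isinstance(X, FeatureMatrix):
        if np.isnan(X.values).any():
            raise ValueError("gap statistic requires a complete matrix")
        pts = X.values.T  # samples as rows
    else:
        pts = np.asarray(X, dtype=float)
    if np.ptp(pts, axis=0).max() == 0:
        raise ValueError("degenerate constant data")
    ks = sorted(assignments)
    # W == 0 (perfectly tight clusters) maps to log W = -inf, hence Gap = +inf
    with np.errstate(divide="ignore"):
        log_W = np.log(np.array([
            _pooled_within_dispersion(pts, assignments[k].to_array()) for k in ks
        ]))
    rng = np.random.default_rng(seed)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    log_W_ref = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=pts.shape)
        Z = scipy_linkage(pdist(ref, metric="euclidean"), method="complete")
        for j, k in enumerate(ks):
            lab = _cut_to_labels(Z, k)
            log_W_ref[b, j] = np.log(_pooled_within_dispersion(ref, lab))
    gap = log_W_ref.mean(axis=0) - log_W
    sd = log_W_ref.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / B)
    return IndexProfile(index_name="gap", k_grid=ks, values=gap, direction="special", se=se)


# ---------------------------------------------------------------------------
# Best-K decisions
# ---------------------------------------------------------------------------

def decide_best_k(profile: IndexProfile) -> int:
    """Reduce an index profile to its preferred K.

    minimize -> K of the smallest value; maximize -> K of the largest; the
    gap statistic uses Tibshirani's one-standard-error rule (smallest K
    with Gap(K) >= Gap(K+1) - s_{K+1}), falling back to the argmax.  Ties
    break toward the smallest K; missing values are skipped.
    """
    vals = profile.values
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError(f"index {profile.index_name!r} has no defined values")
    ks = np.asarray(profile.k_grid)
    if profile.direction == "special":  # gap
        se = profile.se if profile.se is not None else np.zeros_like(vals)
        for j in range(len(ks) - 1):
            if not (ok[j] and ok[j + 1]):
                continue
            if vals[j] >= vals[j + 1] - se[j + 1]:
                return int(ks[j])
        return int(ks[ok][np.argmax(vals[ok])])
    if profile.direction == "minimize":
        return int(ks[ok][np.argmin(vals[ok])])
    return int(ks[ok][np.argmax(vals[ok])])


def build_decision_matrix(profiles: list[IndexProfile]) -> DecisionMatrix:
    """Stack one-hot best-K votes, rows in canonical index order."""
    if not profiles:
        raise ValueError("no index profiles given")
    grid = profiles[0].k_grid
    for p in profiles:
        if p.k_grid != grid:
            raise ValueError("all profiles must share the same K grid")
    canon = {name: i for i, name in enumerate(INDEX_NAMES)}
    ordered = sorted(profiles, key=lambda p: canon.get(p.index_name, len(canon)))
    d = np.zeros((len(ordered), len(grid)), dtype=int)
    for t, p in enumerate(ordered):
        d[t, grid.index(decide_best_k(p))] = 1
    return DecisionMatrix(d=d, index_names=[p.index_name for p in ordered], k_grid=list(grid))


def compute_index_profiles(
    m: FeatureMatrix,
    consensus_by_k: dict[int, ConsensusMatrix],
    assignments: dict[int, ClusterAssignment],
    dist: np.ndarray,
    pac_bounds: tuple[float, float] = (0.1, 0.9),
    cophenetic_linkage: str = "complete",
    gap_b: int = 50,
    gap_seed: int = 0,
) -> list[IndexProfile]:
    """All ten index profiles for one matrix over its K grid."""
    ks = sorted(consensus_by_k)
    if sorted(assignments) != ks:
        raise ValueError("consensus matrices and assignments must share the K grid")
    pac_vals, coph_vals = [], []
    part_vals: dict[str, list[float]] = {name: [] for name in INDEX_NAMES
                                         if name not in ("pac", "cophenetic", "gap")}
    for k in ks:
        pac_vals.append(pac(consensus_by_k[k], *pac_bounds))
        corr, _ = cophenetic_index(consensus_by_k[k], linkage=cophenetic_linkage)
        coph_vals.append(corr)
        pi = partition_indices(dist, m.values.T, assignments[k])
        for name in part_vals:
            part_vals[name].append(pi[name])
    profiles = [
        IndexProfile("pac", ks, np.array(pac_vals), "minimize"),
        IndexProfile("cophenetic", ks, np.array(coph_vals), "maximize"),
    ]
    for name, vals in part_vals.items():
        profiles.append(IndexProfile(name, ks, np.array(vals), INDEX_DIRECTIONS[name]))
    profiles.append(gap_statistic(m, assignments, B=gap_b, seed=gap_seed))
    return profiles
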