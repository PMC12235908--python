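"""Feature selection: gene-set restriction and variance/MAD/PCA ranking.

Selecting an informative feature subset per omics layer — by membership in
a curated gene set (e.g. metabolic pathway genes) or by a spread statistic
— sharpens the sample-to-sample geometry that the consensus clustering
stage works on.  Output is always a row subset of the input; samples are
untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from sklearn.decomposition import PCA

from .preprocess import FeatureMatrix

log = logging.getLogger("wmrca")


@dataclass
class GeneSet:
    """Named set of gene identifiers (GMT record)."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(str(m) for m in self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line needs name, description and >=1 member: {line[:60]}")
            members = [p for p in parts[2:] if p]
            sets.append(GeneSet(name=parts[0], description=parts[1], members=frozenset(members)))
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def select_by_gene_set(m: FeatureMatrix, gs: GeneSet) -> FeatureMatrix:
    """Restrict rows to feature ids in the set, preserving input order."""
    keep = [f for f in m.feature_ids if f in gs.members]
    if not keep:
        raise ValueError(
            f"gene set {gs.name!r} has no overlap with layer {m.layer_name!r} features"
        )
    log.info("select_by_gene_set(%s): %d/%d features matched set %r",
             m.layer_name, len(keep), m.n_features, gs.name)
    return m.subset_features(keep)


def select_top_features(
    m: FeatureMatrix,
    method: Literal["variance", "mad", "pca"] = "variance",
    n_top: int = 1000,
    n_components: int = 10,
) -> FeatureMatrix:
    """Keep the n_top features ranked by a spread/loadings score.

    variance: per-feature sample variance (ddof=1).
    mad: unscaled median absolute deviation from the feature median.
    pca: per-feature sum over the leading ``n_components`` principal
    components of |loading| × component standard deviation, computed on
    feature-centered data; a feature that drives a large share of the
    sample-to-sample variance therefore scores high.  Ties break toward
    earlier input rows.
    """
    if np.isnan(m.values).any():
        raise ValueError("select_top_features requires a complete matrix; impute first")
    if not 0 < n_top <= m.n_features:
        raise ValueError(f"n_top must be in [1, {m.n_features}]")
    X = m.values
    if method == "variance":
        scores = np.var(X, axis=1, ddof=1)
    elif method == "mad":
        scores = np.median(np.abs(X - np.median(X, axis=1, keepdims=True)), axis=1)
    elif method == "pca":
        if n_components <= 0:
            raise ValueError("n_components must be positive")
        Z = X - X.mean(axis=1, keepdims=True)
        nc = min(n_components, m.n_samples - 1, m.n_features)
        pca = PCA(n_components=nc, svd_solver="full")
        pca.fit(Z.T)  # samples as observations
        comp_sd = np.sqrt(pca.explained_variance_)
        scores = np.abs(pca.components_).T @ comp_sd
    else:
        raise ValueError(f"unknown selection method {method!r}")
    order = np.argsort(-scores, kind="stable")[:n_top]
    order = np.sort(order)  # preserve input feature order among the selected
    keep = [m.feature_ids[i] for i in order]
    return m.subset_features(keep)
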