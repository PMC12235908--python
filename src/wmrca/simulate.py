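"""Synthetic multi-omics data with known latent subtypes.

The generator plants k_true subtypes shared across every layer.  Each
layer is a Gaussian features × samples matrix in which an informative
subset of features carries a subtype-specific mean shift: for each
informative feature one subtype (chosen at random, fixed across samples)
is shifted by ``effect_size`` standard-deviation units against the
others.  Methylation-like layers are squashed to (0, 1) with a logistic
transform to emulate beta values; entries are masked missing completely
at random.  A companion generator tiles chromosomes with copy-number
segments whose values carry the same subtype structure, so the
segment-to-gene projection can be exercised end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import GeneSet
from .preprocess import FeatureMatrix, GeneModel, SegmentTable

log = logging.getLogger("wmrca")


@dataclass
class LayerSpec:
    layer_name: str
    n_features: int = 100
    informative_fraction: float = 0.4
    effect_size: float = 8.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.informative_fraction > 0 and self.n_features == 0:
            raise ValueError("informative features requested but n_features is 0")


@dataclass
class SimConfig:
    n_samples: int = 60
    k_true: int = 2
    layers: list[LayerSpec] = field(default_factory=lambda: [
        LayerSpec("mrna", 120), LayerSpec("mirna", 80), LayerSpec("methylation", 100),
    ])
    seed: int = 0
    cluster_proportions: tuple[float, ...] | None = None  # None = equal

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            if p.shape != (self.k_true,) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValueError("cluster_proportions must be a simplex of length k_true")


def _assign_subtypes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    p = (np.full(cfg.k_true, 1 / cfg.k_true) if cfg.cluster_proportions is None
         else np.asarray(cfg.cluster_proportions, dtype=float))
    truth = rng.choice(cfg.k_true, size=cfg.n_samples, p=p) + 1
    # guarantee every subtype appears so downstream label contracts hold
    for k in range(1, cfg.k_true + 1):
        if not (truth == k).any():
            truth[rng.integers(cfg.n_samples)] = k
    return truth


def simulate_multiomics(cfg: SimConfig) -> tuple[list[FeatureMatrix], dict[str, int]]:
    """Generate one matrix per layer plus the true subtype of each sample."""
    rng = np.random.default_rng(cfg.seed)
    truth = _assign_subtypes(cfg, rng)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    matrices: list[FeatureMatrix] = []
    for spec in cfg.layers:
        n_info = int(round(spec.informative_fraction * spec.n_features))
        X = rng.normal(0.0, spec.noise_sd, size=(spec.n_features, cfg.n_samples))
        up_subtype = rng.integers(1, cfg.k_true + 1, size=n_info)
        for f in range(n_info):
            X[f, truth == up_subtype[f]] += spec.effect_size
        if "meth" in spec.layer_name.lower():
            X = 1.0 / (1.0 + np.exp(-X))  # beta-value-like bounded signal
        if spec.missing_rate > 0:
            X[rng.random(X.shape) < spec.missing_rate] = np.nan
        feature_ids = [f"{spec.layer_name}_g{f + 1:04d}" for f in range(spec.n_features)]
        matrices.append(FeatureMatrix(X, feature_ids, sample_ids, layer_name=spec.layer_name))
    return matrices, {s: int(t) for s, t in zip(sample_ids, truth)}


def informative_feature_ids(m: FeatureMatrix, spec: LayerSpec) -> list[str]:
    """Ids of the planted informative features (the leading block)."""
    n_info = int(round(spec.informative_fraction * spec.n_features))
    return m.feature_ids[:n_info]


@dataclass
class CnvSimConfig:
    informative_genes: list[str]
    effect_size: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0


def simulate_cnv_segments(
    truth: dict[str, int],
    genes: GeneModel,
    cfg: CnvSimConfig,
) -> SegmentTable:
    """Tile chromosomes with segments carrying subtype-dependent log-ratios.

    Designated (informative) genes sit in their own segments whose mean is
    ``effect_size`` for one subtype per gene and 0 otherwise; the rest of
    each chromosome is background noise.  Projecting the segments back
    onto the gene model recovers the planted shifts.
    """
    if len(genes) == 0:
        raise ValueError("empty gene model")
    unknown = [g for g in cfg.informative_genes if g not in genes.genes]
    if unknown:
        raise ValueError(f"informative genes not in the gene model: {unknown}")
    k_true = max(truth.values())
    rng = np.random.default_rng(cfg.seed)
    up_subtype = {g: int(rng.integers(1, k_true + 1)) for g in cfg.informative_genes}

    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for gid, (chrom, start, end) in genes.genes.items():
        by_chrom.setdefault(chrom, []).append((gid, start, end))
    info = set(cfg.informative_genes)
    for chrom, glist in by_chrom.items():
        marked = sorted([g for g in glist if g[0] in info], key=lambda g: g[1])
        for (g1, _, e1), (g2, s2, _) in zip(marked, marked[1:]):
            if s2 <= e1:
                raise ValueError(f"designated genes {g1} and {g2} overlap on {chrom}")

    rows = []
    for sample, subtype in truth.items():
        for chrom, glist in sorted(by_chrom.items()):
            chrom_end = max(e for _, _, e in glist) + 1000
            marked = sorted([g for g in glist if g[0] in info], key=lambda g: g[1])
            pos = 1
            for gid, gstart, gend in marked:
                if gstart > pos:
                    rows.append((sample, chrom, pos, gstart - 1,
                                 rng.normal(0.0, cfg.noise_sd)))
                shift = cfg.effect_size if subtype == up_subtype[gid] else 0.0
                rows.append((sample, chrom, gstart, gend,
                             shift + rng.normal(0.0, cfg.noise_sd)))
                pos = gend + 1
            if pos < chrom_end:
                rows.append((sample, chrom, pos, chrom_end, rng.normal(0.0, cfg.noise_sd)))
    return SegmentTable(pd.DataFrame(rows, columns=list(SegmentTable.COLUMNS)))


def make_gene_set_fixture(
    m: FeatureMatrix,
    informative_ids: list[str],
    decoy_count: int = 0,
    seed: int = 0,
    name: str = "synthetic_informative_set",
) -> GeneSet:
    """Gene set of all informative features plus random decoys.

    A synthetic stand-in for a curated pathway set (e.g. lipid-metabolism
    genes): it contains every planted informative feature of the layer and
    ``decoy_count`` randomly drawn uninformative ones.
    """
    missing = set(informative_ids) - set(m.feature_ids)
    if missing:
        raise ValueError(f"informative ids not in the matrix: {sorted(missing)[:5]}")
    pool = [f for f in m.feature_ids if f not in set(informative_ids)]
    if decoy_count > len(pool):
        raise ValueError(f"decoy_count {decoy_count} exceeds the {len(pool)} available decoys")
    rng = np.random.default_rng(seed)
    decoys = list(rng.choice(pool, size=decoy_count, replace=False)) if decoy_count else []
    return GeneSet(name=name, members=frozenset([*informative_ids, *decoys]),
                   description="synthetic fixture")
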