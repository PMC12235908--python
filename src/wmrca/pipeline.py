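"""The full subtype-discovery pipeline: per-layer consensus + voting,
cluster-of-clusters (COCA) integration, and a second voting round.

Each omics layer is consensus-clustered over a grid of candidate K; ten
validation indices vote (weighted majority) for that layer's K, and the
layer's samples get labels at the winning K.  The per-layer assignments
are one-hot encoded into an N × C binary membership matrix (C = sum of
the per-layer Ks), which is itself consensus-clustered and voted on to
produce the final integrated subtypes.  With L layers the procedure runs
L + 1 voting rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .consensus import (
    CdfCurve,
    ClusterAssignment,
    ConsensusMatrix,
    assign_consensus_labels,
    build_consensus_matrix,
    consensus_cdf,
    delta_area_curve,
    sample_dissimilarity,
)
from .features import GeneSet, select_by_gene_set
from .indices import DecisionMatrix, IndexProfile, build_decision_matrix, compute_index_profiles
from .preprocess import FeatureMatrix
from .voting import VotingResult, weighted_vote

log = logging.getLogger("wmrca")


@dataclass
class WmrcaConfig:
    """Analysis parameters shared by every consensus + voting round."""

    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_reps: int = 250
    subsample_fraction: float = 0.8
    base_algorithm: str = "hierarchical"
    distance: str = "pearson"
    linkage: str = "complete"
    binary_distance: str = "pearson"  # distance for the COCA round ("pearson" or "jaccard")
    pac_x1: float = 0.1
    pac_x2: float = 0.9
    gap_b: int = 50
    weights: tuple[float, ...] | None = None  # one per index, None = all 1
    theta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_grid)
        if not ks or ks[0] < 2 or ks != tuple(range(ks[0], ks[0] + len(ks))):
            raise ValueError("k_grid must be contiguous integers with minimum >= 2")
        self.k_grid = ks


@dataclass
class LayerResult:
    """Everything computed for one consensus + voting round."""

    layer_name: str
    assignment: ClusterAssignment
    decision: DecisionMatrix
    voting: VotingResult
    consensus_by_k: dict[int, ConsensusMatrix]
    assignments_by_k: dict[int, ClusterAssignment]
    profiles: list[IndexProfile]
    cdfs: dict[int, CdfCurve]
    delta_area: dict[int, float]

    @property
    def selected_k(self) -> int:
        return self.voting.selected_k


@dataclass
class BinaryMembershipMatrix:
    """N × C one-hot encoding of per-layer cluster memberships (COCA)."""

    B: np.ndarray
    sample_ids: list[str]
    block_sizes: list[int]
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=int)
        n, c = self.B.shape
        if n != len(self.sample_ids):
            raise ValueError("row count must match sample_ids")
        if c != sum(self.block_sizes):
            raise ValueError("column count must equal the sum of block sizes")
        if not np.isin(self.B, (0, 1)).all():
            raise ValueError("membership matrix must be binary")
        m = len(self.block_sizes)
        if not (self.B.sum(axis=1) == m).all():
            raise ValueError("every row must sum to the number of layers")
        off = 0
        for size in self.block_sizes:
            if not (self.B[:, off:off + size].sum(axis=1) == 1).all():
                raise ValueError("each row must be one-hot within every layer block")
            off += size

    @property
    def C(self) -> int:
        return int(self.B.shape[1])

    def column_ids(self) -> list[str]:
        names = []
        for m, size in enumerate(self.block_sizes):
            layer = self.layer_names[m] if self.layer_names else f"layer{m + 1}"
            names.extend(f"{layer}.c{j + 1}" for j in range(size))
        return names


@dataclass
class SubtypeResult:
    final_k: int
    final_labels: ClusterAssignment
    per_omics: dict[str, LayerResult]
    final_layer: LayerResult
    binary_matrix: BinaryMembershipMatrix
    sample_ids: list[str]
    restricted_layers: list[str] = field(default_factory=list)

    @property
    def final_voting(self) -> VotingResult:
        return self.final_layer.voting

    @property
    def n_voting_rounds(self) -> int:
        return len(self.per_omics) + 1


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def build_binary_matrix(
    assignments: list[ClusterAssignment],
    layer_names: list[str] | None = None,
) -> BinaryMembershipMatrix:
    """Concatenate per-layer one-hot membership blocks in layer order."""
    if not assignments:
        raise ValueError("no assignments given")
    samples = assignments[0].sample_ids
    for a in assignments[1:]:
        if set(a.labels) != set(samples):
            raise ValueError("all layers must share the same sample set")
    blocks = []
    for a in assignments:
        block = np.zeros((len(samples), a.K), dtype=int)
        for i, s in enumerate(samples):
            block[i, a.labels[s] - 1] = 1
        blocks.append(block)
    return BinaryMembershipMatrix(
        B=np.hstack(blocks),
        sample_ids=list(samples),
        block_sizes=[a.K for a in assignments],
        layer_names=list(layer_names) if layer_names else [],
    )


def _consensus_round(m: FeatureMatrix, config: WmrcaConfig, seed: int) -> LayerResult:
    """One full consensus + indices + voting round on a complete matrix."""
    rng = np.random.default_rng(seed)
    consensus_by_k: dict[int, ConsensusMatrix] = {}
    assignments: dict[int, ClusterAssignment] = {}
    cdfs: dict[int, CdfCurve] = {}
    for k in config.k_grid:
        cm = build_consensus_matrix(
            m, K=k, n_reps=config.n_reps,
            subsample_fraction=config.subsample_fraction,
            base_algorithm=config.base_algorithm,
            distance=config.distance, linkage=config.linkage,
            seed=int(rng.integers(2**31)),
        )
        consensus_by_k[k] = cm
        assignments[k] = assign_consensus_labels(cm, linkage=config.linkage)
        cdfs[k] = consensus_cdf(cm)
    dist = sample_dissimilarity(m.values, config.distance)
    profiles = compute_index_profiles(
        m, consensus_by_k, assignments, dist,
        pac_bounds=(config.pac_x1, config.pac_x2),
        cophenetic_linkage=config.linkage,
        gap_b=config.gap_b, gap_seed=int(rng.integers(2**31)),
    )
    decision = build_decision_matrix(profiles)
    voting = weighted_vote(decision, config.weights, config.theta)
    # the delta-area diagnostic is anchored at K=2 by definition
    delta = delta_area_curve(cdfs) if config.k_grid[0] == 2 else {}
    return LayerResult(
        layer_name=m.layer_name,
        assignment=assignments[voting.selected_k],
        decision=decision,
        voting=voting,
        consensus_by_k=consensus_by_k,
        assignments_by_k=assignments,
        profiles=profiles,
        cdfs=cdfs,
        delta_area=delta,
    )


def per_omics_optimal_k(
    m: FeatureMatrix,
    k_grid: tuple[int, ...] | None = None,
    config: WmrcaConfig | None = None,
    seed: int | None = None,
) -> LayerResult:
    """Consensus-cluster one layer over the K grid and vote for its K.

    Returns a :class:`LayerResult` whose ``assignment``, ``decision`` and
    ``voting`` fields carry the chosen labels, the 10 × |k_grid| decision
    matrix and the voting summary, along with all diagnostics.
    """
    config = config or WmrcaConfig()
    if k_grid is not None:
        config = replace(config, k_grid=tuple(k_grid))
    return _consensus_round(m, config, config.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def _common_samples(layers: list[FeatureMatrix]) -> list[str]:
    common = set(layers[0].sample_ids)
    for m in layers[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("layers share no samples")
    return [s for s in layers[0].sample_ids if s in common]


def wmrca(layers: list[FeatureMatrix], config: WmrcaConfig | None = None) -> SubtypeResult:
    """Run the full multi-omics pipeline and return the final subtypes.

    Layers are reduced to their common samples (order of the first layer).
    Per-layer rounds and the COCA round each draw their seeds from the one
    root seed in ``config``, so a fixed config reproduces results exactly.
    """
    if not layers:
        raise ValueError("at least one layer is required")
    config = config or WmrcaConfig()
    names = [m.layer_name for m in layers]
    if len(set(names)) != len(names):
        raise ValueError(f"layer names must be unique, got {names}")
    samples = _common_samples(layers)
    dropped = max(m.n_samples for m in layers) - len(samples)
    if dropped:
        log.info("restricting to %d common samples", len(samples))
    root = np.random.default_rng(config.seed)
    layer_seeds = [int(root.integers(2**31)) for _ in layers]
    final_seed = int(root.integers(2**31))

    per_omics: dict[str, LayerResult] = {}
    for m, s in zip(layers, layer_seeds):
        sub = m.subset_samples(samples)
        per_omics[m.layer_name] = _consensus_round(sub, config, s)

    bmm = build_binary_matrix(
        [per_omics[n].assignment for n in names], layer_names=names)
    binary_fm = FeatureMatrix(
        values=bmm.B.T.astype(float),
        feature_ids=bmm.column_ids(),
        sample_ids=bmm.sample_ids,
        layer_name="coca",
    )
    final_config = replace(config, distance=config.binary_distance)
    final = _consensus_round(binary_fm, final_config, final_seed)
    return SubtypeResult(
        final_k=final.selected_k,
        final_labels=final.assignment,
        per_omics=per_omics,
        final_layer=final,
        binary_matrix=bmm,
        sample_ids=samples,
    )


def wmrca_plus(
    layers: list[FeatureMatrix],
    gene_sets: dict[str, GeneSet],
    config: WmrcaConfig | None = None,
) -> SubtypeResult:
    """WMRCA with gene-set restriction of designated layers before clustering.

    ``gene_sets`` maps layer names (typically the expression-like layers)
    to the set used to restrict them, e.g. a lipid-metabolism gene set.
    """
    if not gene_sets:
        raise ValueError("provide a gene set for at least one layer")
    known = {m.layer_name for m in layers}
    unknown = set(gene_sets) - known
    if unknown:
        raise ValueError(f"gene sets reference unknown layers: {sorted(unknown)}")
    restricted: list[str] = []
    prepared = []
    for m in layers:
        if m.layer_name in gene_sets:
            prepared.append(select_by_gene_set(m, gene_sets[m.layer_name]))
            restricted.append(m.layer_name)
        else:
            prepared.append(m)
    result = wmrca(prepared, config)
    result.restricted_layers = restricted
    return result
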