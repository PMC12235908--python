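"""YAML run configuration, validation, and the one-step pipeline runner.

A run config lists the omics layers (path + per-layer preprocessing and
feature-selection choices) and the analysis parameters (K grid, consensus
settings, index settings, voting weights, seed).  ``run_from_config``
executes preprocess -> select -> wmrca/wmrca+ -> evaluate and writes all
result tables plus a manifest (config hash, seed, library versions) so a
run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .consensus import ClusterAssignment
from .evaluate import (
    ari,
    classification_metrics,
    cluster_affinity_scores,
    confusion_counts,
    match_labels,
    roc_auc_from_labels,
    roc_auc_from_scores,
)
from .features import read_gmt, select_top_features
from .indices import INDEX_NAMES
from .pipeline import SubtypeResult, WmrcaConfig, wmrca, wmrca_plus
from .preprocess import (
    FeatureMatrix,
    filter_by_missingness,
    impute_missing,
    normalize_features,
    read_feature_matrix,
)

log = logging.getLogger("wmrca")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImputeSpec(_Strict):
    method: Literal["median", "mean", "knn"] = "knn"
    k: int = Field(default=5, gt=0)


class FilterSpec(_Strict):
    threshold: float = Field(default=0.8, ge=0.0, le=1.0)
    mode: Literal["max_missing", "min_observed"] = "max_missing"


class NormalizeSpec(_Strict):
    center: Literal["median", "mean", "zscore"] = "median"
    log2_transform: bool = False
    pseudocount: float = Field(default=1.0, ge=0.0)


class SelectSpec(_Strict):
    method: Literal["variance", "mad", "pca", "geneset"] = "variance"
    n_top: int = Field(default=1000, gt=0)
    n_components: int = Field(default=10, gt=0)
    gene_set: Optional[str] = None  # GMT path, required for method=geneset
    set_name: Optional[str] = None  # defaults to the first set in the file


class LayerConfig(_Strict):
    path: str
    layer_name: str
    filter: Optional[FilterSpec] = None
    impute: Optional[ImputeSpec] = None
    normalize: Optional[NormalizeSpec] = None
    select: Optional[SelectSpec] = None


class ConsensusSpec(_Strict):
    n_reps: int = Field(default=250, gt=0)
    subsample_fraction: float = Field(default=0.8, gt=0.0, le=1.0)
    base_algorithm: Literal["hierarchical", "kmeans", "pam"] = "hierarchical"
    distance: Literal["pearson", "spearman", "euclidean"] = "pearson"
    linkage: str = "complete"
    binary_distance: Literal["pearson", "jaccard", "euclidean"] = "pearson"


class IndicesSpec(_Strict):
    pac_x1: float = Field(default=0.1, ge=0.0)
    pac_x2: float = Field(default=0.9, le=1.0)
    gap_b: int = Field(default=50, ge=10)


class VotingSpec(_Strict):
    theta: float = Field(default=1.0, ge=0.0)
    weights: Optional[dict[str, float]] = None  # index name -> weight, rest 1

    @field_validator("weights")
    @classmethod
    def _known_indices(cls, v):
        if v is not None:
            unknown = set(v) - set(INDEX_NAMES)
            if unknown:
                raise ValueError(
                    f"unknown index name(s) {sorted(unknown)}; valid: {list(INDEX_NAMES)}")
            if any(w < 0 for w in v.values()):
                raise ValueError("weights must be non-negative")
        return v


class RunConfig(_Strict):
    layers: list[LayerConfig] = Field(min_length=1)
    k_grid: list[int] = Field(default=[2, 3, 4, 5, 6])
    consensus: ConsensusSpec = ConsensusSpec()
    indices: IndicesSpec = IndicesSpec()
    voting: VotingSpec = VotingSpec()
    seed: int = 0
    output_dir: str = "wmrca_results"
    truth: Optional[str] = None  # TSV: sample_id <tab> class

    def weight_vector(self) -> tuple[float, ...] | None:
        if self.voting.weights is None:
            return None
        return tuple(self.voting.weights.get(name, 1.0) for name in INDEX_NAMES)

    def to_wmrca_config(self) -> WmrcaConfig:
        return WmrcaConfig(
            k_grid=tuple(self.k_grid),
            n_reps=self.consensus.n_reps,
            subsample_fraction=self.consensus.subsample_fraction,
            base_algorithm=self.consensus.base_algorithm,
            distance=self.consensus.distance,
            linkage=self.consensus.linkage,
            binary_distance=self.consensus.binary_distance,
            pac_x1=self.indices.pac_x1,
            pac_x2=self.indices.pac_x2,
            gap_b=self.indices.gap_b,
            weights=self.weight_vector(),
            theta=self.voting.theta,
            seed=self.seed,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.model_validate(raw)


def read_truth(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: truth file needs sample_id and class columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Layer preparation
# ---------------------------------------------------------------------------

def prepare_layer(cfg: LayerConfig, base_dir: Path) -> tuple[FeatureMatrix, Optional[str]]:
    """Read, QC and (optionally) feature-select one layer.

    Returns the prepared matrix and, when gene-set selection was
    requested, the GMT path (resolved) so the pipeline can run in WMRCA+
    mode; gene-set restriction itself happens inside ``wmrca_plus`` so the
    restriction is recorded on the result.
    """
    path = Path(cfg.path)
    if not path.is_absolute():
        path = base_dir / path
    m = read_feature_matrix(path, layer_name=cfg.layer_name)
    if cfg.filter is not None:
        m = filter_by_missingness(m, cfg.filter.threshold, cfg.filter.mode)
    if cfg.impute is not None:
        m = impute_missing(m, cfg.impute.method, cfg.impute.k)
    elif np.isnan(m.values).any():
        raise ValueError(f"layer {cfg.layer_name!r} has missing values but no impute step")
    if cfg.normalize is not None:
        m = normalize_features(m, cfg.normalize.center, cfg.normalize.log2_transform,
                               cfg.normalize.pseudocount)
    gmt_path: Optional[str] = None
    if cfg.select is not None:
        if cfg.select.method == "geneset":
            if cfg.select.gene_set is None:
                raise ValueError(f"layer {cfg.layer_name!r}: geneset selection needs gene_set")
            gp = Path(cfg.select.gene_set)
            gmt_path = str(gp if gp.is_absolute() else base_dir / gp)
        else:
            n_top = min(cfg.select.n_top, m.n_features)
            m = select_top_features(m, cfg.select.method, n_top, cfg.select.n_components)
    return m, gmt_path


# ---------------------------------------------------------------------------
# Artifact writing
# ---------------------------------------------------------------------------

def _write_labels(labels: ClusterAssignment, path: Path) -> None:
    pd.DataFrame(
        {"sample_id": list(labels.labels), "cluster": list(labels.labels.values())}
    ).to_csv(path, sep="\t", index=False)


def _write_layer_tables(result, layer: str, out: Path) -> None:
    lr = result.per_omics[layer] if layer != "coca" else result.final_layer
    _write_labels(lr.assignment, out / f"{layer}_labels.tsv")
    idx = pd.DataFrame(
        {p.index_name: p.values for p in lr.profiles},
        index=pd.Index(lr.profiles[0].k_grid, name="K"),
    ).T
    idx.to_csv(out / f"{layer}_indices.tsv", sep="\t", float_format="%.10g")
    ks = sorted(lr.voting.vote_totals)
    pd.DataFrame({
        "K": ks,
        "vote_total": [lr.voting.vote_totals[k] for k in ks],
        "prediction": [lr.voting.predictions[k] for k in ks],
        "selected": [int(k == lr.voting.selected_k) for k in ks],
    }).to_csv(out / f"{layer}_voting.tsv", sep="\t", index=False, float_format="%.10g")
    if lr.delta_area:
        pd.DataFrame(sorted(lr.delta_area.items()), columns=["K", "delta_area"]).to_csv(
            out / f"{layer}_delta_area.tsv", sep="\t", index=False, float_format="%.10g")


def _evaluate_result(result: SubtypeResult, truth: dict[str, str], out: Path) -> pd.DataFrame:
    mapping, relabeled = match_labels(result.final_labels, truth)
    classes = sorted(set(truth[s] for s in relabeled))
    final_cm = result.final_layer.consensus_by_k[result.final_k]
    rows = []
    for cls in classes:
        counts = confusion_counts(relabeled, truth, cls)
        metrics = classification_metrics(counts)
        auc_hard, _ = roc_auc_from_labels(relabeled, truth, cls)
        clusters = [c for c, mapped in mapping.items() if mapped == cls]
        scores = cluster_affinity_scores(final_cm, result.final_labels, clusters)
        common = [s for s in scores if s in truth]
        auc_score, _ = roc_auc_from_scores(
            np.array([scores[s] for s in common]),
            np.array([truth[s] == cls for s in common]))
        rows.append({"class": cls, **metrics.as_dict(),
                     "AUC_labels": auc_hard, "AUC_consensus": auc_score})
    df = pd.DataFrame(rows)
    df["ARI"] = ari(result.final_labels, truth)
    df.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    conf = pd.crosstab(
        pd.Series({s: relabeled[s] for s in relabeled}, name="predicted"),
        pd.Series({s: truth[s] for s in relabeled}, name="true"))
    conf.to_csv(out / "confusion.tsv", sep="\t")
    return df


def run_from_config(path: str | Path, make_plots: bool = False) -> SubtypeResult:
    """Execute a full configured run and write its results directory."""
    path = Path(path)
    cfg = load_config(path)
    base_dir = path.parent
    out = Path(cfg.output_dir)
    if not out.is_absolute():
        out = base_dir / out
    out.mkdir(parents=True, exist_ok=True)

    prepared: list[FeatureMatrix] = []
    gene_sets = {}
    for layer_cfg in cfg.layers:
        m, gmt_path = prepare_layer(layer_cfg, base_dir)
        prepared.append(m)
        if gmt_path is not None:
            sets = read_gmt(gmt_path)
            wanted = layer_cfg.select.set_name
            if wanted is None:
                gene_sets[layer_cfg.layer_name] = sets[0]
            else:
                by_name = {s.name: s for s in sets}
                if wanted not in by_name:
                    raise ValueError(f"gene set {wanted!r} not found in {gmt_path}")
                gene_sets[layer_cfg.layer_name] = by_name[wanted]

    wc = cfg.to_wmrca_config()
    result = wmrca_plus(prepared, gene_sets, wc) if gene_sets else wmrca(prepared, wc)

    _write_labels(result.final_labels, out / "final_labels.tsv")
    for layer in result.per_omics:
        _write_layer_tables(result, layer, out)
    _write_layer_tables(result, "coca", out)
    pd.DataFrame(result.binary_matrix.B,
                 index=pd.Index(result.binary_matrix.sample_ids, name="sample_id"),
                 columns=result.binary_matrix.column_ids()).to_csv(
        out / "binary_membership.tsv", sep="\t")

    if cfg.truth is not None:
        tp = Path(cfg.truth)
        truth = read_truth(tp if tp.is_absolute() else base_dir / tp)
        _evaluate_result(result, truth, out)

    config_text = json.dumps(cfg.model_dump(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "final_k": result.final_k,
        "n_samples": len(result.sample_ids),
        "restricted_layers": result.restricted_layers,
        "versions": {
            "wmrca": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    if make_plots:
        from . import plotting
        for layer, lr in [*result.per_omics.items(), ("coca", result.final_layer)]:
            k = lr.selected_k
            plotting.consensus_heatmap(lr.consensus_by_k[k], lr.assignment,
                                       out / f"{layer}_consensus_K{k}.png")
            plotting.cdf_curves(lr.cdfs, out / f"{layer}_cdf.png")
            if lr.delta_area:
                plotting.delta_area_plot(lr.delta_area, out / f"{layer}_delta_area.png")
            plotting.voting_bar_chart(lr.voting, out / f"{layer}_voting.png")
    log.info("run complete: final K=%d, results in %s", result.final_k, out)
    return result
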