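"""Reading and quality control of per-omics feature matrices.

Every downstream stage consumes a :class:`FeatureMatrix`: a real-valued
features × samples table with NaN marking missing entries.  The operators
here cover the standard pre-clustering hygiene for multi-omics inputs:
missing-value imputation, missingness filtering, per-feature normalization,
feature-specific quantile normalization (FSQN) for cross-platform data, and
projection of segment-level copy-number calls onto a gene-level matrix.

Coordinate convention: segment and gene intervals are 1-based and inclusive
on both ends (SEG / GTF style), so a segment [10, 20] covers 11 bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger("wmrca")

#: cell contents recognized as missing in delimited inputs
MISSING_TOKENS = ("", "NA", "NaN", "nan")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Features × samples matrix with NaN for missing values.

    Parameters
    ----------
    values
        2-D float array, one row per feature, one column per sample.
    feature_ids, sample_ids
        Unique, ordered identifiers matching the array dimensions.
    layer_name
        Tag for the omics layer (``mrna``, ``mirna``, ``lncrna``, ``cnv``,
        ``methylation`` or anything else).
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    layer_name: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if np.isinf(self.values).any():
            raise ValueError("non-finite (infinite) values present")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, layer_name: str = "other") -> "FeatureMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            layer_name=layer_name,
        )

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        """Column subset in the given order (all ids must exist)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return replace(self, values=self.values[:, idx], sample_ids=list(sample_ids))

    def subset_features(self, feature_ids: list[str]) -> "FeatureMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return replace(self, values=self.values[idx, :], feature_ids=list(feature_ids))


@dataclass
class SegmentTable:
    """Segment-level copy-number calls (SEG-style records)."""

    records: pd.DataFrame  # columns: sample, chrom, start, end, value

    COLUMNS = ("sample", "chrom", "start", "end", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        df["sample"] = df["sample"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["value"] = df["value"].astype(float)
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("every segment must satisfy start < end")
        if len(df) and not np.isfinite(df["value"]).all():
            raise ValueError("segment values must be finite")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneModel:
    """Map of gene id -> (chrom, start, end), 1-based inclusive."""

    genes: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, (chrom, start, end) in self.genes.items():
            if not start < end:
                raise ValueError(f"gene {gid}: start must be < end")
        # dict keys are unique by construction

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_feature_matrix(path: str | Path, layer_name: str = "other") -> FeatureMatrix:
    """Read a TSV with a feature-id first column and one column per sample.

    ``NA`` and empty cells are missing; any other non-numeric cell is an
    error.  Duplicate feature ids are collapsed by their (missing-aware)
    mean, with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, keep_default_na=False,
            na_values=list(MISSING_TOKENS), dtype=str,
        )
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from exc
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        log.warning("%s: %d duplicated feature ids collapsed by mean: %s",
                    path.name, len(dups), ", ".join(dups[:10]))
        df = df.groupby(level=0, sort=False).mean()
    return FeatureMatrix.from_frame(df, layer_name=layer_name)


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


def _maybe_skip_header(path: Path, int_cols: tuple[int, ...]) -> int:
    """Return 0 if the first line looks like a header (non-integer coords)."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    try:
        for c in int_cols:
            int(first[c])
    except (ValueError, IndexError):
        return 0
    return None  # type: ignore[return-value]  # pandas header=None


def read_segments(path: str | Path) -> SegmentTable:
    """Read a 5-column SEG-style TSV: sample, chrom, start, end, value."""
    path = Path(path)
    header = _maybe_skip_header(path, (2, 3))
    df = pd.read_csv(path, sep="\t", header=header)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected 5 columns (sample, chrom, start, end, value)")
    df = df.iloc[:, :5]
    df.columns = list(SegmentTable.COLUMNS)
    return SegmentTable(df)


def write_segments(seg: SegmentTable, path: str | Path) -> None:
    seg.records.to_csv(path, sep="\t", index=False)


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a 4-column TSV: gene_id, chrom, start, end."""
    path = Path(path)
    header = _maybe_skip_header(path, (2, 3))
    df = pd.read_csv(path, sep="\t", header=header)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (gene_id, chrom, start, end)")
    genes: dict[str, tuple[str, int, int]] = {}
    for gid, chrom, start, end in df.iloc[:, :4].itertuples(index=False):
        gid = str(gid)
        if gid in genes:
            raise ValueError(f"{path}: duplicate gene id {gid}")
        genes[gid] = (str(chrom), int(start), int(end))
    return GeneModel(genes)


def write_gene_model(gm: GeneModel, path: str | Path) -> None:
    rows = [(g, c, s, e) for g, (c, s, e) in gm.genes.items()]
    pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False)


def read_gtf_gene_model(path: str | Path) -> GeneModel:
    """Extract ``gene`` records from a (possibly minimal) GTF file."""
    genes: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
            gid = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("gene_id"):
                    gid = item.split(None, 1)[1].strip().strip('"')
                    break
            if gid is None:
                raise ValueError(f"GTF gene record without gene_id: {line[:80]}")
            genes[gid] = (chrom, start, end)
    return GeneModel(genes)


# ---------------------------------------------------------------------------
# Quality-control operators
# ---------------------------------------------------------------------------

def impute_missing(
    m: FeatureMatrix,
    method: Literal["median", "mean", "knn"] = "knn",
    k: int = 5,
) -> FeatureMatrix:
    """Fill missing entries; observed entries are never altered.

    ``median`` / ``mean`` fill each feature with its per-feature statistic
    over the observed samples.  ``knn`` fills entry (g, s) with the mean of
    feature g over the k nearest samples to s — plain Euclidean distance on
    the features observed in both samples — that have g observed.
    """
    if method not in ("median", "mean", "knn"):
        raise ValueError(f"unknown imputation method {method!r}")
    X = m.values.copy()
    miss = np.isnan(X)
    if not miss.any():
        return replace(m, values=X)
    fully_missing = miss.all(axis=1)
    if fully_missing.any():
        bad = [m.feature_ids[i] for i in np.flatnonzero(fully_missing)]
        raise ValueError(
            f"features entirely missing ({', '.join(bad[:5])}"
            f"{'...' if len(bad) > 5 else ''}); run filter_by_missingness first"
        )
    if method in ("median", "mean"):
        stat = np.nanmedian(X, axis=1) if method == "median" else np.nanmean(X, axis=1)
        gi, si = np.nonzero(miss)
        X[gi, si] = stat[gi]
        return replace(m, values=X)

    # knn
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k >= m.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    obs = ~miss
    for s in np.flatnonzero(miss.any(axis=0)):
        # distance from sample s to every other sample over co-observed features
        dist = np.full(m.n_samples, np.inf)
        for t in range(m.n_samples):
            if t == s:
                continue
            both = obs[:, s] & obs[:, t]
            if both.any():
                diff = X[both, s] - X[both, t]
                dist[t] = np.sqrt(np.sum(diff * diff))
        order = np.argsort(dist, kind="stable")
        for g in np.flatnonzero(miss[:, s]):
            donors = [t for t in order if np.isfinite(dist[t]) and obs[g, t]]
            if not donors:
                raise ValueError(
                    f"no donor sample observes feature {m.feature_ids[g]!r} "
                    f"with co-observed features for sample {m.sample_ids[s]!r}"
                )
            X[g, s] = float(np.mean([m.values[g, t] for t in donors[:k]]))
    return replace(m, values=X)


def filter_by_missingness(
    m: FeatureMatrix,
    threshold: float = 0.8,
    mode: Literal["max_missing", "min_observed"] = "max_missing",
) -> FeatureMatrix:
    """Drop features by missing fraction; samples are untouched.

    ``max_missing`` (default) drops a feature when its missing fraction
    exceeds ``threshold``.  ``min_observed`` reads the threshold as a
    completeness floor and keeps features observed in at least that
    fraction of samples.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = np.isnan(m.values).mean(axis=1)
    if mode == "max_missing":
        keep = frac <= threshold
    elif mode == "min_observed":
        keep = (1.0 - frac) >= threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    removed = [m.feature_ids[i] for i in np.flatnonzero(~keep)]
    if removed:
        log.info("filter_by_missingness(%s): removed %d/%d features: %s%s",
                 m.layer_name, len(removed), m.n_features,
                 ", ".join(removed[:10]), "..." if len(removed) > 10 else "")
    return replace(
        m,
        values=m.values[keep, :],
        feature_ids=[f for f, k_ in zip(m.feature_ids, keep) if k_],
    )


def normalize_features(
    m: FeatureMatrix,
    center: Literal["median", "mean", "zscore"] = "median",
    log2_transform: bool = False,
    pseudocount: float = 1.0,
) -> FeatureMatrix:
    """Optional log2(x + pseudocount), then per-feature centering/scaling.

    ``zscore`` centers by the mean and divides by the sample standard
    deviation (ddof=1); zero-variance features are left centered with a
    warning.  Missing entries stay missing.
    """
    if center not in ("median", "mean", "zscore"):
        raise ValueError(f"unknown centering {center!r}")
    X = m.values.copy()
    if log2_transform:
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        shifted = X + pseudocount
        if np.nanmin(shifted) <= 0:
            raise ValueError("log2 of non-positive value; increase pseudocount")
        X = np.log2(shifted)
    if center == "median":
        X = X - np.nanmedian(X, axis=1, keepdims=True)
    else:
        X = X - np.nanmean(X, axis=1, keepdims=True)
        if center == "zscore":
            nobs = (~np.isnan(X)).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                sd = np.nanstd(X, axis=1, ddof=1)
            sd[nobs < 2] = 0.0
            zero = sd == 0
            if zero.any():
                log.warning("normalize_features(%s): %d zero-variance features "
                            "left centered", m.layer_name, int(zero.sum()))
            sd_safe = np.where(zero, 1.0, sd)
            X = X / sd_safe[:, None]
    return replace(m, values=X)


def fsqn_normalize(target: FeatureMatrix, reference: FeatureMatrix) -> FeatureMatrix:
    """Feature-specific quantile normalization onto a reference platform.

    Each target feature is independently mapped onto the distribution of
    the same feature in the reference: the rank-r target value becomes the
    corresponding quantile of the reference values, with linear
    interpolation when sample counts differ and average ranks for ties.
    """
    if target.feature_ids != reference.feature_ids:
        raise ValueError("target and reference must share identical feature_ids")
    if np.isnan(target.values).any() or np.isnan(reference.values).any():
        raise ValueError("FSQN requires complete matrices; impute first")
    nt = target.n_samples
    out = np.empty_like(target.values)
    for i in range(target.n_features):
        ref_sorted = np.sort(reference.values[i])
        if nt == 1:
            out[i] = np.quantile(ref_sorted, 0.5)
            continue
        ranks = rankdata(target.values[i], method="average")
        p = (ranks - 1.0) / (nt - 1.0)
        out[i] = np.quantile(ref_sorted, p)
    return replace(target, values=out)


def cnv_segments_to_matrix(
    segments: SegmentTable,
    genes: GeneModel,
    aggregation: Literal["weighted_mean", "max_abs"] = "weighted_mean",
) -> FeatureMatrix:
    """Project segment values onto genes (genes × samples).

    Entry (g, s) aggregates the values of sample s's segments overlapping
    gene g: by default the overlap-length-weighted mean; ``max_abs`` takes
    the value of largest magnitude instead.  Genes with no overlapping
    segment in a sample are missing.  Intervals are 1-based inclusive.
    """
    if len(segments) == 0:
        raise ValueError("empty segment table")
    if len(genes) == 0:
        raise ValueError("empty gene model")
    if aggregation not in ("weighted_mean", "max_abs"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    samples = list(dict.fromkeys(segments.records["sample"]))
    gene_ids = list(genes.genes)
    out = np.full((len(gene_ids), len(samples)), np.nan)
    srow = {s: j for j, s in enumerate(samples)}
    for (sample, chrom), grp in segments.records.groupby(["sample", "chrom"], sort=False):
        seg_start = grp["start"].to_numpy()
        seg_end = grp["end"].to_numpy()
        seg_val = grp["value"].to_numpy()
        j = srow[sample]
        for gi, gid in enumerate(gene_ids):
            gchrom, gstart, gend = genes.genes[gid]
            if gchrom != chrom:
                continue
            ov = np.minimum(seg_end, gend) - np.maximum(seg_start, gstart) + 1
            hit = ov > 0
            if not hit.any():
                continue
            if aggregation == "weighted_mean":
                w = ov[hit].astype(float)
                out[gi, j] = float(np.sum(w * seg_val[hit]) / np.sum(w))
            else:
                vals = seg_val[hit]
                out[gi, j] = float(vals[np.argmax(np.abs(vals))])
    return FeatureMatrix(out, gene_ids, samples, layer_name="cnv")
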