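"""Weighted majority voting over per-index best-K decisions.

Each of the T validation indices casts a one-hot vote d_{t,j} for a
candidate cluster number j, and carries a weight w_t.  The vote total for
j is sum_t w_t d_{t,j}; the prediction indicator for j is 1 when that
total reaches a threshold theta, and the selected cluster number is the
argmax of the totals (ties broken toward the smallest K).  With all
weights and theta fixed at 1 this reduces to plain majority voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .indices import DecisionMatrix

log = logging.getLogger("wmrca")


@dataclass
class VotingResult:
    vote_totals: dict[int, float]
    predictions: dict[int, int]
    selected_k: int
    weights: np.ndarray
    theta: float
    tied_ks: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        best = max(self.vote_totals.values())
        if self.vote_totals[self.selected_k] != best:
            raise ValueError("selected_k must attain the maximum vote total")


def weighted_vote(
    d: DecisionMatrix,
    weights: np.ndarray | list[float] | None = None,
    theta: float = 1.0,
) -> VotingResult:
    """Combine index votes into a final K.

    ``weights`` defaults to all ones (one full vote per index).  Ties in
    the argmax break toward the smallest K and are reported via
    ``tied_ks`` and a log warning.
    """
    w = np.ones(d.T) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (d.T,):
        raise ValueError(f"need {d.T} weights, got {w.shape}")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("at least one weight must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    totals = w @ d.d
    predictions = (totals >= theta).astype(int)
    best = totals.max()
    winners = [k for k, t in zip(d.k_grid, totals) if t == best]
    if len(winners) > 1:
        log.warning("vote tie between K=%s; choosing the smallest", winners)
    return VotingResult(
        vote_totals={k: float(t) for k, t in zip(d.k_grid, totals)},
        predictions={k: int(p) for k, p in zip(d.k_grid, predictions)},
        selected_k=winners[0],
        weights=w,
        theta=float(theta),
        tied_ks=winners if len(winners) > 1 else [],
    )
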