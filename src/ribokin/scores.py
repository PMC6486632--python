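"""Combining RNA–protein interaction predictor outputs into a single rank.

Two kinds of predictor scores are combined for each candidate RNA: an
interaction-propensity score (does the pair interact at all) and an
affinity score in [0, 1] (how strongly). The affinity score is thresholded
to call interactors, and the two scores are min–max normalised over a
length-matched background population and averaged (configurable weights)
into a combined interaction score, from which the target's percentile in
the background is reported.

Predictor scores are inputs — this module never computes or fetches them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["ScoredSequence", "classify_interactor", "combined_rank",
           "read_score_table", "DEFAULT_AFFINITY_THRESHOLD"]

#: significance threshold of the affinity predictor
DEFAULT_AFFINITY_THRESHOLD = 0.25


@dataclass(frozen=True)
class ScoredSequence:
    """One RNA with its two predictor scores (both in [0, 1])."""

    identifier: str
    length_nt: int
    interaction_score: float
    affinity_score: float

    def __post_init__(self):
        for name in ("interaction_score", "affinity_score"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {v}")
        if self.length_nt <= 0:
            raise DomainError(f"length_nt must be positive, got {self.length_nt}")


def classify_interactor(affinity: float,
                        threshold: float = DEFAULT_AFFINITY_THRESHOLD) -> str:
    """Call ``interactor`` iff the affinity score meets the threshold.

    The boundary is inclusive (score == threshold -> interactor).
    """
    if not 0.0 <= affinity <= 1.0:
        raise DomainError(f"affinity score must be in [0, 1], got {affinity}")
    return "interactor" if affinity >= threshold else "non_interactor"


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        # zero spread carries no ranking information: neutral 0.5 for all
        return np.full_like(values, 0.5)
    return (values - lo) / (hi - lo)


def combined_rank(target: ScoredSequence, background: list[ScoredSequence],
                  weights: tuple[float, float] = (0.5, 0.5)) -> dict:
    """Rank the target against a length-matched background by the combined
    interaction score.

    Both scores are min–max normalised over background ∪ target, then
    linearly combined with ``weights`` (interaction, affinity; normalised
    to sum 1). The percentile is the target's rank among background ∪
    target, ``(1 + #{background >= target}) / (n_background + 1)`` — small
    is strong, and a target dominating every background sequence scores
    1/(n+1).
    """
    if not background:
        raise DomainError("background must be non-empty")
    if any(b.length_nt != target.length_nt for b in background):
        raise DomainError("background sequences must match the target length")
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise DomainError("weights must be non-negative and not all zero")
    w = w / w.sum()

    pop = [target] + list(background)
    inter = _minmax(np.array([s.interaction_score for s in pop]))
    aff = _minmax(np.array([s.affinity_score for s in pop]))
    combined = w[0] * inter + w[1] * aff
    target_score = combined[0]
    bg = combined[1:]
    n = len(background)
    percentile = (1.0 + float(np.sum(bg >= target_score))) / (n + 1)
    return {
        "combined_score": float(target_score),
        "percentile": percentile,
        "n_background": n,
        "top_percent": 100.0 * percentile,
    }


def read_score_table(path) -> list[ScoredSequence]:
    """Read a CSV of (id, length_nt, interaction_score, affinity_score)."""
    df = pd.read_csv(path)
    required = ["id", "length_nt", "interaction_score", "affinity_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"score table missing column(s) {missing}")
    return [ScoredSequence(str(r.id), int(r.length_nt),
                           float(r.interaction_score), float(r.affinity_score))
            for r in df.itertuples(index=False)]
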