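"""Reliable negative sample selection (positive-unlabeled setting).

For a given side-effect the drugs known to cause it form the positive set;
every other drug is merely *unlabeled* — some are undiscovered positives.
Training a binary classifier therefore needs negatives chosen with care.

The selection rule implemented here rests on the inverse of the guilt-by-
similarity assumption: drugs dissimilar to every known causer are unlikely
to cause the side-effect.  Each candidate c receives an accumulative score

    Score(c) = sum over positives p of S_com(c, p),

candidates are ranked in ascending score order, and the n lowest-scoring
candidates become the reliable negative set.  A uniformly random draw from
the candidates serves as the baseline selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Dataset
from ._rng import substream
from .similarity import SimilarityMatrix

__all__ = [
    "GoldStandard",
    "accumulative_score",
    "rank_candidates",
    "select_reliable_negatives",
    "select_random_negatives",
]


@dataclass
class GoldStandard:
    """Positive set plus selected negative set for one side-effect.

    ``scores`` maps every candidate (selected or not) to its accumulative
    similarity score so selections can be audited; it is empty for random
    selection.  ``normalized_scores`` divides by the positive count — a
    reporting convenience only; ranking uses the raw sum.
    """

    side_effect_id: str
    positives: list[str]
    negatives: list[str]
    selection_method: str
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(
                f"{self.side_effect_id}: drugs in both positive and negative sets: {sorted(overlap)}"
            )

    @property
    def normalized_scores(self) -> dict[str, float]:
        n = len(self.positives)
        return {d: s / n for d, s in self.scores.items()} if n else dict(self.scores)

    def members(self) -> list[str]:
        """Gold-standard drugs: positives then negatives."""
        return list(self.positives) + list(self.negatives)


def accumulative_score(candidate: str, positives: list[str], S: SimilarityMatrix) -> float:
    """Sum of comprehensive similarities from ``candidate`` to each positive drug."""
    if candidate in set(positives):
        raise ValueError(f"candidate {candidate!r} is in the positive set")
    ci = S.index(candidate)
    if not positives:
        return 0.0
    pos_idx = [S.index(p) for p in positives]
    return float(S.values[ci, pos_idx].sum())


def rank_candidates(
    candidates: list[str], positives: list[str], S: SimilarityMatrix
) -> list[tuple[str, float]]:
    """Candidates with accumulative scores, ascending by (score, drug id).

    The lexicographic id tie-break makes the ranking invariant to input
    ordering.
    """
    pos_idx = [S.index(p) for p in positives]
    cand_idx = [S.index(c) for c in candidates]
    if pos_idx:
        scores = S.values[np.ix_(cand_idx, pos_idx)].sum(axis=1)
    else:
        scores = np.zeros(len(cand_idx))
    order = sorted(range(len(candidates)), key=lambda i: (scores[i], candidates[i]))
    return [(candidates[i], float(scores[i])) for i in order]


def _check_n(n: int, n_candidates: int, side_effect_id: str) -> None:
    if not 1 <= n <= n_candidates:
        raise ValueError(
            f"{side_effect_id}: requested {n} negatives but only "
            f"{n_candidates} candidate drugs are available"
        )


def select_reliable_negatives(
    dataset: Dataset, side_effect_id: str, S: SimilarityMatrix, n: int
) -> GoldStandard:
    """Select the ``n`` candidates least accumulatively similar to the positives."""
    positives = dataset.positives(side_effect_id)
    candidates = dataset.candidates(side_effect_id)
    _check_n(n, len(candidates), side_effect_id)
    ranked = rank_candidates(candidates, positives, S)
    return GoldStandard(
        side_effect_id=side_effect_id,
        positives=positives,
        negatives=[d for d, _ in ranked[:n]],
        selection_method="reliable",
        scores={d: s for d, s in ranked},
    )


def select_random_negatives(
    dataset: Dataset, side_effect_id: str, n: int, seed: int
) -> GoldStandard:
    """Baseline: uniform sample of ``n`` candidates without replacement."""
    positives = dataset.positives(side_effect_id)
    candidates = dataset.candidates(side_effect_id)
    _check_n(n, len(candidates), side_effect_id)
    rng = substream(seed, "random-negatives", side_effect_id)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return GoldStandard(
        side_effect_id=side_effect_id,
        positives=positives,
        negatives=[candidates[i] for i in chosen],
        selection_method="random",
    )
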