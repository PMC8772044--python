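"""Nearest-profile similarity transfer for low-degree (TWSNI) targets.

Targets at or below the degree threshold have too few positives to train
their own classifier, so their interactions are inferred from the most
similar neighbour's profile.  For a new (test) drug ``d`` and target ``t``:

* drug side:    ``s_d(d, d*) * Y[d*, :]`` where ``d*`` is the most similar
  *training* drug;
* target side:  ``s_t(t, t*) * Yhat[d, t*]`` where ``t*`` is the most
  similar other target (searched over *all* targets, so the low-degree part
  can borrow from the high-degree part);
* final score: the arithmetic mean of the two sides.

Because ``d`` is a cold-start drug, ``Y[d, t*]`` is unobserved at training
time; it is replaced by its own drug-side nearest-profile estimate
``s_d(d, d*) * Y[d*, t*]`` — strictly the same one-neighbour rule, and no
test label ever enters a score.  Only the single nearest neighbour is used:
with imperfect similarity measures, more distant neighbours carry worse
signal than no signal.

All (test drug, target) cells are scored; the evaluator then pools only the
TWSNI cells into a single AUC, keeping the result from being dominated by
the high-degree part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import InteractionMatrix, ScoreMatrix, SimilarityMatrix
from .evaluation import UndefinedAUCError, auc
from .partitioning import TargetPartition

logger = logging.getLogger("mcsdti")

__all__ = [
    "NeighborLookup",
    "nearest_neighbor",
    "np_target_side",
    "np_drug_side",
    "np_pair_score",
    "run_twsni_fold",
    "evaluate_twsni",
    "TwsniEvaluation",
]


@dataclass(frozen=True)
class NeighborLookup:
    query_id: str
    neighbor_id: str
    similarity: float

    def __post_init__(self) -> None:
        if self.neighbor_id == self.query_id:
            raise ValueError(f"{self.query_id!r} cannot be its own neighbour")


def nearest_neighbor(
    S: SimilarityMatrix, query_id: str, candidate_ids: set[str] | list[str]
) -> NeighborLookup:
    """Most similar candidate to the query, excluding the query itself.

    Exact similarity ties break to the lexicographically smallest identifier
    so the choice is deterministic.
    """
    candidates = sorted(set(candidate_ids) - {query_id})
    if not candidates:
        raise ValueError(f"no candidates for {query_id!r} after self-exclusion")
    qi = S.index(query_id)
    sims = [S.values[qi, S.index(c)] for c in candidates]
    best = int(np.argmax(sims))  # argmax keeps the first = smallest id on ties
    return NeighborLookup(query_id, candidates[best], float(sims[best]))


def _column_of(Y: InteractionMatrix | ScoreMatrix, target_id: str) -> np.ndarray:
    if isinstance(Y, ScoreMatrix):
        return Y.scores[:, Y.target_index(target_id)]
    return Y.column(target_id).astype(float)


def np_target_side(
    S_t: SimilarityMatrix,
    Y_known: InteractionMatrix | ScoreMatrix,
    t_query: str,
    candidate_targets: set[str] | list[str],
) -> np.ndarray:
    """Target-side nearest-profile column: ``s_t(t, t*) * Y[:, t*]``."""
    nn = nearest_neighbor(S_t, t_query, candidate_targets)
    return nn.similarity * _column_of(Y_known, nn.neighbor_id)


def np_drug_side(
    S_d: SimilarityMatrix,
    Y: InteractionMatrix,
    d_query: str,
    candidate_drugs: set[str] | list[str],
) -> np.ndarray:
    """Drug-side nearest-profile row: ``s_d(d, d*) * Y[d*, :]``."""
    nn = nearest_neighbor(S_d, d_query, candidate_drugs)
    return nn.similarity * Y.row(nn.neighbor_id).astype(float)


def np_pair_score(drug_side: float, target_side: float) -> float:
    """Combine the two one-sided estimates by their arithmetic mean."""
    return 0.5 * (float(drug_side) + float(target_side))


def run_twsni_fold(
    S_d: SimilarityMatrix,
    S_t: SimilarityMatrix,
    Y: InteractionMatrix,
    train_drugs: set[str] | list[str],
    test_drugs: set[str] | list[str],
) -> ScoreMatrix:
    """Nearest-profile scores for every (test drug, target) pair.

    Drug neighbours are searched among training drugs only; target
    neighbours among all targets.  Training and prediction happen in one
    pass — there is no fitted model.
    """
    train_set, test_set = set(train_drugs), set(test_drugs)
    if train_set & test_set:
        raise ValueError(f"train/test drugs overlap: {sorted(train_set & test_set)}")
    test_ids = [d for d in Y.drug_ids if d in test_set]

    # Per-target nearest neighbour is independent of the drug: precompute.
    t_near_idx = np.empty(Y.n_targets, dtype=int)
    t_near_sim = np.empty(Y.n_targets)
    for j, t in enumerate(Y.target_ids):
        nn = nearest_neighbor(S_t, t, Y.target_ids)
        t_near_idx[j] = Y.target_index(nn.neighbor_id)
        t_near_sim[j] = nn.similarity

    drug_side = np.zeros((len(test_ids), Y.n_targets))
    degenerate = 0
    for i, d in enumerate(test_ids):
        row = np_drug_side(S_d, Y, d, train_set)
        if not row.any():
            degenerate += 1
        drug_side[i] = row
    if degenerate == len(test_ids) and test_ids:
        logger.warning(
            "degenerate drug similarity: every test drug scored 0 on the drug side"
        )
    # Chained target side: Yhat[d, t*] is the drug-side estimate at t*.
    target_side = t_near_sim[None, :] * drug_side[:, t_near_idx]
    scores = 0.5 * (drug_side + target_side)
    return ScoreMatrix(
        tuple(test_ids), Y.target_ids, scores, np.ones_like(scores, dtype=bool)
    )


@dataclass(frozen=True)
class TwsniEvaluation:
    """Single pooled AUC over all (test drug, TWSNI target) pairs."""

    pooled_auc: float | None
    n_pos: int
    n_neg: int

    @property
    def status(self) -> str:
        return "ok" if self.pooled_auc is not None else "not-evaluable"


def evaluate_twsni(
    scores: ScoreMatrix, Y_test: InteractionMatrix, partition: TargetPartition
) -> TwsniEvaluation:
    """Pool every (test drug, TWSNI target) cell into one AUC.

    Per-target AUC is mostly undefined here (a degree-1 target rarely has a
    positive *and* a negative among the test drugs), so the low-degree part
    is evaluated as one pooled ranking problem.
    """
    cols = [scores.target_index(t) for t in partition.twsni_ids]
    if not cols:
        return TwsniEvaluation(pooled_auc=None, n_pos=0, n_neg=0)
    if not scores.mask[:, cols].all():
        raise ValueError("unscored TWSNI cells in the score matrix")
    test_rows = [Y_test.drug_index(d) for d in scores.drug_ids]
    y_cols = [Y_test.target_index(t) for t in partition.twsni_ids]
    labels = Y_test.values[np.ix_(test_rows, y_cols)].ravel()
    pooled = scores.scores[:, cols].ravel()
    try:
        value = auc(pooled, labels)
    except UndefinedAUCError:
        return TwsniEvaluation(
            pooled_auc=None, n_pos=int(labels.sum()), n_neg=int((1 - labels).sum())
        )
    return TwsniEvaluation(
        pooled_auc=value, n_pos=int(labels.sum()), n_neg=int((1 - labels).sum())
    )
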