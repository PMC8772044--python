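"""Drug-wise cross-validation harness, tie-aware AUC, and report aggregation.

Folds partition *drugs*, never pairs: a test drug has no observed
interactions at training time (cold-start evaluation).  Within each fold the
high-degree part is scored by per-target trees and evaluated by macro AUC;
the low-degree part by nearest-profile transfer and a pooled AUC.  The two
parts are aggregated to ``mean ± sd`` over folds separately and are never
averaged into one number — pooling them would let the handful of promiscuous
targets dominate the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from .containers import FeatureMatrix, InteractionMatrix, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger("mcsdti")

__all__ = [
    "FoldSplit",
    "make_drug_folds",
    "UndefinedAUCError",
    "auc",
    "auc_oracle",
    "EvaluationReport",
    "run_mcsdti",
    "run_scored_cv",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined: the labels contain only one class."""


@dataclass(frozen=True)
class FoldSplit:
    """Balanced random assignment of drugs to k folds."""

    k: int
    assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> tuple[str, ...]:
        return tuple(d for d, f in self.assignments.items() if f == fold)

    def train_test(self, fold: int) -> tuple[set[str], set[str]]:
        test = set(self.fold_ids(fold))
        train = set(self.assignments) - test
        return train, test


def make_drug_folds(drug_ids: list[str] | tuple[str, ...], k: int, seed: int) -> FoldSplit:
    """Uniformly random balanced fold assignment, deterministic given seed."""
    drug_ids = list(drug_ids)
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if k > len(drug_ids):
        raise ValueError(f"{k} folds requested for only {len(drug_ids)} drugs")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(drug_ids))
    assignments = {drug_ids[i]: int(pos % k) for pos, i in enumerate(order)}
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form with midrank ties.

    Equals (number of positive-negative pairs ranked correctly + half the
    tied pairs) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ValueError(f"{scores.shape} scores vs {labels.shape} labels")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(f"labels are single-class ({n_pos} positive of {labels.size})")
    ranks = rankdata(scores)  # midranks
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_oracle(scores, labels) -> float:
    """Brute-force AUC: literal loop over every positive-negative pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUCError("labels are single-class")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def _aggregate(values: list[float]) -> dict:
    if not values:
        return {"status": "not evaluated", "fold_values": [], "mean": None, "sd": None}
    arr = np.asarray(values, dtype=float)
    return {
        "status": "ok",
        "fold_values": [float(v) for v in arr],
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
    }


@dataclass
class EvaluationReport:
    """Per-fold detail plus per-part aggregate in JSON-ready form."""

    per_fold: list[dict]
    aggregate: dict
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "aggregate": self.aggregate, "config": self.config}

    @classmethod
    def from_dict(cls, data: dict) -> "EvaluationReport":
        return cls(
            per_fold=data["per_fold"],
            aggregate=data["aggregate"],
            config=data.get("config", {}),
        )


def _restrict(Y: InteractionMatrix, drug_ids: tuple[str, ...]) -> InteractionMatrix:
    rows = [Y.drug_index(d) for d in drug_ids]
    return InteractionMatrix(drug_ids, Y.target_ids, Y.values[rows])


def run_mcsdti(
    D: FeatureMatrix,
    T: FeatureMatrix,
    Y: InteractionMatrix,
    S_d: SimilarityMatrix,
    S_t: SimilarityMatrix,
    *,
    tau: int,
    k: int = 5,
    seed: int = 0,
    partition_per_fold: bool = False,
    tree_params=None,
) -> EvaluationReport:
    """Full pipeline: partition, per-fold dual-strategy scoring, aggregation.

    By default targets are partitioned once on the full interaction matrix
    (the preprocessing step); ``partition_per_fold`` recomputes the split on
    each fold's training rows for leakage-averse use.
    """
    from .partitioning import partition_targets
    from .twlni import run_twlni_fold, evaluate_twlni
    from .twsni import run_twsni_fold, evaluate_twsni

    folds = make_drug_folds(list(Y.drug_ids), k, seed)
    full_partition = partition_targets(Y, tau)
    per_fold: list[dict] = []
    twlni_values: list[float] = []
    twsni_values: list[float] = []
    for fold in range(k):
        train, test = folds.train_test(fold)
        if partition_per_fold:
            part = partition_targets(_restrict(Y, tuple(d for d in Y.drug_ids if d in train)), tau)
        else:
            part = full_partition
        try:
            twlni_scores = run_twlni_fold(
                D, Y, part, train, test, params=tree_params, seed=seed + fold
            )
        except Exception as exc:  # pragma: no cover - stage naming contract
            raise RuntimeError(f"TWLNI scoring failed in fold {fold}: {exc}") from exc
        y_test = _restrict(Y, twlni_scores.drug_ids)
        twlni_eval = evaluate_twlni(twlni_scores, y_test, part)
        try:
            twsni_scores = run_twsni_fold(S_d, S_t, Y, train, test)
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"TWSNI scoring failed in fold {fold}: {exc}") from exc
        twsni_eval = evaluate_twsni(twsni_scores, _restrict(Y, twsni_scores.drug_ids), part)

        if twlni_eval.macro_auc is not None:
            twlni_values.append(twlni_eval.macro_auc)
        if twsni_eval.pooled_auc is not None:
            twsni_values.append(twsni_eval.pooled_auc)
        per_fold.append(
            {
                "fold": fold,
                "test_drugs": sorted(test),
                "twlni": {
                    "status": twlni_eval.status,
                    "macro_auc": twlni_eval.macro_auc,
                    "per_target": twlni_eval.per_target,
                    "excluded_targets": list(twlni_eval.excluded),
                    "skipped_targets": list(twlni_eval.skipped),
                },
                "twsni": {
                    "status": twsni_eval.status,
                    "pooled_auc": twsni_eval.pooled_auc,
                    "n_pos": twsni_eval.n_pos,
                    "n_neg": twsni_eval.n_neg,
                },
            }
        )
    config = {
        "tau": tau,
        "folds": k,
        "seed": seed,
        "partition_per_fold": partition_per_fold,
        "fold_assignments": folds.assignments,
        "twlni_target_count": len(full_partition.twlni_ids),
        "twsni_target_count": len(full_partition.twsni_ids),
    }
    aggregate = {"twlni": _aggregate(twlni_values), "twsni": _aggregate(twsni_values)}
    return EvaluationReport(per_fold=per_fold, aggregate=aggregate, config=config)


def run_scored_cv(
    score_fn: Callable[[set[str], set[str]], ScoreMatrix],
    Y: InteractionMatrix,
    *,
    tau: int,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate any full-matrix scorer under the identical harness.

    ``score_fn(train_drugs, test_drugs)`` must return a ScoreMatrix over all
    targets for the test drugs.  The TWLNI part is evaluated by macro AUC
    over its targets and the TWSNI part by pooled AUC, exactly as for the
    dual-strategy pipeline, so comparison methods share folds and evaluators.
    """
    from .partitioning import partition_targets
    from .twlni import evaluate_twlni
    from .twsni import evaluate_twsni

    folds = make_drug_folds(list(Y.drug_ids), k, seed)
    part = partition_targets(Y, tau)
    per_fold: list[dict] = []
    twlni_values: list[float] = []
    twsni_values: list[float] = []
    for fold in range(k):
        train, test = folds.train_test(fold)
        scores = score_fn(train, test)
        y_test = _restrict(Y, scores.drug_ids)
        twlni_eval = evaluate_twlni(scores, y_test, part)
        twsni_eval = evaluate_twsni(scores, y_test, part)
        if twlni_eval.macro_auc is not None:
            twlni_values.append(twlni_eval.macro_auc)
        if twsni_eval.pooled_auc is not None:
            twsni_values.append(twsni_eval.pooled_auc)
        per_fold.append(
            {
                "fold": fold,
                "test_drugs": sorted(test),
                "twlni": {"status": twlni_eval.status, "macro_auc": twlni_eval.macro_auc},
                "twsni": {"status": twsni_eval.status, "pooled_auc": twsni_eval.pooled_auc},
            }
        )
    config = {"tau": tau, "folds": k, "seed": seed, "fold_assignments": folds.assignments}
    return EvaluationReport(
        per_fold=per_fold,
        aggregate={"twlni": _aggregate(twlni_values), "twsni": _aggregate(twsni_values)},
        config=config,
    )
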