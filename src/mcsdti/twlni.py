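"""Per-target decision-tree strategy for high-degree (TWLNI) targets.

Each TWLNI target gets its own binary classifier trained *only* on that
target's own interaction column: the drugs are the samples, the drug
fingerprint matrix the features, and the target's column of Y the labels.
Pooling a target's training set with its neighbours' would drown the few
positives in the neighbours' negatives (interactions are sparse), so no
neighbour column is ever touched.  A CART tree handles the
high-dimension/small-sample shape because its splits use only informative
features.  Evaluation is per-target: one AUC per target over its test drugs,
then the macro mean over evaluable targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureMatrix, InteractionMatrix, ScoreMatrix
from .evaluation import UndefinedAUCError, auc
from .partitioning import TargetPartition

logger = logging.getLogger("mcsdti")

__all__ = [
    "UnfittableTargetError",
    "TargetModel",
    "TreeParams",
    "fit_target_tree",
    "score_target_tree",
    "run_twlni_fold",
    "evaluate_twlni",
    "TwlniEvaluation",
]


class UnfittableTargetError(ValueError):
    """The target's training column is single-class; no model can be fitted."""


@dataclass(frozen=True)
class TreeParams:
    """CART hyperparameters.

    Defaults emulate the common MATLAB-style classification-tree defaults:
    Gini impurity, no depth cap, minimum leaf size 1, minimum parent size 10
    (``min_samples_split``), no pruning.
    """

    criterion: str = "gini"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    min_samples_split: int = 10

    def build(self, seed: int) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            min_samples_split=self.min_samples_split,
            random_state=seed % (2**31 - 1),
        )


@dataclass
class TargetModel:
    """A fitted per-target tree plus bookkeeping."""

    target_id: str
    tree: DecisionTreeClassifier
    train_positive_count: int
    n_features: int = field(default=0)


def fit_target_tree(
    D_train: np.ndarray,
    y_column: np.ndarray,
    *,
    target_id: str = "",
    params: TreeParams | None = None,
    seed: int = 0,
) -> TargetModel:
    """Fit a CART tree on one target's own labelled drugs.

    Raises :class:`UnfittableTargetError` when the label column is
    single-class; the caller decides whether to skip or substitute.
    """
    D_train = np.asarray(D_train, dtype=float)
    y = np.asarray(y_column).astype(int).ravel()
    if D_train.shape[0] != y.shape[0]:
        raise ValueError(
            f"{D_train.shape[0]} feature rows vs {y.shape[0]} labels for {target_id!r}"
        )
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise UnfittableTargetError(
            f"target {target_id!r}: training labels are single-class "
            f"({n_pos}/{y.size} positive)"
        )
    params = params or TreeParams()
    tree = params.build(seed)
    tree.fit(D_train, y)
    return TargetModel(
        target_id=target_id,
        tree=tree,
        train_positive_count=n_pos,
        n_features=D_train.shape[1],
    )


def score_target_tree(model: TargetModel, D_test: np.ndarray) -> np.ndarray:
    """Score drugs with a fitted target model.

    The ranking score is the positive-class fraction in the leaf each drug
    reaches — the natural continuous score of an unpruned CART tree.
    """
    D_test = np.asarray(D_test, dtype=float)
    if D_test.ndim != 2 or D_test.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {D_test.shape[1] if D_test.ndim == 2 else '?'} "
            f"does not match training dimension {model.n_features}"
        )
    proba = model.tree.predict_proba(D_test)
    pos_col = list(model.tree.classes_).index(1)
    return proba[:, pos_col]


def run_twlni_fold(
    D: FeatureMatrix,
    Y: InteractionMatrix,
    partition: TargetPartition,
    train_drugs: set[str] | list[str],
    test_drugs: set[str] | list[str],
    *,
    params: TreeParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """Train one tree per TWLNI target on the training drugs, score the test drugs.

    Targets whose training column is single-class are skipped (their cells
    stay unmasked) and logged.  Only the target's own column of Y is read —
    never a neighbour's — and only training rows enter the fit.
    """
    train_set, test_set = set(train_drugs), set(test_drugs)
    if train_set & test_set:
        raise ValueError(f"train/test drugs overlap: {sorted(train_set & test_set)}")
    train_ids = [d for d in Y.drug_ids if d in train_set]
    test_ids = [d for d in Y.drug_ids if d in test_set]
    D_train = D.rows(train_ids)
    D_test = D.rows(test_ids)
    train_rows = [Y.drug_index(d) for d in train_ids]

    scores = np.zeros((len(test_ids), Y.n_targets))
    mask = np.zeros_like(scores, dtype=bool)
    twlni = set(partition.twlni_ids)
    if not twlni:
        logger.warning("empty TWLNI part: no per-target models fitted")
    for j, t in enumerate(Y.target_ids):
        if t not in twlni:
            continue
        y_col = Y.values[train_rows, j]
        try:
            model = fit_target_tree(
                D_train, y_col, target_id=t, params=params, seed=seed
            )
        except UnfittableTargetError:
            logger.info("skipping target %s: single-class training column", t)
            continue
        scores[:, j] = score_target_tree(model, D_test)
        mask[:, j] = True
    return ScoreMatrix(tuple(test_ids), Y.target_ids, scores, mask)


@dataclass(frozen=True)
class TwlniEvaluation:
    """Per-target AUC detail and the macro mean over evaluable targets."""

    per_target: dict[str, float]
    macro_auc: float | None
    excluded: tuple[str, ...]  # single-class test labels: AUC undefined
    skipped: tuple[str, ...]  # never scored (unfittable in training)

    @property
    def status(self) -> str:
        return "ok" if self.macro_auc is not None else "no-evaluable-targets"


def evaluate_twlni(
    scores: ScoreMatrix, Y_test: InteractionMatrix, partition: TargetPartition
) -> TwlniEvaluation:
    """Macro-averaged per-target AUC over the TWLNI part.

    Each scored target contributes one AUC over its test drugs; targets whose
    test labels are single-class are excluded from the mean and listed.
    """
    per_target: dict[str, float] = {}
    excluded: list[str] = []
    skipped: list[str] = []
    test_rows = [Y_test.drug_index(d) for d in scores.drug_ids]
    for t in partition.twlni_ids:
        j = scores.target_index(t)
        if not scores.mask[:, j].all():
            skipped.append(t)
            continue
        labels = Y_test.values[test_rows, Y_test.target_index(t)]
        try:
            per_target[t] = auc(scores.scores[:, j], labels)
        except UndefinedAUCError:
            excluded.append(t)
    macro = float(np.mean(list(per_target.values()))) if per_target else None
    return TwlniEvaluation(
        per_target=per_target,
        macro_auc=macro,
        excluded=tuple(excluded),
        skipped=tuple(skipped),
    )
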