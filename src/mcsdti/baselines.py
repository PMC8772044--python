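"""Comparison methods run under the identical cross-validation harness.

Four classical chemogenomic predictors whose logic is fully reconstructible
from the standard literature formulations:

* ``dt``  — one global decision tree over concatenated [drug || target]
  feature vectors of every training pair;
* ``np``  — nearest profile over the full matrix (the same one-neighbour
  transfer the low-degree strategy uses, applied to all targets);
* ``wp``  — weighted profile: similarity-weighted average of *all*
  candidate profiles instead of the single nearest;
* ``nbi`` — network-based inference: two-pass degree-normalised resource
  diffusion on the bipartite training graph, using no chemical or sequence
  similarity at all.

All of them produce a full ScoreMatrix per fold and are evaluated with the
same fold assignments and the same per-part evaluators as the dual-strategy
pipeline.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import FeatureMatrix, InteractionMatrix, ScoreMatrix, SimilarityMatrix
from .evaluation import EvaluationReport, run_scored_cv
from .twlni import TreeParams
from .twsni import run_twsni_fold

logger = logging.getLogger("mcsdti")

__all__ = [
    "global_tree_baseline",
    "weighted_profile",
    "run_wp_fold",
    "nbi_diffusion",
    "nbi_scores",
    "run_baseline",
]


def global_tree_baseline(
    D: FeatureMatrix,
    T: FeatureMatrix,
    Y: InteractionMatrix,
    train_drugs: set[str] | list[str],
    test_drugs: set[str] | list[str],
    *,
    params: TreeParams | None = None,
    seed: int = 0,
) -> ScoreMatrix:
    """One tree over all training pairs, features = [drug || target] (p+q dims)."""
    train_set, test_set = set(train_drugs), set(test_drugs)
    if train_set & test_set:
        raise ValueError(f"train/test drugs overlap: {sorted(train_set & test_set)}")
    train_ids = [d for d in Y.drug_ids if d in train_set]
    test_ids = [d for d in Y.drug_ids if d in test_set]
    Dm, Tm = D.rows(train_ids), T.rows(list(Y.target_ids))
    n_tr, v = len(train_ids), Y.n_targets
    X_train = np.hstack(
        [np.repeat(Dm, v, axis=0), np.tile(Tm, (n_tr, 1))]
    ).astype(np.float32)
    y_train = Y.values[[Y.drug_index(d) for d in train_ids]].ravel()
    if y_train.min() == y_train.max():
        raise ValueError("global tree baseline: training pairs are single-class")
    params = params or TreeParams()
    tree = params.build(seed)
    tree.fit(X_train, y_train)
    X_test = np.hstack(
        [np.repeat(D.rows(test_ids), v, axis=0), np.tile(Tm, (len(test_ids), 1))]
    ).astype(np.float32)
    pos_col = list(tree.classes_).index(1)
    scores = tree.predict_proba(X_test)[:, pos_col].reshape(len(test_ids), v)
    return ScoreMatrix(
        tuple(test_ids), Y.target_ids, scores, np.ones_like(scores, dtype=bool)
    )


def weighted_profile(
    S: SimilarityMatrix,
    Y: InteractionMatrix,
    query_id: str,
    axis: str,
    candidates: set[str] | list[str],
) -> np.ndarray:
    """Similarity-weighted average profile over all candidates.

    ``axis="drug"`` averages candidate drug rows of Y; ``axis="target"``
    averages candidate target columns.  A zero total similarity yields zero
    scores with a warning (no profile to transfer).
    """
    cands = sorted(set(candidates) - {query_id})
    if not cands:
        raise ValueError(f"no candidates for {query_id!r}")
    qi = S.index(query_id)
    sims = np.array([S.values[qi, S.index(c)] for c in cands])
    if axis == "drug":
        profiles = np.stack([Y.row(c).astype(float) for c in cands])
    elif axis == "target":
        profiles = np.stack([Y.column(c).astype(float) for c in cands])
    else:
        raise ValueError(f"axis must be 'drug' or 'target', got {axis!r}")
    denom = sims.sum()
    if denom == 0:
        logger.warning("weighted profile: zero total similarity for %s", query_id)
        return np.zeros(profiles.shape[1])
    return sims @ profiles / denom


def run_wp_fold(
    S_d: SimilarityMatrix,
    S_t: SimilarityMatrix,
    Y: InteractionMatrix,
    train_drugs: set[str] | list[str],
    test_drugs: set[str] | list[str],
) -> ScoreMatrix:
    """Weighted-profile scores for all (test drug, target) pairs.

    Drug side is the weighted average over training drugs; the target side
    is the similarity-weighted average of the drug-side estimates at the
    other targets (the cold-start drug has no observed row to average), and
    the pair score is the mean of the two sides.
    """
    train_set, test_set = set(train_drugs), set(test_drugs)
    if train_set & test_set:
        raise ValueError("train/test drugs overlap")
    test_ids = [d for d in Y.drug_ids if d in test_set]
    drug_side = np.stack(
        [weighted_profile(S_d, Y, d, "drug", train_set) for d in test_ids]
    ) if test_ids else np.zeros((0, Y.n_targets))
    # target-side weights: all other targets
    St = S_t.values[np.ix_(
        [S_t.index(t) for t in Y.target_ids], [S_t.index(t) for t in Y.target_ids]
    )].copy()
    np.fill_diagonal(St, 0.0)
    denom = St.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        target_side = drug_side @ St.T / np.where(denom > 0, denom, 1.0)[None, :]
    target_side[:, denom == 0] = 0.0
    scores = 0.5 * (drug_side + target_side)
    return ScoreMatrix(
        tuple(test_ids), Y.target_ids, scores, np.ones_like(scores, dtype=bool)
    )


def nbi_diffusion(Y: InteractionMatrix, train_drugs: set[str] | list[str]):
    """Two-pass resource diffusion on the bipartite training graph.

    Resource on each drug spreads equally over its targets (divide by drug
    degree) and back from each target equally over its drugs (divide by
    target degree).  Returns ``(train_ids, W, F)`` with ``W`` the drug-drug
    transfer matrix (columns over connected drugs sum to 1: resource is
    conserved) and ``F = W @ A`` the scores of the training drugs over all
    targets.
    """
    train_ids = [d for d in Y.drug_ids if d in set(train_drugs)]
    A = Y.values[[Y.drug_index(d) for d in train_ids]].astype(float)
    if A.sum() == 0:
        raise ValueError("NBI: empty training graph")
    kd = A.sum(axis=1)  # drug degrees
    kt = A.sum(axis=0)  # target degrees
    inv_kd = np.where(kd > 0, 1.0 / np.maximum(kd, 1), 0.0)
    inv_kt = np.where(kt > 0, 1.0 / np.maximum(kt, 1), 0.0)
    # W[i, j] = sum_l A[i, l] A[j, l] / (k_t(l) * k_d(j))
    W = (A * inv_kt[None, :]) @ A.T * inv_kd[None, :]
    F = W @ A
    return train_ids, W, F


def nbi_scores(
    Y: InteractionMatrix,
    train_drugs: set[str] | list[str],
    test_drugs: set[str] | list[str],
) -> ScoreMatrix:
    """NBI scores for the test drugs.

    NBI uses no chemical similarity, so a drug with no edges in the training
    graph cannot receive resource.  Under drug-wise cross-validation every
    test drug is such a cold-start drug: its row scores 0, with a warning.
    """
    test_ids = [d for d in Y.drug_ids if d in set(test_drugs)]
    train_ids, _, F = nbi_diffusion(Y, train_drugs)
    lookup = {d: i for i, d in enumerate(train_ids)}
    scores = np.zeros((len(test_ids), Y.n_targets))
    cold = 0
    for i, d in enumerate(test_ids):
        if d in lookup:
            scores[i] = F[lookup[d]]
        else:
            cold += 1
    if cold:
        logger.warning(
            "NBI: %d test drug(s) have no training edges; their scores are 0", cold
        )
    scores = scores / scores.max() if scores.max() > 0 else scores
    return ScoreMatrix(
        tuple(test_ids), Y.target_ids, scores, np.ones_like(scores, dtype=bool)
    )


def run_baseline(
    method: str,
    Y: InteractionMatrix,
    *,
    D: FeatureMatrix | None = None,
    T: FeatureMatrix | None = None,
    S_d: SimilarityMatrix | None = None,
    S_t: SimilarityMatrix | None = None,
    tau: int,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Run one comparison method under the shared CV harness."""
    if method == "dt":
        if D is None or T is None:
            raise ValueError("dt baseline needs drug and target features")
        score_fn = lambda tr, te: global_tree_baseline(D, T, Y, tr, te, seed=seed)
    elif method == "np":
        if S_d is None or S_t is None:
            raise ValueError("np baseline needs similarity matrices")
        score_fn = lambda tr, te: run_twsni_fold(S_d, S_t, Y, tr, te)
    elif method == "wp":
        if S_d is None or S_t is None:
            raise ValueError("wp baseline needs similarity matrices")
        score_fn = lambda tr, te: run_wp_fold(S_d, S_t, Y, tr, te)
    elif method == "nbi":
        score_fn = lambda tr, te: nbi_scores(Y, tr, te)
    else:
        raise ValueError(f"unknown baseline {method!r}; pick dt, np, wp or nbi")
    report = run_scored_cv(score_fn, Y, tau=tau, k=k, seed=seed)
    report.config["method"] = method
    return report
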