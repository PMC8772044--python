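# Methods

## Model and procedure

The package predicts binary drug–target interactions from a chemogenomic
dataset `(Y, D, T, S_d, S_t)`: interaction matrix `Y ∈ {0,1}^{u×v}`, binary
drug fingerprints `D ∈ {0,1}^{u×p}`, real-valued target descriptors
`T ∈ R^{v×q}`, and similarity matrices over drugs and targets. The central
modelling claim is that no single classification strategy serves both the
few promiscuous targets that hold most interactions and the long tail of
near-orphan targets, and that the two groups must also be *evaluated*
separately, or the tail's results are drowned by the head.

1. **Partition.** Targets with interaction count > τ form the high-degree
   part (TWLNI); count ≤ τ the low-degree part (TWSNI). The boundary case
   (count exactly τ) goes to the low-degree part, so τ = 1 makes TWSNI the
   degree-≤1 targets. Counts are taken on the full matrix before
   cross-validation (the split is a preprocessing step, analogous to
   choosing which assay panel a target belongs to); a
   `partition_per_fold` flag recomputes them on each training split for
   users worried about that mild dependence on test rows.

2. **High-degree strategy.** One CART tree per target, trained on
   `(D, Y[:, j])` restricted to training drugs. Hyperparameters follow the
   common MATLAB-style classification-tree defaults: Gini impurity, no
   depth cap, minimum leaf size 1, minimum parent size 10, no pruning; all
   exposed via `TreeParams`. The ranking score of a drug is the positive
   fraction of the leaf it reaches (a CART tree's natural continuous
   score). Targets whose training column is single-class are skipped and
   reported — there is no principled fallback within the per-target model.

3. **Low-degree strategy.** Nearest-profile transfer: the drug side copies
   the most similar *training* drug's row scaled by that similarity; the
   target side copies the most similar other target's value scaled by the
   target similarity. Because the queried cell of the neighbour target's
   column belongs to a cold-start test drug, it is unobserved; we
   substitute its own drug-side nearest-profile estimate
   `s_d(d, d*)·Y[d*, t*]`. This chaining stays strictly within the
   one-neighbour transfer rule and introduces no test-label leakage; it is
   a design choice where the original formulation is silent (the published
   formulas assume the neighbour column is observed). Target neighbours
   are searched over *all* targets so the tail can borrow from the head;
   similarity ties break to the lexicographically smallest identifier.

4. **Evaluation.** Drug-wise 5-fold CV with balanced random folds. Within
   each fold the high-degree part gets one AUC per target (targets with
   single-class test labels are excluded and listed), macro-averaged; the
   low-degree part gets a single AUC pooled over all its (test drug,
   target) cells, because per-target AUC is usually undefined for degree-1
   targets. Fold values aggregate to mean ± sample (n−1) standard
   deviation per part. AUC uses the Mann–Whitney formulation with midrank
   tie handling; a brute-force pairwise oracle (`auc_oracle`) guards the
   implementation in the tests.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the method depends on,
not chemistry:

* **Sparsity.** Default 54 drugs × 26 targets at density 0.064 — the shape
  of the smallest public benchmark — so a full CV run takes well under a
  second. The total interaction count is apportioned exactly.
* **Degree skew.** Per-target degrees follow a truncated Zipf law with
  exponent `skew` (default 1.0), apportioned by largest-remainder rounding
  so the concentration invariant (top 20 % of targets ≥ 50 % of
  interactions for skew ≥ 1, v ≥ 20) holds deterministically; which target
  receives which degree is a seeded permutation.
* **Plantable signal.** Targets belong to latent families (≈ v/5 groups).
  Each target owns `round(signal·p)` informative fingerprint bits, half
  shared with its family, half private. Interacting drugs carry a
  target's bits with probability 0.9 against a 0.05 background. Private
  bits make per-target trees work; shared bits plus family-centroid target
  descriptors (Gaussian, sd 0.5 around the centroid) make similarity
  transfer work for low-degree targets. `signal = 0` plants nothing and
  every predictor falls to chance — the null the tests check. Default
  `signal = 0.05` (≈ 51 informative bits of 1024) and `noise = 0`
  (label-flip probability): a clean world in which recovery is expected;
  the noise dial exists to probe degradation.
* **Similarities.** Tanimoto (Jaccard) on fingerprints for drugs; Gaussian
  RBF with the median-squared-distance bandwidth heuristic on descriptors
  for targets — the same constructions a practitioner would use when a
  dataset ships no precomputed similarities.

A green recovery test therefore establishes that the pipeline finds a
feature→interaction signal of this planted form under cold-start CV; it
says nothing about absolute AUC on the real benchmarks, which require
external feature extraction pipelines and are out of scope.

## Numerical choices and degenerate inputs

* Similarity matrices must be symmetric within 1e-9, entries in [0,1],
  unit diagonal; interaction entries exactly {0,1}. Validators report all
  violations at once.
* AUC ties use midranks; single-class label vectors raise a typed error
  rather than returning a number.
* Nearest-neighbour ties break lexicographically; the query is always
  excluded even when self-similarity would win.
* An all-zero fingerprint row is Tanimoto-similar only to itself; a
  degenerate (all-zero off-diagonal) drug similarity yields zero scores
  with a warning.
* Network-based inference uses no similarity, so cold-start test drugs
  (all of them, under drug-wise CV) score zero with a warning — the
  baseline is retained for completeness of the comparison set, not because
  it can compete in this protocol.
* Fold assignment is a seeded permutation with round-robin fill: sizes
  differ by at most one, reruns are bit-identical.

## Design choices made where the design was open

* **Boundary of the partition** (`≤ τ` = small): chosen so τ = 1 isolates
  the degree-1 targets, matching the motivation that nearest-profile suits
  targets with very few interactions.
* **Per-target-then-per-fold averaging** for the high-degree part: each
  fold's macro AUC is the mean over its evaluable targets; the report's
  headline is the mean ± sd of the five fold values.
* **Pooled AUC** for the low-degree part (rather than macro): per-target
  AUC is undefined for most degree-1 targets under any drug split.
* **± is the sample sd over folds**; recorded in the report so readers
  need not guess.
* **Tree score = leaf positive fraction**: AUC needs a continuous score
  and a plain class prediction would waste the ranking information.

## Known limitations

* The synthetic world has no realistic chemistry: fingerprints are
  independent Bernoulli bits outside the planted sets, and target
  descriptors are isotropic Gaussians around family centroids.
* Absolute AUC values on the public benchmarks are not reproduced here;
  they depend on external feature extraction (substructure fingerprints
  from SMILES, sequence descriptors from protein sequences) that this
  package deliberately does not perform.
* Only the four comparison methods whose formulations are fully standard
  (global tree, nearest profile, weighted profile, network-based
  inference) are included; ensemble and kernel-regression competitors
  require machinery from their own publications.
* The chaining rule for the unobserved neighbour-column cell is one
  defensible reading; alternatives (e.g. using the raw neighbour value for
  training drugs only) would change low-degree scores.
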