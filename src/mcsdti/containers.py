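"""Core in-memory containers for chemogenomic DTI data.

A chemogenomic dataset is a drug set, a target set, a binary interaction
matrix ``Y`` (drugs x targets), companion feature tables (binary substructure
fingerprints for drugs, real-valued sequence descriptors for targets) and
square similarity matrices over drugs and targets.  Every container validates
its invariants on construction and reports *all* violations at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "InteractionMatrix",
    "FeatureMatrix",
    "SimilarityMatrix",
    "ScoreMatrix",
    "DatasetSummary",
]

SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """A container failed one or more structural invariants."""


def _check_ids(ids: tuple[str, ...], label: str, problems: list[str]) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        problems.append(f"duplicate {label} identifiers: {dupes}")


@dataclass(frozen=True)
class InteractionMatrix:
    """Binary drug x target interaction matrix ``Y``.

    ``values[i, j] == 1`` iff drug ``drug_ids[i]`` interacts with target
    ``target_ids[j]``.
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(str(d) for d in self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(str(t) for t in self.target_ids))
        vals = np.asarray(self.values)
        object.__setattr__(self, "values", vals)
        problems: list[str] = []
        _check_ids(self.drug_ids, "drug", problems)
        _check_ids(self.target_ids, "target", problems)
        if vals.shape != (len(self.drug_ids), len(self.target_ids)):
            problems.append(
                f"shape {vals.shape} does not match "
                f"({len(self.drug_ids)}, {len(self.target_ids)}) identifiers"
            )
        else:
            bad = ~np.isin(vals, (0, 1))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                problems.append(
                    f"non-binary entry {vals[i, j]!r} at "
                    f"({self.drug_ids[i]}, {self.target_ids[j]}) "
                    f"and {int(bad.sum()) - 1} more"
                )
        if problems:
            raise ValidationError("; ".join(problems))
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def target_index(self, target_id: str) -> int:
        return self.target_ids.index(target_id)

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_index(drug_id)]

    def column(self, target_id: str) -> np.ndarray:
        return self.values[:, self.target_index(target_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.drug_ids), columns=list(self.target_ids)
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature table: drug fingerprints (binary) or target descriptors (real)."""

    row_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    kind: str  # "drug" | "target"

    def __post_init__(self) -> None:
        object.__setattr__(self, "row_ids", tuple(str(r) for r in self.row_ids))
        object.__setattr__(
            self, "feature_names", tuple(str(f) for f in self.feature_names)
        )
        vals = np.asarray(self.values, dtype=float)
        problems: list[str] = []
        if self.kind not in ("drug", "target"):
            problems.append(f"kind must be 'drug' or 'target', got {self.kind!r}")
        _check_ids(self.row_ids, "row", problems)
        if vals.shape != (len(self.row_ids), len(self.feature_names)):
            problems.append(
                f"shape {vals.shape} does not match "
                f"({len(self.row_ids)}, {len(self.feature_names)}) labels"
            )
        else:
            if np.isnan(vals).any():
                problems.append(f"{int(np.isnan(vals).sum())} missing values")
            elif self.kind == "drug" and not np.isin(vals, (0.0, 1.0)).all():
                problems.append("drug fingerprint matrix contains non-{0,1} entries")
        if problems:
            raise ValidationError("; ".join(problems))
        object.__setattr__(self, "values", vals)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def rows(self, ids: list[str] | tuple[str, ...]) -> np.ndarray:
        index = {r: i for i, r in enumerate(self.row_ids)}
        return self.values[[index[i] for i in ids]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_ids), columns=list(self.feature_names)
        )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        vals = np.asarray(self.values, dtype=float)
        problems: list[str] = []
        _check_ids(self.ids, "similarity", problems)
        n = len(self.ids)
        if vals.shape != (n, n):
            problems.append(f"shape {vals.shape} is not ({n}, {n})")
        else:
            asym = np.abs(vals - vals.T).max(initial=0.0)
            if asym > SYMMETRY_TOL:
                i, j = np.unravel_index(np.argmax(np.abs(vals - vals.T)), vals.shape)
                problems.append(
                    f"asymmetric beyond {SYMMETRY_TOL:g}: "
                    f"S[{self.ids[i]},{self.ids[j]}]={vals[i, j]:g} vs "
                    f"S[{self.ids[j]},{self.ids[i]}]={vals[j, i]:g}"
                )
            if vals.size and (vals.min() < -SYMMETRY_TOL or vals.max() > 1 + SYMMETRY_TOL):
                problems.append(
                    f"entries outside [0, 1]: min={vals.min():g}, max={vals.max():g}"
                )
            if n and np.abs(np.diag(vals) - 1.0).max() > SYMMETRY_TOL:
                problems.append("diagonal entries not all 1")
        if problems:
            raise ValidationError("; ".join(problems))
        object.__setattr__(self, "values", vals)

    def index(self, item_id: str) -> int:
        return self.ids.index(item_id)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class ScoreMatrix:
    """Real-valued prediction scores for (drug, target) cells.

    ``mask[i, j]`` is True where a score was actually produced; unmasked cells
    (e.g. targets skipped because their training column was single-class) hold
    no meaningful value.
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    scores: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(str(d) for d in self.drug_ids))
        object.__setattr__(self, "target_ids", tuple(str(t) for t in self.target_ids))
        scores = np.asarray(self.scores, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        problems: list[str] = []
        shape = (len(self.drug_ids), len(self.target_ids))
        if scores.shape != shape or mask.shape != shape:
            problems.append(
                f"score shape {scores.shape} / mask shape {mask.shape} != {shape}"
            )
        else:
            scored = scores[mask]
            if scored.size and not np.isfinite(scored).all():
                problems.append("non-finite score in a scored cell")
            elif scored.size and (scored.min() < 0 or scored.max() > 1):
                problems.append(
                    f"scores outside [0, 1]: min={scored.min():g}, max={scored.max():g}"
                )
        if problems:
            raise ValidationError("; ".join(problems))
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "mask", mask)

    def drug_index(self, drug_id: str) -> int:
        return self.drug_ids.index(drug_id)

    def target_index(self, target_id: str) -> int:
        return self.target_ids.index(target_id)

    def column(self, target_id: str) -> np.ndarray:
        return self.scores[:, self.target_index(target_id)]


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset size counts plus interaction density as a percentage."""

    n_drugs: int
    n_targets: int
    n_interactions: int
    density_percent: float = field(init=False)

    def __post_init__(self) -> None:
        pairs = self.n_drugs * self.n_targets
        if pairs <= 0:
            raise ValidationError("empty matrix: zero drugs or targets")
        object.__setattr__(
            self, "density_percent", 100.0 * self.n_interactions / pairs
        )

    def density_rounded(self, decimals: int) -> float:
        """Density at a display precision; the stored value is never rounded."""
        return round(self.density_percent, decimals)
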