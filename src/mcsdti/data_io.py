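"""Readers, writers and summary statistics for DTI tables.

Two interaction-file dialects are supported: a two-column pair list (no
header, one interacting pair per line) and a dense labelled matrix (header
row of target identifiers, first column of drug identifiers).  Dense tables
are also used for feature and similarity matrices.  Delimiter is tab by
default; identifiers are case-sensitive opaque strings.  Data errors are
always fatal; recoverable oddities (duplicate pairs) are logged.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    DatasetSummary,
    FeatureMatrix,
    InteractionMatrix,
    ScoreMatrix,
    SimilarityMatrix,
    ValidationError,
)

logger = logging.getLogger("mcsdti")

__all__ = [
    "read_pair_list",
    "write_pair_list",
    "read_dense_matrix",
    "write_dense_matrix",
    "dataset_summary",
    "degree_concentration",
    "format_mean_sd",
    "write_report",
    "read_report",
]


def read_pair_list(
    path: str | Path,
    *,
    column_order: str = "drug-target",
    all_drugs: Sequence[str] | None = None,
    all_targets: Sequence[str] | None = None,
    delimiter: str = "\t",
) -> InteractionMatrix:
    """Read a two-column pair list into an interaction matrix.

    ``column_order`` declares whether lines are ``drug-target`` or
    ``target-drug``; there is no sniffing.  The identifier universe is the
    union of listed identifiers (in sorted order) unless explicit lists are
    supplied.  Duplicate pairs are accepted idempotently with a warning; a
    pair referencing an identifier outside a supplied universe is fatal.
    """
    if column_order not in ("drug-target", "target-drug"):
        raise ValueError(f"column_order must be 'drug-target' or 'target-drug', got {column_order!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(delimiter)
            if len(fields) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            a, b = (f.strip() for f in fields)
            pairs.append((a, b) if column_order == "drug-target" else (b, a))

    drugs = list(all_drugs) if all_drugs is not None else sorted({d for d, _ in pairs})
    targets = (
        list(all_targets) if all_targets is not None else sorted({t for _, t in pairs})
    )
    d_index = {d: i for i, d in enumerate(drugs)}
    t_index = {t: j for j, t in enumerate(targets)}
    values = np.zeros((len(drugs), len(targets)), dtype=np.int8)
    seen: set[tuple[str, str]] = set()
    for d, t in pairs:
        if d not in d_index:
            raise ValidationError(f"pair references unknown drug identifier {d!r}")
        if t not in t_index:
            raise ValidationError(f"pair references unknown target identifier {t!r}")
        if (d, t) in seen:
            logger.warning("duplicate pair (%s, %s) in %s; kept once", d, t, path)
        seen.add((d, t))
        values[d_index[d], t_index[t]] = 1
    return InteractionMatrix(tuple(drugs), tuple(targets), values)


def write_pair_list(
    Y: InteractionMatrix, path: str | Path, *, delimiter: str = "\t"
) -> None:
    with open(path, "w") as handle:
        for i, d in enumerate(Y.drug_ids):
            for j, t in enumerate(Y.target_ids):
                if Y.values[i, j]:
                    handle.write(f"{d}{delimiter}{t}\n")


def read_dense_matrix(
    path: str | Path, kind: str, *, delimiter: str = "\t", feature_kind: str = "drug"
) -> InteractionMatrix | SimilarityMatrix | FeatureMatrix:
    """Read a dense labelled table as interaction, similarity or feature matrix.

    The first row holds column identifiers, the first column row identifiers.
    Validation failures raise :class:`ValidationError` listing every violated
    invariant.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    rows = tuple(frame.index)
    cols = tuple(frame.columns)
    values = frame.to_numpy()
    if kind == "interaction":
        return InteractionMatrix(rows, cols, values)
    if kind == "similarity":
        if rows != cols:
            raise ValidationError(
                f"{path}: similarity row labels differ from column labels"
            )
        return SimilarityMatrix(rows, values)
    if kind == "feature":
        return FeatureMatrix(rows, cols, values, kind=feature_kind)
    raise ValueError(f"unknown kind {kind!r}")


def write_dense_matrix(
    obj: InteractionMatrix | SimilarityMatrix | FeatureMatrix | ScoreMatrix,
    path: str | Path,
    *,
    delimiter: str = "\t",
) -> None:
    if isinstance(obj, ScoreMatrix):
        frame = pd.DataFrame(
            obj.scores, index=list(obj.drug_ids), columns=list(obj.target_ids)
        )
    else:
        frame = obj.to_frame()
    frame.to_csv(path, sep=delimiter)


def dataset_summary(Y: InteractionMatrix) -> DatasetSummary:
    """Counts and interaction density (percentage of positive cells)."""
    if Y.n_drugs == 0 or Y.n_targets == 0:
        raise ValidationError("empty interaction matrix")
    return DatasetSummary(Y.n_drugs, Y.n_targets, int(Y.values.sum()))


def degree_concentration(Y: InteractionMatrix, top_fraction: float) -> float:
    """Share of all interactions held by the most-connected targets.

    Sorts targets by interaction count descending and returns the fraction of
    interactions that fall on the top ``ceil(top_fraction * n_targets)``
    targets.  Benchmark chemogenomic datasets are strongly concentrated:
    typically 50-60%+ of interactions sit on the top fifth of targets.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    counts = np.sort(Y.values.sum(axis=0))[::-1]
    total = counts.sum()
    if total == 0:
        raise ValidationError("degree_concentration undefined for zero interactions")
    k = math.ceil(top_fraction * Y.n_targets)
    return float(counts[:k].sum() / total)


def format_mean_sd(values: Iterable[float]) -> str:
    """Render fold values as ``mean ± sd`` with the sample (n-1) deviation."""
    arr = np.asarray(list(values), dtype=float)
    mean = arr.mean()
    sd = arr.std(ddof=1) if arr.size > 1 else float("nan")
    return f"{mean:.4f} ± {sd:.4f}"


def _summary_lines(report: dict) -> list[str]:
    lines = ["MCSDTI evaluation summary", "=" * 25]
    cfg = report.get("config", {})
    if cfg:
        lines.append(
            "config: "
            + ", ".join(f"{k}={cfg[k]}" for k in sorted(cfg) if not isinstance(cfg[k], dict))
        )
    for part in ("twlni", "twsni"):
        agg = report.get("aggregate", {}).get(part)
        if not agg or agg.get("fold_values") in (None, []):
            lines.append(f"{part.upper()}: not evaluated")
            continue
        lines.append(
            f"{part.upper()} AUC: {format_mean_sd(agg['fold_values'])} "
            f"(over {len(agg['fold_values'])} folds)"
        )
    return lines


def write_report(report: dict, path: str | Path, *, text_path: str | Path | None = None) -> None:
    """Write the full machine-readable report (JSON) plus a text summary.

    The JSON document round-trips exactly through :func:`read_report`.  The
    companion plain-text file carries the per-part ``mean ± sd`` lines in the
    shape the AUC tables of the benchmark literature use.
    """
    path = Path(path)
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    text_path = Path(text_path) if text_path is not None else path.with_suffix(".txt")
    with open(text_path, "w") as handle:
        handle.write("\n".join(_summary_lines(report)) + "\n")


def read_report(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)
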