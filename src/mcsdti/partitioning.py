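"""Split targets by interaction count into high- and low-degree parts.

Benchmark interaction matrices are dominated by a handful of promiscuous
targets: most interactions concentrate on a small fraction of targets, while
the long tail of targets has one or two known interactions each.  Targets
with more than ``tau`` interactions (TWLNI, "targets with larger numbers of
interactions") have enough positive examples to train their own classifier;
targets at or below the threshold (TWSNI) do not, and are better served by
similarity transfer.  Boundary semantics: a target with exactly ``tau``
interactions is *small*, so ``tau = 1`` puts the degree-1 targets in TWSNI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import InteractionMatrix

__all__ = ["TargetPartition", "count_target_interactions", "partition_targets"]


@dataclass(frozen=True)
class TargetPartition:
    """Disjoint TWLNI/TWSNI split at integer threshold ``tau``."""

    tau: int
    twlni_ids: tuple[str, ...]  # interaction count > tau
    twsni_ids: tuple[str, ...]  # interaction count <= tau
    counts: dict[str, int]

    def __post_init__(self) -> None:
        overlap = set(self.twlni_ids) & set(self.twsni_ids)
        if overlap:
            raise ValueError(f"targets in both parts: {sorted(overlap)}")

    @property
    def all_target_ids(self) -> tuple[str, ...]:
        return self.twlni_ids + self.twsni_ids

    def part_of(self, target_id: str) -> str:
        return "twlni" if target_id in set(self.twlni_ids) else "twsni"


def count_target_interactions(Y: InteractionMatrix) -> np.ndarray:
    """Per-target interaction counts (column sums of Y, in target order)."""
    return Y.values.sum(axis=0)


def partition_targets(Y: InteractionMatrix, tau: int) -> TargetPartition:
    """Partition targets of ``Y`` at threshold ``tau``.

    TWLNI holds targets with count > tau, TWSNI those with count <= tau.
    Membership depends only on the counts, never on target order; increasing
    tau can only move targets from TWLNI into TWSNI.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    counts = count_target_interactions(Y)
    twlni = tuple(t for t, c in zip(Y.target_ids, counts) if c > tau)
    twsni = tuple(t for t, c in zip(Y.target_ids, counts) if c <= tau)
    return TargetPartition(
        tau=int(tau),
        twlni_ids=twlni,
        twsni_ids=twsni,
        counts={t: int(c) for t, c in zip(Y.target_ids, counts)},
    )
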