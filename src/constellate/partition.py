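"""Significance filtering and multi-set Venn partitioning of per-level proteomics.

A stepwise ectopic-expression ("constellation") experiment yields one list of
significantly altered proteins per expression level.  This module filters the
raw quantification table at explicit significance criteria and partitions the
per-level protein sets into their Venn cells: proteins unique to one level,
shared by a given subset of levels, or common to all levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping

from .io_formats import ConstellateError, GeneID, QuantTable, SpecError

__all__ = [
    "SignificanceCriteria",
    "DEFAULT_CRITERIA",
    "ConstellationPartition",
    "filter_significant",
    "venn_partition",
    "unique_percentages",
    "common_core",
    "round_half_even",
]


@dataclass(frozen=True)
class SignificanceCriteria:
    """Thresholds defining a "significantly altered" protein.

    A protein passes at a level iff its p-value is <= ``max_p`` AND the
    absolute log2 ratio is >= ``min_abs_log2_ratio``.  The defaults
    (p <= 0.05, |log2 FC| >= log2(1.2)) are the conventional proteomics
    cutoffs; both are explicit configuration, never implied.
    """

    max_p: float = 0.05
    min_abs_log2_ratio: float = math.log2(1.2)

    def __post_init__(self) -> None:
        if not (0.0 < self.max_p <= 1.0):
            raise SpecError(f"max_p must be in (0,1], got {self.max_p}")
        if self.min_abs_log2_ratio < 0:
            raise SpecError("min_abs_log2_ratio must be >= 0")

    def passes(self, log2_ratio: float, p_value: float) -> bool:
        return p_value <= self.max_p and abs(log2_ratio) >= self.min_abs_log2_ratio


DEFAULT_CRITERIA = SignificanceCriteria()


@dataclass(frozen=True)
class ConstellationPartition:
    """The Venn partition of per-level significant protein sets.

    ``cells`` maps each non-empty subset of levels (a frozenset of level
    labels) to the proteins present in exactly those levels.  Cells are
    pairwise disjoint and jointly cover the union of all level sets.
    """

    per_level_sets: Mapping[str, frozenset[GeneID]]
    cells: Mapping[frozenset, frozenset[GeneID]]
    level_totals: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_level_sets", dict(self.per_level_sets))
        object.__setattr__(self, "cells", dict(self.cells))
        object.__setattr__(self, "level_totals", dict(self.level_totals))


def filter_significant(
    table: QuantTable, criteria: SignificanceCriteria = DEFAULT_CRITERIA
) -> dict[str, frozenset[GeneID]]:
    """Per-level sets of proteins passing the significance criteria."""
    out: dict[str, set[GeneID]] = {level: set() for level in table.levels}
    for rec in table:
        if criteria.passes(rec.log2_ratio, rec.p_value):
            out[rec.level].add(rec.protein)
    return {level: frozenset(s) for level, s in out.items()}


def venn_partition(sets: Mapping[str, frozenset[GeneID] | set[GeneID]]) -> ConstellationPartition:
    """Partition >=2 named sets into their Venn cells.

    Each gene lands in exactly one cell, keyed by the frozenset of levels
    containing it; empty cells are omitted.
    """
    if len(sets) < 2:
        raise SpecError(f"venn_partition needs >=2 sets, got {len(sets)}")
    per_level = {level: frozenset(members) for level, members in sets.items()}
    cells: dict[frozenset, set[GeneID]] = {}
    for gene in frozenset().union(*per_level.values()):
        key = frozenset(level for level, members in per_level.items() if gene in members)
        cells.setdefault(key, set()).add(gene)
    return ConstellationPartition(
        per_level_sets=per_level,
        cells={k: frozenset(v) for k, v in cells.items()},
        level_totals={level: len(members) for level, members in per_level.items()},
    )


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding at a fixed decimal precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def unique_percentages(p: ConstellationPartition, ndigits: int = 2) -> dict[str, float]:
    """Percentage of each level's proteins found at that level only.

    100 * |singleton cell for the level| / level total, rounded half-even.
    Raises for any level with an empty set (percentage undefined).
    """
    out: dict[str, float] = {}
    for level, total in p.level_totals.items():
        if total == 0:
            raise ConstellateError(f"level {level!r} has no proteins; percentage undefined")
        unique = p.cells.get(frozenset([level]), frozenset())
        out[level] = round_half_even(100.0 * len(unique) / total, ndigits)
    return out


def common_core(p: ConstellationPartition) -> frozenset[GeneID]:
    """Proteins present at every level (the all-levels Venn cell)."""
    all_levels = frozenset(p.per_level_sets)
    return p.cells.get(all_levels, frozenset())
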