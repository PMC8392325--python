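"""Family-level rearrangement richness and survey summaries.

The richness of a family for a rearrangement unit (or the whole
mitogenome) is the number of distinct rearranged arrangements of that unit
found in the family, divided by the total number of distinct rearranged
arrangements of the unit across the whole catalog.  An arrangement shared
verbatim by several families is counted once in the denominator but once
in each family's numerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .catalog import Catalog, CatalogRecord
from .gene_order import CODING_GENES, GeneOrder
from .rearrangements import (
    DEFAULT_BLOCKS,
    DEFAULT_UNITS,
    BlockDefinition,
    UnitDefinition,
    UnitSignature,
    group_signatures,
    is_unit_rearranged,
    order_is_rearranged,
    orders_equivalent,
    region_signature,
    unit_signature,
)

__all__ = [
    "WHOLE",
    "DistinctArrangementIndex",
    "RichnessTable",
    "build_index",
    "richness",
    "survey_counts",
    "block_diversity",
    "render_percent",
]

WHOLE = "whole"


@dataclass(frozen=True)
class DistinctArrangementIndex:
    """Distinct rearranged arrangements per column (six units + whole).

    ``families_per_group`` maps each column to a list of identity groups,
    each group being the set of families carrying that arrangement.
    ``families`` preserves catalog appearance order.
    """

    columns: tuple[str, ...]
    families: tuple[str, ...]
    families_per_group: Mapping[str, tuple[frozenset[str], ...]]

    def union_size(self, column: str) -> int:
        return len(self.families_per_group[column])

    def family_count(self, column: str, family: str) -> int:
        return sum(1 for fams in self.families_per_group[column]
                   if family in fams)


def _record_families(record: CatalogRecord) -> tuple[str, ...]:
    return record.families


def build_index(catalog: Catalog,
                units: Sequence[UnitDefinition] = DEFAULT_UNITS,
                ) -> DistinctArrangementIndex:
    """Collect the distinct rearranged arrangements of every unit and of the
    whole mitogenome across the catalog, deduplicated by signature identity
    within the union (and per family in the numerators)."""
    ancestral = catalog.ancestral
    rearranged = catalog.rearranged_records()
    families: list[str] = []
    for rec in rearranged:
        for fam in rec.families:
            if fam not in families:
                families.append(fam)

    groups: dict[str, tuple[frozenset[str], ...]] = {}
    for unit in units:
        sigs: list[UnitSignature] = []
        fams: list[tuple[str, ...]] = []
        for rec in rearranged:
            sig = unit_signature(rec.order, unit, ancestral)
            if not sig.unknown and is_unit_rearranged(sig, ancestral):
                sigs.append(sig)
                fams.append(rec.families)
        grouped = group_signatures(sigs)
        groups[unit.name] = tuple(
            frozenset(f for i in g for f in fams[i]) for g in grouped)

    # whole mitogenome: group rearranged orders by known-arc identity
    reps: list[GeneOrder] = []
    whole: list[set[str]] = []
    ordered = sorted(rearranged,
                     key=lambda r: (-len(r.order.known_genes()),
                                    r.taxon))
    for rec in ordered:
        for g, rep in enumerate(reps):
            if orders_equivalent(rec.order, rep):
                whole[g].update(rec.families)
                break
        else:
            reps.append(rec.order)
            whole.append(set(rec.families))
    groups[WHOLE] = tuple(frozenset(f) for f in whole)

    columns = tuple(u.name for u in units) + (WHOLE,)
    return DistinctArrangementIndex(columns, tuple(families), groups)


@dataclass(frozen=True)
class RichnessTable:
    """Family x column richness ratios in [0, 1]; NaN marks an undefined
    column (no rearrangement of that unit anywhere in the catalog)."""

    ratios: pd.DataFrame  # index = families, columns = units + whole

    def percent(self, family: str, column: str) -> float | None:
        """Cell as a percentage rounded to one decimal (half away from
        zero), the survey's reporting convention; None when undefined."""
        value = self.ratios.loc[family, column]
        if pd.isna(value):
            return None
        return render_percent(value)

    def to_percent_frame(self) -> pd.DataFrame:
        return self.ratios.map(
            lambda v: float("nan") if pd.isna(v) else render_percent(v))


def render_percent(ratio: float) -> float:
    """0.4286 -> 42.9 (one decimal, ties rounded half away from zero)."""
    return float(Decimal(repr(float(ratio) * 100)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def richness(index: DistinctArrangementIndex) -> RichnessTable:
    """Richness ratios per family and column from a built index."""
    data = {}
    for col in index.columns:
        denom = index.union_size(col)
        data[col] = [
            (index.family_count(col, fam) / denom) if denom else float("nan")
            for fam in index.families
        ]
    frame = pd.DataFrame(data, index=list(index.families))
    return RichnessTable(frame)


def survey_counts(catalog: Catalog) -> dict[str, int]:
    """Catalog-wide survey summary.

    Returns ``n_distinct_orders`` (ancestral ground pattern + distinct
    rearranged whole-genome orders), ``n_rearranged_orders``,
    ``n_rearranged_species`` (species carrying a rearranged order) and
    ``n_families_with_rearrangement``.
    """
    index = build_index(catalog)
    n_rearranged = index.union_size(WHOLE)
    species = sum(r.species_count for r in catalog.rearranged_records())
    families = set()
    for rec in catalog.rearranged_records():
        families.update(rec.families)
    return {
        "n_distinct_orders": n_rearranged + 1,
        "n_rearranged_orders": n_rearranged,
        "n_rearranged_species": species,
        "n_families_with_rearrangement": len(families),
    }


def block_diversity(catalog: Catalog,
                    blocks: Sequence[BlockDefinition] = DEFAULT_BLOCKS,
                    ) -> dict[str, int]:
    """Number of distinct rearranged block-level arrangements per block."""
    ancestral = catalog.ancestral
    out: dict[str, int] = {}
    for block in blocks:
        sigs: list[UnitSignature] = []
        for rec in catalog.rearranged_records():
            sig = region_signature(rec.order, block.name, block.members,
                                   ancestral)
            if not sig.unknown and is_unit_rearranged(sig, ancestral):
                sigs.append(sig)
        out[block.name] = len(group_signatures(sigs))
    return out
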