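"""Taxon gene-order catalogs: records, TSV I/O and the packaged survey.

A catalog row couples taxon metadata (infraorder, family, how many species
carry the order) with one gene order and an optional synapomorphy level —
the clade depth at which the rearranged order is a candidate shared derived
character.  A single order shared verbatim across families is stored as one
record listing the families slash-separated (``Largidae/Pyrrhocoridae``)
with species counts aligned (``4/12``).

The packaged fixture ``data/heteroptera_catalog.tsv`` transcribes the
published survey of heteropteran mitogenome rearrangements: 19 rearranged
records spanning 11 families plus one aggregated pseudo-record for the taxa
retaining the ancestral ground pattern.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .gene_order import (
    GeneOrder,
    GeneOrderError,
    ancestral_order,
    format_gene_order,
    parse_gene_order,
)

__all__ = [
    "SYNAPOMORPHY_LEVELS",
    "CatalogError",
    "CatalogRecord",
    "Catalog",
    "read_catalog",
    "write_catalog",
    "load_heteroptera_catalog",
]

SYNAPOMORPHY_LEVELS = ("none", "genus", "family", "superfamily", "infraorder")

_COLUMNS = ("taxon", "infraorder", "family", "species_count", "gene_order",
            "synapomorphy")


class CatalogError(ValueError):
    """Malformed catalog file or inconsistent record."""


@dataclass(frozen=True)
class CatalogRecord:
    """One catalog entry: metadata plus a gene order.

    ``families`` and ``species_counts`` are parallel; most records list a
    single family.
    """

    taxon: str
    infraorder: str
    families: tuple[str, ...]
    species_counts: tuple[int, ...]
    order: GeneOrder
    synapomorphy_level: str = "none"

    def __post_init__(self):
        if not self.families or len(self.families) != len(self.species_counts):
            raise CatalogError(
                f"{self.taxon}: families and species counts must align")
        if any(c < 1 for c in self.species_counts):
            raise CatalogError(f"{self.taxon}: species_count must be >= 1")
        if self.synapomorphy_level not in SYNAPOMORPHY_LEVELS:
            raise CatalogError(
                f"{self.taxon}: bad synapomorphy level "
                f"{self.synapomorphy_level!r}")

    @property
    def family(self) -> str:
        return "/".join(self.families)

    @property
    def species_count(self) -> int:
        return sum(self.species_counts)

    def family_counts(self) -> Iterable[tuple[str, int]]:
        return zip(self.families, self.species_counts)


@dataclass(frozen=True)
class Catalog:
    """A record set scored against one ancestral (ground-pattern) order."""

    records: tuple[CatalogRecord, ...]
    ancestral: GeneOrder = field(default_factory=ancestral_order)

    def __post_init__(self):
        if not self.ancestral.complete or self.ancestral.absent:
            raise CatalogError("ancestral order must be complete and "
                               "absence-free")
        syms = [t.symbol for t in self.ancestral.tokens]
        if len(syms) != len(set(syms)):
            raise CatalogError("ancestral order must be duplication-free")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def rearranged_records(self) -> tuple[CatalogRecord, ...]:
        """Records whose order differs from the ancestral ground pattern."""
        from .rearrangements import order_is_rearranged  # cycle-safe
        return tuple(r for r in self.records
                     if order_is_rearranged(r.order, self.ancestral))


def _parse_record(row: dict, lineno: int) -> CatalogRecord:
    families = tuple(f.strip() for f in row["family"].split("/"))
    counts_raw = [c.strip() for c in str(row["species_count"]).split("/")]
    try:
        counts = tuple(int(c) for c in counts_raw)
    except ValueError:
        raise CatalogError(
            f"line {lineno}: species_count {row['species_count']!r} "
            f"is not an integer (or slash-list of integers)") from None
    try:
        order = parse_gene_order(row["gene_order"], taxon=row["taxon"])
    except GeneOrderError as exc:
        raise CatalogError(f"line {lineno}: {exc}") from exc
    syn = (row.get("synapomorphy") or "none").strip() or "none"
    try:
        return CatalogRecord(row["taxon"].strip(), row["infraorder"].strip(),
                             families, counts, order, syn)
    except CatalogError as exc:
        raise CatalogError(f"line {lineno}: {exc}") from exc


def read_catalog(path: str | Path, ancestral: GeneOrder | None = None) -> Catalog:
    """Read a catalog TSV (UTF-8, ``#`` comment lines allowed).

    Columns: taxon, infraorder, family, species_count, gene_order,
    synapomorphy.  Malformed rows raise :class:`CatalogError` with the line
    number; duplicate taxon labels are rejected.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        return _read_catalog_lines(handle, ancestral)


def _read_catalog_lines(lines: Iterable[str],
                        ancestral: GeneOrder | None) -> Catalog:
    header: list[str] | None = None
    records: list[CatalogRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = set(_COLUMNS) - set(header)
            if missing:
                raise CatalogError(
                    f"line {lineno}: missing columns {sorted(missing)}")
            continue
        if len(fields) != len(header):
            raise CatalogError(
                f"line {lineno}: expected {len(header)} fields, "
                f"got {len(fields)}")
        rec = _parse_record(dict(zip(header, fields)), lineno)
        if rec.taxon in seen:
            raise CatalogError(f"line {lineno}: duplicate taxon "
                               f"{rec.taxon!r}")
        seen.add(rec.taxon)
        records.append(rec)
    if header is None:
        raise CatalogError("catalog file has no header line")
    return Catalog(tuple(records),
                   ancestral if ancestral is not None else ancestral_order())


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Write a catalog TSV; inverse of :func:`read_catalog` on canonical
    catalogs."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_COLUMNS)
        for rec in catalog.records:
            writer.writerow([
                rec.taxon,
                rec.infraorder,
                rec.family,
                "/".join(str(c) for c in rec.species_counts),
                format_gene_order(rec.order),
                rec.synapomorphy_level,
            ])


def load_heteroptera_catalog() -> Catalog:
    """Load the packaged heteropteran rearrangement survey."""
    ref = resources.files("mitorearr.data").joinpath("heteroptera_catalog.tsv")
    with ref.open("r", encoding="utf-8") as handle:
        return _read_catalog_lines(handle, None)
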