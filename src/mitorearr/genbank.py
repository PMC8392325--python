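"""Extract gene orders (and sequence) from annotated GenBank records.

This reads *existing* annotations — it does no gene prediction.  Features
are sorted by 5' coordinate on the majority strand; complement-strand
features become minority tokens; a gene/CDS (or gene/tRNA, gene/rRNA) pair
annotating the same locus collapses to one token.  Products that cannot be
mapped to the gene vocabulary become NCR tokens and are listed in the
warnings of the returned report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO

from .gene_order import GeneOrder, GeneOrderError, GeneToken, MAJORITY, MINORITY

__all__ = ["GenBankOrderReport", "order_from_genbank"]

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}

_PCG_ALIASES = {
    "ND1": "ND1", "NAD1": "ND1", "NADH1": "ND1",
    "ND2": "ND2", "NAD2": "ND2", "NADH2": "ND2",
    "ND3": "ND3", "NAD3": "ND3", "NADH3": "ND3",
    "ND4": "ND4", "NAD4": "ND4", "NADH4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L", "NADH4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5", "NADH5": "ND5",
    "ND6": "ND6", "NAD6": "ND6", "NADH6": "ND6",
    "COI": "COI", "COX1": "COI", "CO1": "COI", "COXI": "COI",
    "COII": "COII", "COX2": "COII", "CO2": "COII", "COXII": "COII",
    "COIII": "COIII", "COX3": "COIII", "CO3": "COIII", "COXIII": "COIII",
    "ATP6": "ATP6", "ATPASE6": "ATP6", "ATPASE 6": "ATP6",
    "ATP8": "ATP8", "ATPASE8": "ATP8", "ATPASE 8": "ATP8",
    "CYTB": "CYTB", "COB": "CYTB", "CYB": "CYTB",
    "RRNL": "rrnL", "16S": "rrnL", "L-RRNA": "rrnL", "RRN16": "rrnL",
    "RRNS": "rrnS", "12S": "rrnS", "S-RRNA": "rrnS", "RRN12": "rrnS",
}

_PRODUCT_PATTERNS = (
    (re.compile(r"NADH DEHYDROGENASE SUBUNIT 4L"), "ND4L"),
    (re.compile(r"NADH DEHYDROGENASE SUBUNIT (\d)"), "ND{}"),
    (re.compile(r"CYTOCHROME C OXIDASE SUBUNIT I{3}|"
                r"CYTOCHROME C OXIDASE SUBUNIT 3"), "COIII"),
    (re.compile(r"CYTOCHROME C OXIDASE SUBUNIT I{2}(?!I)|"
                r"CYTOCHROME C OXIDASE SUBUNIT 2"), "COII"),
    (re.compile(r"CYTOCHROME C OXIDASE SUBUNIT I(?!I)|"
                r"CYTOCHROME C OXIDASE SUBUNIT 1"), "COI"),
    (re.compile(r"CYTOCHROME B"), "CYTB"),
    (re.compile(r"ATP SYNTHASE.*6"), "ATP6"),
    (re.compile(r"ATP SYNTHASE.*8"), "ATP8"),
    (re.compile(r"16S|LARGE SUBUNIT RIBOSOMAL RNA"), "rrnL"),
    (re.compile(r"12S|SMALL SUBUNIT RIBOSOMAL RNA"), "rrnS"),
)

_SER_LEU = {
    ("S", "AGN"): "trnS1", ("S", "GCT"): "trnS1", ("S", "UCN"): "trnS2",
    ("S", "TGA"): "trnS2", ("S", "UGA"): "trnS2",
    ("L", "CUN"): "trnL1", ("L", "TAG"): "trnL1", ("L", "UAG"): "trnL1",
    ("L", "UUR"): "trnL2", ("L", "TAA"): "trnL2", ("L", "UAA"): "trnL2",
}


@dataclass
class GenBankOrderReport:
    """Result of reading one GenBank record."""

    order: GeneOrder
    sequence: str
    features: tuple[tuple[str, int, int, int], ...]  # (symbol, start, end, strand)
    warnings: tuple[str, ...] = ()


def _map_trna(names: Iterable[str], codon: str | None) -> str | None:
    for raw in names:
        up = raw.upper().strip()
        m = re.match(r"^TRN([A-Z])(\d)?$", up.replace("-", ""))
        if m:
            letter, idx = m.group(1), m.group(2)
            return _resolve_trna(letter, idx, codon)
        m = re.match(r"^TRNA[- ]([A-Z]{3})\s*(?:\(([A-Z]{3})\))?$", up)
        if m:
            aa3, anticodon = m.group(1), m.group(2)
            if aa3 == "SER":
                return _resolve_trna("S", None, anticodon or codon)
            if aa3 == "LEU":
                return _resolve_trna("L", None, anticodon or codon)
            if aa3 in _AA3:
                return "trn" + _AA3[aa3]
    return None


def _resolve_trna(letter: str, idx: str | None, codon: str | None) -> str | None:
    if letter in ("S", "L"):
        if idx in ("1", "2"):
            return f"trn{letter}{idx}"
        if codon:
            return _SER_LEU.get((letter, codon.upper()))
        return None
    return "trn" + letter if letter in set(_AA3.values()) else None


def _map_feature(feature) -> str | None:
    quals = feature.qualifiers
    names = [*quals.get("gene", []), *quals.get("product", []),
             *quals.get("note", [])]
    codon = None
    for key in ("codon_recognized", "anticodon"):
        if quals.get(key):
            codon = str(quals[key][0]).strip("() ").split(":")[-1]
    if feature.type in ("D-loop",):
        return "CR"
    joined = " ".join(names).upper()
    if feature.type == "misc_feature" and (
            "CONTROL REGION" in joined or "D-LOOP" in joined
            or "A+T-RICH" in joined or "AT-RICH" in joined):
        return "CR"
    if feature.type in ("tRNA",) or any(n.upper().startswith(("TRN", "TRNA"))
                                        for n in names):
        mapped = _map_trna(names, codon)
        if mapped:
            return mapped
    for raw in names:
        key = raw.upper().strip().replace("-", "")
        if key in _PCG_ALIASES:
            return _PCG_ALIASES[key]
    for pattern, template in _PRODUCT_PATTERNS:
        m = pattern.search(joined)
        if m:
            return template.format(*m.groups()) if "{}" in template else template
    return None


def order_from_genbank(source: str | Path | IO[str],
                       taxon: str | None = None) -> GenBankOrderReport:
    """Read gene order and sequence from a GenBank flat file.

    Raises :class:`~mitorearr.gene_order.GeneOrderError` when the record has
    no recognizable gene/tRNA/rRNA/CDS features.
    """
    record = SeqIO.read(source, "genbank")
    wanted = ("gene", "CDS", "tRNA", "rRNA", "D-loop", "misc_feature")
    entries: list[tuple[int, int, int, str | None, str]] = []
    warnings: list[str] = []
    for feature in record.features:
        if feature.type not in wanted:
            continue
        start = int(feature.location.start)
        end = int(feature.location.end)
        strand = -1 if feature.location.strand == -1 else 1
        symbol = _map_feature(feature)
        if symbol is None:
            if feature.type == "misc_feature":
                continue
            label = (feature.qualifiers.get("product")
                     or feature.qualifiers.get("gene") or ["?"])[0]
            warnings.append(
                f"unmappable {feature.type} {label!r} at "
                f"{start + 1}..{end}: recorded as NCR")
            symbol = "NCR"
        entries.append((start, end, strand, symbol, feature.type))
    if not any(sym not in ("NCR",) for *_, sym, _t in entries):
        raise GeneOrderError("no recognizable features in GenBank record")

    # collapse overlapping duplicate annotations of the same locus
    entries.sort(key=lambda e: (e[0], e[1]))
    collapsed: list[tuple[int, int, int, str]] = []
    for start, end, strand, symbol, _type in entries:
        if collapsed:
            pstart, pend, pstrand, psym = collapsed[-1]
            if psym == symbol and pstrand == strand and start < pend:
                collapsed[-1] = (pstart, max(pend, end), strand, symbol)
                continue
        collapsed.append((start, end, strand, symbol))

    tokens = tuple(
        GeneToken(sym, MAJORITY if (strand == 1 or sym in ("CR", "NCR"))
                  else MINORITY)
        for start, end, strand, sym in collapsed)
    order = GeneOrder(tokens, taxon=taxon or record.id or "")
    return GenBankOrderReport(
        order=order,
        sequence=str(record.seq),
        features=tuple((sym, s, e, st) for s, e, st, sym in collapsed),
        warnings=tuple(warnings),
    )
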