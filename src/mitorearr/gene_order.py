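"""Circular, stranded mitochondrial gene orders and their text grammar.

The insect mitogenome is a circular molecule carrying 13 protein-coding
genes, 2 rRNAs, 22 tRNAs and a large non-coding control region (CR).  A
gene order is the cyclic sequence of these loci together with the strand
each sits on.  This module defines the controlled gene vocabulary, the
token/order data model, a loss-free text grammar for orders, and circular
canonicalization so that rotations of the same molecule compare equal.

Grammar
-------
Tokens are separated by ``-``.  A leading ``~`` marks a gene on the
minority (complement) strand.  ``[X]`` records that gene X is known to be
absent from the genome (it joins the absence set, not the positional
sequence).  ``//`` marks an unsequenced gap.  Example::

    CR-trnI-trnW-~trnQ-trnM-ND2-~trnC-~trnY-COI

CR, NCR and GAP tokens carry no strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "PCGS",
    "RRNAS",
    "TRNAS",
    "CODING_GENES",
    "VOCABULARY",
    "STRANDLESS",
    "MAJORITY",
    "MINORITY",
    "ANCESTRAL_ORDER_TEXT",
    "ANCESTRAL_STRAND",
    "GeneOrderError",
    "GeneOrderParseError",
    "GeneToken",
    "GeneOrder",
    "parse_gene_order",
    "format_gene_order",
    "canonicalize",
    "ancestral_order",
]

# ---------------------------------------------------------------------------
# Vocabulary

PCGS = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB",
)
RRNAS = ("rrnL", "rrnS")
TRNAS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
CODING_GENES = frozenset(PCGS) | frozenset(RRNAS) | frozenset(TRNAS)

#: Non-gene tokens: the control region, unassigned non-coding regions and
#: unsequenced gaps.  They carry no strand.
STRANDLESS = frozenset({"CR", "NCR", "GAP"})

VOCABULARY = CODING_GENES | STRANDLESS

MAJORITY = "+"
MINORITY = "-"

#: Ambiguous legacy names that must be disambiguated (serine and leucine
#: tRNAs each occur twice in the genome).
_AMBIGUOUS = ("trnS", "trnL")

# ---------------------------------------------------------------------------
# The ancestral (pancrustacean) gene order — the ground pattern against
# which heteropteran rearrangements are scored.  Minority-strand genes are
# marked ``~``; the 23 remaining genes sit on the majority strand.

ANCESTRAL_ORDER_TEXT = (
    "CR-trnI-~trnQ-trnM-ND2-trnW-~trnC-~trnY-COI-trnL2-COII-trnK-trnD-"
    "ATP8-ATP6-COIII-trnG-ND3-trnA-trnR-trnN-trnS1-trnE-~trnF-~ND5-~trnH-"
    "~ND4-~ND4L-trnT-~trnP-ND6-CYTB-trnS2-~ND1-~trnL1-~rrnL-~trnV-~rrnS"
)


class GeneOrderError(ValueError):
    """Inconsistent gene-order content (duplicate absence, bad strand...)."""


class GeneOrderParseError(GeneOrderError):
    """Malformed gene-order text; carries the offending token and position."""

    def __init__(self, message: str, token: str | None = None,
                 position: int | None = None):
        super().__init__(message)
        self.token = token
        self.position = position


def _check_symbol(name: str, position: int | None = None,
                  aliases: Mapping[str, str] | None = None) -> str:
    if aliases and name in aliases:
        name = aliases[name]
    if name in _AMBIGUOUS:
        raise GeneOrderParseError(
            f"ambiguous gene name {name!r}: use {name}1/{name}2 or supply "
            f"an alias table", token=name, position=position)
    if name not in VOCABULARY:
        raise GeneOrderParseError(
            f"unknown gene token {name!r}"
            + (f" at position {position}" if position is not None else ""),
            token=name, position=position)
    return name


@dataclass(frozen=True)
class GeneToken:
    """One locus in a gene order: a vocabulary symbol plus its strand."""

    symbol: str
    strand: str = MAJORITY

    def __post_init__(self):
        _check_symbol(self.symbol)
        if self.symbol in STRANDLESS:
            if self.strand != MAJORITY:
                raise GeneOrderError(
                    f"{self.symbol} carries no strand annotation")
        elif self.strand not in (MAJORITY, MINORITY):
            raise GeneOrderError(f"bad strand {self.strand!r}")

    @property
    def is_gap(self) -> bool:
        return self.symbol == "GAP"

    def format(self) -> str:
        if self.is_gap:
            return "//"
        return ("~" if self.strand == MINORITY else "") + self.symbol

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


@dataclass(frozen=True)
class GeneOrder:
    """A circular, stranded, possibly incomplete gene order for one taxon.

    ``tokens`` is read circularly on the majority strand; ``absent`` holds
    genes known to be missing from the genome (they never appear in
    ``tokens``).  An order containing a GAP token is incomplete.
    """

    tokens: tuple[GeneToken, ...]
    absent: frozenset[str] = frozenset()
    taxon: str = ""

    def __post_init__(self):
        if not self.tokens:
            raise GeneOrderError("a gene order needs at least one token")
        present = {t.symbol for t in self.tokens}
        clash = present & set(self.absent)
        if clash:
            raise GeneOrderError(
                f"genes recorded absent but present in sequence: "
                f"{sorted(clash)}")
        for sym in self.absent:
            _check_symbol(sym)
            if sym in STRANDLESS:
                raise GeneOrderError(f"{sym} cannot be in the absence set")

    # -- basic queries ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[GeneToken]:
        return iter(self.tokens)

    @property
    def complete(self) -> bool:
        """False when any stretch of the molecule is unsequenced."""
        return not any(t.is_gap for t in self.tokens)

    def symbols(self) -> tuple[str, ...]:
        return tuple(t.symbol for t in self.tokens)

    def multiplicity(self, symbol: str) -> int:
        return sum(1 for t in self.tokens if t.symbol == symbol)

    def strand_of(self, symbol: str) -> str:
        for t in self.tokens:
            if t.symbol == symbol:
                return t.strand
        raise KeyError(symbol)

    def known_genes(self) -> frozenset[str]:
        """Genes whose status is known: present in tokens or recorded absent."""
        return frozenset(
            t.symbol for t in self.tokens if t.symbol in CODING_GENES
        ) | self.absent

    def rotated(self, start: int) -> "GeneOrder":
        n = len(self.tokens)
        start %= n
        return GeneOrder(self.tokens[start:] + self.tokens[:start],
                         self.absent, self.taxon)

    def with_taxon(self, taxon: str) -> "GeneOrder":
        return GeneOrder(self.tokens, self.absent, taxon)

    # -- identity -----------------------------------------------------------

    def canonical_key(self) -> tuple:
        """Rotation-invariant identity: canonical tokens plus absence set."""
        canon = canonicalize(self)
        return (tuple((t.symbol, t.strand) for t in canon.tokens),
                tuple(sorted(self.absent)))

    def equivalent(self, other: "GeneOrder") -> bool:
        """Rotation-invariant equality of token sequence and absences."""
        return self.canonical_key() == other.canonical_key()


# ---------------------------------------------------------------------------
# Grammar


def parse_gene_order(text: str, taxon: str = "",
                     aliases: Mapping[str, str] | None = None) -> GeneOrder:
    """Parse gene-order text into a :class:`GeneOrder`.

    Raises :class:`GeneOrderParseError` for unknown tokens (naming the token
    and its position) and :class:`GeneOrderError` when a gene is recorded
    both absent and present.
    """
    if not text or not text.strip():
        raise GeneOrderParseError("empty gene-order string")
    tokens: list[GeneToken] = []
    absent: set[str] = set()
    for pos, raw in enumerate(text.strip().split("-")):
        piece = raw.strip()
        if not piece:
            raise GeneOrderParseError("empty token", token=raw, position=pos)
        if piece == "//":
            tokens.append(GeneToken("GAP"))
            continue
        if piece.startswith("[") and piece.endswith("]"):
            name = _check_symbol(piece[1:-1], pos, aliases)
            if name in absent:
                raise GeneOrderError(f"gene {name} recorded absent twice")
            absent.add(name)
            continue
        strand = MAJORITY
        if piece.startswith("~"):
            strand = MINORITY
            piece = piece[1:]
        name = _check_symbol(piece, pos, aliases)
        if name in STRANDLESS and strand == MINORITY:
            raise GeneOrderParseError(
                f"{name} carries no strand annotation", token=raw,
                position=pos)
        tokens.append(GeneToken(name, strand))
    return GeneOrder(tuple(tokens), frozenset(absent), taxon)


def format_gene_order(order: GeneOrder) -> str:
    """Render an order in the grammar; absences trail as ``[X]`` sorted."""
    parts = [t.format() for t in order.tokens]
    parts.extend(f"[{sym}]" for sym in sorted(order.absent))
    return "-".join(parts)


# ---------------------------------------------------------------------------
# Canonicalization


def canonicalize(order: GeneOrder) -> GeneOrder:
    """Rotate to a deterministic anchor so circular equality is testable.

    Anchor: the CR token when present exactly once, otherwise the
    lexicographically smallest rotation of the formatted token sequence.
    Strands are untouched; the function is idempotent.
    """
    syms = order.symbols()
    n = len(syms)
    if n == 1:
        return order
    if syms.count("CR") == 1:
        return order.rotated(syms.index("CR"))
    strings = [t.format() for t in order.tokens]
    best = min(range(n), key=lambda i: strings[i:] + strings[:i])
    return order.rotated(best)


def ancestral_order() -> GeneOrder:
    """The insect ancestral (ground-pattern) gene order, canonical form."""
    return parse_gene_order(ANCESTRAL_ORDER_TEXT, taxon="ancestral")


#: Strand each gene occupies in the ancestral order.  Heteropteran
#: rearrangements involve no inversion, so observed strands match this map.
ANCESTRAL_STRAND: dict[str, str] = {
    t.symbol: t.strand for t in parse_gene_order(ANCESTRAL_ORDER_TEXT).tokens
}
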