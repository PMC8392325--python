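"""Rearrangement typing and block/unit signature extraction.

Observed gene orders are scored against the ancestral ground pattern.
Rearrangements are classified into the event types seen in true bugs —
gene translocation, gene duplication, gene loss (inversion is detected but
does not occur in Heteroptera) — and localized to three gene blocks and
six rearrangement units, contiguous gene sets of the ancestral order:

======  ======  =============================================
block   unit    members
======  ======  =============================================
A       1       trnI trnQ trnM
A       2       trnW trnC trnY
B       3       trnA trnR trnN trnS1 trnE trnF
C       4       trnT trnP
C       5       ND6 CYTB trnS2 ND1
C       6       rrnL trnV rrnS
======  ======  =============================================

A *unit signature* is the exact token run occupying the unit's region in
an observed order: the minimal cyclic window covering every copy of every
unit member that is present, plus the unit members recorded absent.  Two
signatures identical in token sequence, strand, multiplicity and absences
are the same arrangement.  The minimal-window rule keeps a unit whose
internal order is untouched un-rearranged even when the genes around it
have moved — which is how internally-intact units inside heavily shuffled
blocks are scored in the survey this package reproduces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .gene_order import (
    ANCESTRAL_STRAND,
    CODING_GENES,
    MINORITY,
    STRANDLESS,
    TRNAS,
    GeneOrder,
    GeneOrderError,
    canonicalize,
)

__all__ = [
    "BlockDefinition",
    "UnitDefinition",
    "DEFAULT_BLOCKS",
    "DEFAULT_UNITS",
    "UnitSignature",
    "RearrangementCall",
    "unit_signature",
    "region_signature",
    "ancestral_signature",
    "is_unit_rearranged",
    "signatures_equivalent",
    "group_signatures",
    "classify_events",
    "order_is_rearranged",
    "orders_equivalent",
    "units_from_yaml",
]


@dataclass(frozen=True)
class BlockDefinition:
    """A contiguous rearrangement-prone gene block of the ancestral order."""

    name: str
    members: tuple[str, ...]
    bounds: tuple[str, str]  # flanking conserved loci


@dataclass(frozen=True)
class UnitDefinition:
    """A named rearrangement unit: a contiguous gene set within one block."""

    name: str
    members: tuple[str, ...]
    parent_block: str


DEFAULT_BLOCKS: tuple[BlockDefinition, ...] = (
    BlockDefinition("A", ("trnI", "trnQ", "trnM", "ND2", "trnW", "trnC",
                          "trnY"), ("CR", "COI")),
    BlockDefinition("B", ("trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"),
                    ("ND3", "ND5")),
    BlockDefinition("C", ("trnH", "ND4", "ND4L", "trnT", "trnP", "ND6",
                          "CYTB", "trnS2", "ND1", "trnL1", "rrnL", "trnV",
                          "rrnS"), ("ND5", "CR")),
)

DEFAULT_UNITS: tuple[UnitDefinition, ...] = (
    UnitDefinition("1", ("trnI", "trnQ", "trnM"), "A"),
    UnitDefinition("2", ("trnW", "trnC", "trnY"), "A"),
    UnitDefinition("3", ("trnA", "trnR", "trnN", "trnS1", "trnE", "trnF"),
                   "B"),
    UnitDefinition("4", ("trnT", "trnP"), "C"),
    UnitDefinition("5", ("ND6", "CYTB", "trnS2", "ND1"), "C"),
    UnitDefinition("6", ("rrnL", "trnV", "rrnS"), "C"),
)


def units_from_yaml(path) -> tuple[tuple[UnitDefinition, ...],
                                   tuple[BlockDefinition, ...]]:
    """Load user unit/block definitions from a small YAML config.

    Schema::

        blocks:
          - {name: A, members: [trnI, ...], bounds: [CR, COI]}
        units:
          - {name: "1", members: [trnI, trnQ, trnM], parent_block: A}
    """
    import yaml

    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    blocks = tuple(
        BlockDefinition(str(b["name"]), tuple(b["members"]),
                        tuple(b.get("bounds", ("CR", "CR"))))
        for b in doc.get("blocks", []))
    if not blocks:
        blocks = DEFAULT_BLOCKS
    units = tuple(
        UnitDefinition(str(u["name"]), tuple(u["members"]),
                       str(u.get("parent_block", "")))
        for u in doc.get("units", []))
    if not units:
        units = DEFAULT_UNITS
    return units, blocks


# ---------------------------------------------------------------------------
# Signatures


@dataclass(frozen=True)
class UnitSignature:
    """The observed arrangement occupying one unit's (or block's) region.

    ``tokens`` is the minimal cyclic window covering all present copies of
    the members; ``absences`` the members recorded absent; ``known_members``
    the members whose status (present/absent) is known; ``order_known`` the
    full set of genes the source order knows about, used when comparing
    signatures from incomplete genomes.  An ``unknown`` signature (region
    unsequenced) compares equal to nothing.
    """

    unit: str
    members: tuple[str, ...]
    tokens: tuple[tuple[str, str], ...]
    absences: frozenset[str]
    known_members: frozenset[str]
    order_known: frozenset[str]
    unknown: bool = False

    def key(self) -> tuple:
        return (self.unit, self.tokens, tuple(sorted(self.absences)))

    def matches(self, other: "UnitSignature") -> bool:
        if self.unknown or other.unknown:
            return False
        return self.key() == other.key()


def _covering_window(order: GeneOrder, members: set[str]) -> tuple[int, int] | None:
    """(start, length) of the minimal cyclic token window covering every
    copy of every present member; None when no member is present."""
    syms = order.symbols()
    n = len(syms)
    positions = [i for i, s in enumerate(syms) if s in members]
    if not positions:
        return None
    if len(positions) == 1:
        return positions[0], 1
    # the window is the complement of the largest member-free cyclic gap
    best_gap, best_j = -1, 0
    k = len(positions)
    for j in range(k):
        nxt = positions[(j + 1) % k]
        gap = (nxt - positions[j] - 1) % n
        if gap > best_gap:
            best_gap, best_j = gap, j
    start = positions[(best_j + 1) % k]
    length = (positions[best_j] - start) % n + 1
    return start, length


def region_signature(order: GeneOrder, name: str, members: Sequence[str],
                     ancestral: GeneOrder) -> UnitSignature:
    """Signature of an arbitrary contiguous member set (unit or block)."""
    member_set = set(members)
    bad = member_set - CODING_GENES
    if bad:
        raise GeneOrderError(f"unit {name}: non-gene members {sorted(bad)}")
    order = canonicalize(order)
    present = {t.symbol for t in order.tokens} & member_set
    absences = frozenset(order.absent & member_set)
    # a member unrecorded in a complete order is effectively absent
    if order.complete:
        absences |= member_set - present - absences
    known = frozenset(present) | absences
    order_known = order.known_genes() | (
        {"CR"} if "CR" in order.symbols() else set())
    if not present:
        if absences == member_set:
            return UnitSignature(name, tuple(members), (), absences, known,
                                 order_known)
        return UnitSignature(name, tuple(members), (), absences, known,
                             order_known, unknown=True)
    window = _covering_window(order, present)
    start, length = window
    run = tuple(order.tokens[(start + i) % len(order.tokens)]
                for i in range(length))
    if any(t.is_gap for t in run):
        return UnitSignature(name, tuple(members), (), absences, known,
                             order_known, unknown=True)
    return UnitSignature(name, tuple(members),
                         tuple((t.symbol, t.strand) for t in run),
                         absences, known, order_known)


def unit_signature(order: GeneOrder, unit: UnitDefinition,
                   ancestral: GeneOrder) -> UnitSignature:
    """Observed signature of one rearrangement unit."""
    return region_signature(order, unit.name, unit.members, ancestral)


def ancestral_signature(unit: UnitDefinition | BlockDefinition,
                        ancestral: GeneOrder,
                        restrict_to: Iterable[str] | None = None) -> UnitSignature:
    """The ground-pattern signature of a unit, optionally restricted to the
    member subset an incomplete order actually knows about."""
    members = (tuple(m for m in unit.members if m in set(restrict_to))
               if restrict_to is not None else unit.members)
    return region_signature(ancestral, unit.name, members, ancestral)


def is_unit_rearranged(signature: UnitSignature,
                       ancestral: GeneOrder) -> bool:
    """True iff the signature differs from the ancestral arrangement of the
    same (known) members.  Unknown signatures conservatively return False."""
    if signature.unknown:
        return False
    if signature.absences:
        return True
    present = [m for m in signature.members
               if m in signature.known_members and m not in signature.absences]
    ref = region_signature(ancestral, signature.unit, present, ancestral)
    return signature.tokens != ref.tokens


def signatures_equivalent(a: UnitSignature, b: UnitSignature) -> bool:
    """Identity of two arrangements, tolerant of unsequenced regions.

    Genes whose status is unknown to the other order are dropped from each
    token run before comparing; absences must agree on the mutually known
    members.  Exact equality for two complete genomes.
    """
    if a.unknown or b.unknown or a.unit != b.unit:
        return False
    common = a.known_members & b.known_members
    if (a.absences & common) != (b.absences & common):
        return False

    def restrict(sig: UnitSignature, other: UnitSignature):
        keep = []
        for sym, strand in sig.tokens:
            if sym in CODING_GENES and sym not in other.order_known:
                continue
            if sym == "NCR":
                continue
            keep.append((sym, strand))
        return tuple(keep)

    return restrict(a, b) == restrict(b, a)


def group_signatures(signatures: Sequence[UnitSignature]) -> list[list[int]]:
    """Group signature indices into identity classes.

    Greedy, seeded from the most completely known signature so a partial
    arrangement joins the complete arrangement it agrees with.
    """
    idx = sorted(range(len(signatures)),
                 key=lambda i: (-len(signatures[i].order_known), i))
    groups: list[list[int]] = []
    reps: list[UnitSignature] = []
    for i in idx:
        sig = signatures[i]
        if sig.unknown:
            continue
        for g, rep in enumerate(reps):
            if signatures_equivalent(sig, rep):
                groups[g].append(i)
                break
        else:
            groups.append([i])
            reps.append(sig)
    return groups


# ---------------------------------------------------------------------------
# Whole-order comparison


def _reduced_cycle(order: GeneOrder, keep: set[str]) -> tuple[tuple[str, str], ...]:
    return tuple((t.symbol, t.strand) for t in canonicalize(order).tokens
                 if t.symbol in keep)


def _rotation_equal(a: Sequence, b: Sequence) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    a2, b2 = list(a) + list(a), list(b)
    for i in range(len(a)):
        if a2[i:i + len(b2)] == b2:
            return True
    return False


def orders_equivalent(a: GeneOrder, b: GeneOrder) -> bool:
    """Whole-genome arrangement identity, comparing mutually known genes.

    Two orders are the same arrangement iff their absence sets agree on
    mutually known genes and the cyclic sequences restricted to mutually
    known genes (plus CR when both carry it) coincide, strands included.
    """
    known_a, known_b = a.known_genes(), b.known_genes()
    common = known_a & known_b
    if (a.absent & common) != (b.absent & common):
        return False
    keep = set(common)
    if "CR" in a.symbols() and "CR" in b.symbols():
        keep.add("CR")
    return _rotation_equal(_reduced_cycle(a, keep), _reduced_cycle(b, keep))


def order_is_rearranged(order: GeneOrder, ancestral: GeneOrder) -> bool:
    """True iff the order's known content departs from the ground pattern."""
    if order.absent:
        return True
    syms = [s for s in order.symbols() if s in CODING_GENES]
    if len(syms) != len(set(syms)):
        return True
    return not orders_equivalent(order, ancestral)


# ---------------------------------------------------------------------------
# Event classification


@dataclass(frozen=True)
class RearrangementCall:
    """Typed rearrangement events of one order vs the ground pattern.

    ``unresolved_genes`` holds genes recorded missing from an incomplete
    genome: they may sit in the unsequenced region or be genuinely lost, so
    they are reported separately rather than forced into the loss list.
    """

    taxon: str
    event_types: frozenset[str]
    moved_genes: tuple[str, ...]
    duplicated_genes: tuple[str, ...]
    lost_genes: tuple[str, ...]
    inverted_genes: tuple[str, ...]
    unresolved_genes: tuple[str, ...]
    affected_units: frozenset[str]
    rearranged: bool


def _arcs(order: GeneOrder, keep: set[str]) -> list[list[tuple[str, str]]]:
    """Maximal GAP-free runs of kept tokens, in circular sequence."""
    toks = canonicalize(order).tokens
    n = len(toks)
    if order.complete:
        return [[(t.symbol, t.strand) for t in toks if t.symbol in keep]]
    # rotate so index 0 is a GAP, then split
    start = next(i for i, t in enumerate(toks) if t.is_gap)
    arcs: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for i in range(n):
        t = toks[(start + i) % n]
        if t.is_gap:
            if current:
                arcs.append(current)
                current = []
        elif t.symbol in keep:
            current.append((t.symbol, t.strand))
    if current:
        arcs.append(current)
    return arcs


def _agrees(order: GeneOrder, ancestral: GeneOrder, keep: set[str]) -> bool:
    """Do the order's known arcs, restricted to ``keep``, embed in the
    ancestral cycle in consistent circular sequence?"""
    anc = _reduced_cycle(ancestral, keep)
    arcs = [a for a in _arcs(order, keep) if a]
    if order.complete:
        return _rotation_equal(arcs[0] if arcs else [], anc)
    if not anc:
        return all(not a for a in arcs)
    n = len(anc)
    pos = {sym: i for i, (sym, _) in enumerate(anc)}  # keep-genes are unique
    spans = []
    for arc in arcs:
        first = arc[0]
        if first not in set(anc):
            return False
        i = pos[first[0]]
        for j, tok in enumerate(arc):
            if anc[(i + j) % n] != tok:
                return False
        spans.append((i, len(arc)))
    # arcs must occupy disjoint ancestral spans, in the same circular order
    covered: set[int] = set()
    for i, ln in spans:
        span = {(i + j) % n for j in range(ln)}
        if span & covered:
            return False
        covered |= span
    starts = [s for s, _ in spans]
    rel = [(s - starts[0]) % n for s in starts]
    return rel == sorted(rel)


def _minimal_moved(order: GeneOrder, ancestral: GeneOrder,
                   universe: set[str], max_moved: int = 8) -> tuple[str, ...]:
    """Smallest gene set whose removal reconciles the observed and ancestral
    cyclic orders over ``universe``; ties prefer tRNA-rich, then
    lexicographically first sets."""
    if _agrees(order, ancestral, universe):
        return ()
    # candidate pool: genes flanking a broken adjacency
    anc = _reduced_cycle(ancestral, universe)
    anc_adj = {(anc[i][0], anc[(i + 1) % len(anc)][0])
               for i in range(len(anc))}
    pool: set[str] = set()
    for arc in _arcs(order, universe):
        m = len(arc)
        pairs = zip(range(m), range(1, m + (1 if order.complete else 0)))
        for i, j in pairs:
            a_sym, b_sym = arc[i][0], arc[j % m][0]
            if (a_sym, b_sym) not in anc_adj:
                pool.update((a_sym, b_sym))
    pool_sorted = sorted(pool)
    for k in range(1, min(max_moved, len(pool_sorted)) + 1):
        winners = [combo for combo in itertools.combinations(pool_sorted, k)
                   if _agrees(order, ancestral, universe - set(combo))]
        if winners:
            return min(winners,
                       key=lambda c: (-sum(g in TRNAS for g in c), c))
    raise GeneOrderError(
        f"{order.taxon or 'order'}: no translocation explanation with "
        f"<= {max_moved} moved genes")


def classify_events(order: GeneOrder, ancestral: GeneOrder,
                    units: Sequence[UnitDefinition] = DEFAULT_UNITS,
                    max_moved: int = 8) -> RearrangementCall:
    """Classify the rearrangement events of ``order`` vs the ground pattern.

    Loss is only called for complete genomes; a recorded absence in a gapped
    genome is reported as unresolved (absent-or-in-gap).  Translocation is
    detected breakpoint-style on the cyclic order of shared single-copy
    same-strand genes, so it is invariant under rotation and robust to
    duplications and losses; a duplicated gene additionally counts as
    translocated unless its copies form one tandem run sitting at the
    ancestral position.
    """
    order = canonicalize(order)
    anc_genes = {t.symbol for t in ancestral.tokens if t.symbol in CODING_GENES}
    present = {t.symbol for t in order.tokens if t.symbol in CODING_GENES}
    shared = present & anc_genes
    if not shared:
        raise GeneOrderError("no comparison basis: no shared genes with the "
                             "ancestral order")

    if order.complete:
        lost = tuple(sorted(order.absent & anc_genes))
        unresolved: tuple[str, ...] = ()
    else:
        lost = ()
        unresolved = tuple(sorted(order.absent & anc_genes))

    counts: dict[str, int] = {}
    for sym in order.symbols():
        if sym in CODING_GENES:
            counts[sym] = counts.get(sym, 0) + 1
    duplicated = tuple(sorted(s for s, c in counts.items() if c > 1))

    inverted = tuple(sorted(
        sym for sym in shared
        if any(t.symbol == sym and t.strand != ANCESTRAL_STRAND[sym]
               for t in order.tokens)))

    # translocation, part 1: shared single-copy same-strand genes (+ CR)
    universe = {s for s in shared
                if counts[s] == 1 and s not in inverted}
    if order.symbols().count("CR") == 1 and \
            ancestral.symbols().count("CR") == 1:
        universe.add("CR")
    moved = set(_minimal_moved(order, ancestral, universe, max_moved))

    # part 2: duplicated genes displaced from the ancestral position
    syms = order.symbols()
    n = len(syms)
    anc_syms = ancestral.symbols()
    for g in duplicated:
        if g not in anc_genes:
            moved.add(g)
            continue
        pos = [i for i, s in enumerate(syms) if s == g]
        pset = set(pos)
        runs = sum(1 for i in pos if (i - 1) % n not in pset)
        if runs != 1:
            moved.add(g)
            continue
        start = next(i for i in pos if (i - 1) % n not in pset)
        left = syms[(start - 1) % n]
        right = syms[(start + len(pos)) % n]
        ai = anc_syms.index(g)
        anc_left = anc_syms[(ai - 1) % len(anc_syms)]
        anc_right = anc_syms[(ai + 1) % len(anc_syms)]
        if not ((left == anc_left or left == "GAP")
                and (right == anc_right or right == "GAP")):
            moved.add(g)

    moved_t = tuple(sorted(moved))
    affected = frozenset(
        u.name for u in units
        if is_unit_rearranged(unit_signature(order, u, ancestral), ancestral))

    types = set()
    if moved_t:
        types.add("translocation")
    if duplicated:
        types.add("duplication")
    if lost:
        types.add("loss")
    if inverted:
        types.add("inversion")

    return RearrangementCall(
        taxon=order.taxon,
        event_types=frozenset(types),
        moved_genes=moved_t,
        duplicated_genes=duplicated,
        lost_genes=lost,
        inverted_genes=inverted,
        unresolved_genes=unresolved,
        affected_units=affected,
        rearranged=bool(types),
    )
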