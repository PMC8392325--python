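"""Tandem duplication / random loss (TDRL) modelling and scenario search.

Under the TDRL model a contiguous segment of the circular genome is
duplicated in tandem and the redundant gene copies are subsequently deleted
or pseudogenized; the surviving copies are left in a new order.  TDRL moves
genes without ever flipping a strand, which is why it explains lineages
whose rearrangements show no inversion.

A :class:`TDRLStep` records the duplicated segment (a cyclic index interval
of the source order) and, per duplicated position, which copy is lost
(``first`` | ``second``; the extensions ``none`` — keep both, producing a
gene duplication — and ``both`` — full loss, only valid with
``allow_full_loss`` — let the same engine express the duplication and loss
rearrangement types).  Scenario identity is the sequence of intermediate
orders, including the post-duplication intermediate, so duplications with
different boundaries that pass through different intermediates are distinct
mechanisms even when they yield the same final order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .gene_order import (
    CODING_GENES,
    GeneOrder,
    GeneOrderError,
    GeneToken,
    canonicalize,
)

__all__ = [
    "TDRLStep",
    "TDRLScenario",
    "RemnantPrediction",
    "apply_tdrl",
    "enumerate_single_tdrl",
    "search_scenarios",
    "predict_remnants",
]

_LOSS_CHOICES = ("first", "second", "none", "both")


@dataclass(frozen=True)
class TDRLStep:
    """One tandem duplication plus loss pattern.

    ``start``/``length`` index the duplicated segment on the token tuple of
    the order the step applies to (the interval may wrap).  ``losses[i]``
    says which copy of segment position ``i`` is deleted-or-pseudogenized.
    """

    start: int
    length: int
    losses: tuple[str, ...]

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if len(self.losses) != self.length:
            raise ValueError("one loss choice per duplicated position")
        bad = set(self.losses) - set(_LOSS_CHOICES)
        if bad:
            raise ValueError(f"bad loss choices {sorted(bad)}")


@dataclass(frozen=True)
class TDRLScenario:
    """An ordered list of TDRL steps from a source to a target order.

    ``duplicated`` holds the post-duplication (pre-loss) intermediate of
    each step and ``intermediates`` the order after each step; replaying
    ``steps`` from the source yields each intermediate and finally the
    target.
    """

    source: GeneOrder
    steps: tuple[TDRLStep, ...]
    duplicated: tuple[GeneOrder, ...]
    intermediates: tuple[GeneOrder, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def target(self) -> GeneOrder:
        return self.intermediates[-1] if self.intermediates else self.source

    def total_duplicated_length(self) -> int:
        return sum(s.length for s in self.steps)

    def identity_key(self) -> tuple:
        return tuple((d.canonical_key(), o.canonical_key())
                     for d, o in zip(self.duplicated, self.intermediates))

    def verify(self, allow_full_loss: bool = False) -> bool:
        """Replay the steps and confirm each recorded intermediate."""
        cur = canonicalize(self.source)
        for step, dup, out in zip(self.steps, self.duplicated,
                                  self.intermediates):
            d = _duplicate(cur, step)
            if not d.equivalent(dup):
                return False
            cur = apply_tdrl(cur, step, allow_full_loss=allow_full_loss)
            if not cur.equivalent(out):
                return False
        return True


@dataclass(frozen=True)
class RemnantPrediction:
    """Adjacencies of the final order where deleted-copy remnants are
    expected as intergenic / non-coding sequence."""

    sites: tuple[tuple[str, str], ...]


# ---------------------------------------------------------------------------
# Applying a step


def _segment(order: GeneOrder, step: TDRLStep) -> tuple[GeneToken, ...]:
    n = len(order.tokens)
    if not 1 <= step.length <= n - 1:
        raise GeneOrderError(
            f"segment length {step.length} invalid for a {n}-token order")
    seg = tuple(order.tokens[(step.start + i) % n] for i in range(step.length))
    if any(t.is_gap for t in seg):
        raise GeneOrderError("cannot duplicate across an unsequenced gap")
    return seg


def _duplicate(order: GeneOrder, step: TDRLStep) -> GeneOrder:
    """The post-duplication (pre-loss) intermediate order, canonical."""
    seg = _segment(order, step)
    n = len(order.tokens)
    rotated = tuple(order.tokens[(step.start + i) % n] for i in range(n))
    dup = seg + seg + rotated[step.length:]
    return canonicalize(GeneOrder(dup, order.absent, order.taxon))


def apply_tdrl(order: GeneOrder, step: TDRLStep,
               allow_full_loss: bool = False) -> GeneOrder:
    """Apply one TDRL step; deterministic, result canonicalized.

    ``step.start`` indexes the token tuple of ``order`` exactly as passed
    (steps returned by :func:`search_scenarios` index the canonical form of
    each predecessor order).  Raises when the loss pattern would remove
    every copy of a gene and ``allow_full_loss`` is off.
    """
    seg = _segment(order, step)
    n = len(order.tokens)
    first = tuple(seg[i] for i in range(step.length)
                  if step.losses[i] in ("second", "none"))
    second = tuple(seg[i] for i in range(step.length)
                   if step.losses[i] in ("first", "none"))
    rotated = tuple(order.tokens[(step.start + i) % n] for i in range(n))
    new_tokens = first + second + rotated[step.length:]

    survivors = [t.symbol for t in new_tokens]
    absent = set(order.absent)
    for g in {t.symbol for t in seg if t.symbol in CODING_GENES}:
        if g not in survivors:
            if not allow_full_loss:
                raise GeneOrderError(
                    f"gene extinction not permitted: loss pattern removes "
                    f"every copy of {g}")
            absent.add(g)
    if not new_tokens:
        raise GeneOrderError("loss pattern removes the whole genome")
    return canonicalize(GeneOrder(new_tokens, frozenset(absent), order.taxon))


# ---------------------------------------------------------------------------
# Enumeration and search
#
# The search inner loop runs on bare (symbol, strand) tuples instead of
# GeneOrder objects: a 38-gene genome with max_segment 8 means ~2e4 candidate
# steps per expanded state, and dataclass validation would dominate.


_Toks = tuple[tuple[str, str], ...]


def _as_toks(order: GeneOrder) -> _Toks:
    return tuple((t.symbol, t.strand) for t in order.tokens)


def _toks_order(toks: _Toks, absent: frozenset[str]) -> GeneOrder:
    return GeneOrder(tuple(GeneToken(s, st) for s, st in toks), absent)


def _canon_toks(toks: _Toks) -> _Toks:
    n = len(toks)
    if n == 1:
        return toks
    cr = [i for i, (s, _) in enumerate(toks) if s == "CR"]
    if len(cr) == 1:
        i = cr[0]
        return toks[i:] + toks[:i]
    best = min(range(n), key=lambda i: toks[i:] + toks[:i])
    return toks[best:] + toks[:best]


def _fast_apply(toks: _Toks, step: TDRLStep,
                allow_full_loss: bool) -> _Toks | None:
    """Apply a {first,second}-loss step to a gap-free token tuple; None when
    the pattern would extinguish a gene and full loss is off."""
    n = len(toks)
    rotated = toks[step.start:] + toks[:step.start]
    seg = rotated[:step.length]
    first = tuple(seg[i] for i in range(step.length)
                  if step.losses[i] in ("second", "none"))
    second = tuple(seg[i] for i in range(step.length)
                   if step.losses[i] in ("first", "none"))
    new = first + second + rotated[step.length:]
    if not allow_full_loss:
        survivors = {s for s, _ in new}
        for s, _ in seg:
            if s in CODING_GENES and s not in survivors:
                return None
    return new


def _dup_toks(toks: _Toks, step: TDRLStep) -> _Toks:
    rotated = toks[step.start:] + toks[:step.start]
    return rotated[:step.length] * 2 + rotated[step.length:]


def _steps(order: GeneOrder, max_segment: int,
           allow_full_loss: bool) -> Iterable[TDRLStep]:
    n = len(order.tokens)
    choices = ("first", "second") + (("both",) if allow_full_loss else ())
    gaps = [i for i, t in enumerate(order.tokens) if t.is_gap]
    for start in range(n):
        for length in range(1, min(max_segment, n - 1) + 1):
            if any((g - start) % n < length for g in gaps):
                continue
            for losses in itertools.product(choices, repeat=length):
                yield TDRLStep(start, length, losses)


def _extinct(toks: _Toks, new: _Toks) -> frozenset[str]:
    survivors = {s for s, _ in new}
    return frozenset(s for s, _ in toks
                     if s in CODING_GENES and s not in survivors)


def enumerate_single_tdrl(order: GeneOrder, max_segment: int,
                          allow_full_loss: bool = False) -> set[GeneOrder]:
    """Exact set of orders reachable by one valid TDRL step with segment
    length <= ``max_segment``, deduplicated by canonical equality."""
    if max_segment < 0:
        raise ValueError("max_segment must be >= 0")
    order = canonicalize(order.with_taxon(""))
    toks = _as_toks(order)
    out: dict[tuple, GeneOrder] = {}
    for step in _steps(order, max_segment, allow_full_loss):
        new = _fast_apply(toks, step, allow_full_loss)
        if new is None:
            continue
        absent = order.absent
        if allow_full_loss:
            absent = absent | _extinct(toks, new)
        canon = _canon_toks(new)
        key = (canon, tuple(sorted(absent)))
        if key not in out:
            out[key] = _toks_order(canon, absent)
    return set(out.values())


def search_scenarios(source: GeneOrder, target: GeneOrder,
                     max_steps: int = 2, max_segment: int = 8,
                     allow_full_loss: bool = False) -> list[TDRLScenario]:
    """All minimal-step TDRL scenarios from ``source`` to ``target``.

    Breadth-first over canonical orders; scenarios are deduplicated by their
    intermediate-order sequences (post-duplication and post-loss) and sorted
    by total duplicated length, then segment coordinates.  Empty list when
    the target is unreachable within the bounds; a 0-step (empty) scenario
    when source and target are already the same arrangement.
    """
    if max_steps < 1 or max_segment < 1:
        raise ValueError("max_steps and max_segment must be >= 1")
    source = canonicalize(source.with_taxon(""))
    target = canonicalize(target.with_taxon(""))
    if source.equivalent(target):
        return [TDRLScenario(source, (), (), ())]
    tgt = (_canon_toks(_as_toks(target)), tuple(sorted(target.absent)))

    # a path is (steps, duplicated token tuples, (toks, absent) per step)
    skey = (_canon_toks(_as_toks(source)), tuple(sorted(source.absent)))
    frontier: dict[tuple, list[tuple]] = {skey: [((), (), ())]}
    for depth in range(1, max_steps + 1):
        hits: dict[tuple, TDRLScenario] = {}
        next_frontier: dict[tuple, list[tuple]] = {}
        for (toks, absent_t), paths in frontier.items():
            absent = frozenset(absent_t)
            cur = _toks_order(toks, absent)
            seen_edges: set[tuple] = set()
            for step in _steps(cur, max_segment, allow_full_loss):
                new = _fast_apply(toks, step, allow_full_loss)
                if new is None:
                    continue
                new_absent = absent
                if allow_full_loss:
                    new_absent = absent | _extinct(toks, new)
                rkey = (_canon_toks(new), tuple(sorted(new_absent)))
                if rkey == tgt:
                    dup = _canon_toks(_dup_toks(toks, step))
                    edge = (dup, rkey)
                    if edge in seen_edges:
                        continue
                    seen_edges.add(edge)
                    for steps, dups, mids in paths:
                        scen = _build_scenario(
                            source, steps + (step,), dups + (dup,),
                            mids + (rkey,))
                        hits.setdefault(scen.identity_key(), scen)
                elif depth < max_steps:
                    dup = _canon_toks(_dup_toks(toks, step))
                    edge = (dup, rkey)
                    if edge in seen_edges:
                        continue
                    seen_edges.add(edge)
                    entry = next_frontier.setdefault(rkey, [])
                    for steps, dups, mids in paths:
                        entry.append((steps + (step,), dups + (dup,),
                                      mids + (rkey,)))
        if hits:
            return sorted(
                hits.values(),
                key=lambda s: (s.total_duplicated_length(),
                               tuple((st.start, st.length, st.losses)
                                     for st in s.steps)))
        frontier = next_frontier
        if not frontier:
            break
    return []


def _build_scenario(source: GeneOrder, steps: tuple, dups: tuple,
                    mids: tuple) -> TDRLScenario:
    # a duplicated intermediate precedes its step's losses, so it carries
    # the absence set of the state before the step
    prev_absent = source.absent
    dup_orders = []
    mid_orders = []
    for d, (t, a) in zip(dups, mids):
        dup_orders.append(_toks_order(d, prev_absent))
        mid_orders.append(_toks_order(t, frozenset(a)))
        prev_absent = frozenset(a)
    return TDRLScenario(source, steps, tuple(dup_orders), tuple(mid_orders))


# ---------------------------------------------------------------------------
# Remnant prediction


def predict_remnants(scenario: TDRLScenario,
                     allow_full_loss: bool = False) -> RemnantPrediction:
    """Predict where deleted-copy remnants sit in the final order.

    Each maximal run of deleted copies leaves residue between its surviving
    neighbours; a site is reported when that adjacency is still intact in
    the final order.  Raises when the scenario does not replay.
    """
    if not scenario.verify(allow_full_loss=allow_full_loss):
        raise GeneOrderError("scenario does not replay from its source")
    final = canonicalize(scenario.target)
    final_adj = _adjacency_set(final)

    sites: list[tuple[str, str]] = []
    cur = canonicalize(scenario.source)
    for step, out in zip(scenario.steps, scenario.intermediates):
        n = len(cur.tokens)
        rotated = [cur.tokens[(step.start + i) % n] for i in range(n)]
        seg = rotated[:step.length]
        # duplicated layout: [first copy][second copy][rest]
        layout = seg + seg + rotated[step.length:]
        kept = (
            [step.losses[i] in ("second", "none") for i in range(step.length)]
            + [step.losses[i] in ("first", "none") for i in range(step.length)]
            + [True] * (n - step.length)
        )
        m = len(layout)
        if not all(kept):
            # walk maximal deleted runs starting from a kept anchor
            s = kept.index(True)
            i = 0
            while i < m:
                if kept[(s + i) % m]:
                    i += 1
                    continue
                j = i
                while j < m and not kept[(s + j) % m]:
                    j += 1
                left = layout[(s + i - 1) % m]   # kept: runs are maximal
                right = layout[(s + j) % m]
                sites.append((left.symbol, right.symbol))
                i = j
        cur = out
    dedup: list[tuple[str, str]] = []
    for site in sites:
        if site not in dedup and site in final_adj:
            dedup.append(site)
    return RemnantPrediction(tuple(dedup))


def _adjacency_set(order: GeneOrder) -> set[tuple[str, str]]:
    syms = order.symbols()
    n = len(syms)
    return {(syms[i], syms[(i + 1) % n]) for i in range(n)}
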