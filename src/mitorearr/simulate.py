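"""Synthetic gene orders, catalogs and sequences with known ground truth.

Everything here is seed-deterministic.  The TDRL simulator draws random
valid duplication/loss steps, mirroring the mechanism the rearrangement
analysis assumes; the catalog generator plants a richness structure
(which families carry which arrangements, and which arrangements are
shared) whose richness table is computed arithmetically from the plan, so
recovery tests compare the analysis pipeline against an independent
calculation.  Sequences are sampled per-base with probabilities solving
the target AT content and skews exactly in expectation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .catalog import Catalog, CatalogRecord
from .gene_order import GeneOrder, GeneOrderError, ancestral_order, canonicalize
from .rearrangements import DEFAULT_UNITS, UnitDefinition
from .tdrl import TDRLScenario, TDRLStep, apply_tdrl, _duplicate

__all__ = [
    "EvolutionPlan",
    "PlannedArrangement",
    "CatalogPlan",
    "simulate_tdrl_evolution",
    "generate_catalog",
    "random_sequence",
    "random_catalog_plan",
]


# ---------------------------------------------------------------------------
# TDRL evolution


@dataclass(frozen=True)
class EvolutionPlan:
    """Forward-simulation settings for TDRL evolution.

    Defaults mirror the rearrangements seen in true bugs: single events
    with short duplicated segments (all surveyed scenarios are single-step
    with segments of at most six genes).
    """

    k_events: int = 1
    min_segment: int = 1
    max_segment: int = 6
    allow_full_loss: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.k_events < 0:
            raise ValueError("k_events must be >= 0")
        if not 1 <= self.min_segment <= self.max_segment:
            raise ValueError("need 1 <= min_segment <= max_segment")


def simulate_tdrl_evolution(ancestral: GeneOrder,
                            plan: EvolutionPlan) -> tuple[GeneOrder, TDRLScenario]:
    """Apply ``k_events`` random valid TDRL steps; returns the evolved order
    and the true scenario.  Deterministic per seed."""
    rng = np.random.default_rng(plan.seed)
    cur = canonicalize(ancestral.with_taxon(""))
    source = cur
    steps: list[TDRLStep] = []
    dups: list[GeneOrder] = []
    mids: list[GeneOrder] = []
    for _ in range(plan.k_events):
        step = _random_step(cur, plan, rng)
        dups.append(_duplicate(cur, step))
        cur = apply_tdrl(cur, step, allow_full_loss=plan.allow_full_loss)
        steps.append(step)
        mids.append(cur)
    return cur, TDRLScenario(source, tuple(steps), tuple(dups), tuple(mids))


def _random_step(order: GeneOrder, plan: EvolutionPlan,
                 rng: np.random.Generator) -> TDRLStep:
    n = len(order.tokens)
    hi = min(plan.max_segment, n - 1)
    if hi < plan.min_segment:
        raise GeneOrderError("no valid step: order too short for the plan")
    choices = ("first", "second") + (("both",) if plan.allow_full_loss else ())
    for _ in range(1000):  # rejection sampling over valid steps
        start = int(rng.integers(0, n))
        length = int(rng.integers(plan.min_segment, hi + 1))
        losses = tuple(str(choices[i])
                       for i in rng.integers(0, len(choices), size=length))
        step = TDRLStep(start, length, losses)
        try:
            apply_tdrl(order, step, allow_full_loss=plan.allow_full_loss)
        except GeneOrderError:
            continue
        return step
    raise GeneOrderError("no valid TDRL step found under the plan constraints")


# ---------------------------------------------------------------------------
# Catalog plans


@dataclass(frozen=True)
class PlannedArrangement:
    """A planted rearrangement: a non-identity permutation of one unit's
    members, applied in place on the ancestral order.  Distinct permutations
    give distinct unit signatures confined to that unit."""

    unit: str
    permutation: tuple[int, ...]

    def __post_init__(self):
        if tuple(sorted(self.permutation)) != tuple(range(len(self.permutation))):
            raise ValueError("permutation must reorder 0..k-1")
        if self.permutation == tuple(range(len(self.permutation))):
            raise ValueError("planted arrangement must differ from ancestral")


@dataclass(frozen=True)
class CatalogPlan:
    """Which families carry which planted arrangements.

    ``assignments`` maps family -> tuple of arrangement indices (one record
    per entry; repeats across families model shared rearrangements).  The
    implied richness table is validated arithmetically at construction.
    """

    arrangements: tuple[PlannedArrangement, ...]
    assignments: tuple[tuple[str, tuple[int, ...], tuple[int, ...]], ...]
    # (family, arrangement indices, species counts per record)
    units: tuple[UnitDefinition, ...] = DEFAULT_UNITS

    def __post_init__(self):
        unit_names = {u.name for u in self.units}
        for arr in self.arrangements:
            if arr.unit not in unit_names:
                raise ValueError(f"unknown unit {arr.unit!r} in plan")
            members = next(u.members for u in self.units if u.name == arr.unit)
            if len(arr.permutation) != len(members):
                raise ValueError("permutation size must match unit size")
        for family, idxs, counts in self.assignments:
            if len(idxs) != len(counts):
                raise ValueError(f"{family}: indices and counts must align")
            if any(not 0 <= i < len(self.arrangements) for i in idxs):
                raise ValueError(f"{family}: arrangement index out of range")
            if any(c < 1 for c in counts):
                raise ValueError(f"{family}: species counts must be >= 1")
        if not self.arrangements or not self.assignments:
            raise ValueError("plan needs arrangements and assignments")
        used = {i for _, idxs, _ in self.assignments for i in idxs}
        if used != set(range(len(self.arrangements))):
            raise ValueError("every planted arrangement must be assigned")

    def planted_richness(self) -> dict[str, dict[str, float]]:
        """family -> column -> ratio, computed arithmetically from the
        sharing structure (no signature machinery involved)."""
        columns = [u.name for u in self.units] + ["whole"]
        fam_sets: dict[str, set[int]] = {}
        for family, idxs, _ in self.assignments:
            fam_sets.setdefault(family, set()).update(idxs)
        table: dict[str, dict[str, float]] = {f: {} for f in fam_sets}
        for col in columns:
            if col == "whole":
                union = set(range(len(self.arrangements)))
            else:
                union = {i for i, a in enumerate(self.arrangements)
                         if a.unit == col}
            for family, idxs in fam_sets.items():
                table[family][col] = (
                    len(idxs & union) / len(union) if union else float("nan"))
        return table


def _arrangement_order(arr: PlannedArrangement, ancestral: GeneOrder,
                       units: Sequence[UnitDefinition]) -> GeneOrder:
    members = next(u.members for u in units if u.name == arr.unit)
    positions = [i for i, t in enumerate(ancestral.tokens)
                 if t.symbol in set(members)]
    # units are contiguous on the ancestral order
    unit_tokens = [ancestral.tokens[i] for i in positions]
    permuted = [unit_tokens[j] for j in arr.permutation]
    tokens = list(ancestral.tokens)
    for pos, tok in zip(positions, permuted):
        tokens[pos] = tok
    return canonicalize(GeneOrder(tuple(tokens)))


def generate_catalog(plan: CatalogPlan,
                     ancestral: GeneOrder | None = None,
                     ) -> tuple[Catalog, dict[str, dict[str, float]]]:
    """Emit a catalog realizing the plan plus its planted richness table.

    Shared planted arrangements are byte-identical orders across families;
    the computed richness of the emitted catalog equals the planted table
    exactly.
    """
    ancestral = canonicalize(ancestral if ancestral is not None
                             else ancestral_order())
    orders = [_arrangement_order(a, ancestral, plan.units)
              for a in plan.arrangements]
    records: list[CatalogRecord] = []
    for family, idxs, counts in plan.assignments:
        for k, (i, count) in enumerate(zip(idxs, counts)):
            taxon = f"{family} record {k + 1} (arrangement {i})"
            records.append(CatalogRecord(
                taxon=taxon, infraorder="synthetic", families=(family,),
                species_counts=(count,),
                order=orders[i].with_taxon(taxon)))
    return (Catalog(tuple(records), ancestral), plan.planted_richness())


def random_catalog_plan(seed: int, n_families: int = 4,
                        n_arrangements: int = 6,
                        units: Sequence[UnitDefinition] = DEFAULT_UNITS,
                        ) -> CatalogPlan:
    """A random consistent plan: random unit permutations, random sharing."""
    rng = np.random.default_rng(seed)
    usable = [u for u in units if len(u.members) >= 2]
    arrangements: list[PlannedArrangement] = []
    seen: set[tuple] = set()
    while len(arrangements) < n_arrangements:
        unit = usable[int(rng.integers(0, len(usable)))]
        k = len(unit.members)
        perm = tuple(int(x) for x in rng.permutation(k))
        if perm == tuple(range(k)) or (unit.name, perm) in seen:
            continue
        seen.add((unit.name, perm))
        arrangements.append(PlannedArrangement(unit.name, perm))
    families = [f"Family{i + 1}" for i in range(n_families)]
    assignments = []
    unassigned = set(range(n_arrangements))
    for fam in families:
        n_rec = int(rng.integers(1, 4))
        idxs = tuple(int(i) for i in rng.choice(n_arrangements, size=n_rec))
        counts = tuple(int(c) for c in rng.integers(1, 13, size=n_rec))
        unassigned -= set(idxs)
        assignments.append((fam, idxs, counts))
    # ensure every arrangement is used at least once
    for i in sorted(unassigned):
        fam, idxs, counts = assignments[i % n_families]
        assignments[i % n_families] = (fam, idxs + (i,), counts + (1,))
    return CatalogPlan(tuple(arrangements), tuple(assignments),
                       tuple(units))


# ---------------------------------------------------------------------------
# Sequences


def random_sequence(length: int, at_content: float = 0.756,
                    at_skew: float = 0.15, gc_skew: float = -0.25,
                    seed: int = 0) -> str:
    """Random nucleotide sequence hitting the targets exactly in expectation.

    Defaults are typical of an AT-rich insect mitogenome majority strand
    (high A+T, positive A skew, negative C skew).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 <= at_content <= 1:
        raise ValueError("at_content must be in [0, 1]")
    for name, skew in (("at_skew", at_skew), ("gc_skew", gc_skew)):
        if not -1 <= skew <= 1:
            raise ValueError(f"{name} must be in [-1, 1]")
    p = np.array([
        at_content * (1 + at_skew) / 2,        # A
        at_content * (1 - at_skew) / 2,        # T
        (1 - at_content) * (1 + gc_skew) / 2,  # G
        (1 - at_content) * (1 - gc_skew) / 2,  # C
    ])
    if (p < 0).any():
        raise ValueError("infeasible composition targets")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=length, p=p / p.sum())
    return "".join("ATGC"[i] for i in draws)
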