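# Methods

## Gene-order model

A gene order is a circular sequence of tokens from a fixed vocabulary (13
protein-coding genes, 2 rRNAs, 22 tRNAs with trnS1/trnS2 and trnL1/trnL2
kept distinct, plus CR, NCR and GAP), each coding token carrying a strand.
Genes known to be missing from a genome live in a separate absence set, not
in the positional sequence.  An order containing a GAP token is incomplete:
the gap hides an unsequenced run of unknown content.

**Canonical form.** Circular equality is decided after rotating to a
deterministic anchor: the CR token when present exactly once, otherwise the
lexicographically smallest rotation.  Canonicalization is idempotent, never
touches strands, and never reflects the molecule (the two reading directions
of a circular genome are distinguished by strand annotation, not by order
reversal).

**Text grammar.** Tokens joined by `-`; `~` prefixes minority-strand genes;
`[X]` records an absence; `//` a gap.  `format(parse(s)) == s` on canonical
strings and `parse(format(o)) == o` on canonical orders (property-tested).

**Strand reconstruction.** The packaged survey carries no inversions
(heteropteran rearrangements lack them), so every gene keeps the strand it
occupies in the ancestral order; the catalog fixture assigns strands from
that map.

## Blocks, units and signatures

Rearrangements in true bugs concentrate in three blocks of the ancestral
order — A (between CR and COI), B (between ND3 and ND5), C (between ND5 and
CR) — subdivided into six units (1: trnI-trnQ-trnM, 2: trnW-trnC-trnY,
3: trnA-trnR-trnN-trnS1-trnE-trnF, 4: trnT-trnP, 5: ND6-CYTB-trnS2-ND1,
6: rrnL-trnV-rrnS).  Both are configurable (YAML) for other taxa.

**Unit signature = minimal covering window.**  The signature of a unit in an
observed order is the token run of the *minimal cyclic window* containing
every copy of every present unit member (the complement of the largest
member-free arc), together with the unit members recorded absent.  Two
signatures are the same arrangement iff token sequence, strands,
multiplicities and absences all agree.  Design rationale: an alternative
rule — walking outward to the nearest conserved flanking genes — inflates a
unit's signature whenever its *neighbours* move.  In the packaged survey the
unique-headed bugs relocate the whole trnI-trnQ-trnM cluster (with CR and
half of block C) without touching its internal order; the published richness
table scores that unit as un-rearranged there, which the minimal-window rule
reproduces and the flank rule does not.  A displaced intruder (e.g. trnW
between trnI and trnQ) falls inside the window of the unit it lands in, so
destination units register the event.

A unit whose members fall in a gap, or whose covering window crosses a gap,
yields an *unknown* signature: it compares equal to nothing and counts as
un-rearranged (conservative).

**Identity across incomplete genomes.**  When comparing two signatures (or
two whole orders), genes whose status is unknown to one order are dropped
from the other, GAP/NCR tokens are dropped, absence sets must agree on the
mutually known genes, and the reduced runs (cyclic sequences, for whole
orders) must coincide exactly.  This is exact equality for two complete
genomes.  Grouping is greedy from the most completely known signature, so a
partial genome joins the complete arrangement it agrees with rather than
founding a spurious new variant.

## Event classification

Against the ancestral order, for one observed order:

- **loss** — genes in the absence set, *only for complete genomes*.  In a
  gapped genome an absence is reported as `unresolved` (absent-or-in-gap):
  the data cannot distinguish loss from translocation into the gap.
- **duplication** — genes with copy number > 1.
- **inversion** — shared genes whose strand differs from ancestral (never
  fires on the packaged survey).
- **translocation** — breakpoint-style: the smallest set of shared
  single-copy same-strand genes (CR included when single-copy) whose removal
  makes the observed cyclic order embed in the ancestral one.  The search
  enumerates subsets of breakpoint-adjacent genes by increasing size (bound:
  8 moved genes, enough for the most shuffled surveyed order, which needs
  7); ties prefer tRNA-rich sets (a moved tRNA is the parsimonious reading)
  and then resolve lexicographically, so a two-gene swap may report either
  gene — event *types* are unaffected.  A duplicated gene additionally
  counts as translocated unless its copies form one tandem run flanked by
  the gene's ancestral neighbours (trnF-trnF in place: duplication only;
  trnT-trnP-trnT: duplication + translocation).

Classification canonicalizes its input, so it is rotation-invariant.

## Richness statistics

For each unit (and the whole mitogenome) the *distinct-arrangement index*
collects rearranged signatures, deduplicated by the identity above, within
each family and across the catalog.  Richness of family *f* for column *u*
is |f's distinct arrangements| / |all distinct arrangements|; a column with
an empty union is undefined (NaN, rendered "—").  Shared arrangements
(byte-identical orders in several families) count once in the denominator
and once per family in numerators, so summed numerators ≥ the union size.
Whole-genome distinctness uses the same mutually-known-genes rule; records
equal to the ancestral pattern contribute the "+1" ground pattern to the
distinct-order count and to no numerator.

Percentages render at one decimal, ties rounded half away from zero
(matching 3/7 → 42.9 and 2/7 → 28.6).

## TDRL model

A TDRL step duplicates a contiguous segment (cyclic interval, wrap allowed,
never across a gap) in tandem and deletes one copy of each duplicated
position (`first`/`second`; the `none`/`both` extensions express retained
duplications and full gene loss — `both` requires the `allow_full_loss`
flag, otherwise gene extinction is an error).  Strands are never touched.
Without full loss, gene content is invariant under any scenario.

`enumerate_single_tdrl` is the exhaustive oracle: every (start, length ≤
max_segment, loss pattern) product, deduplicated by canonical equality.
`search_scenarios` does breadth-first search over canonical orders and
returns *all* scenarios of minimal step count, deduplicated by intermediate
sequence — where the intermediates include the post-duplication (pre-loss)
order, so duplications with different boundaries count as distinct
mechanisms even when every subsequent order coincides.  Results sort by
total duplicated length, then segment coordinates.  Default bounds
(max_steps = 2, max_segment = 8) keep the search desk-scale on a 38-token
genome for single-step questions; two-step search at full genome size is
exponential in practice and intended for reduced gene sets.

**Remnant prediction.**  Every maximal run of deleted copies leaves residue
between its surviving neighbours; `predict_remnants` reports those
adjacencies, keeping only the ones still intact in the final order.  For
multi-step scenarios sites from earlier steps that a later step disrupts are
dropped rather than traced through the duplication — exact for the
single-step scenarios this package targets; a limitation for longer ones.

## Synthetic data

- **TDRL evolution**: k random valid steps (uniform start; length uniform
  on [1, 6] by default, matching the surveyed scenarios, all of which are
  single steps with ≤ 6-gene segments; loss pattern uniform over
  first/second per position, i.e. "random loss" read literally), rejection-
  sampled against the extinction guard.  Returns the true scenario.
- **Catalog plans** plant arrangements as non-identity permutations of one
  unit's members applied in place on the ancestral order: distinct
  permutations give distinct signatures confined to that unit, so the
  planted richness table is computed *arithmetically from the sharing
  structure* — an independent oracle for the analysis pipeline, not a
  re-derivation through it.  Plans validate at construction (every
  arrangement assigned, counts positive, permutations non-identity), so
  recovery tests cannot pass vacuously.
- **Sequences** are sampled i.i.d. per base with probabilities solving the
  target AT content and both skews exactly in expectation; defaults
  (AT = 0.756, AT-skew = 0.15, GC-skew = −0.25) are typical of an AT-rich
  insect mitogenome majority strand.

What a green synthetic test does *not* establish: real catalogs contain
partial genomes, shared-vs-convergent arrangements and multi-unit events,
which the planted catalogs deliberately avoid (they isolate the counting
semantics); and real TDRL events leave sequence-level remnants this package
predicts only positionally, never aligns.

## The packaged survey catalog

`data/heteroptera_catalog.tsv` transcribes the published heteropteran
survey: 21 rearranged records (two of them single records shared across two
families each, with slash-separated family/species-count lists) plus one
aggregated record for the 374 species retaining the ground pattern.  The
published table marks minority-strand genes and absent genes
typographically; strands are restored from the ancestral map (no inversions)
and the four loss rows name their lost tRNA either from the source text
(trnI for the Nabidae/Reduviidae shared loss) or by the unique assignment
consistent with the published per-unit denominators (see the fixture's
header comments).  Three genuinely partial genomes keep their `//` gaps;
rows whose printed form merely elides un-rearranged stretches are stored as
full orders embedded in the ancestral background.

## Known limitations

- Known-arc identity treats the junction across a gap as a real adjacency
  after reduction; two partial orders differing only in how their arcs
  interleave around the circle could in principle be conflated (does not
  arise in the packaged survey).
- The translocation minimal-removal search is exponential in the number of
  breakpoint genes (capped at 8 moved genes; beyond that it raises rather
  than guess).
- Two-step TDRL search over full-size genomes is memory- and time-hungry;
  remnant prediction is step-local.
- No phylogenetic polarity: events are scored against the ancestral order,
  not reconstructed along a tree.
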