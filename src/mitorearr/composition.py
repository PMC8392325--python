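"""Nucleotide composition and strand-skew statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed on the
majority strand as deposited.  Skews are strand-asymmetry statistics:
reverse-complementing a sequence negates both.  IUPAC ambiguity codes are
excluded from the four base counts and reported separately, so
at_content + gc_content + ambiguity_fraction = 1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = ["SequenceComposition", "composition", "composition_report"]

_BASES = set("ACGT")
_AMBIGUITY = set("RYSWKMBDHVN")


@dataclass(frozen=True)
class SequenceComposition:
    """Base counts and derived statistics for one nucleotide sequence."""

    a: int
    t: int
    g: int
    c: int
    ambiguous: int

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.ambiguous

    @property
    def at_content(self) -> float:
        return (self.a + self.t) / self.length

    @property
    def gc_content(self) -> float:
        return (self.g + self.c) / self.length

    @property
    def ambiguity_fraction(self) -> float:
        return self.ambiguous / self.length

    @property
    def at_skew(self) -> float | None:
        """None when A + T = 0 (undefined)."""
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float | None:
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)

    def rounded(self) -> dict:
        """Reporting convention: percentages to one decimal, skews to two."""
        return {
            "length": self.length,
            "at_percent": round(self.at_content * 100, 1),
            "at_skew": None if self.at_skew is None else round(self.at_skew, 2),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, 2),
        }


def composition(seq: str) -> SequenceComposition:
    """Composition of a nucleotide sequence (case-insensitive, U folded
    into T, ambiguity codes counted separately).  Empty input is an error."""
    if not seq:
        raise ValueError("empty sequence")
    s = str(seq).upper().replace("U", "T")
    counts = {"A": 0, "T": 0, "G": 0, "C": 0}
    ambiguous = 0
    for ch in s:
        if ch in _BASES:
            counts[ch] += 1
        elif ch in _AMBIGUITY:
            ambiguous += 1
        else:
            raise ValueError(f"invalid nucleotide character {ch!r}")
    return SequenceComposition(counts["A"], counts["T"], counts["G"],
                               counts["C"], ambiguous)


def composition_report(sequence: str,
                       regions: Sequence[tuple[str, int, int]] | None = None,
                       ) -> pd.DataFrame:
    """Whole-genome plus per-region composition table.

    ``regions`` is a list of (name, start, end) with 0-based half-open
    coordinates on the majority strand (the convention the GenBank reader
    emits); rows are independent.  Out-of-bounds regions are an error.
    """
    rows = []
    whole = composition(sequence)
    rows.append({"region": "genome", "start": 0, "end": len(sequence),
                 **_stats(whole)})
    for name, start, end in regions or ():
        if not (0 <= start < end <= len(sequence)):
            raise ValueError(
                f"region {name}: [{start}, {end}) outside sequence bounds "
                f"[0, {len(sequence)})")
        comp = composition(sequence[start:end])
        rows.append({"region": name, "start": start, "end": end,
                     **_stats(comp)})
    return pd.DataFrame(rows)


def _stats(comp: SequenceComposition) -> dict:
    return {
        "length": comp.length,
        "A": comp.a, "T": comp.t, "G": comp.g, "C": comp.c,
        "ambiguous": comp.ambiguous,
        "at_content": comp.at_content,
        "at_skew": comp.at_skew,
        "gc_skew": comp.gc_skew,
    }
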