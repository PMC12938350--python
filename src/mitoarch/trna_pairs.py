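"""Classification of base pairs in tRNA secondary structures.

Mitochondrial tRNAs fold into the cloverleaf (acceptor, D, anticodon and
TPsiC arms) but tolerate non-Watson-Crick pairs in their stems: the
relatively stable G-U wobble pair and the weaker A-C pair are counted
separately here because their abundance is a structural signature of a
genome's tRNA complement.  This module consumes structures (dot-bracket
plus sequence, or explicit pair lists) -- it does not predict them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "TRNAStructure",
    "PairClassCounts",
    "classify_pairs",
    "aggregate_pairs",
    "parse_structure",
    "StructureError",
]


class StructureError(ValueError):
    pass


@dataclass
class TRNAStructure:
    """A tRNA with an explicit (pseudoknot-free) base pairing.

    ``pairing`` holds 1-based position pairs ``(i, j)`` with ``i < j`` and
    each position in at most one pair.  DNA input is transcribed to RNA
    before any classification.
    """

    name: str
    sequence: str
    pairing: list[tuple[int, int]] = field(default_factory=list)
    arms: Optional[dict[str, list[tuple[int, int]]]] = None

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        n = len(self.sequence)
        used: set[int] = set()
        for i, j in self.pairing:
            if i == j:
                raise StructureError(f"{self.name}: pair ({i},{j}) is degenerate")
            if not (1 <= i <= n and 1 <= j <= n):
                raise StructureError(
                    f"{self.name}: pair ({i},{j}) outside sequence of length {n}"
                )
            for p in (i, j):
                if p in used:
                    raise StructureError(
                        f"{self.name}: position {p} paired more than once"
                    )
                used.add(p)
        self.pairing = [tuple(sorted(p)) for p in self.pairing]


@dataclass(frozen=True)
class PairClassCounts:
    """Partition of a structure's pairs into WC / G-U / A-C / other."""

    watson_crick: int = 0
    g_u: int = 0
    a_c: int = 0
    other: int = 0

    @property
    def total(self) -> int:
        return self.watson_crick + self.g_u + self.a_c + self.other

    def __add__(self, other: "PairClassCounts") -> "PairClassCounts":
        return PairClassCounts(
            self.watson_crick + other.watson_crick,
            self.g_u + other.g_u,
            self.a_c + other.a_c,
            self.other + other.other,
        )

    def to_dict(self) -> dict[str, int]:
        return {
            "watson_crick": self.watson_crick,
            "g_u": self.g_u,
            "a_c": self.a_c,
            "other": self.other,
        }


_WC = ({"A", "U"}, {"G", "C"})


def classify_pairs(structure: TRNAStructure) -> PairClassCounts:
    """Classify each pair by its unordered nucleotide set.

    {A,U} and {G,C} are Watson-Crick; {G,U} is the wobble class; {A,C} its
    own class; anything else (including homo-pairs like G-G) is ``other``.
    Classification is symmetric in the pair's endpoints.
    """
    wc = gu = ac = other = 0
    for i, j in structure.pairing:
        duo = {structure.sequence[i - 1], structure.sequence[j - 1]}
        if duo in _WC:
            wc += 1
        elif duo == {"G", "U"}:
            gu += 1
        elif duo == {"A", "C"}:
            ac += 1
        else:
            other += 1
    return PairClassCounts(wc, gu, ac, other)


def aggregate_pairs(structures: Iterable[TRNAStructure]) -> PairClassCounts:
    """Component-wise sum of per-structure pair-class counts."""
    total = PairClassCounts()
    for s in structures:
        total = total + classify_pairs(s)
    return total


def parse_structure(
    dot_bracket: str, sequence: str, name: str = "tRNA"
) -> TRNAStructure:
    """Build a structure from a dot-bracket string and its sequence."""
    if len(dot_bracket) != len(sequence):
        raise StructureError(
            f"{name}: structure length {len(dot_bracket)} != sequence "
            f"length {len(sequence)}"
        )
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dot_bracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(
                    f"{name}: unbalanced ')' at position {pos}"
                )
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise StructureError(f"{name}: unexpected character {ch!r}")
    if stack:
        raise StructureError(f"{name}: {len(stack)} unclosed '(' in structure")
    return TRNAStructure(name=name, sequence=sequence, pairing=sorted(pairs))


def pair_table(structures: Sequence[TRNAStructure]):
    """One row per tRNA plus a totals row (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for s in structures:
        d = classify_pairs(s).to_dict()
        d["tRNA"] = s.name
        rows.append(d)
    total = aggregate_pairs(structures).to_dict()
    total["tRNA"] = "total"
    rows.append(total)
    return pd.DataFrame(rows).set_index("tRNA")[
        ["watson_crick", "g_u", "a_c", "other"]
    ]
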