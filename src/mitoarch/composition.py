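"""Base composition and strand-skew statistics per genomic region class.

Strand compositional asymmetry is summarized by two ratios,

    GC-skew = (G - C) / (G + C)        AT-skew = (A - T) / (A + T),

computed either from raw base counts or from percentages (the ratios are
scale-invariant, so both give the same value).  Region profiles pool the
strand-oriented sequence of every feature in a region class (PCGs, rRNAs,
tRNAs, control region) or the raw heavy strand for the whole genome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from .records import FeatureCategory, MitogenomeRecord

__all__ = [
    "SkewUndefinedError",
    "EmptyRegionError",
    "gc_skew",
    "at_skew",
    "CompositionProfile",
    "region_composition",
    "composition_table",
    "REGIONS",
]

#: Region classes in reporting order.
REGIONS = ("PCGs", "rRNA", "tRNA", "control", "genome")

_REGION_CATEGORY = {
    "PCGs": FeatureCategory.PCG,
    "rRNA": FeatureCategory.RRNA,
    "tRNA": FeatureCategory.TRNA,
    "control": FeatureCategory.CONTROL,
}

Number = Union[int, float]


class SkewUndefinedError(ZeroDivisionError):
    """Raised when a skew denominator is zero."""


class EmptyRegionError(ValueError):
    """Raised when a region class has no features on the record."""


def gc_skew(g: Number, c: Number) -> float:
    """(G - C) / (G + C); accepts counts or percentages."""
    if g + c == 0:
        raise SkewUndefinedError("GC-skew undefined: G + C = 0")
    return (g - c) / (g + c)


def at_skew(a: Number, t: Number) -> float:
    """(A - T) / (A + T); accepts counts or percentages."""
    if a + t == 0:
        raise SkewUndefinedError("AT-skew undefined: A + T = 0")
    return (a - t) / (a + t)


@dataclass
class CompositionProfile:
    """Base counts for one region plus the derived percentage/skew summary.

    Ambiguity codes are excluded from both counts and denominators.
    Percentages are conventionally reported to 2 decimals and skews to 5,
    but the stored values are unrounded.
    """

    region: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.get(b, 0) for b in "TCAG")

    def percent(self, base: str) -> float:
        return 100.0 * self.counts.get(base, 0) / self.total

    @property
    def at_percent(self) -> float:
        return self.percent("A") + self.percent("T")

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.counts.get("G", 0), self.counts.get("C", 0))

    @property
    def at_skew(self) -> float:
        return at_skew(self.counts.get("A", 0), self.counts.get("T", 0))

    def as_row(self) -> dict[str, float]:
        """One table row: ``T% C% A% G% AT% GC Skew AT Skew`` (rounded)."""
        return {
            "Region": self.region,
            "T%": round(self.percent("T"), 2),
            "C%": round(self.percent("C"), 2),
            "A%": round(self.percent("A"), 2),
            "G%": round(self.percent("G"), 2),
            "AT%": round(self.at_percent, 2),
            "GC Skew": round(self.gc_skew, 5),
            "AT Skew": round(self.at_skew, 5),
        }

    @classmethod
    def from_sequences(cls, region: str, seqs: Iterable[str]) -> "CompositionProfile":
        counts: Counter = Counter()
        for s in seqs:
            counts.update(s.upper().replace("U", "T"))
        clean = {b: counts.get(b, 0) for b in "TCAG"}
        return cls(region=region, counts=clean)


def region_composition(
    record: MitogenomeRecord,
    region: str,
    strand_oriented: bool = True,
) -> CompositionProfile:
    """Composition profile of one region class of a sequenced record.

    Multi-feature regions concatenate each feature's strand-oriented
    (coding/structural) sequence; ``strand_oriented=False`` counts the
    heavy strand as annotated instead.  ``region='genome'`` counts the
    whole heavy strand regardless of annotation.
    """
    if record.sequence is None:
        raise ValueError(f"{record.species_id}: record carries no sequence")
    if region == "genome":
        return CompositionProfile.from_sequences("genome", [record.sequence])
    if region not in _REGION_CATEGORY:
        raise ValueError(f"unknown region {region!r}; accepted: {', '.join(REGIONS)}")
    feats = record.by_category(_REGION_CATEGORY[region])
    if not feats:
        raise EmptyRegionError(f"{record.species_id}: no {region} features")
    if strand_oriented:
        seqs = [record.feature_sequence(f) for f in feats]
    else:
        seqs = [_heavy(record, f) for f in feats]
    return CompositionProfile.from_sequences(region, seqs)


def _heavy(record: MitogenomeRecord, f) -> str:
    if f.wraps_origin:
        return record.sequence[f.start - 1:] + record.sequence[: f.end]
    return record.sequence[f.start - 1: f.end]


def composition_table(
    record: MitogenomeRecord,
    regions: Optional[Iterable[str]] = None,
    strand_oriented: bool = True,
) -> pd.DataFrame:
    """Composition summary table across region classes (one row per region)."""
    rows = [
        region_composition(record, r, strand_oriented).as_row()
        for r in (regions or REGIONS)
    ]
    return pd.DataFrame(rows).set_index("Region")
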