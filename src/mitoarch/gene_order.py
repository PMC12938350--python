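"""tRNA gene-cluster orders between ND2 and COI (the WANCY region).

In the canonical vertebrate mitogenome the block between ND2 and COI holds
five tRNAs -- Trp, Ala, Asn, Cys, Tyr (WANCY) -- plus the light-strand
replication origin.  Rearranged mitogenomes permute and/or duplicate these
tRNAs; this module extracts the cluster from an annotated record as a
letter sequence and classifies it against the named arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .feature_table import AA_3TO1
from .records import FeatureCategory, MitogenomeRecord

__all__ = ["GeneOrder", "extract_cluster", "classify_pattern", "NAMED_PATTERNS"]

#: Named tRNA-cluster arrangements: the canonical vertebrate order and the
#: three rearranged states observed in snailfishes.
NAMED_PATTERNS = ("WANCY", "WYANC", "WNCYAC", "WNCYAA")


@dataclass(frozen=True)
class GeneOrder:
    """An ordered tRNA cluster between two anchor genes.

    ``letters`` are single-letter amino-acid codes of the tRNAs in genomic
    order; ``strands`` (optional) parallel them.  Pattern matching ignores
    strand.
    """

    letters: tuple[str, ...]
    strands: Optional[tuple[str, ...]] = None
    left_anchor: str = "ND2"
    right_anchor: str = "COXI"

    def __post_init__(self):
        if self.strands is not None and len(self.strands) != len(self.letters):
            raise ValueError("strands must parallel letters")

    def __str__(self) -> str:
        return "".join(self.letters)

    def __len__(self) -> int:
        return len(self.letters)

    @classmethod
    def from_string(cls, s: str, **kwargs) -> "GeneOrder":
        return cls(letters=tuple(s.upper()), **kwargs)


def extract_cluster(
    record: MitogenomeRecord,
    left_anchor: str = "ND2",
    right_anchor: str = "COXI",
) -> GeneOrder:
    """tRNAs lying strictly between the anchors, in genomic order.

    Only tRNA features count (the light-strand origin inside the cluster
    is ignored).  Anchors missing from the record raise ``KeyError``.
    """
    left = record.get(left_anchor)
    right = record.get(right_anchor)
    letters, strands = [], []
    for f in record.by_category(FeatureCategory.TRNA):
        if left.end < f.start and f.end < right.start:
            aa = f.amino_acid or AA_3TO1.get(f.trna_aa3 or "", "?")
            letters.append(aa)
            strands.append(f.strand)
    return GeneOrder(
        letters=tuple(letters),
        strands=tuple(strands),
        left_anchor=left_anchor,
        right_anchor=right_anchor,
    )


def classify_pattern(order: GeneOrder | Sequence[str] | str) -> str:
    """Exact-match classification against the named arrangements.

    Returns one of ``WANCY, WYANC, WNCYAC, WNCYAA`` or ``"OTHER"``.
    Strand is ignored.
    """
    if isinstance(order, GeneOrder):
        s = str(order)
    elif isinstance(order, str):
        s = order.upper()
    else:
        s = "".join(order).upper()
    return s if s in NAMED_PATTERNS else "OTHER"
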