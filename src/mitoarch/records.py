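"""Domain model for annotated circular mitogenomes.

A vertebrate mitochondrial genome is a circular molecule of roughly
15--20 kb carrying 13 protein-coding genes (PCGs), 2 rRNAs, 22 (sometimes
23) tRNAs, the control region (D-loop) and the light-strand replication
origin (O_L).  This module holds the record model shared by the whole
package, the 1-based fully-inclusive coordinate arithmetic that goes with
a circular chromosome, and a validator that cross-checks a record's
declared bookkeeping (printed sizes, spacers, amino-acid counts,
anticodons) against what its coordinates imply.

Conventions
-----------
* Coordinates are 1-based and inclusive on both ends; a feature spanning
  positions 1-68 has size 68.
* ``wraps_origin`` marks a feature crossing the circular origin; its
  ``end`` is then numerically smaller than its ``start``.
* The intergenic spacer between consecutive features is
  ``next.start - prev.end - 1``; negative values denote overlap.
* Minus-strand features store heavy-strand coordinates; orientation is
  applied only when sequence is extracted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "FeatureCategory",
    "GeneFeature",
    "MitogenomeRecord",
    "Violation",
    "ValidationReport",
    "gene_size",
    "intergenic_spacer",
    "validate_record",
    "reverse_complement",
    "STANDARD_ANTICODONS",
    "PCG_NAMES",
]


class FeatureCategory(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"
    OL = "OL"


#: Protein-coding gene labels in the canonical vertebrate gene order.
PCG_NAMES = (
    "ND1", "ND2", "COXI", "COXII", "ATPase8", "ATPase6", "COXIII",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "Cytb",
)

#: Stop-codon tokens: complete stops and the incomplete forms (completed
#: to TAA by polyadenylation of the mature transcript).
STOP_TOKENS = ("TAA", "TAG", "AGA", "AGG", "TA-", "T-")

#: Standard vertebrate mitochondrial tRNA anticodons (DNA alphabet, as
#: annotated on the gene).  Leu and Ser have two isoacceptors each.
STANDARD_ANTICODONS: dict[str, frozenset[str]] = {
    "Phe": frozenset({"GAA"}),
    "Val": frozenset({"TAC"}),
    "Leu": frozenset({"TAA", "TAG"}),  # UUR / CUN
    "Ile": frozenset({"GAT"}),
    "Gln": frozenset({"TTG"}),
    "Met": frozenset({"CAT"}),
    "Trp": frozenset({"TCA"}),
    "Ala": frozenset({"TGC"}),
    "Asn": frozenset({"GTT"}),
    "Cys": frozenset({"GCA"}),
    "Tyr": frozenset({"GTA"}),
    "Ser": frozenset({"TGA", "GCT"}),  # UCN / AGY
    "Asp": frozenset({"GTC"}),
    "Lys": frozenset({"TTT"}),
    "Gly": frozenset({"TCC"}),
    "Arg": frozenset({"TCG"}),
    "His": frozenset({"GTG"}),
    "Glu": frozenset({"TTC"}),
    "Thr": frozenset({"TGT"}),
    "Pro": frozenset({"TGG"}),
}

_COMPLEMENT = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """Raised for coordinate queries that are impossible on the record."""


@dataclass
class GeneFeature:
    """One annotated feature on a mitogenome.

    ``declared_size``, ``declared_spacer`` and ``aa_count`` hold values as
    printed in an annotation table (when the record came from one) so the
    validator can compare them against coordinate-derived values.
    """

    name: str
    category: FeatureCategory
    strand: str
    start: int
    end: int
    wraps_origin: bool = False
    anticodon: Optional[str] = None
    amino_acid: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    aa_count: Optional[int] = None
    declared_size: Optional[int] = None
    declared_spacer: Optional[int] = None

    def __post_init__(self) -> None:
        self.category = FeatureCategory(self.category)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start and not self.wraps_origin:
            raise ValueError(
                f"{self.name}: end < start ({self.end} < {self.start}) "
                "without wraps_origin"
            )
        if self.stop_codon is not None and self.category is not FeatureCategory.PCG:
            raise ValueError(f"{self.name}: stop_codon is only valid for PCGs")
        if self.stop_codon is not None and self.stop_codon not in STOP_TOKENS:
            raise ValueError(
                f"{self.name}: unknown stop codon {self.stop_codon!r}; "
                f"accepted: {', '.join(STOP_TOKENS)}"
            )
        if self.category is FeatureCategory.TRNA and self.amino_acid is None:
            raise ValueError(f"{self.name}: tRNA features need amino_acid")

    @property
    def base_name(self) -> str:
        """Gene label with any duplicate-disambiguating ordinal stripped."""
        parts = self.name.rsplit("-", 1)
        if len(parts) == 2 and parts[1].isdigit():
            return parts[0]
        return self.name

    @property
    def trna_aa3(self) -> Optional[str]:
        """Three-letter amino-acid code for tRNA features (from the name)."""
        if self.category is not FeatureCategory.TRNA:
            return None
        base = self.base_name
        return base.split("-", 1)[1] if "-" in base else None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "category": self.category.value,
            "strand": self.strand,
            "start": self.start,
            "end": self.end,
            "wraps_origin": self.wraps_origin,
        }
        for key in ("anticodon", "amino_acid", "start_codon", "stop_codon",
                    "aa_count", "declared_size", "declared_spacer"):
            value = getattr(self, key)
            if value is not None:
                d[key] = value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneFeature":
        return cls(**d)


def gene_size(feature: GeneFeature, genome_length: Optional[int] = None) -> int:
    """Length in bp of a feature under 1-based inclusive coordinates.

    Features wrapping the circular origin need ``genome_length``:
    the size is ``(genome_length - start + 1) + end``.
    """
    if feature.wraps_origin:
        if genome_length is None:
            raise CoordinateError(
                f"{feature.name}: wraps_origin features need genome_length"
            )
        return (genome_length - feature.start + 1) + feature.end
    return feature.end - feature.start + 1


def intergenic_spacer(
    prev: GeneFeature,
    nxt: GeneFeature,
    genome_length: int,
    circular: bool = True,
) -> int:
    """Signed spacer between two consecutive features.

    ``next.start - prev.end - 1`` in the linear case; negative values mean
    the features overlap.  When ``nxt`` lies before ``prev`` in coordinate
    space (the wrap-around pair of a circular record) the spacer crosses
    the origin: ``genome_length - prev.end + nxt.start - 1``.
    """
    if nxt.start >= prev.start and not prev.wraps_origin:
        return nxt.start - prev.end - 1
    if not circular:
        raise CoordinateError(
            f"spacer {prev.name}->{nxt.name} crosses the origin of a "
            "non-circular record"
        )
    prev_end = prev.end if not prev.wraps_origin else prev.end - genome_length
    # Wrap-around: distance from prev.end forward to the origin, plus the
    # run-up from the origin to nxt.start.
    return genome_length - prev_end + nxt.start - 1


@dataclass
class MitogenomeRecord:
    """An annotated (optionally sequenced) circular mitogenome."""

    species_id: str
    genome_length: int
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    accession: Optional[str] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"{self.species_id}: sequence length {len(self.sequence)} "
                    f"!= genome_length {self.genome_length}"
                )
        for f in self.features:
            if not f.wraps_origin and f.end > self.genome_length:
                raise ValueError(
                    f"{self.species_id}/{f.name}: end {f.end} exceeds genome "
                    f"length {self.genome_length}"
                )

    # -- queries ---------------------------------------------------------
    def by_category(self, category: FeatureCategory) -> list[GeneFeature]:
        category = FeatureCategory(category)
        return [f for f in self.features if f.category is category]

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name or f.base_name == name:
                return f
        raise KeyError(f"{self.species_id}: no feature named {name!r}")

    def gene_counts(self) -> dict[str, int]:
        """Counts of PCG/tRNA/rRNA features plus their total.

        Control region and O_L are structural landmarks, not genes, and are
        excluded from the total (a 37- or 38-'gene' genome in the usual
        accounting).
        """
        counts = {
            "PCG": len(self.by_category(FeatureCategory.PCG)),
            "tRNA": len(self.by_category(FeatureCategory.TRNA)),
            "rRNA": len(self.by_category(FeatureCategory.RRNA)),
        }
        counts["total"] = counts["PCG"] + counts["tRNA"] + counts["rRNA"]
        return counts

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Strand-oriented sequence of a feature (reverse complement for -)."""
        if self.sequence is None:
            raise ValueError(f"{self.species_id}: record has no sequence")
        if feature.wraps_origin:
            raw = self.sequence[feature.start - 1:] + self.sequence[:feature.end]
        else:
            raw = self.sequence[feature.start - 1:feature.end]
        return reverse_complement(raw) if feature.strand == "-" else raw

    def spacers(self) -> list[int]:
        """Computed spacers between consecutive features, wrap pair included
        when the record is circular."""
        if len(self.features) < 2:
            return []
        out = [
            intergenic_spacer(a, b, self.genome_length, self.circular)
            for a, b in zip(self.features, self.features[1:])
        ]
        if self.circular:
            out.append(
                intergenic_spacer(
                    self.features[-1], self.features[0], self.genome_length
                )
            )
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "species_id": self.species_id,
            "genome_length": self.genome_length,
            "circular": self.circular,
            "features": [f.to_dict() for f in self.features],
        }
        if self.accession is not None:
            d["accession"] = self.accession
        if self.sequence is not None:
            d["sequence"] = self.sequence
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MitogenomeRecord":
        d = dict(d)
        d["features"] = [GeneFeature.from_dict(f) for f in d["features"]]
        return cls(**d)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "MitogenomeRecord":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "MitogenomeRecord":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

RULES = (
    "size-mismatch",
    "aa-mismatch",
    "spacer-mismatch",
    "anticodon-nonstandard",
    "count-anomaly",
)


@dataclass(frozen=True)
class Violation:
    feature: str
    rule: str
    expected: object
    observed: object

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.feature}: expected {self.expected}, observed {self.observed}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.violations

    def by_rule(self, rule: str) -> list[Violation]:
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule!r}; accepted: {', '.join(RULES)}")
        return [v for v in self.violations if v.rule == rule]

    def to_dict(self) -> dict:
        return {
            "n_violations": len(self.violations),
            "violations": [vars(v) for v in self.violations],
        }


def validate_record(
    record: MitogenomeRecord,
    expected_counts: Optional[dict[str, object]] = None,
) -> ValidationReport:
    """Cross-check a record's declared bookkeeping against its coordinates.

    Checks, per feature where the relevant declared value is present:

    * ``size-mismatch``  -- printed size vs coordinate-derived size;
    * ``aa-mismatch``    -- printed amino-acid count vs the count implied
      by the printed size and stop-codon class (a non-integral frame also
      lands here);
    * ``spacer-mismatch`` -- printed spacer to the next listed feature vs
      the coordinate-derived spacer (the final wrap-around pair is not
      checked: printed tables leave the control region unannotated there);
    * ``anticodon-nonstandard`` -- tRNA anticodon outside the standard
      vertebrate mitochondrial assignment for its amino acid;
    * ``count-anomaly``  -- gene-class totals outside the vertebrate
      expectation (13 PCGs, 2 rRNAs, 22-23 tRNAs) or outside explicitly
      supplied ``expected_counts``.

    Violations are data, not exceptions: an empty report means the record
    is internally consistent under the package's conventions.
    """
    from .codons import FrameInconsistencyError, amino_acid_length

    report = ValidationReport()
    L = record.genome_length

    for f in record.features:
        computed = gene_size(f, L)
        if f.declared_size is not None and f.declared_size != computed:
            report.violations.append(
                Violation(f.name, "size-mismatch", computed, f.declared_size)
            )
        if (
            f.category is FeatureCategory.PCG
            and f.aa_count is not None
            and f.stop_codon is not None
        ):
            size = f.declared_size if f.declared_size is not None else computed
            try:
                implied = amino_acid_length(size, f.stop_codon)
            except FrameInconsistencyError:
                implied = None
            if implied != f.aa_count:
                report.violations.append(
                    Violation(f.name, "aa-mismatch", implied, f.aa_count)
                )
        if f.category is FeatureCategory.TRNA and f.anticodon is not None:
            aa3 = f.trna_aa3
            standard = STANDARD_ANTICODONS.get(aa3)
            if standard is not None and f.anticodon not in standard:
                report.violations.append(
                    Violation(
                        f.name,
                        "anticodon-nonstandard",
                        "/".join(sorted(standard)),
                        f.anticodon,
                    )
                )

    for prev, nxt in zip(record.features, record.features[1:]):
        if prev.declared_spacer is None:
            continue
        computed = intergenic_spacer(prev, nxt, L, record.circular)
        if computed != prev.declared_spacer:
            report.violations.append(
                Violation(
                    f"{prev.name}->{nxt.name}",
                    "spacer-mismatch",
                    computed,
                    prev.declared_spacer,
                )
            )

    counts = record.gene_counts()
    expectation: dict[str, object] = {"PCG": 13, "rRNA": 2, "tRNA": (22, 23)}
    if expected_counts:
        expectation.update(expected_counts)
    for key, want in expectation.items():
        got = counts.get(key)
        allowed = want if isinstance(want, (tuple, list, set)) else (want,)
        if got not in allowed:
            report.violations.append(
                Violation(f"genome/{key}", "count-anomaly", want, got)
            )
    return report
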