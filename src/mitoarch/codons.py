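"""Codon accounting under the vertebrate mitochondrial genetic code.

Covers start/stop codon bookkeeping (including the incomplete stops T-
and TA- completed to TAA by polyadenylation), CDS extraction from
sequenced records, Relative Synonymous Codon Usage (RSCU), and
concatenation of the 13 PCGs for downstream phylogenetics.

The genetic code is fixed to NCBI translation table 2 (vertebrate
mitochondrial): AGA/AGG are stops, ATA codes Met, TGA codes Trp.  RSCU
for codon ``c`` of amino acid ``a`` is::

    RSCU(c) = count(c) * |family(a)| / sum(count(c') for c' in family(a))

i.e. observed over expected under uniform synonymous use; a family whose
total count is zero gets RSCU 0 for all members and is flagged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio.Data import CodonTable

from .records import (
    FeatureCategory,
    MitogenomeRecord,
    PCG_NAMES,
    gene_size,
)

__all__ = [
    "FrameInconsistencyError",
    "amino_acid_length",
    "stop_length",
    "extract_cds",
    "CDSRecord",
    "compute_rscu",
    "CodonUsageTable",
    "concatenate_pcgs",
    "MITO_TABLE",
    "SYNONYMOUS_FAMILIES",
]

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

#: Codons of table 2 grouped into synonymous families by amino acid.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(MITO_TABLE.forward_table.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

ALL_CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in MITO_TABLE.stop_codons)

_STOP_LENGTH = {"TAA": 3, "TAG": 3, "AGA": 3, "AGG": 3, "TA-": 2, "T-": 1}


class FrameInconsistencyError(ValueError):
    """Gene size is not compatible with its stop-codon class."""


def stop_length(stop_codon: str) -> int:
    """Nucleotides the stop token occupies at the gene's 3' end (3, 2 or 1)."""
    try:
        return _STOP_LENGTH[stop_codon]
    except KeyError:
        raise ValueError(
            f"unknown stop codon token {stop_codon!r}; "
            f"accepted: {', '.join(_STOP_LENGTH)}"
        ) from None


def amino_acid_length(size: int, stop_codon: str) -> int:
    """Amino acids encoded by a gene of ``size`` bp ending in ``stop_codon``.

    ``(size - stop_length) / 3``; raises :class:`FrameInconsistencyError`
    when the result is not an integer (the usual symptom of an annotation
    error in a printed table).
    """
    s = stop_length(stop_codon)
    if size <= s:
        raise ValueError(f"gene size {size} not larger than stop length {s}")
    coding = size - s
    if coding % 3:
        raise FrameInconsistencyError(
            f"size {size} with stop {stop_codon!r} leaves {coding} coding nt, "
            "not a codon multiple"
        )
    return coding // 3


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


@dataclass
class CDSRecord:
    """Extracted coding sequence of one PCG."""

    gene: str
    codons: list[str]
    start_codon: str
    stop_codon: str  # token: TAA/TAG/AGA/AGG or TA-/T-
    warnings: list[str] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """Stop-stripped coding sequence."""
        return "".join(self.codons)

    def translate(self) -> str:
        return "".join(
            MITO_TABLE.forward_table.get(c, "X") for c in self.codons
        )


def _infer_stop(seq: str) -> str:
    rem = len(seq) % 3
    if rem == 1 and seq.endswith("T"):
        return "T-"
    if rem == 2 and seq.endswith("TA"):
        return "TA-"
    if rem == 0 and seq[-3:] in ("TAA", "TAG", "AGA", "AGG"):
        return seq[-3:]
    raise FrameInconsistencyError(
        f"cannot infer stop codon from length {len(seq)} ending {seq[-3:]!r}"
    )


def extract_cds(record: MitogenomeRecord) -> dict[str, CDSRecord]:
    """Extract strand-oriented codons for every PCG of a sequenced record.

    An incomplete terminal stop (T- / TA-) is completed to TAA by appending
    A's before the stop is stripped; the reported codon count therefore
    equals the encoded amino-acid count.  Internal stop codons are reported
    as warnings with their codon position.
    """
    out: dict[str, CDSRecord] = {}
    for f in record.by_category(FeatureCategory.PCG):
        seq = record.feature_sequence(f)
        stop = f.stop_codon if f.stop_codon is not None else _infer_stop(seq)
        s = stop_length(stop)
        coding = len(seq) - s
        if coding % 3:
            raise FrameInconsistencyError(
                f"{record.species_id}/{f.name}: {len(seq)} bp with stop "
                f"{stop!r} is frame-inconsistent"
            )
        codons = [seq[i:i + 3] for i in range(0, coding, 3)]
        notes = []
        for pos, codon in enumerate(codons[1:], start=2):
            if codon in MITO_TABLE.stop_codons:
                notes.append(f"internal stop {codon} at codon {pos}")
        if notes:
            warnings.warn(f"{record.species_id}/{f.name}: " + "; ".join(notes))
        out[f.name] = CDSRecord(
            gene=f.name,
            codons=codons,
            start_codon=seq[:3],
            stop_codon=stop,
            warnings=notes,
        )
    return out


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU plus per-amino-acid usage (table 2 code)."""

    counts: dict[str, int]
    rscu: dict[str, float]
    aa_counts: dict[str, int]
    empty_families: tuple[str, ...]
    genetic_code_id: int = 2

    @property
    def aa_frequencies(self) -> dict[str, float]:
        total = sum(self.aa_counts.values())
        if total == 0:
            return {aa: 0.0 for aa in self.aa_counts}
        return {aa: n / total for aa, n in self.aa_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Codon": c,
                "AminoAcid": MITO_TABLE.forward_table.get(c, "*"),
                "Count": self.counts.get(c, 0),
                "RSCU": round(self.rscu.get(c, float("nan")), 4)
                if c in self.rscu
                else float("nan"),
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows).set_index("Codon")


def compute_rscu(counts: Mapping[str, int]) -> CodonUsageTable:
    """RSCU over the sense codons of the vertebrate mitochondrial code.

    ``counts`` maps codons (DNA alphabet) to non-negative integers; codons
    absent from the mapping count zero and stop codons are ignored.
    """
    clean: dict[str, int] = {}
    for codon, n in counts.items():
        c = codon.upper().replace("U", "T")
        if n < 0:
            raise ValueError(f"negative count for codon {c}: {n}")
        if c in MITO_TABLE.stop_codons:
            continue
        if c not in MITO_TABLE.forward_table:
            raise ValueError(f"{c!r} is not a codon of translation table 2")
        clean[c] = clean.get(c, 0) + int(n)

    rscu: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    empty: list[str] = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(clean.get(c, 0) for c in family)
        aa_counts[aa] = total
        if total == 0:
            empty.append(aa)
            for c in family:
                rscu[c] = 0.0
            continue
        k = len(family)
        for c in family:
            rscu[c] = clean.get(c, 0) * k / total
    return CodonUsageTable(
        counts={c: clean.get(c, 0) for c in SENSE_CODONS},
        rscu=rscu,
        aa_counts=aa_counts,
        empty_families=tuple(empty),
    )


def codon_counts(cds: Mapping[str, CDSRecord]) -> dict[str, int]:
    """Pooled codon counts over extracted CDS records."""
    counts: dict[str, int] = {}
    for rec in cds.values():
        for c in rec.codons:
            counts[c] = counts.get(c, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# PCG concatenation
# ---------------------------------------------------------------------------


class MissingGeneError(KeyError):
    pass


def concatenate_pcgs(
    records: Iterable[MitogenomeRecord],
    gene_order: tuple[str, ...] = PCG_NAMES,
) -> dict[str, str]:
    """Stop-stripped, fixed-order concatenation of the 13 PCGs per species.

    The canonical order is ND1..Cytb as laid out on the genome.  A missing
    PCG raises :class:`MissingGeneError` naming species and gene.
    """
    out: dict[str, str] = {}
    for record in records:
        cds = extract_cds(record)
        parts = []
        for gene in gene_order:
            if gene not in cds:
                raise MissingGeneError(
                    f"{record.species_id}: PCG {gene} missing; cannot concatenate"
                )
            parts.append(cds[gene].sequence)
        out[record.species_id] = "".join(parts)
    return out


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
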