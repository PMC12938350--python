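"""Reader/writer for tab-separated mitogenome annotation tables.

The dialect is the one used in published mitogenome feature tables:
columns ``Gene, Strand, Location, Size(bp), Intergenics Length, Anticodon,
AminoAcids, StartCodon, StopCodon``, with gene names possibly carrying
emphasis markup (``*tRNA^Leu^*``), locations written ``start–end`` with an
en-dash and optional thousands separators, and Unicode minus signs in
negative spacers.  Everything is normalized on the way in; the writer
emits a plain-ASCII version of the same layout that round-trips through
the parser.
"""

from __future__ import annotations

import re
from typing import Optional

from .records import (
    FeatureCategory,
    GeneFeature,
    MitogenomeRecord,
)

__all__ = ["parse_feature_table", "write_feature_table", "canonical_gene_name"]

# Three-letter amino-acid codes to one-letter, for tRNA features.
AA_3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_PCG_ALIASES = {
    "ND1": "ND1", "NAD1": "ND1",
    "ND2": "ND2", "NAD2": "ND2",
    "ND3": "ND3", "NAD3": "ND3",
    "ND4": "ND4", "NAD4": "ND4",
    "ND4L": "ND4L", "NAD4L": "ND4L",
    "ND5": "ND5", "NAD5": "ND5",
    "ND6": "ND6", "NAD6": "ND6",
    "COXI": "COXI", "COI": "COXI", "CO1": "COXI", "COX1": "COXI",
    "COXII": "COXII", "COII": "COXII", "CO2": "COXII", "COX2": "COXII",
    "COXIII": "COXIII", "COIII": "COXIII", "CO3": "COXIII", "COX3": "COXIII",
    "ATPASE6": "ATPase6", "ATP6": "ATPase6",
    "ATPASE8": "ATPase8", "ATP8": "ATPase8",
    "CYTB": "Cytb", "COB": "Cytb", "CYB": "Cytb",
}

_RRNA_ALIASES = {
    "12SRRNA": "12S-rRNA", "12S": "12S-rRNA", "RRNS": "12S-rRNA",
    "SRRNA": "12S-rRNA",
    "16SRRNA": "16S-rRNA", "16S": "16S-rRNA", "RRNL": "16S-rRNA",
    "LRRNA": "16S-rRNA",
}

_CONTROL_ALIASES = {"DLOOP": "D-loop", "CONTROLREGION": "D-loop", "CR": "D-loop"}
_OL_ALIASES = {"OL": "OL", "O_L": "OL", "ORIL": "OL"}

# trnF -> Phe etc., for compact tRNA labels.
_TRNA_LETTER_TO_AA3 = {v: k for k, v in AA_3TO1.items()}

_DASHES = "–—−-"  # en dash, em dash, minus sign, hyphen


class TableParseError(ValueError):
    """Raised for malformed rows or unknown gene labels."""


def _strip_markup(token: str) -> str:
    return token.replace("*", "").replace("^", "").strip()


def _normalize_int(token: str) -> int:
    token = token.strip().replace(",", "")
    for dash in "−–—":
        token = token.replace(dash, "-")
    return int(token)


def canonical_gene_name(raw: str) -> tuple[str, FeatureCategory, Optional[str]]:
    """Map a raw gene label to (canonical name, category, amino acid 1-letter).

    Accepts common aliases: ``*tRNA^Leu^*``, ``trnL``, ``nad1``, ``COI``,
    ``rrnS`` ...  An ordinal suffix used to disambiguate duplicated tRNAs
    (``tRNA-Ala-2``) is tolerated and stripped.
    """
    name = _strip_markup(raw)
    m = re.fullmatch(r"(.+?)-(\d+)", name)
    if m and m.group(1).lower().startswith("trna"):
        name = m.group(1)

    m = re.fullmatch(r"tRNA[-_ ]?([A-Za-z]{3})", name, flags=re.IGNORECASE)
    if m:
        aa3 = m.group(1).capitalize()
        if aa3 not in AA_3TO1:
            raise TableParseError(
                f"unknown tRNA amino acid {aa3!r} in label {raw!r}; "
                f"accepted: {', '.join(sorted(AA_3TO1))}"
            )
        return f"tRNA-{aa3}", FeatureCategory.TRNA, AA_3TO1[aa3]
    m = re.fullmatch(r"trn([A-Z])\d?", name)
    if m and m.group(1) in _TRNA_LETTER_TO_AA3:
        aa3 = _TRNA_LETTER_TO_AA3[m.group(1)]
        return f"tRNA-{aa3}", FeatureCategory.TRNA, m.group(1)

    key = re.sub(r"[\s\-_]", "", name).upper()
    if key in _PCG_ALIASES:
        return _PCG_ALIASES[key], FeatureCategory.PCG, None
    if key in _RRNA_ALIASES:
        return _RRNA_ALIASES[key], FeatureCategory.RRNA, None
    if key in _CONTROL_ALIASES:
        return _CONTROL_ALIASES[key], FeatureCategory.CONTROL, None
    if key in _OL_ALIASES:
        return _OL_ALIASES[key], FeatureCategory.OL, None
    accepted = sorted(
        set(_PCG_ALIASES.values())
        | set(_RRNA_ALIASES.values())
        | {"tRNA-<Aaa>", "D-loop", "OL"}
    )
    raise TableParseError(
        f"unknown gene label {raw!r}; accepted labels: {', '.join(accepted)}"
    )


_LOCATION_RE = re.compile(r"^\s*([\d,]+)\s*[%s]\s*([\d,]+)\s*$" % _DASHES)


def _parse_location(token: str, row_no: int, gene: str) -> tuple[int, int]:
    m = _LOCATION_RE.match(token)
    if not m:
        raise TableParseError(
            f"row {row_no} ({gene}): malformed Location {token!r}; "
            "expected 'start-end'"
        )
    return _normalize_int(m.group(1)), _normalize_int(m.group(2))


_HEADER_KEYS = {
    "gene": "gene",
    "strand": "strand",
    "location": "location",
    "size(bp)": "size",
    "size": "size",
    "intergenicslength": "spacer",
    "intergenics": "spacer",
    "anticodon": "anticodon",
    "aminoacids": "aa_count",
    "startcodon": "start_codon",
    "stopcodon": "stop_codon",
}


def parse_feature_table(
    text: str,
    genome_length: int,
    species_id: str,
    accession: Optional[str] = None,
    circular: bool = True,
) -> MitogenomeRecord:
    """Parse an annotation table into a :class:`MitogenomeRecord`.

    The header row is required; rows keep their printed order.  Declared
    size / spacer / amino-acid-count columns are retained verbatim so that
    :func:`mitoarch.records.validate_record` can compare them against the
    coordinate-derived values.  Duplicated gene labels (two tRNA-Ala, the
    two Leu/Ser isoacceptors) are disambiguated with an ordinal suffix in
    genomic order.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableParseError("empty table: header row required")
    header = [
        _HEADER_KEYS.get(re.sub(r"\s", "", _strip_markup(c)).lower())
        for c in lines[0].split("\t")
    ]
    if "gene" not in header or "location" not in header:
        raise TableParseError("header must contain Gene and Location columns")

    features: list[GeneFeature] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        row = {
            key: cells[i].strip()
            for i, key in enumerate(header)
            if key is not None and i < len(cells) and cells[i].strip()
        }
        if "gene" not in row:
            raise TableParseError(f"row {row_no}: missing gene label")
        name, category, aa1 = canonical_gene_name(row["gene"])
        if "location" not in row:
            raise TableParseError(f"row {row_no} ({name}): missing Location")
        start, end = _parse_location(row["location"], row_no, name)
        strand = row.get("strand", "+").replace("−", "-")
        if strand not in ("+", "-"):
            raise TableParseError(
                f"row {row_no} ({name}): bad strand {row.get('strand')!r}"
            )
        stop = row.get("stop_codon")
        if stop is not None:
            stop = stop.replace("–", "-").replace("−", "-")
        features.append(
            GeneFeature(
                name=name,
                category=category,
                strand=strand,
                start=start,
                end=end,
                wraps_origin=end < start,
                anticodon=row.get("anticodon"),
                amino_acid=aa1,
                start_codon=row.get("start_codon"),
                stop_codon=stop,
                aa_count=_normalize_int(row["aa_count"]) if "aa_count" in row else None,
                declared_size=_normalize_int(row["size"]) if "size" in row else None,
                declared_spacer=_normalize_int(row["spacer"]) if "spacer" in row else None,
            )
        )

    _disambiguate_duplicates(features)
    return MitogenomeRecord(
        species_id=species_id,
        genome_length=genome_length,
        features=features,
        circular=circular,
        accession=accession,
    )


def _disambiguate_duplicates(features: list[GeneFeature]) -> None:
    from collections import Counter

    tally = Counter(f.name for f in features)
    seen: dict[str, int] = {}
    for f in features:
        if tally[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            f.name = f"{f.name}-{seen[f.name]}"


def write_feature_table(record: MitogenomeRecord) -> str:
    """Serialize a record back to the annotation-table dialect (plain ASCII)."""
    header = (
        "Gene\tStrand\tLocation\tSize(bp)\tIntergenics Length\t"
        "Anticodon\tAminoAcids\tStartCodon\tStopCodon"
    )
    rows = [header]
    for f in record.features:
        size = f.declared_size if f.declared_size is not None else ""
        spacer = f.declared_spacer if f.declared_spacer is not None else ""
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    f.name,
                    f.strand,
                    f"{f.start}-{f.end}",
                    size,
                    spacer,
                    f.anticodon or "",
                    f.aa_count if f.aa_count is not None else "",
                    f.start_codon or "",
                    f.stop_codon or "",
                )
            )
        )
    return "\n".join(rows) + "\n"
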