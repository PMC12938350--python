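"""GenBank flat-file I/O for mitogenome records.

Thin adapter between Biopython's GenBank machinery and the package's
:class:`~mitoarch.records.MitogenomeRecord` model.  CDS features map to
PCGs, ``tRNA``/``rRNA``/``D-loop``/``rep_origin`` features to their
categories; a ``join()`` location whose parts bracket the origin becomes a
single wrapping feature.  Files without an ORIGIN block yield a
sequence-less record with a warning.
"""

from __future__ import annotations

import io
import warnings
from typing import Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    CompoundLocation,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .feature_table import canonical_gene_name, _disambiguate_duplicates
from .records import FeatureCategory, GeneFeature, MitogenomeRecord

__all__ = ["read_genbank", "write_genbank"]

_TYPE_CATEGORY = {
    "CDS": FeatureCategory.PCG,
    "tRNA": FeatureCategory.TRNA,
    "rRNA": FeatureCategory.RRNA,
    "D-loop": FeatureCategory.CONTROL,
    "misc_feature": None,
    "rep_origin": FeatureCategory.OL,
}


def _feature_name(feat) -> Optional[str]:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    if feat.type == "D-loop":
        return "D-loop"
    if feat.type == "rep_origin":
        return "OL"
    return None


def read_genbank(source: Union[str, TextIO]) -> MitogenomeRecord:
    """Read a GenBank flat file into a :class:`MitogenomeRecord`.

    ``source`` may be a path or an open text handle.
    """
    handle = open(source) if isinstance(source, str) else source
    try:
        seqrec = SeqIO.read(handle, "genbank")
    finally:
        if isinstance(source, str):
            handle.close()

    try:
        sequence: Optional[str] = str(seqrec.seq).upper()
        if sequence and set(sequence) == {"N"}:  # undefined contig sequence
            sequence = None
    except Exception:
        sequence = None
    length = len(seqrec.seq) if seqrec.seq is not None else None
    if length in (None, 0):
        length = int(seqrec.annotations.get("source_length", 0)) or None
    if sequence is None:
        warnings.warn(
            f"{seqrec.id}: no ORIGIN sequence; returning sequence-less record"
        )

    features: list[GeneFeature] = []
    for feat in seqrec.features:
        category = _TYPE_CATEGORY.get(feat.type)
        if category is None:
            continue
        raw = _feature_name(feat)
        if raw is None:
            continue
        try:
            name, cat2, aa1 = canonical_gene_name(raw)
        except ValueError:
            continue
        # The annotated feature type wins over what the label suggests.
        if cat2 is not category and category in (
            FeatureCategory.CONTROL,
            FeatureCategory.OL,
        ):
            name, aa1 = raw, None
            cat2 = category
        loc = feat.location
        wraps = False
        if isinstance(loc, CompoundLocation) and length is not None:
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # join(n..L, 1..m): two parts bracketing the circular origin
            if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
                start, end, wraps = int(parts[1].start) + 1, int(parts[0].end), True
            else:
                start, end = int(loc.start) + 1, int(loc.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        anticodon = feat.qualifiers.get("anticodon", [None])[0]
        if anticodon and "(" in anticodon:  # e.g. "(pos:...,aa:Phe,seq:gaa)"
            import re

            m = re.search(r"seq:([a-zA-Z]{3})", anticodon)
            anticodon = m.group(1).upper() if m else None
        aa_count = None
        if "translation" in feat.qualifiers:
            aa_count = len(feat.qualifiers["translation"][0])
        features.append(
            GeneFeature(
                name=name,
                category=cat2,
                strand="-" if loc.strand == -1 else "+",
                start=start,
                end=end,
                wraps_origin=wraps,
                anticodon=anticodon.upper() if anticodon else None,
                amino_acid=aa1,
                aa_count=aa_count,
            )
        )

    features.sort(key=lambda f: f.start)
    _disambiguate_duplicates(features)
    topology = seqrec.annotations.get("topology", "circular")
    return MitogenomeRecord(
        species_id=seqrec.annotations.get("organism", seqrec.id) or seqrec.id,
        genome_length=length if length else len(sequence or ""),
        features=features,
        circular=topology == "circular",
        accession=seqrec.id,
        sequence=sequence,
    )


_CATEGORY_TYPE = {
    FeatureCategory.PCG: "CDS",
    FeatureCategory.TRNA: "tRNA",
    FeatureCategory.RRNA: "rRNA",
    FeatureCategory.CONTROL: "D-loop",
    FeatureCategory.OL: "rep_origin",
}


def write_genbank(record: MitogenomeRecord, target: Union[str, TextIO]) -> None:
    """Write a sequenced record as a GenBank flat file."""
    if record.sequence is None:
        raise ValueError(f"{record.species_id}: cannot write GenBank without sequence")
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession or record.species_id.replace(" ", "_")[:16],
        name=(record.accession or "MITOGENOME")[:16],
        description=f"{record.species_id} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
            "organism": record.species_id,
        },
    )
    L = record.genome_length
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers: dict = {"gene": [f.name]}
        if f.anticodon:
            qualifiers["anticodon"] = [f.anticodon]
        sf = SeqFeature(loc, type=_CATEGORY_TYPE[f.category], qualifiers=qualifiers)
        seqrec.features.append(sf)
    if isinstance(target, str):
        with open(target, "w") as fh:
            SeqIO.write(seqrec, fh, "genbank")
    else:
        SeqIO.write(seqrec, target, "genbank")


def roundtrip(record: MitogenomeRecord) -> MitogenomeRecord:
    """write -> read, used to exercise GenBank identity in tests."""
    buf = io.StringIO()
    write_genbank(record, buf)
    buf.seek(0)
    return read_genbank(buf)
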