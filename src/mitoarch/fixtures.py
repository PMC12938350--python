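"""Packaged study fixtures: two Yellow Sea snailfish mitogenomes.

The package ships the published annotation tables (coordinates only, no
sequence) of the *Liparis chefuensis* (18,870 bp, 37 genes, WYANC
cluster) and *Liparis tanakae* (17,485 bp, 38 genes with a duplicated
tRNA-Ala, WNCYAA cluster) mitochondrial genomes, their per-region base
composition summaries, the 16-taxon Liparidae phylogeny inferred from the
13 concatenated PCGs, and the per-species tRNA-cluster pattern and
habitat-depth character maps.  Printed values are kept verbatim --
including the handful of internal inconsistencies in the *L. chefuensis*
table that :func:`mitoarch.records.validate_record` is designed to flag.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .feature_table import parse_feature_table
from .records import MitogenomeRecord

__all__ = [
    "chefuensis_record",
    "tanakae_record",
    "composition_table",
    "liparidae_newick",
    "pattern_map",
    "depth_map",
    "study_fixtures",
    "GENOME_LENGTHS",
]

GENOME_LENGTHS = {
    "Liparis_chefuensis": 18870,
    "Liparis_tanakae": 17485,
}

ACCESSIONS = {
    "Liparis_chefuensis": "PX718959",
    "Liparis_tanakae": "PX718960",
}


def _read_text(name: str) -> str:
    return (resources.files("mitoarch") / "data" / name).read_text()


def chefuensis_record() -> MitogenomeRecord:
    """The shallow-water *L. chefuensis* mitogenome (coordinates only)."""
    return parse_feature_table(
        _read_text("liparis_chefuensis.features.tsv"),
        genome_length=GENOME_LENGTHS["Liparis_chefuensis"],
        species_id="Liparis_chefuensis",
        accession=ACCESSIONS["Liparis_chefuensis"],
    )


def tanakae_record() -> MitogenomeRecord:
    """The deep-water *L. tanakae* mitogenome (coordinates only)."""
    return parse_feature_table(
        _read_text("liparis_tanakae.features.tsv"),
        genome_length=GENOME_LENGTHS["Liparis_tanakae"],
        species_id="Liparis_tanakae",
        accession=ACCESSIONS["Liparis_tanakae"],
    )


def composition_table(species: str) -> pd.DataFrame:
    """Published per-region base composition (percent) and skews.

    Rows: PCGs, rRNA, tRNA, Control region, Genome.  Columns as printed:
    ``T% C% A% G% AT% GC Skew AT Skew`` (the skews are unitless ratios).
    """
    key = species if species in GENOME_LENGTHS else f"Liparis_{species}"
    if key not in GENOME_LENGTHS:
        raise KeyError(f"unknown species {species!r}")
    name = key.lower() + ".composition.tsv"
    text = _read_text(name)
    rows = []
    for line in text.splitlines()[1:]:
        cells = line.split("\t")
        rows.append(
            {
                "Region": cells[0],
                "T%": float(cells[1]),
                "C%": float(cells[2]),
                "A%": float(cells[3]),
                "G%": float(cells[4]),
                "AT%": float(cells[5]),
                "GC Skew": float(cells[6].replace("−", "-")),
                "AT Skew": float(cells[7].replace("−", "-")),
            }
        )
    return pd.DataFrame(rows).set_index("Region")


def liparidae_newick() -> str:
    """Newick topology of the 16-taxon PCG phylogeny (outgroup: Cottus)."""
    return _read_text("liparidae_pcg.nwk").strip()


def _two_column_map(name: str) -> dict[str, str]:
    lines = _read_text(name).splitlines()
    return {
        row.split("\t")[0]: row.split("\t")[1]
        for row in lines[1:]
        if row.strip()
    }


def pattern_map() -> dict[str, str]:
    """tRNA-cluster pattern per tree tip (all 16 taxa)."""
    return _two_column_map("cluster_patterns.tsv")


def depth_map() -> dict[str, str]:
    """Habitat-depth class per *Liparis* tip: shallow (<30 m) or deep
    (>100 m; intermediate depths would map by the 100 m threshold)."""
    return _two_column_map("depth_classes.tsv")


def study_fixtures() -> dict:
    """Everything at once: records, character maps, and the topology."""
    return {
        "records": {
            "Liparis_chefuensis": chefuensis_record(),
            "Liparis_tanakae": tanakae_record(),
        },
        "pattern_map": pattern_map(),
        "depth_map": depth_map(),
        "newick": liparidae_newick(),
    }
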