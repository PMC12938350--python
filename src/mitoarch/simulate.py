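"""Synthetic mitogenome generator with known ground truth.

Generates fully annotated, sequenced circular mitogenomes that look like
a vertebrate (snailfish-like) mitochondrial genome: 13 PCGs with realistic
sizes and incomplete stop codons, 2 rRNAs, 22-23 tRNAs with cloverleaf
secondary structures carrying a controlled number of G-U and A-C pairs, a
configurable ND2-COI tRNA cluster order, an O_L and a control region that
absorbs the remaining length.  Every quantity the analysis pipeline is
supposed to recover (base counts per region, cluster pattern, amino-acid
counts, planted pair counts) is written to a ground-truth ledger holding
*realized* values, so recovery tests can be exact.

Randomness: a single integer seed drives one ``numpy`` generator; draws
occur in a fixed order (PCG codon pool, rRNAs, tRNAs in genomic order,
O_L, control region), so output is byte-stable for a given seed and
package version.  Base composition is realized by balanced sampling --
the base/codon multiset matches the target proportions up to integer
rounding and only its arrangement is random -- so recovered composition
differs from the target by O(1/length), not by binomial noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codons import SENSE_CODONS, amino_acid_length, stop_length
from .feature_table import AA_3TO1, write_feature_table
from .records import (
    FeatureCategory,
    GeneFeature,
    MitogenomeRecord,
    STANDARD_ANTICODONS,
    reverse_complement,
)

__all__ = [
    "GeneratorSpec",
    "generate_record",
    "generate_labeled_tree",
    "write_outputs",
    "InfeasibleSpecError",
]


class InfeasibleSpecError(ValueError):
    pass


#: Per-region base composition targets (T, C, A, G), defaults taken from
#: the measured composition of a shallow-water snailfish mitogenome.
DEFAULT_COMPOSITION: dict[str, tuple[float, float, float, float]] = {
    "PCGs": (0.3308, 0.2661, 0.2595, 0.1437),
    "rRNA": (0.2277, 0.2474, 0.3326, 0.1923),
    "tRNA": (0.2841, 0.2021, 0.2957, 0.2182),
    "control": (0.3194, 0.1371, 0.4325, 0.1110),
}

#: PCG sizes (bp) and stop-codon classes typical of the family; all sizes
#: are frame-consistent with their stop class.
DEFAULT_PCGS: dict[str, tuple[int, str, str]] = {
    # name: (size, start codon, stop token)
    "ND1": (975, "ATG", "TAA"),
    "ND2": (1046, "ATG", "TA-"),
    "COXI": (1545, "GTG", "TAA"),
    "COXII": (691, "ATG", "T-"),
    "ATPase8": (168, "ATG", "TAA"),
    "ATPase6": (683, "ATG", "TA-"),
    "COXIII": (785, "ATG", "TA-"),
    "ND3": (349, "ATG", "T-"),
    "ND4L": (297, "ATG", "TAA"),
    "ND4": (1381, "ATG", "T-"),
    "ND5": (1839, "ATG", "TAA"),
    "ND6": (522, "ATG", "TAA"),
    "Cytb": (1141, "ATG", "T-"),
}

_CLUSTER_AA3 = {"W": "Trp", "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr"}

_RRNA_SIZES = {"12S-rRNA": 944, "16S-rRNA": 1688}
_OL_LENGTH = 37
_STEM_PAIRS = 21  # 7 acceptor + 4 D + 5 anticodon + 5 T


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic mitogenome.

    ``composition`` proportions are per region in (T, C, A, G) order and
    are normalized to sum to 1.  ``gu_per_trna`` / ``ac_per_trna`` plant
    that many G-U wobble and A-C pairs in each tRNA's 21 stem pairs.
    ``codon_bias`` > 1 sharpens within-family synonymous codon preference,
    < 1 flattens it (1 = composition-driven only).
    """

    seed: int = 0
    genome_length: int = 17000
    cluster_pattern: str = "WANCY"
    composition: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    codon_bias: float = 1.0
    gu_per_trna: int = 1
    ac_per_trna: int = 0
    pcgs: dict[str, tuple[int, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_PCGS)
    )
    species_id: str = "synthetic"

    def __post_init__(self):
        self.cluster_pattern = self.cluster_pattern.upper()
        bad = set(self.cluster_pattern) - set(_CLUSTER_AA3)
        if bad:
            raise InfeasibleSpecError(
                f"cluster letters {sorted(bad)} outside {sorted(_CLUSTER_AA3)}"
            )
        if not self.cluster_pattern:
            raise InfeasibleSpecError("cluster pattern must not be empty")
        if self.gu_per_trna + self.ac_per_trna > _STEM_PAIRS:
            raise InfeasibleSpecError(
                f"{self.gu_per_trna} G-U + {self.ac_per_trna} A-C pairs exceed "
                f"{_STEM_PAIRS} stem pairs"
            )
        norm = {}
        for region, props in self.composition.items():
            arr = np.asarray(props, dtype=float)
            if arr.min() < 0 or arr.sum() <= 0:
                raise InfeasibleSpecError(f"bad composition for {region}: {props}")
            if abs(arr.sum() - 1.0) > 0.05:
                raise InfeasibleSpecError(
                    f"{region} proportions sum to {arr.sum():.3f}, expected ~1"
                )
            norm[region] = tuple(arr / arr.sum())
        self.composition = norm
        for name, (size, start, stop) in self.pcgs.items():
            amino_acid_length(size, stop)  # raises if frame-inconsistent

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome_length": self.genome_length,
            "cluster_pattern": self.cluster_pattern,
            "composition": {k: list(v) for k, v in self.composition.items()},
            "codon_bias": self.codon_bias,
            "gu_per_trna": self.gu_per_trna,
            "ac_per_trna": self.ac_per_trna,
            "species_id": self.species_id,
        }


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _balanced_multiset(items: Sequence[str], probs: np.ndarray, n: int, rng) -> list[str]:
    """A shuffled multiset of ``n`` items whose counts match ``probs`` up to
    integer rounding (largest-remainder; leftover units assigned at random
    proportionally to the remainders)."""
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    base = np.floor(probs * n).astype(int)
    rem = int(n - base.sum())
    if rem > 0:
        frac = probs * n - base
        frac = np.where(frac > 0, frac, 0.0)
        extra = rng.choice(len(items), size=rem, replace=False, p=frac / frac.sum())
        base[extra] += 1
    pool = np.repeat(np.arange(len(items)), base)
    rng.shuffle(pool)
    return [items[int(k)] for k in pool]


def _codon_distribution(
    props: tuple[float, float, float, float], bias: float
) -> dict[str, float]:
    """Sense-codon distribution whose pooled base marginal matches the
    target composition (iterative proportional fitting), optionally tilted
    within synonymous families by ``bias``."""
    target = dict(zip("TCAG", props))
    w = dict(target)
    q: dict[str, float] = {}
    for _ in range(500):
        q = {c: w[c[0]] * w[c[1]] * w[c[2]] for c in SENSE_CODONS}
        z = sum(q.values())
        q = {c: v / z for c, v in q.items()}
        marginal = {b: 0.0 for b in "TCAG"}
        for c, v in q.items():
            for b in c:
                marginal[b] += v / 3.0
        if max(abs(marginal[b] - target[b]) for b in "TCAG") < 1e-10:
            break
        for b in "TCAG":
            if marginal[b] > 0 and target[b] > 0:
                w[b] *= (target[b] / marginal[b]) ** 0.8
            elif target[b] == 0:
                w[b] = 0.0
    if bias != 1.0:
        from .codons import SYNONYMOUS_FAMILIES

        tilted = dict(q)
        for family in SYNONYMOUS_FAMILIES.values():
            mass = sum(q[c] for c in family)
            raised = {c: q[c] ** bias for c in family}
            z = sum(raised.values())
            if z > 0:
                for c in family:
                    tilted[c] = raised[c] / z * mass
        q = tilted
    return q


# ---------------------------------------------------------------------------
# tRNA construction
# ---------------------------------------------------------------------------


def _build_trna(
    anticodon: str,
    comp: tuple[float, float, float, float],
    n_gu: int,
    n_ac: int,
    rng,
) -> tuple[str, str, dict[str, int]]:
    """One cloverleaf tRNA: (DNA sequence, dot-bracket, planted pair counts).

    Stems: acceptor 7 bp, D 4 bp, anticodon 5 bp, T 5 bp (21 pairs); loop
    lengths vary a little so genes span roughly 70-74 bp.  ``n_gu`` G-U and
    ``n_ac`` A-C pairs are planted at random stem positions, the rest are
    Watson-Crick with identity drawn from the composition target.
    """
    d_loop = 7 + int(rng.integers(0, 3))
    var = 3 + int(rng.integers(0, 3))
    segments = [
        ("acc5", 7), ("link1", 2), ("d5", 4), ("dloop", d_loop), ("d3", 4),
        ("link2", 1), ("ac5", 5), ("acl1", 2), ("anticodon", 3), ("acl2", 2),
        ("ac3", 5), ("var", var), ("t5", 5), ("tloop", 7), ("t3", 5),
        ("acc3", 7), ("disc", 1),
    ]
    offset, pos = {}, 0
    for name, ln in segments:
        offset[name] = pos
        pos += ln
    total = pos

    pairs: list[tuple[int, int]] = []  # 0-based
    for five, three, ln in (
        ("acc5", "acc3", 7), ("d5", "d3", 4), ("ac5", "ac3", 5), ("t5", "t3", 5)
    ):
        for k in range(ln):
            pairs.append((offset[five] + k, offset[three] + ln - 1 - k))

    special = rng.choice(_STEM_PAIRS, size=n_gu + n_ac, replace=False)
    gu_slots = set(int(x) for x in special[:n_gu])
    ac_slots = set(int(x) for x in special[n_gu:])

    t, c, a, g = comp
    wc_pairs = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
    wc_w = np.array([a * t, t * a, g * c, c * g], dtype=float)
    wc_w = wc_w / wc_w.sum()

    seq = [""] * total
    for slot, (i, j) in enumerate(pairs):
        if slot in gu_slots:
            x, y = ("G", "T") if rng.random() < 0.5 else ("T", "G")
        elif slot in ac_slots:
            x, y = ("A", "C") if rng.random() < 0.5 else ("C", "A")
        else:
            x, y = wc_pairs[int(rng.choice(4, p=wc_w))]
        seq[i], seq[j] = x, y

    bases = np.array(list("TCAG"))
    comp_arr = np.asarray(comp)
    for k in range(total):
        if not seq[k]:
            seq[k] = str(rng.choice(bases, p=comp_arr))
    ac_off = offset["anticodon"]
    seq[ac_off:ac_off + 3] = list(anticodon)

    db = ["."] * total
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    counts = {
        "watson_crick": _STEM_PAIRS - n_gu - n_ac,
        "g_u": n_gu,
        "a_c": n_ac,
        "other": 0,
    }
    return "".join(seq), "".join(db), counts


# ---------------------------------------------------------------------------
# record generation
# ---------------------------------------------------------------------------


def _gene_layout(pattern: str) -> list[tuple[str, str, str, Optional[str]]]:
    """(name, kind, strand, anticodon) in genomic order."""
    lay: list[tuple[str, str, str, Optional[str]]] = [
        ("tRNA-Phe", "tRNA", "+", "GAA"),
        ("12S-rRNA", "rRNA", "+", None),
        ("tRNA-Val", "tRNA", "+", "TAC"),
        ("16S-rRNA", "rRNA", "+", None),
        ("tRNA-Leu", "tRNA", "+", "TAA"),
        ("ND1", "PCG", "+", None),
        ("tRNA-Ile", "tRNA", "+", "GAT"),
        ("tRNA-Gln", "tRNA", "-", "TTG"),
        ("tRNA-Met", "tRNA", "+", "CAT"),
        ("ND2", "PCG", "+", None),
    ]
    ol_placed = False
    for letter in pattern:
        aa3 = _CLUSTER_AA3[letter]
        strand = "+" if letter == "W" else "-"
        anticodon = sorted(STANDARD_ANTICODONS[aa3])[0]
        lay.append((f"tRNA-{aa3}", "tRNA", strand, anticodon))
        if letter == "N" and not ol_placed:
            lay.append(("OL", "OL", "+", None))
            ol_placed = True
    if not ol_placed:
        lay.append(("OL", "OL", "+", None))
    lay += [
        ("COXI", "PCG", "+", None),
        ("tRNA-Ser", "tRNA", "-", "TGA"),
        ("tRNA-Asp", "tRNA", "+", "GTC"),
        ("COXII", "PCG", "+", None),
        ("tRNA-Lys", "tRNA", "+", "TTT"),
        ("ATPase8", "PCG", "+", None),
        ("ATPase6", "PCG", "+", None),
        ("COXIII", "PCG", "+", None),
        ("tRNA-Gly", "tRNA", "+", "TCC"),
        ("ND3", "PCG", "+", None),
        ("tRNA-Arg", "tRNA", "+", "TCG"),
        ("ND4L", "PCG", "+", None),
        ("ND4", "PCG", "+", None),
        ("tRNA-His", "tRNA", "+", "GTG"),
        ("tRNA-Ser", "tRNA", "+", "GCT"),
        ("tRNA-Leu", "tRNA", "+", "TAG"),
        ("ND5", "PCG", "+", None),
        ("ND6", "PCG", "-", None),
        ("tRNA-Glu", "tRNA", "-", "TTC"),
        ("Cytb", "PCG", "+", None),
        ("tRNA-Thr", "tRNA", "+", "TGT"),
        ("tRNA-Pro", "tRNA", "-", "TGG"),
        ("D-loop", "control", "+", None),
    ]
    return lay


def generate_record(spec: GeneratorSpec) -> tuple[MitogenomeRecord, dict]:
    """Generate one annotated, sequenced mitogenome plus its ground truth.

    Returns ``(record, ledger)``.  The ledger's ``composition`` block holds
    realized per-region base counts (strand-oriented, matching the
    convention of :func:`mitoarch.composition.region_composition`), so
    pipeline-recovery comparisons can be exact.
    """
    rng = np.random.default_rng(spec.seed)
    layout = _gene_layout(spec.cluster_pattern)

    # 1. PCG codon pool (balanced sampling from the IPF-fitted distribution)
    q = _codon_distribution(spec.composition["PCGs"], spec.codon_bias)
    codon_items = sorted(q)
    codon_probs = np.array([q[c] for c in codon_items])
    pcg_aa = {
        name: amino_acid_length(size, stop)
        for name, (size, start, stop) in spec.pcgs.items()
    }
    n_inner = sum(aa - 1 for aa in pcg_aa.values())
    pool = _balanced_multiset(codon_items, codon_probs, n_inner, rng)

    pcg_seqs: dict[str, str] = {}
    cursor = 0
    for name, kind, strand, _ in layout:
        if kind != "PCG":
            continue
        size, start, stop = spec.pcgs[name]
        aa = pcg_aa[name]
        inner = pool[cursor:cursor + (aa - 1)]
        cursor += aa - 1
        pcg_seqs[name] = start + "".join(inner) + stop.rstrip("-")
        if len(pcg_seqs[name]) != size:
            raise AssertionError("PCG assembly length mismatch")

    # 2. rRNAs
    rrna_seqs = {
        name: "".join(
            _balanced_multiset(list("TCAG"), np.asarray(spec.composition["rRNA"]), ln, rng)
        )
        for name, ln in _RRNA_SIZES.items()
    }

    # 3. tRNAs (genomic order), 4. O_L, 5. control region
    trna_seqs: list[tuple[int, str, str, dict]] = []  # (layout idx, seq, db, counts)
    for idx, (name, kind, strand, anticodon) in enumerate(layout):
        if kind != "tRNA":
            continue
        seq, db, counts = _build_trna(
            anticodon, spec.composition["tRNA"], spec.gu_per_trna,
            spec.ac_per_trna, rng,
        )
        trna_seqs.append((idx, seq, db, counts))
    trna_by_idx = {idx: (seq, db, counts) for idx, seq, db, counts in trna_seqs}

    ol_seq = "".join(
        _balanced_multiset(
            list("TCAG"), np.asarray(spec.composition["control"]), _OL_LENGTH, rng
        )
    )

    fixed_total = (
        sum(size for size, _, _ in spec.pcgs.values())
        + sum(_RRNA_SIZES.values())
        + sum(len(s) for _, s, _, _ in trna_seqs)
        + _OL_LENGTH
    )
    control_len = spec.genome_length - fixed_total
    if control_len < 100:
        raise InfeasibleSpecError(
            f"genome_length {spec.genome_length} leaves only {control_len} bp "
            "for the control region (need >= 100)"
        )
    control_seq = "".join(
        _balanced_multiset(
            list("TCAG"), np.asarray(spec.composition["control"]), control_len, rng
        )
    )

    # assemble heavy strand and features
    features: list[GeneFeature] = []
    heavy_parts: list[str] = []
    pos = 0
    trna_records: list[tuple[str, str, str, dict]] = []  # name, seq, db, counts
    for idx, (name, kind, strand, anticodon) in enumerate(layout):
        if kind == "PCG":
            functional = pcg_seqs[name]
        elif kind == "rRNA":
            functional = rrna_seqs[name]
        elif kind == "tRNA":
            functional = trna_by_idx[idx][0]
        elif kind == "OL":
            functional = ol_seq
        else:
            functional = control_seq
        heavy = reverse_complement(functional) if strand == "-" else functional
        start_pos, end_pos = pos + 1, pos + len(functional)
        pos = end_pos
        heavy_parts.append(heavy)
        category = {
            "PCG": FeatureCategory.PCG,
            "tRNA": FeatureCategory.TRNA,
            "rRNA": FeatureCategory.RRNA,
            "OL": FeatureCategory.OL,
            "control": FeatureCategory.CONTROL,
        }[kind]
        kwargs: dict = {}
        if kind == "PCG":
            size, start_codon, stop = spec.pcgs[name]
            kwargs = {
                "start_codon": start_codon,
                "stop_codon": stop,
                "aa_count": pcg_aa[name],
            }
        elif kind == "tRNA":
            aa3 = name.split("-", 1)[1]
            kwargs = {"anticodon": anticodon, "amino_acid": AA_3TO1[aa3]}
        feature = GeneFeature(
            name=name,
            category=category,
            strand=strand,
            start=start_pos,
            end=end_pos,
            declared_size=len(functional),
            declared_spacer=0 if idx < len(layout) - 1 else None,
            **kwargs,
        )
        features.append(feature)
        if kind == "tRNA":
            trna_records.append((name, functional, trna_by_idx[idx][1], trna_by_idx[idx][2]))

    from .feature_table import _disambiguate_duplicates

    _disambiguate_duplicates(features)
    # mirror the disambiguated names onto the structure ledger entries
    trna_names = [f.name for f in features if f.category is FeatureCategory.TRNA]
    assert len(trna_names) == len(trna_records)

    sequence = "".join(heavy_parts)
    if len(sequence) != spec.genome_length:
        raise AssertionError("assembled genome length mismatch")
    record = MitogenomeRecord(
        species_id=spec.species_id,
        genome_length=spec.genome_length,
        features=features,
        circular=True,
        sequence=sequence,
    )

    def _counts(seqs: list[str]) -> dict[str, int]:
        tally = {b: 0 for b in "TCAG"}
        for s in seqs:
            for b in s:
                tally[b] = tally.get(b, 0) + 1
        return tally

    structures = {
        uniq: {"sequence": seq, "dot_bracket": db, "pairs": counts}
        for uniq, (name, seq, db, counts) in zip(trna_names, trna_records)
    }
    pair_totals = {
        key: sum(s["pairs"][key] for s in structures.values())
        for key in ("watson_crick", "g_u", "a_c", "other")
    }
    ledger = {
        "spec": spec.to_dict(),
        "pattern": spec.cluster_pattern,
        "genome_length": spec.genome_length,
        "gene_counts": record.gene_counts(),
        "composition": {
            "PCGs": _counts(list(pcg_seqs.values())),
            "rRNA": _counts(list(rrna_seqs.values())),
            "tRNA": _counts([seq for _, seq, _, _ in trna_records]),
            "control": _counts([control_seq]),
            "genome": _counts([sequence]),
        },
        "pcg": {
            name: {
                "aa_count": pcg_aa[name],
                "start_codon": spec.pcgs[name][1],
                "stop_codon": spec.pcgs[name][2],
                "size": spec.pcgs[name][0],
            }
            for name in spec.pcgs
        },
        "trna_structures": structures,
        "pair_totals": pair_totals,
    }
    return record, ledger


# ---------------------------------------------------------------------------
# labeled random trees
# ---------------------------------------------------------------------------


def generate_labeled_tree(
    n_tips: int,
    states: Sequence[str],
    clustering: str = "clustered",
    seed: int = 0,
):
    """Random rooted tree plus a categorical tip character.

    ``clustering='clustered'`` assigns states clade-wise: tips are split
    into one clade per state and the clades are joined caterpillar-style,
    so the character needs exactly ``len(states) - 1`` changes.
    ``'random'`` assigns states to tips independently and uniformly.
    Returns ``(dendropy.Tree, {tip: state})``.
    """
    from .phylo import parse_newick

    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    states = list(states)
    if len(states) > n_tips:
        raise ValueError(f"{len(states)} states for {n_tips} tips")
    if clustering not in ("clustered", "random"):
        raise ValueError("clustering must be 'clustered' or 'random'")
    rng = np.random.default_rng(seed)
    tips = [f"t{i + 1:02d}" for i in range(n_tips)]

    def subtree(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return leaves[0]
        k = int(rng.integers(1, len(leaves)))
        return f"({subtree(leaves[:k])},{subtree(leaves[k:])})"

    char_map: dict[str, str] = {}
    if clustering == "clustered":
        blocks = [list(b) for b in np.array_split(np.array(tips), len(states))]
        for state, block in zip(states, blocks):
            for tip in block:
                char_map[tip] = state
        newick = subtree(blocks[0])
        for block in blocks[1:]:
            newick = f"({newick},{subtree(block)})"
        newick += ";"
    else:
        shuffled = list(tips)
        rng.shuffle(shuffled)
        newick = subtree(shuffled) + ";"
        for tip in tips:
            char_map[tip] = states[int(rng.integers(0, len(states)))]
    return parse_newick(newick), char_map


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_outputs(record: MitogenomeRecord, ledger: dict, outdir) -> dict[str, str]:
    """Write FASTA + feature table + dot-bracket structures + ledger JSON.

    Returns the mapping of logical name to file path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / f"{record.species_id}.fa",
        "table": outdir / f"{record.species_id}.features.tsv",
        "structures": outdir / f"{record.species_id}.structures.db",
        "ledger": outdir / f"{record.species_id}.ledger.json",
        "record": outdir / f"{record.species_id}.record.json",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{record.species_id}\n")
        for i in range(0, len(record.sequence), 70):
            fh.write(record.sequence[i:i + 70] + "\n")
    with open(paths["table"], "w") as fh:
        fh.write(write_feature_table(record))
    with open(paths["structures"], "w") as fh:
        for name, entry in ledger["trna_structures"].items():
            fh.write(f">{name}\n{entry['sequence']}\n{entry['dot_bracket']}\n")
    with open(paths["ledger"], "w") as fh:
        json.dump(ledger, fh, indent=2)
    record.save(paths["record"])
    return {k: str(v) for k, v in paths.items()}
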