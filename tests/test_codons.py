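"""Codon accounting, incomplete stops, RSCU, PCG concatenation."""

import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from mitoarch.codons import (
    FrameInconsistencyError,
    MissingGeneError,
    amino_acid_length,
    codon_counts,
    compute_rscu,
    concatenate_pcgs,
    extract_cds,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
)
from mitoarch.records import FeatureCategory, GeneFeature, MitogenomeRecord


class TestAminoAcidLength:
    @pytest.mark.parametrize(
        "size,stop,expected",
        [
            (1046, "TA-", 348),  # ND2
            (1141, "T-", 380),   # Cytb
            (975, "TAA", 324),   # ND1
            (1137, "AGA", 378),  # complete AGA stop
        ],
    )
    def test_published_gene_sizes(self, size, stop, expected):
        assert amino_acid_length(size, stop) == expected

    def test_frame_inconsistency_surfaces(self):
        # 1382 bp with a 1-nt stop leaves 1381 nt: not a codon multiple
        with pytest.raises(FrameInconsistencyError):
            amino_acid_length(1382, "T-")

    def test_unknown_stop_token(self):
        with pytest.raises(ValueError, match="accepted"):
            amino_acid_length(100, "TGA")

    def test_inverse_of_generator_construction(self, synthetic_wncyaa):
        rec, ledger = synthetic_wncyaa
        for f in rec.by_category(FeatureCategory.PCG):
            size = f.end - f.start + 1
            assert amino_acid_length(size, f.stop_codon) == f.aa_count


def _pcg_record(cds_heavy, strand="+", name="ND1", stop=None):
    return MitogenomeRecord(
        species_id="toy",
        genome_length=len(cds_heavy),
        sequence=cds_heavy,
        features=[
            GeneFeature(name, FeatureCategory.PCG, strand, 1, len(cds_heavy),
                        stop_codon=stop)
        ],
    )


class TestExtractCds:
    def test_minimal_gene_atg_taa(self):
        cds = extract_cds(_pcg_record("ATGTAA"))
        assert cds["ND1"].codons == ["ATG"]
        assert cds["ND1"].stop_codon == "TAA"

    def test_minus_strand_codons_from_reverse_complement(self):
        # functional CDS ATG AAA TGC TAA placed on the light strand
        functional = "ATGAAATGCTAA"
        heavy = str(Seq(functional).reverse_complement())
        cds = extract_cds(_pcg_record(heavy, strand="-"))
        assert cds["ND1"].codons == ["ATG", "AAA", "TGC"]
        assert cds["ND1"].translate() == "MKC"

    def test_incomplete_stop_completed_and_stripped(self):
        cds = extract_cds(_pcg_record("ATGAAATA", stop="TA-"))
        assert cds["ND1"].codons == ["ATG", "AAA"]
        assert cds["ND1"].stop_codon == "TA-"

    def test_internal_stop_warns_with_position(self):
        with pytest.warns(UserWarning, match="internal stop.*codon 2"):
            extract_cds(_pcg_record("ATGAGAAAATAA"))

    def test_generator_bookkeeping_oracle(self, synthetic_wncyaa):
        rec, ledger = synthetic_wncyaa
        cds = extract_cds(rec)
        for gene, truth in ledger["pcg"].items():
            assert len(cds[gene].codons) == truth["aa_count"]
            assert cds[gene].start_codon == truth["start_codon"]
            assert cds[gene].stop_codon == truth["stop_codon"]
            # no internal stops in generator output under table 2
            assert cds[gene].warnings == []


class TestRscu:
    def test_equal_counts_fourfold_family(self):
        counts = {c: 5 for c in SYNONYMOUS_FAMILIES["A"]}  # GCx, 4-fold
        table = compute_rscu(counts)
        for c in SYNONYMOUS_FAMILIES["A"]:
            assert table.rscu[c] == pytest.approx(1.0)

    def test_twofold_all_or_nothing(self):
        fam = SYNONYMOUS_FAMILIES["C"]  # TGT/TGC
        table = compute_rscu({fam[0]: 10, fam[1]: 0})
        assert table.rscu[fam[0]] == pytest.approx(2.0)
        assert table.rscu[fam[1]] == 0.0

    def test_met_family_is_atg_ata(self):
        assert set(SYNONYMOUS_FAMILIES["M"]) == {"ATG", "ATA"}
        assert set(SYNONYMOUS_FAMILIES["W"]) >= {"TGA"}  # TGA = Trp in table 2

    def test_stop_codons_excluded(self):
        table = compute_rscu({"TAA": 50, "AGA": 10, "ATG": 3})
        assert "TAA" not in table.rscu and "AGA" not in table.rscu

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            compute_rscu({"ATG": -1})

    @given(st.lists(st.integers(0, 40), min_size=60, max_size=60))
    def test_matches_direct_formula_oracle(self, values):
        counts = dict(zip(SENSE_CODONS, values))
        table = compute_rscu(counts)
        # independent recomputation: translate each codon with Biopython and
        # apply the definition family by family
        by_aa = {}
        for codon, n in counts.items():
            aa = str(Seq(codon).translate(table=2))
            by_aa.setdefault(aa, []).append((codon, n))
        for aa, members in by_aa.items():
            total = sum(n for _, n in members)
            for codon, n in members:
                expected = 0.0 if total == 0 else n * len(members) / total
                assert table.rscu[codon] == pytest.approx(expected)
            if total > 0:
                mean = sum(table.rscu[c] for c, _ in members) / len(members)
                assert mean == pytest.approx(1.0)

    @given(st.integers(1, 50))
    def test_scale_invariance(self, k):
        base = {c: (i % 7) for i, c in enumerate(SENSE_CODONS)}
        scaled = {c: v * k for c, v in base.items()}
        t1, t2 = compute_rscu(base), compute_rscu(scaled)
        for c in SENSE_CODONS:
            assert t1.rscu[c] == pytest.approx(t2.rscu[c])

    def test_family_sums_equal_family_size(self):
        counts = {c: (i * 37) % 11 for i, c in enumerate(SENSE_CODONS)}
        table = compute_rscu(counts)
        for aa, family in SYNONYMOUS_FAMILIES.items():
            if table.aa_counts[aa] > 0:
                assert sum(table.rscu[c] for c in family) == pytest.approx(
                    len(family)
                )


class TestConcatenation:
    def test_length_is_sum_of_stop_stripped_sizes(self, synthetic_wncyaa):
        rec, ledger = synthetic_wncyaa
        (seq,) = concatenate_pcgs([rec]).values()
        assert len(seq) == sum(3 * v["aa_count"] for v in ledger["pcg"].values())

    def test_deterministic(self, synthetic_wncyaa):
        rec, _ = synthetic_wncyaa
        assert concatenate_pcgs([rec]) == concatenate_pcgs([rec])

    def test_missing_gene_names_species_and_gene(self, synthetic_wncyaa):
        rec, _ = synthetic_wncyaa
        trimmed = MitogenomeRecord(
            species_id=rec.species_id,
            genome_length=rec.genome_length,
            sequence=rec.sequence,
            features=[f for f in rec.features if f.name != "ND6"],
        )
        with pytest.raises(MissingGeneError, match="synthetic.*ND6"):
            concatenate_pcgs([trimmed])
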