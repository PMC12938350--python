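"""Record model, annotation-table parsing, coordinate arithmetic, validation."""

import io

import pytest

from mitoarch.feature_table import (
    TableParseError,
    parse_feature_table,
    write_feature_table,
)
from mitoarch.genbank import read_genbank, roundtrip, write_genbank
from mitoarch.records import (
    FeatureCategory,
    GeneFeature,
    MitogenomeRecord,
    gene_size,
    intergenic_spacer,
    validate_record,
)

HEADER = (
    "Gene\tStrand\tLocation\tSize(bp)\tIntergenics Length\t"
    "Anticodon\tAminoAcids\tStartCodon\tStopCodon"
)


def _feature(start, end, name="tRNA-Phe", wraps=False, **kw):
    kw.setdefault("category", FeatureCategory.TRNA)
    kw.setdefault("amino_acid", "F")
    return GeneFeature(
        name=name, strand="+", start=start, end=end, wraps_origin=wraps, **kw
    )


class TestParsing:
    def test_markup_dialect_row(self):
        text = HEADER + "\n*tRNA^Leu^*\t+\t2773–2846\t74\t600\tTAA\t\t\t"
        rec = parse_feature_table(text, genome_length=17485, species_id="x")
        (f,) = rec.features
        assert (f.name, f.strand, f.start, f.end) == ("tRNA-Leu", "+", 2773, 2846)
        assert f.declared_size == 74 and f.declared_spacer == 600

    def test_anticodon_and_thousands_separator(self):
        text = (
            HEADER
            + "\n*tRNA^Phe^*\t+\t1–68\t68\t0\tGAA\t\t\t"
            + "\n*ND4*\t+\t11,425–12,805\t1381\t0\t\t460\tATG\tT-"
        )
        rec = parse_feature_table(text, genome_length=17485, species_id="x")
        assert rec.features[0].anticodon == "GAA"
        nd4 = rec.features[1]
        assert (nd4.start, nd4.end, nd4.aa_count, nd4.stop_codon) == (
            11425, 12805, 460, "T-",
        )

    def test_header_only_gives_empty_record(self):
        rec = parse_feature_table(HEADER, genome_length=100, species_id="x")
        assert rec.features == []

    def test_malformed_location_names_row(self):
        text = HEADER + "\n*ND1*\t+\tnowhere\t975\t0\t\t324\tATG\tTAA"
        with pytest.raises(TableParseError, match="row 2.*Location"):
            parse_feature_table(text, genome_length=17485, species_id="x")

    def test_unknown_gene_lists_accepted_labels(self):
        text = HEADER + "\n*XYZZY*\t+\t1–10\t10\t0\t\t\t\t"
        with pytest.raises(TableParseError, match="accepted labels"):
            parse_feature_table(text, genome_length=100, species_id="x")

    def test_duplicate_trnas_get_ordinal_suffixes(self, tanakae):
        names = [f.name for f in tanakae.features]
        assert "tRNA-Ala-1" in names and "tRNA-Ala-2" in names
        assert "tRNA-Leu-1" in names and "tRNA-Ser-2" in names

    def test_table_write_read_is_identity(self, tanakae):
        text = write_feature_table(tanakae)
        again = parse_feature_table(
            text, genome_length=tanakae.genome_length, species_id=tanakae.species_id
        )
        assert [f.to_dict() for f in again.features] == [
            f.to_dict() for f in tanakae.features
        ]

    def test_record_json_roundtrip(self, tanakae):
        again = MitogenomeRecord.from_json(tanakae.to_json())
        assert again.to_dict() == tanakae.to_dict()


class TestCoordinates:
    @pytest.mark.parametrize(
        "start,end,wraps,length,expected",
        [
            (2773, 2846, False, 17485, 74),
            (5, 5, False, 100, 1),
            # wrap: positions 95..100 and 1..4, counted one by one
            (95, 4, True, 100, 10),
        ],
    )
    def test_gene_size(self, start, end, wraps, length, expected):
        f = _feature(start, end, wraps=wraps)
        assert gene_size(f, length) == expected

    def test_spacer_conventions(self):
        leu = _feature(2773, 2846, name="tRNA-Leu")
        nd1 = GeneFeature("ND1", FeatureCategory.PCG, "+", 3447, 4421)
        assert intergenic_spacer(leu, nd1, 17485) == 600
        a8 = GeneFeature("ATPase8", FeatureCategory.PCG, "+", 9018, 9185)
        a6 = GeneFeature("ATPase6", FeatureCategory.PCG, "+", 9176, 9858)
        assert intergenic_spacer(a8, a6, 17485) == -10
        x = _feature(1, 100)
        y = _feature(101, 150)
        assert intergenic_spacer(x, y, 200) == 0

    def test_wraparound_spacer_and_noncircular_error(self):
        pro = _feature(16660, 16729, name="tRNA-Pro")
        phe = _feature(1, 68)
        assert intergenic_spacer(pro, phe, 17485) == 17485 - 16729
        with pytest.raises(ValueError, match="origin"):
            intergenic_spacer(pro, phe, 17485, circular=False)

    def test_circular_conservation_on_study_records(self, chefuensis, tanakae):
        # sum of sizes plus signed spacers (wrap pair included) telescopes
        # to the genome length for any feature list on a circular record
        for rec in (chefuensis, tanakae):
            total = sum(gene_size(f, rec.genome_length) for f in rec.features)
            assert total + sum(rec.spacers()) == rec.genome_length


class TestValidation:
    def test_deep_water_table_is_internally_consistent(self, tanakae):
        report = validate_record(tanakae)
        assert report.is_empty

    def test_shallow_water_table_anomalies_are_flagged(self, chefuensis):
        report = validate_record(chefuensis)
        rules = {(v.rule, v.feature) for v in report.violations}
        assert ("aa-mismatch", "ND4") in rules  # 1382 bp with T- is frame-broken
        assert ("spacer-mismatch", "ATPase8->ATPase6") in rules  # -8 printed, -10 real
        assert ("spacer-mismatch", "ND5->ND6") in rules  # -2 printed, -4 real
        # Tyr/Ala/Asn/Cys anticodons are permuted relative to the standard set
        nonstd = {v.feature for v in report.by_rule("anticodon-nonstandard")}
        assert nonstd == {"tRNA-Tyr", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys"}

    def test_zero_size_mismatches_in_deep_water_table(self, tanakae):
        assert validate_record(tanakae).by_rule("size-mismatch") == []

    def test_count_anomaly(self, tanakae):
        trimmed = MitogenomeRecord(
            species_id="x",
            genome_length=tanakae.genome_length,
            features=[f for f in tanakae.features if f.name != "ND6"],
        )
        report = validate_record(trimmed)
        assert any(v.rule == "count-anomaly" for v in report.violations)


class TestGenBank:
    def _two_gene_flatfile(self):
        seq = "ATGAAATGCTAACCCC" + "A" * 24
        rec = MitogenomeRecord(
            species_id="Toy species",
            genome_length=40,
            sequence=seq,
            features=[
                GeneFeature("ND1", FeatureCategory.PCG, "+", 1, 12, stop_codon="TAA"),
                _feature(13, 40, name="tRNA-Phe", anticodon="GAA"),
            ],
        )
        buf = io.StringIO()
        write_genbank(rec, buf)
        return buf.getvalue()

    def test_minimal_flatfile_parses_two_features(self):
        rec = read_genbank(io.StringIO(self._two_gene_flatfile()))
        assert [f.name for f in rec.features] == ["ND1", "tRNA-Phe"]
        assert rec.sequence is not None and rec.genome_length == 40

    def test_roundtrip_identity(self, synthetic_wncyaa):
        rec, _ = synthetic_wncyaa
        again = roundtrip(rec)
        assert again.sequence == rec.sequence
        assert [
            (f.name, f.category, f.strand, f.start, f.end, f.wraps_origin)
            for f in again.features
        ] == [
            (f.name, f.category, f.strand, f.start, f.end, f.wraps_origin)
            for f in rec.features
        ]

    def test_join_over_origin_becomes_wrapping_feature(self):
        rec = MitogenomeRecord(
            species_id="wrapper",
            genome_length=40,
            sequence="A" * 30 + "ATGAAATGCT",
            features=[
                GeneFeature(
                    "ND1", FeatureCategory.PCG, "+", 31, 2,
                    wraps_origin=True, stop_codon="T-",
                )
            ],
        )
        again = roundtrip(rec)
        (f,) = again.features
        assert f.wraps_origin and (f.start, f.end) == (31, 2)
        # size by position enumeration: 31..40 plus 1..2
        assert gene_size(f, 40) == len(range(31, 41)) + len(range(1, 3))
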