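import pytest

from plastokit.errors import CoordinateError, ParseError
from plastokit.genome_io import (
    FeatureAnnotation,
    PlastomeRecord,
    Spacer,
    extract_feature_sequence,
    flip_record,
    list_intergenic_spacers,
    read_genbank,
    revcomp,
    rotate_record,
    write_genbank,
)

SEQ60 = "ACGTACGGTTCAGGCATAACGTTGCATACGGATCCAGTTACGGATTACCAGGCATGCAAT"


def make_record(features, seq=SEQ60, rid="toy"):
    return PlastomeRecord(id=rid, sequence=seq, circular=True, features=list(features))


class TestRoundTrip:
    def test_genbank_round_trip_preserves_record(self, tmp_path):
        rec = make_record([
            FeatureAnnotation("psbA", "CDS", ((5, 14, "+"),)),
            FeatureAnnotation("petB", "CDS", ((40, 50, "-"), (20, 30, "-"))),
            FeatureAnnotation("trnH-GUG", "tRNA", ((31, 39, "+",),)),
        ])
        path = tmp_path / "toy.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert back == rec

    def test_synthetic_genome_round_trip(self, tmp_path, small_genome):
        rec, _, _ = small_genome
        path = tmp_path / "syn.gb"
        write_genbank(rec, path)
        assert read_genbank(path) == rec

    def test_minimal_two_gene_fixture(self, tmp_path):
        rec = make_record([
            FeatureAnnotation("geneA", "CDS", ((0, 9, "+"),)),
            FeatureAnnotation("geneB", "CDS", ((30, 45, "-"),)),
        ])
        path = tmp_path / "two.gb"
        write_genbank(rec, path)
        back = read_genbank(path)
        assert len(back.features) == 2
        assert [p[2] for f in back.features for p in f.parts] == ["+", "-"]


class TestParsing:
    def test_missing_sequence_block_is_parse_error(self, tmp_path):
        path = tmp_path / "empty.gb"
        path.write_text("LOCUS       x 0 bp DNA circular\n//\n")
        with pytest.raises(ParseError):
            read_genbank(path)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ParseError, match="A/C/G/T/N"):
            PlastomeRecord(id="x", sequence="ACGTRY")

    def test_out_of_range_feature_is_coordinate_error(self):
        with pytest.raises(CoordinateError, match="geneA"):
            make_record([FeatureAnnotation("geneA", "CDS", ((50, 70, "+"),))])


class TestExtraction:
    def test_plus_strand_single_exon_is_verbatim_substring(self):
        rec = make_record([FeatureAnnotation("g", "CDS", ((5, 20, "+"),))])
        assert extract_feature_sequence(rec, rec.features[0]) == SEQ60[5:20]

    def test_minus_strand_two_exon_matches_hand_spliced_oracle(self):
        # transcription order: exon at 40..50 first, then exon at 10..20
        feat = FeatureAnnotation("g", "CDS", ((40, 50, "-"), (10, 20, "-")))
        rec = make_record([feat])
        expected = revcomp(SEQ60[40:50]) + revcomp(SEQ60[10:20])
        assert extract_feature_sequence(rec, feat) == expected

    def test_synthetic_cds_lengths_divisible_by_three(self, small_genome):
        rec, _, _ = small_genome
        for feat in rec.features:
            if feat.kind == "CDS":
                assert len(extract_feature_sequence(rec, feat)) % 3 == 0


class TestSpacers:
    def test_adjacent_genes_yield_gap_spacer(self):
        rec = make_record([
            FeatureAnnotation("geneA", "CDS", ((0, 5, "+"),)),
            FeatureAnnotation("geneB", "CDS", ((15, 25, "+"),)),
        ])
        spacers = list_intergenic_spacers(rec)
        assert Spacer("geneA-geneB", 5, 15) in spacers
        # circular closure interval geneB-geneA also present
        names = {s.name for s in spacers}
        assert names == {"geneA-geneB", "geneB-geneA"}

    def test_overlapping_genes_yield_no_spacer(self):
        rec = make_record([
            FeatureAnnotation("geneA", "CDS", ((0, 20, "+"),)),
            FeatureAnnotation("geneB", "CDS", ((10, 30, "+"),)),
        ])
        assert all("geneA-geneB" != s.name for s in list_intergenic_spacers(rec))

    def test_five_gene_circle_matches_interval_complement_oracle(self):
        extents = [(2, 8), (12, 20), (20, 26), (33, 41), (50, 57)]  # two touching
        rec = make_record([
            FeatureAnnotation(f"g{i}", "CDS", ((s, e, "+"),))
            for i, (s, e) in enumerate(extents)
        ])
        spacers = list_intergenic_spacers(rec)
        # oracle: complement of the union of extents on the circle
        occupied = [False] * 60
        for s, e in extents:
            for i in range(s, e):
                occupied[i] = True
        free = {i for i in range(60) if not occupied[i]}
        covered = set()
        for sp in spacers:
            covered |= {i % 60 for i in range(sp.start, sp.end)}
        assert covered == free

    def test_extents_plus_spacers_tile_the_circle(self, small_genome):
        rec, _, _ = small_genome
        from plastokit.genome_io import gene_extent_blocks

        occupied = [False] * rec.length
        for s, e, _ in gene_extent_blocks(rec):
            for i in range(s, e):
                occupied[i] = True
        spacer_cols = [False] * rec.length
        for sp in list_intergenic_spacers(rec):
            for i in range(sp.start, sp.end):
                assert not spacer_cols[i % rec.length], "spacers overlap"
                spacer_cols[i % rec.length] = True
        # every position is either inside a gene extent or inside a spacer
        assert all(a or b for a, b in zip(occupied, spacer_cols))
        assert not any(a and b for a, b in zip(occupied, spacer_cols))


class TestRotation:
    def test_rotate_then_unrotate_is_identity(self, small_genome):
        rec, _, _ = small_genome
        assert rotate_record(rotate_record(rec, 1234), rec.length - 1234).sequence == rec.sequence

    def test_flip_is_involution(self, small_genome):
        rec, _, _ = small_genome
        assert flip_record(flip_record(rec)) == rec

    def test_flip_preserves_extracted_gene_sequences(self, small_genome):
        rec, _, _ = small_genome
        flipped = flip_record(rec)
        for feat, feat_f in zip(rec.features, flipped.features):
            assert extract_feature_sequence(rec, feat) == extract_feature_sequence(flipped, feat_f)
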