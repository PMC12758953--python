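import pytest

from plastokit.errors import PlastokitError
from plastokit.gene_inventory import build_inventory, classify_splicing, gene_category
from plastokit.genome_io import FeatureAnnotation, PlastomeRecord, revcomp, rotate_record
from plastokit.quadripartite import CircularInterval, QuadripartitePartition, detect_inverted_repeats


def tiny_partition(l=100, r=60, c=40):
    return QuadripartitePartition(
        lsc=CircularInterval(0, l),
        irb=CircularInterval(l, r),
        ssc=CircularInterval(l + r, c),
        ira=CircularInterval(l + r + c, r),
        genome_length=l + 2 * r + c,
    )


def tiny_record(features, n=260):
    # sequence content is irrelevant for inventory logic
    return PlastomeRecord(id="tiny", sequence="A" * n, circular=True, features=list(features))


class TestDuplication:
    def test_gene_in_both_ir_copies_is_duplicated(self):
        rec = tiny_record([
            FeatureAnnotation("X", "CDS", ((110, 140, "+"),), copy_index=0),
            FeatureAnnotation("X", "CDS", ((220, 250, "-"),), copy_index=1),
        ])
        inv = build_inventory(rec, tiny_partition())
        assert inv.duplicated_in_ir == ["X"]

    def test_junction_overlapping_gene_stays_single_copy(self):
        rec = tiny_record([
            FeatureAnnotation("X", "CDS", ((90, 120, "+"),)),  # straddles LSC/IRb
            FeatureAnnotation("Y", "CDS", ((10, 40, "+"),)),
        ])
        inv = build_inventory(rec, tiny_partition())
        assert inv.duplicated_in_ir == []

    def test_copy_collapse_idempotence(self):
        feats = [
            FeatureAnnotation("A", "CDS", ((10, 40, "+"),)),
            FeatureAnnotation("B", "tRNA", ((50, 80, "+"),)),
        ]
        base = build_inventory(tiny_record(feats), tiny_partition())
        doubled = build_inventory(
            tiny_record(feats + [FeatureAnnotation("A", "CDS", ((110, 140, "+"),), copy_index=1)]),
            tiny_partition(),
        )
        assert doubled.unique_genes == base.unique_genes == 2

    def test_record_without_features_errors(self):
        with pytest.raises(PlastokitError):
            build_inventory(tiny_record([]), tiny_partition())


class TestSplicing:
    def test_single_interval_gene_has_no_introns(self):
        rec = tiny_record([FeatureAnnotation("g", "CDS", ((10, 40, "+"),))])
        [entry] = classify_splicing(rec)
        assert (entry.introns, entry.splicing) == (0, "none")

    def test_two_exon_colinear_gene_is_cis_with_parts_minus_one_introns(self):
        for parts in [((10, 20, "+"), (30, 45, "+")), ((30, 45, "-"), (10, 20, "-"))]:
            rec = tiny_record([FeatureAnnotation("g", "CDS", (parts))])
            [entry] = classify_splicing(rec, tiny_partition())
            assert entry.introns == len(parts) - 1
            assert entry.splicing == "cis"

    def test_exons_split_between_lsc_and_ir_flag_trans(self):
        # exon 1 in LSC, exons 2-3 in IRb: the rps12 arrangement
        rec = tiny_record([
            FeatureAnnotation("rps12", "CDS",
                              ((10, 40, "-"), (110, 130, "+"), (140, 150, "+"))),
        ])
        [entry] = classify_splicing(rec, tiny_partition())
        assert (entry.introns, entry.splicing) == (2, "trans")

    def test_synthetic_truth_agrees_with_structural_calls(self, small_genome):
        rec, truth, _ = small_genome
        calls = {(e.gene, e.copy_index): e for e in classify_splicing(rec, truth.partition)}
        for g in truth.genes:
            entry = calls[(g.name, 0)] if (g.name, 0) in calls else None
            if g.trans:
                assert calls[(g.name, 0)].splicing == "trans"
        # intron counts match planted truth for first copies
        planted = {g.name: g.introns for g in truth.genes}
        for (name, idx), e in calls.items():
            if idx == 0:
                assert e.introns == planted[name]


class TestInventoryCounts:
    def test_synthetic_counts_equal_planted_truth(self, small_genome):
        rec, truth, params = small_genome
        inv = build_inventory(rec, truth.partition)
        expected_cds = params.n_cds + 1  # + trans-spliced gene
        assert inv.cds_genes == expected_cds
        assert inv.trna_genes == params.n_trna
        assert inv.rrna_genes == params.n_rrna
        assert inv.unique_genes == expected_cds + params.n_trna + params.n_rrna
        planted_dup = sorted({g.name for g in truth.genes if g.duplicated_in_ir})
        assert inv.duplicated_in_ir == planted_dup

    def test_inventory_invariant_under_canonical_rotation(self, small_genome):
        rec, truth, _ = small_genome
        rotated = rotate_record(rec, 3_333)
        part = detect_inverted_repeats(rotated, min_ir_len=2000)
        inv_rot = build_inventory(rotated, part)
        inv = build_inventory(rec, truth.partition)
        assert (inv_rot.unique_genes, inv_rot.cds_genes, inv_rot.trna_genes,
                inv_rot.rrna_genes) == (inv.unique_genes, inv.cds_genes,
                                        inv.trna_genes, inv.rrna_genes)
        assert inv_rot.duplicated_in_ir == inv.duplicated_in_ir


class TestCategories:
    @pytest.mark.parametrize("symbol,kind,expected_group", [
        ("psbF", "CDS", "Photosystem II"),
        ("rpl2", "CDS", "Large subunit of ribosome"),
        ("trnfM-CAU", "tRNA", "tRNA genes"),
        ("rrn16", "rRNA", "rRNA genes"),
        ("matK", "CDS", "Maturase"),
    ])
    def test_known_symbols_map_to_their_group(self, symbol, kind, expected_group):
        _, group = gene_category(symbol, kind)
        assert group == expected_group

    def test_unknown_symbol_is_unclassified(self):
        assert gene_category("mysteryORF", "CDS") == ("Unclassified", "Unclassified")

    def test_trn_symbols_with_distinct_suffixes_stay_distinct(self):
        rec = tiny_record([
            FeatureAnnotation("trnM-CAU", "tRNA", ((10, 40, "+"),)),
            FeatureAnnotation("trnfM-CAU", "tRNA", ((50, 80, "+"),)),
        ])
        inv = build_inventory(rec, tiny_partition())
        assert inv.trna_genes == 2
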