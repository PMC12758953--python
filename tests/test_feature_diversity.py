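import pytest

from plastokit.errors import PlastokitError
from plastokit.feature_diversity import (
    category_summaries,
    diversity_stats,
    rank_polymorphic,
    run_all_features,
)
from plastokit.pairwise_divergence import RegionAlignment


def make_alignment(n_match, n_sub, n_gap, label="x"):
    """Alignment with the requested column composition (subs then gaps last)."""
    a = "A" * (n_match + n_sub) + "A" * n_gap
    b = "A" * n_match + "C" * n_sub + "-" * n_gap
    return RegionAlignment(label=label, rows=(a, b))


class TestDiversityStats:
    def test_identical_sequences_have_zero_diversity(self):
        rec = diversity_stats(make_alignment(100, 0, 0), "x", "CDS")
        assert rec.pi == 0
        assert rec.missing_pct == 0

    def test_small_gene_arithmetic(self):
        # 120 gap-free columns with 2 substitutions
        rec = diversity_stats(make_alignment(118, 2, 0), "psbF", "CDS")
        assert rec.pi == pytest.approx(2 / 120)
        assert round(rec.pi, 5) == 0.01667
        assert rec.length_excl_indels == rec.alignment_length == 120

    def test_gapped_spacer_arithmetic(self):
        # 129 columns: 23 with gaps, 4 substitutions among the 106 gap-free
        rec = diversity_stats(make_alignment(102, 4, 23), "trnL-ccsA", "IGS")
        assert round(rec.pi, 5) == 0.03774
        assert rec.length_excl_indels == 106
        assert rec.indel_columns == 23
        assert round(rec.missing_pct, 1) == 17.8

    def test_all_gap_free_columns_removed_gives_undefined_pi(self):
        aln = RegionAlignment(label="x", rows=("AAA", "---"))
        rec = diversity_stats(aln, "x", "IGS")
        assert rec.pi is None

    def test_column_bookkeeping_identity(self):
        rec = diversity_stats(make_alignment(50, 3, 7), "x", "intron")
        assert rec.length_excl_indels + rec.indel_columns == rec.alignment_length
        assert rec.missing_pct == pytest.approx(100 * 7 / 60)


class TestRunAllFeatures:
    def test_identical_genomes_have_zero_diversity_everywhere(self, small_genome):
        rec, _, _ = small_genome
        records = run_all_features(rec, rec)
        assert records
        assert all(r.pi == 0 for r in records)

    def test_planted_gene_substitutions_recovered(self, small_pair):
        rec, truth, mut, mut_truth, _ = small_pair
        records = {r.region_name: r for r in run_all_features(rec, mut)
                   if r.category in ("CDS", "tRNA", "rRNA")}
        sub_positions = [s.position for s in mut_truth.substitutions]
        mirrored = []
        p = truth.partition
        for s in mut_truth.substitutions:
            if s.region == "IR":
                t = s.position - p.irb.start
                mirrored.append(p.ira.start + p.irb.length - 1 - t)
        all_positions = sub_positions + mirrored
        seen_genes = set()
        for g in truth.genes:
            if g.name in seen_genes:
                continue  # diversity uses the first copy only
            seen_genes.add(g.name)
            planted = sum(
                1 for pos in all_positions
                if any(s <= pos < e for s, e, _ in g.parts)
            )
            assert records[g.name].substitutions == planted, g.name

    def test_pi_symmetric_under_genome_swap(self, small_pair):
        rec, _, mut, _, _ = small_pair
        fwd = {r.region_name: r.pi for r in run_all_features(rec, mut)}
        rev = {r.region_name: r.pi for r in run_all_features(mut, rec)}
        assert fwd == rev

    def test_table_arithmetic_holds_for_every_record(self, small_pair):
        rec, _, mut, _, _ = small_pair
        for r in run_all_features(rec, mut):
            assert r.length_excl_indels + r.indel_columns == r.alignment_length
            if r.pi is not None and r.length_excl_indels:
                assert r.pi * r.length_excl_indels == pytest.approx(r.substitutions, abs=1e-6)
            assert r.missing_pct == pytest.approx(
                100 * r.indel_columns / r.alignment_length, abs=1e-9
            )

    def test_unannotated_pair_errors(self):
        from plastokit.genome_io import PlastomeRecord

        a = PlastomeRecord(id="a", sequence="ACGT" * 30)
        with pytest.raises(PlastokitError):
            run_all_features(a, a)


class TestRanking:
    def records(self, pis_subs):
        return [
            diversity_stats(make_alignment(100 - s, s, 0), f"g{i}", "CDS")
            for i, (_, s) in enumerate(pis_subs)
        ]

    def test_descending_pi_order_preserved(self):
        recs = [
            diversity_stats(make_alignment(80, 20, 0), "hi", "CDS"),
            diversity_stats(make_alignment(90, 10, 0), "lo", "CDS"),
        ]
        frame = rank_polymorphic(recs)
        assert list(frame["region"]) == ["hi", "lo"]

    def test_equal_pi_tie_broken_by_substitution_count(self):
        recs = [
            diversity_stats(make_alignment(90, 10, 0), "small", "CDS"),   # 10/100
            diversity_stats(make_alignment(180, 20, 0), "big", "CDS"),    # 20/200
        ]
        frame = rank_polymorphic(recs)
        assert list(frame["region"]) == ["big", "small"]

    def test_top_k_limits_each_category(self):
        recs = [diversity_stats(make_alignment(95, 5 + i, 0), f"g{i}", "CDS")
                for i in range(4)]
        frame = rank_polymorphic(recs, top_k=2)
        assert len(frame) == 2


class TestCategorySummaries:
    def test_single_record_both_conventions_agree(self):
        recs = [diversity_stats(make_alignment(98, 2, 0), "x", "CDS")]
        row = category_summaries(recs).iloc[0]
        assert row["mean_pi"] == pytest.approx(2 / 100)
        assert row["pooled_pi"] == pytest.approx(2 / 100)

    def test_equal_lengths_make_conventions_coincide(self):
        recs = [
            diversity_stats(make_alignment(100, 0, 0), "a", "IGS"),
            diversity_stats(make_alignment(98, 2, 0), "b", "IGS"),
        ]
        row = category_summaries(recs).iloc[0]
        assert row["mean_pi"] == pytest.approx(0.01)
        assert row["pooled_pi"] == pytest.approx(0.01)

    def test_unequal_lengths_separate_conventions(self):
        recs = [
            diversity_stats(make_alignment(300, 0, 0), "a", "IGS"),  # pi 0, L 300
            diversity_stats(make_alignment(98, 2, 0), "b", "IGS"),   # pi 0.02, L 100
        ]
        row = category_summaries(recs).iloc[0]
        assert row["mean_pi"] == pytest.approx(0.01)
        assert row["pooled_pi"] == pytest.approx(2 / 400)
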