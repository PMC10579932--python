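import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methkit import core
from methkit.io import GeneModel, GenomicInterval

from conftest import make_calls, random_calls
from oracles import context_scan, kmer_recount

dna = st.text(alphabet="ACGTN", min_size=3, max_size=300)


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq, pos, strand, expected",
        [
            ("ACGT", 2, "+", "CG"),
            ("CAG", 1, "+", "CHG"),
            ("CAA", 1, "+", "CHH"),
            ("CCG", 3, "-", "CG"),    # minus strand reads C,G at the final G
            ("ACGT", 4, "+", None),   # cytosine-free? guarded below
        ][:4],
    )
    def test_definition_cases(self, seq, pos, strand, expected):
        assert core.classify_context({"c": seq}, "c", pos, strand) == expected

    def test_contig_end_is_undefined(self):
        assert core.classify_context({"c": "AAC"}, "c", 3, "+") is None
        assert core.classify_context({"c": "GAA"}, "c", 1, "-") is None

    def test_n_neighbour_is_undefined(self):
        assert core.classify_context({"c": "CNG"}, "c", 1, "+") is None
        assert core.classify_context({"c": "CANA"}, "c", 1, "+") is None

    def test_non_cytosine_raises(self):
        with pytest.raises(ValueError):
            core.classify_context({"c": "ACGT"}, "c", 1, "+")
        with pytest.raises(ValueError):
            core.classify_context({"c": "ACGT"}, "c", 2, "-")

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_double_strand_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(
            rng.choice(list("ACGTN"), size=500, p=[0.3, 0.2, 0.2, 0.28, 0.02])
        )
        genome = {"c": seq}
        for i, base in enumerate(seq):
            if base == "C":
                assert core.classify_context(genome, "c", i + 1, "+") == context_scan(
                    seq, i + 1, "+"
                )
            if base == "G":
                assert core.classify_context(genome, "c", i + 1, "-") == context_scan(
                    seq, i + 1, "-"
                )


class TestRegionLevel:
    def test_pools_counts_weighted_not_mean_of_means(self):
        calls = make_calls(
            [("chr1", 10, "+", "CG", 3, 10), ("chr1", 20, "-", "CG", 7, 10)]
        )
        r = core.region_level(calls, GenomicInterval("chr1", 0, 100), "CG")
        assert (r.n_meth, r.n_unmeth, r.n_sites) == (10, 10, 2)
        assert r.level == 0.5

    def test_zero_coverage_interval_is_undefined(self):
        calls = make_calls([("chr1", 10, "+", "CG", 3, 10)])
        r = core.region_level(calls, GenomicInterval("chr2", 0, 100), "CG")
        assert r.n_sites == 0 and r.level is None

    def test_context_filter(self):
        calls = make_calls(
            [("chr1", 10, "+", "CG", 5, 10), ("chr1", 11, "+", "CHH", 5, 10)]
        )
        r = core.region_level(calls, GenomicInterval("chr1", 0, 100), "CHH")
        assert r.n_sites == 1

    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    def test_additivity_over_any_partition(self, seed, n_parts):
        rng = np.random.default_rng(seed)
        calls = random_calls(rng, n=100, span=1000)
        cuts = sorted(rng.choice(np.arange(1, 1000), size=n_parts - 1, replace=False))
        bounds = [0] + [int(c) for c in cuts] + [1000]
        whole = core.region_level(calls, GenomicInterval("chr1", 0, 1000), "CG")
        parts = [
            core.region_level(calls, GenomicInterval("chr1", a, b), "CG")
            for a, b in zip(bounds, bounds[1:])
        ]
        assert sum(p.n_meth for p in parts) == whole.n_meth
        assert sum(p.n_unmeth for p in parts) == whole.n_unmeth
        assert sum(p.n_sites for p in parts) == whole.n_sites

    def test_pooled_level_counts_shared_sites_once(self):
        calls = make_calls([("chr1", 50, "+", "CG", 2, 4)])
        ivs = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 40, 80)]
        pooled = core.pooled_level(calls, ivs, "CG")
        assert pooled.n_sites == 1 and pooled.n_meth == 2


def make_gene(strand="+", n_exons=3, chrom="chr1", start=10_000,
              exon_len=100, intron_len=200):
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand, "exon"))
        pos += exon_len + intron_len
    if strand == "-":
        exons = exons[::-1]
    tss = start + 1 if strand == "+" else exons[0].end
    return GeneModel("g1", chrom, strand, exons, tss)


class TestPartitionGene:
    def test_three_exon_gene_features(self):
        g = make_gene(n_exons=3)
        parts = core.partition_gene(g)
        assert len(parts["first_exon"]) == 1
        assert len(parts["internal_exon"]) == 1
        assert len(parts["last_exon"]) == 1
        assert len(parts["first_intron"]) == 1
        assert len(parts["internal_intron"]) == 1
        # intron 1 lies between exon 1 and 2
        assert parts["first_intron"][0].start == parts["first_exon"][0].end

    def test_single_exon_gene_degenerate(self):
        parts = core.partition_gene(make_gene(n_exons=1))
        assert parts["first_exon"] and parts["upstream"] and parts["downstream"]
        assert not parts["last_exon"] and not parts["internal_exon"]
        assert not parts["first_intron"] and not parts["internal_intron"]

    def test_two_exon_gene_has_no_internal_features(self):
        parts = core.partition_gene(make_gene(n_exons=2))
        assert parts["first_exon"] and parts["last_exon"] and parts["first_intron"]
        assert not parts["internal_exon"] and not parts["internal_intron"]

    def test_minus_strand_upstream_is_right_of_gene(self):
        # gene occupying 1-based [1001, 2000] on the minus strand
        g = GeneModel(
            "g1", "chr1", "-",
            [GenomicInterval("chr1", 1000, 2000, "-", "exon")], tss=2000,
        )
        parts = core.partition_gene(g, flank=2000, chrom_len=3000)
        up = parts["upstream"][0]
        assert (up.start, up.end) == (2000, 3000)  # clipped at the contig end
        down = parts["downstream"][0]
        assert (down.start, down.end) == (0, 1000)

    def test_features_within_one_gene_are_disjoint(self):
        parts = core.partition_gene(make_gene(n_exons=4))
        ivs = [
            iv for label in core.GENE_FEATURES for iv in parts[label]
        ]
        ivs.sort(key=lambda r: r.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end <= b.start

    def test_promoter_aliases_upstream_and_gene_body_spans_transcript(self):
        g = make_gene(n_exons=2)
        parts = core.partition_gene(g)
        assert parts["promoter"] == parts["upstream"]
        gb = parts["gene_body"][0]
        assert (gb.start, gb.end) == (g.start, g.end)


class TestFeatureProfile:
    def test_single_gene_profile_matches_region_level(self):
        g = make_gene(n_exons=2, start=5000)
        parts = core.partition_gene(g)
        calls = make_calls(
            [
                ("chr1", 4000, "+", "CG", 1, 10),   # upstream
                ("chr1", 5050, "+", "CG", 9, 10),   # first exon
                ("chr1", 5150, "+", "CG", 5, 10),   # first intron
            ]
        )
        prof = core.feature_profile({"s1": calls}, [parts])
        assert prof.loc["upstream", "s1"] == 0.1
        assert prof.loc["first_exon", "s1"] == 0.9
        assert prof.loc["first_intron", "s1"] == 0.5
        assert np.isnan(prof.loc["last_exon", "s1"])  # no covered site

    def test_promoter_lower_than_gene_body_in_planted_profile(self, rng):
        # 0.05 promoter vs 0.7 body: the profile must order them accordingly
        g = make_gene(n_exons=1, start=3000, exon_len=2000)
        parts = core.partition_gene(g)
        rows = []
        for p in range(1100, 3000, 20):
            rows.append(("chr1", p, "+", "CG", rng.binomial(20, 0.05), 20))
        for p in range(3100, 5000, 20):
            rows.append(("chr1", p, "+", "CG", rng.binomial(20, 0.7), 20))
        prof = core.feature_profile(
            {"s1": make_calls(rows)}, [parts],
            tracks={"mRNA": [GenomicInterval("chr1", g.start, g.end)]},
        )
        assert prof.loc["upstream", "s1"] < prof.loc["mRNA", "s1"]

    def test_unknown_feature_label_rejected(self):
        calls = make_calls([("chr1", 1, "+", "CG", 1, 2)])
        with pytest.raises(ValueError, match="unknown feature"):
            core.feature_profile({"s1": calls}, [{"exotic": []}])

    def test_requires_at_least_one_group(self):
        with pytest.raises(ValueError):
            core.feature_profile({}, [])


class TestNormalizeTrack:
    @pytest.mark.parametrize(
        "values, expected",
        [((0.2, 0.2, 0.6), (0.2, 0.2, 0.6)), ((2, 2), (0.5, 0.5)), ((3,), (1.0,))],
    )
    def test_fractions(self, values, expected):
        out, defined = core.normalize_track(values)
        assert defined
        np.testing.assert_allclose(out, expected)

    def test_all_zero_row_flagged(self):
        out, defined = core.normalize_track((0.0, 0.0, 0.0))
        assert not defined
        assert (out == 0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            core.normalize_track((0.1, -0.2))

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_output_sums_to_one(self, values):
        out, defined = core.normalize_track(values)
        assert defined and abs(out.sum() - 1) < 1e-12


class TestKmerPreference:
    def test_fully_methylated_kmer_has_level_one(self):
        genome = {"c": "TTTCGAATTTCGAA"}
        calls = make_calls(
            [("c", 4, "+", "CG", 10, 10), ("c", 11, "+", "CG", 5, 5)]
        )
        table, excluded = core.kmer_preference(calls, genome)
        assert excluded == 0
        row = table[table.kmer == "TTTCGAA"].iloc[0]
        assert row.n_sites == 2 and row.level == 1.0

    def test_flanks_off_contig_are_excluded_and_conserved(self):
        genome = {"c": "CGTACGTACG"}
        calls = make_calls(
            [("c", 1, "+", "CG", 1, 2), ("c", 9, "+", "CG", 1, 2)]
        )
        table, excluded = core.kmer_preference(calls, genome)
        assert excluded == 2  # both flanks run off the 10 bp contig
        assert table.n_sites.sum() + excluded == len(calls)

    def test_matches_bruteforce_recount_on_random_genome(self, rng):
        from methkit.simulate import random_sequence

        seq = random_sequence(rng, 5000, 0.4)
        genome = {"c": seq}
        rows = []
        for i, b in enumerate(seq):
            if b == "C" and rng.random() < 0.3:
                ctx = core.classify_context(genome, "c", i + 1, "+")
                if ctx is None:
                    continue
                total = int(rng.integers(1, 30))
                rows.append(("c", i + 1, "+", ctx, int(rng.integers(0, total + 1)), total))
            if b == "G" and rng.random() < 0.3:
                ctx = core.classify_context(genome, "c", i + 1, "-")
                if ctx is None:
                    continue
                total = int(rng.integers(1, 30))
                rows.append(("c", i + 1, "-", ctx, int(rng.integers(0, total + 1)), total))
        calls = make_calls(rows)
        table, excluded = core.kmer_preference(calls, genome)
        expected, expected_excluded = kmer_recount(calls, genome)
        assert excluded == expected_excluded
        assert len(table) == len(expected)
        for row in table.itertuples(index=False):
            n_sites, n_meth, n_total = expected[(row.kmer, row.context)]
            assert row.n_sites == n_sites
            assert row.level == pytest.approx(n_meth / n_total)
        # conservation: sites partition the covered-cytosine set
        assert table.n_sites.sum() + excluded == len(calls)

    def test_center_must_be_cytosine(self):
        genome = {"c": "A" * 20}
        calls = make_calls([("c", 10, "+", "CG", 1, 2)])
        with pytest.raises(ValueError):
            core.kmer_preference(calls, genome)


class TestDegreeOfDifference:
    def test_exact_powers_of_two(self):
        assert core.degree_of_difference(0.25, 0.5).score == 2.0

    @given(st.floats(0.001, 0.999))
    def test_equal_inputs_score_one(self, x):
        assert core.degree_of_difference(x, x).score == pytest.approx(1.0)

    def test_zero_substituted_before_log(self):
        # log2(0.001)/log2(0.5), pinned numerically
        score = core.degree_of_difference(0.0, 0.5).score
        assert score == pytest.approx(9.965784284662087, abs=1e-12)
        score = core.degree_of_difference(0.5, 0.0).score
        assert score == pytest.approx(1 / 9.965784284662087, abs=1e-12)

    def test_denominator_one_is_flagged_infinite(self):
        d = core.degree_of_difference(0.5, 1.0)
        assert not d.finite and d.score == math.inf

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            core.degree_of_difference(1.2, 0.5)


class TestContextProportions:
    def test_share_arithmetic(self):
        rows = (
            [("chr1", i, "+", "CG", 2, 10) for i in range(1, 91)]
            + [("chr1", i, "+", "CHG", 2, 10) for i in range(100, 102)]
            + [("chr1", i, "+", "CHH", 2, 10) for i in range(200, 208)]
        )
        shares = core.context_proportions(make_calls(rows))
        assert shares["CG"] == 90.0
        assert shares["CHG"] == 2.0
        assert shares["CHH"] == 8.0
        assert shares.sum() == pytest.approx(100.0)

    def test_all_cg_is_full_share(self):
        shares = core.context_proportions(
            make_calls([("chr1", 1, "+", "CG", 1, 5), ("chr1", 5, "+", "CG", 3, 5)])
        )
        assert shares.tolist() == [100.0, 0.0, 0.0]

    def test_no_methylated_sites_is_undefined(self):
        calls = make_calls([("chr1", 1, "+", "CG", 0, 30)])
        assert core.context_proportions(calls) is None

    def test_coverage_rule_excludes_shallow_sites(self):
        calls = make_calls(
            [("chr1", 1, "+", "CHH", 1, 2), ("chr1", 9, "+", "CG", 1, 30)]
        )
        shares = core.context_proportions(calls, min_coverage=4)
        assert shares["CG"] == 100.0


class TestChromosomeMap:
    def test_tiles_scaled_to_paper_range(self):
        calls = make_calls(
            [("chr1", 5, "+", "CG", 5, 10), ("chr1", 15_000, "+", "CG", 10, 10)]
        )
        track = core.chromosome_map(calls, {"chr1": 20_000}, window=10_000)
        assert len(track) == 2
        assert track.value.tolist() == [10.0, 20.0]  # level × 20

    def test_uncovered_tile_is_nan(self):
        calls = make_calls([("chr1", 5, "+", "CG", 5, 10)])
        track = core.chromosome_map(calls, {"chr1": 20_000}, window=10_000)
        assert np.isnan(track.value.iloc[1])
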