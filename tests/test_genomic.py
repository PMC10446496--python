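"""Gene models, TSS consolidation, promoters and enrichment statistics."""

import numpy as np
import pytest

from lineage_rates import genomic as G
from lineage_rates.motifs import MotifHit, reverse_complement

GFF3 = """\
##gff-version 3
I\ttest\tgene\t101\t1100\t.\t+\t.\tID=gene1;Name=fast-1
I\ttest\tmRNA\t101\t1100\t.\t+\t.\tID=m1;Parent=gene1
I\ttest\texon\t101\t300\t.\t+\t.\tID=e1;Parent=m1
I\ttest\texon\t501\t700\t.\t+\t.\tID=e2;Parent=m1
I\ttest\texon\t901\t1100\t.\t+\t.\tID=e3;Parent=m1
I\ttest\tmRNA\t101\t700\t.\t+\t.\tID=m2;Parent=gene1
I\ttest\texon\t101\t700\t.\t+\t.\tID=e4;Parent=m2
II\ttest\tgene\t2001\t4000\t.\t-\t.\tID=gene2;Name=slow-1
II\ttest\tmRNA\t2001\t4000\t.\t-\t.\tID=m3;Parent=gene2
II\ttest\texon\t2001\t4000\t.\t-\t.\tID=e5;Parent=m3
"""


@pytest.fixture(scope="module")
def models(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "genes.gff3"
    path.write_text(GFF3)
    return G.read_gff3(path)


class TestGeneModels:
    def test_coordinates_converted_to_half_open(self, models):
        g = models["fast-1"]
        assert (g.start, g.end) == (100, 1100)
        assert g.length == 1000
        assert g.n_isoforms == 2

    def test_longest_isoform_defines_structure(self, models):
        g = models["fast-1"]
        assert g.exons == [(100, 300), (500, 700), (900, 1100)]
        assert g.introns == [(300, 500), (700, 900)]

    def test_minus_strand_tss_at_span_end(self, models):
        g = models["slow-1"]
        assert g.strand == "-"
        assert g.tss == 3999  # 0-based last base of the span

    def test_intron_density(self, models):
        assert G.intron_density(models["fast-1"]) == pytest.approx(2.0)
        assert G.intron_density(models["slow-1"]) == 0.0
        # 2 introns in a 4 kb gene -> 0.5 /kb
        g = G.GeneModel("g", "I", "+", 0, 4000,
                        exons=[(0, 1000), (2000, 2500), (3500, 4000)])
        assert G.intron_density(g) == pytest.approx(0.5)


class TestConsolidateTss:
    def cand(self, src, pos, chrom="I"):
        return G.TssCandidate("g", src, chrom, pos)

    def test_identical_candidates(self):
        out = G.consolidate_tss({"g": [self.cand("a", 100), self.cand("b", 100),
                                       self.cand("c", 100)]})
        assert out["g"].position == 100

    def test_median_of_agreeing_pair(self):
        out = G.consolidate_tss(
            {"g": [self.cand("a", 100), self.cand("b", 102), self.cand("c", 500)]},
            window=10,
        )
        assert out["g"].position == 101

    def test_single_source_passthrough(self):
        out = G.consolidate_tss({"g": [self.cand("a", 250)]})
        assert out["g"].position == 250

    def test_disagreement_resolved_by_priority(self):
        out = G.consolidate_tss(
            {"g": [self.cand("low", 100), self.cand("top", 500)]},
            window=10,
            source_priority=["top", "low"],
        )
        assert out["g"].position == 500

    def test_cross_chromosome_candidates_dropped(self):
        out = G.consolidate_tss(
            {"g": [self.cand("a", 100, "I"), self.cand("b", 100, "II")]}
        )
        assert "g" not in out


class TestExtractPromoter:
    GENOME = {"chr": "ACGTACGTACGTACGTACGT"}

    def test_plus_strand_definition(self):
        seq, clipped = G.extract_promoter(self.GENOME, "chr", 10, "+", length=4)
        assert seq == self.GENOME["chr"][6:10]
        assert not clipped

    def test_minus_strand_reverse_complement(self):
        seq, _ = G.extract_promoter(self.GENOME, "chr", 9, "-", length=4)
        assert seq == reverse_complement(self.GENOME["chr"][10:14])

    def test_palindromic_mirror_symmetry(self):
        # genome equal to its own reverse complement: promoters around
        # mirrored TSSs on opposite strands are reverse complements
        pal = "ACGCGT" * 3  # ACGCGT is its own reverse complement
        L = len(pal)
        t = 10
        plus, _ = G.extract_promoter({"c": pal}, "c", t, "+", length=5)
        minus, _ = G.extract_promoter({"c": pal}, "c", L - 1 - t, "-", length=5)
        assert plus == minus

    def test_clipping_at_chromosome_start(self):
        seq, clipped = G.extract_promoter(self.GENOME, "chr", 3, "+", length=500)
        assert clipped and len(seq) == 3

    def test_tss_off_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            G.extract_promoter(self.GENOME, "chr", 99, "+")


class TestPositionalClusters:
    def test_gap_rule(self):
        cl = G.positional_clusters([0, 1000, 2000, 100_000], 10_000)
        assert [(c["start"], c["end"], c["n_genes"]) for c in cl] == [
            (0, 2000, 3), (100_000, 100_000, 1)]

    def test_singletons_and_single_gene(self):
        assert len(G.positional_clusters([5], 100)) == 1
        cl = G.positional_clusters([0, 500, 1000], 100)
        assert all(c["n_genes"] == 1 for c in cl)

    def test_input_order_invariance(self):
        a = G.positional_clusters([0, 1000, 2000, 100_000], 10_000)
        b = G.positional_clusters([100_000, 2000, 0, 1000], 10_000)
        assert [(c["start"], c["end"]) for c in a] == [(c["start"], c["end"]) for c in b]


def hit(gene, motif="inr", offset=-10):
    return MotifHit(gene, motif, offset, "+", 5.0, 1e-5)


class TestOccurrenceEnrichment:
    def test_uniform_hits_no_signal(self):
        sets = {"high": {"a", "b"}, "low": {"c", "d"}}
        hits = [hit(g) for g in "abcd"]
        df = G.occurrence_enrichment(hits, sets)
        assert (df["proportion"] == 1.0).all()
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_chi_square_textbook_value(self):
        # 10/100 vs 30/100 genes with a hit: uncorrected chi-square = 12.5
        high = {f"h{i}" for i in range(100)}
        low = {f"l{i}" for i in range(100)}
        hits = [hit(f"h{i}") for i in range(10)] + [hit(f"l{i}") for i in range(30)]
        df = G.occurrence_enrichment(hits, {"high": high, "low": low})
        assert df["chi2"].iloc[0] == pytest.approx(12.5)

    def test_extreme_proportions(self):
        sets = {"on": {"a", "b"}, "off": {"c", "d"}}
        hits = [hit("a"), hit("b")]
        df = G.occurrence_enrichment(hits, sets).set_index("category")
        assert df.loc["on", "proportion"] == 1.0
        assert df.loc["off", "proportion"] == 0.0

    def test_ci_contains_point_estimate(self):
        high = {f"h{i}" for i in range(40)}
        low = {f"l{i}" for i in range(60)}
        hits = [hit(f"h{i}") for i in range(25)] + [hit(f"l{i}") for i in range(10)]
        df = G.occurrence_enrichment(hits, {"high": high, "low": low})
        assert ((df["ci_low"] <= df["proportion"]) & (df["proportion"] <= df["ci_high"])).all()


class TestPositionalProfile:
    def test_single_bin_adjacent_to_tss(self):
        hits = [MotifHit("a", "inr", -1, "+", 5.0, 1e-5)] * 5
        df = G.tss_positional_profile(hits, {"high": {"a"}}, bin_width=25)
        occupied = df[df["count"] > 0]
        assert len(occupied) == 1
        assert occupied["bin_end"].iloc[0] == 0

    def test_uniform_offsets_flat_histogram(self):
        rng = np.random.default_rng(0)
        hits = [
            MotifHit("a", "inr", int(o), "+", 5.0, 1e-5)
            for o in rng.integers(-500, 0, 4000)
        ]
        df = G.tss_positional_profile(hits, {"high": {"a"}}, bin_width=50)
        dens = df["density"].to_numpy()
        assert np.all(np.abs(dens - 0.1) < 0.03)  # 10 bins ± multinomial error

    def test_empty_hits_zero_histogram(self):
        df = G.tss_positional_profile([], {"high": {"a"}})
        assert len(df) == 0 or (df["count"] == 0).all()


class TestChromosomeEnrichment:
    def test_matching_distribution_statistic_zero(self):
        chrom_map = {f"g{i}": "I" if i % 2 else "II" for i in range(100)}
        all_genes = set(chrom_map)
        cat = {f"g{i}" for i in range(0, 100, 2)}  # exactly mirrors background? no: all II
        # build a category matching the genome-wide distribution instead
        cat = {f"g{i}" for i in range(20)}  # 10 on I, 10 on II = background 50/50
        df = G.chromosome_enrichment({"high": cat}, all_genes, chrom_map)
        assert df["chi2"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_concentrated_category_goodness_of_fit(self):
        chroms = ["I", "II", "III", "IV", "V", "X"]
        chrom_map = {}
        i = 0
        for c in chroms:
            for _ in range(50):
                chrom_map[f"g{i}"] = c
                i += 1
        all_genes = set(chrom_map)
        cat = {g for g, c in chrom_map.items() if c == "II"}  # all 50 on chrII
        df = G.chromosome_enrichment({"high": cat}, all_genes, chrom_map)
        # hand-computed goodness of fit: expected 50/6 per chromosome
        e = 50 / 6
        stat = (50 - e) ** 2 / e + 5 * (0 - e) ** 2 / e
        assert df["chi2"].iloc[0] == pytest.approx(stat)

    def test_small_expected_flagged(self):
        chrom_map = {"a": "I", "b": "II", "c": "I", "d": "II"}
        df = G.chromosome_enrichment({"tiny": {"a"}}, set(chrom_map), chrom_map)
        assert df["small_expected"].all()


class TestCategoryAssociation:
    def test_odds_ratio_textbook(self):
        res = G.category_association([[10, 90], [30, 70]])
        assert res["odds_ratio"] == pytest.approx((10 * 70) / (90 * 30), rel=1e-12)

    def test_identical_proportions(self):
        res = G.category_association([[20, 80], [20, 80]])
        assert res["odds_ratio"] == pytest.approx(1.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_haldane_correction_for_zero_cell(self):
        res = G.category_association([[0, 50], [10, 40]])
        assert res["zero_cell_corrected"]
        assert np.isfinite(res["odds_ratio"]) and res["odds_ratio"] > 0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            G.category_association([[0, 0], [10, 40]])


def test_read_tss_bed(tmp_path):
    bed = tmp_path / "tss.bed"
    bed.write_text("I\t100\t101\tgeneA\t0\t+\nII\t200\t250\tgeneB\t0\t-\n")
    cands = G.read_tss_bed(bed, source="cage")
    assert cands[0].position == 100 and cands[0].strand == "+"
    assert cands[1].position == 249 and cands[1].strand == "-"
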