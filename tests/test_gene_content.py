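import numpy as np
import pandas as pd
import pytest

from array_eval import gene_content as gc
from conftest import make_genotype_table, make_manifest


@pytest.fixture
def toy_genes():
    return [
        gc.GeneRegion("A", "1", [(100, 199)], category="acmg"),
        gc.GeneRegion("B", "1", [(150, 299)], category="acmg"),  # overlaps A
        gc.GeneRegion("C", "2", [(10, 59), (80, 129)], category="acmg"),
    ]


class TestCountGeneVariants:
    def test_single_containment(self, toy_genes):
        m = make_manifest([("1", 120, "A", "G")])
        counts = gc.count_gene_variants(m, toy_genes)
        assert counts.tolist() == [1, 0, 0]

    def test_overlapping_genes_both_count(self, toy_genes):
        m = make_manifest([("1", 160, "A", "G")])
        counts = gc.count_gene_variants(m, toy_genes)
        assert counts["A"] == 1 and counts["B"] == 1

    def test_twelve_variant_fixture_hand_count(self, toy_genes):
        positions = [
            ("1", 100), ("1", 199), ("1", 150),   # A: 3 (150 also B)
            ("1", 250), ("1", 299), ("1", 300),   # B: 150,199,250,299 -> 4; 300 outside
            ("2", 10), ("2", 59), ("2", 60),      # C: 10,59 in; 60 in gap
            ("2", 80), ("2", 129), ("3", 50),     # C: 80,129 in; chrom 3 none
        ]
        m = make_manifest([(c, p, "A", "G") for c, p in positions])
        counts = gc.count_gene_variants(m, toy_genes)
        assert counts["A"] == 3 and counts["B"] == 4 and counts["C"] == 4

    def test_interval_ends_inclusive(self, toy_genes):
        m = make_manifest([("1", 100, "A", "G"), ("1", 199, "C", "T"),
                           ("1", 99, "A", "G"), ("1", 200, "A", "G")])
        counts = gc.count_gene_variants(m, toy_genes)
        assert counts["A"] == 2


class TestProxyDeleterious:
    def cadd(self, entries):
        return pd.DataFrame(entries, columns=["chrom", "pos", "ref", "alt", "cadd_phred"])

    def test_all_low_scores(self, toy_genes):
        m = make_manifest([("1", 120, "A", "G")])
        res = gc.count_proxy_deleterious(m, toy_genes,
                                         self.cadd([("1", 120, "A", "G", 15.0)]))
        assert res.total == 0 and res.median == 0

    def test_threshold_strict(self, toy_genes):
        m = make_manifest([("1", 120, "A", "G"), ("1", 130, "C", "T")])
        cadd = self.cadd([("1", 120, "A", "G", 20.0), ("1", 130, "C", "T", 20.01)])
        res = gc.count_proxy_deleterious(m, toy_genes, cadd)
        assert res.per_gene["A"] == 1  # exactly 20 excluded

    def test_median_iqr_hand_computed(self):
        # five disjoint genes with planted counts 0,1,2,3,10
        genes = [gc.GeneRegion(f"G{i}", "1", [(1000 * i, 1000 * i + 999)])
                 for i in range(1, 6)]
        rows, cadd_rows = [], []
        for i, n in zip(range(1, 6), [0, 1, 2, 3, 10]):
            for k in range(n):
                pos = 1000 * i + k
                rows.append(("1", pos, "A", "G"))
                cadd_rows.append(("1", pos, "A", "G", 30.0))
        m = make_manifest(rows) if rows else None
        res = gc.count_proxy_deleterious(m, genes, self.cadd(cadd_rows))
        assert res.per_gene.tolist() == [0, 1, 2, 3, 10]
        assert res.median == 2
        assert res.iqr == (1, 3)
        assert res.total == 16

    def test_distinct_total_with_overlapping_genes(self, toy_genes):
        m = make_manifest([("1", 160, "A", "G")])
        res = gc.count_proxy_deleterious(m, toy_genes,
                                         self.cadd([("1", 160, "A", "G", 25.0)]))
        assert res.total == 2 and res.distinct_total == 1


class TestStarAlleles:
    def allele(self, tags, gene="CYP2C19", name="*2", **kw):
        return gc.StarAllele(gene=gene, allele=name, tag_snvs=tags, **kw)

    def test_all_tags_present_callable(self):
        m = make_manifest([("10", p, "A", "G") for p in (10, 20, 30)])
        a = self.allele([("10", 10, "A", "G"), ("10", 20, "A", "G"), ("10", 30, "A", "G")])
        assert gc.star_allele_callable(a, m) is gc.Callability.CALLABLE

    def test_all_or_nothing(self):
        m = make_manifest([("10", 10, "A", "G"), ("10", 20, "A", "G")])
        a = self.allele([("10", 10, "A", "G"), ("10", 20, "A", "G"), ("10", 30, "A", "G")])
        assert gc.star_allele_callable(a, m) is gc.Callability.NOT_CALLABLE

    def test_empty_tag_set_not_evaluable(self):
        m = make_manifest([("10", 10, "A", "G")])
        assert gc.star_allele_callable(self.allele([]), m) is gc.Callability.NOT_EVALUABLE

    def test_cnv_based_not_evaluable(self):
        m = make_manifest([("10", 10, "A", "G")])
        a = self.allele([("10", 10, "A", "G")], cnv_based=True)
        assert gc.star_allele_callable(a, m) is gc.Callability.NOT_EVALUABLE

    def test_allele_identity_required_unless_position_only(self):
        m = make_manifest([("10", 10, "A", "G")])
        a = self.allele([("10", 10, "A", "T")])
        assert gc.star_allele_callable(a, m) is gc.Callability.NOT_CALLABLE
        assert gc.star_allele_callable(a, m, position_only=True) is gc.Callability.CALLABLE

    def test_imputed_mode_rescues_high_r2_tags(self):
        m = make_manifest([("10", 10, "A", "G")])
        a = self.allele([("10", 10, "A", "G"), ("10", 20, "C", "T")])
        imputed_hi = make_genotype_table(np.zeros((1, 2), dtype=int), chrom="10",
                                         r2=[0.9])
        imputed_hi.variants.loc[0, ["pos", "ref", "alt"]] = [20, "C", "T"]
        assert gc.star_allele_callable(a, m, imputed_hi) is gc.Callability.CALLABLE
        imputed_lo = make_genotype_table(np.zeros((1, 2), dtype=int), chrom="10",
                                         r2=[0.8])  # strict >
        imputed_lo.variants.loc[0, ["pos", "ref", "alt"]] = [20, "C", "T"]
        assert gc.star_allele_callable(a, m, imputed_lo) is gc.Callability.NOT_CALLABLE

    def test_percent_star_alleles(self):
        m = make_manifest([("10", 10, "A", "G")])
        alleles = [
            self.allele([("10", 10, "A", "G")], name="*2"),
            self.allele([("10", 99, "A", "G")], name="*3"),
            self.allele([("10", 10, "A", "G")], name="*4"),
            self.allele([("10", 98, "A", "G")], name="*5"),
            self.allele([], name="*6"),  # not evaluable, excluded
        ]
        assert gc.percent_star_alleles("CYP2C19", alleles, m) == pytest.approx(50.0)

    def test_percent_undefined_without_evaluable_alleles(self):
        m = make_manifest([("10", 10, "A", "G")])
        assert gc.percent_star_alleles("CYP2C19", [self.allele([])], m) is None

    def test_monotone_under_added_content(self):
        alleles = [self.allele([("10", p, "A", "G")], name=f"*{p}") for p in (10, 20, 30)]
        small = make_manifest([("10", 10, "A", "G")])
        big = make_manifest([("10", 10, "A", "G"), ("10", 20, "A", "G")])
        assert gc.percent_star_alleles("CYP2C19", alleles, big) >= \
            gc.percent_star_alleles("CYP2C19", alleles, small)


class TestHlaByAncestry:
    def test_identical_tag_sets_identical_columns(self):
        m = make_manifest([("6", 100, "A", "G")])
        alleles = [gc.StarAllele("HLA-A", "*01:01", [("6", 100, "A", "G")], ancestry=anc)
                   for anc in ("EUR", "ASN", "AFR")]
        res = gc.hla_percent_by_ancestry(["HLA-A"], alleles, m)
        assert res.table.loc["HLA-A"].nunique() == 1
        assert res.mean_sd.loc["HLA-A", "sd"] == 0.0

    def test_ancestry_specific_extra_tag_lowers_coverage(self):
        m = make_manifest([("6", 100, "A", "G")])
        alleles = [
            gc.StarAllele("HLA-B", "*07", [("6", 100, "A", "G")], ancestry="EUR"),
            gc.StarAllele("HLA-B", "*07", [("6", 100, "A", "G"),
                                           ("6", 200, "C", "T")], ancestry="AFR"),
        ]
        res = gc.hla_percent_by_ancestry(["HLA-B"], alleles, m,
                                         ancestries=("EUR", "AFR"))
        assert res.table.loc["HLA-B", "EUR"] == 100.0
        assert res.table.loc["HLA-B", "AFR"] == 0.0

    def test_missing_ancestry_cell_nan(self):
        m = make_manifest([("6", 100, "A", "G")])
        alleles = [gc.StarAllele("HLA-C", "*01", [("6", 100, "A", "G")], ancestry="EUR")]
        res = gc.hla_percent_by_ancestry(["HLA-C"], alleles, m)
        assert np.isnan(res.table.loc["HLA-C", "ASN"])


class TestMtdnaTally:
    loci = [gc.MtLocus("MT-DLOOP", 1, 600), gc.MtLocus("MT-TF", 577, 647),
            gc.MtLocus("MT-RNR1", 648, 1601)]

    def test_overlapping_loci_both_increment_total_once(self):
        m = make_manifest([("MT", 580, "A", "G")])
        tally = gc.mtdna_tally(m, self.loci)
        assert tally.per_locus["MT-DLOOP"] == 1
        assert tally.per_locus["MT-TF"] == 1
        assert tally.total == 1

    def test_array_without_mt_variants(self):
        m = make_manifest([("1", 100, "A", "G")])
        tally = gc.mtdna_tally(m, self.loci)
        assert tally.total == 0 and (tally.per_locus == 0).all()

    def test_five_variant_fixture_hand_count(self):
        m = make_manifest([("MT", p, "A", "G") for p in (10, 580, 600, 700, 1601)])
        tally = gc.mtdna_tally(m, self.loci)
        assert tally.per_locus["MT-DLOOP"] == 3  # 10, 580, 600
        assert tally.per_locus["MT-TF"] == 2     # 580, 600
        assert tally.per_locus["MT-RNR1"] == 2   # 700, 1601
        assert tally.total == 5
        assert tally.per_locus.sum() >= tally.total

    def test_bad_locus_bounds_rejected(self):
        with pytest.raises(ValueError):
            gc.MtLocus("bad", 0, 10)
        with pytest.raises(ValueError):
            gc.MtLocus("bad", 5, 99_999)


class TestCdsDensity:
    def test_hand_substitution(self):
        genes = [gc.GeneRegion("G1", "1", [(1, 1000)])]
        m = make_manifest([("1", p, "A", "G") for p in (10, 20, 30, 40)])
        out = gc.cds_density(m, genes)
        assert out.loc["G1", "mean_distance"] == pytest.approx(200.0)

    def test_zero_snvs_distance_equals_length(self):
        genes = [gc.GeneRegion("G1", "1", [(1, 500)])]
        m = make_manifest([("2", 10, "A", "G")])
        out = gc.cds_density(m, genes)
        assert out.loc["G1", "mean_distance"] == 500.0

    def test_saturated_gene(self):
        genes = [gc.GeneRegion("G1", "1", [(1, 1000)])]
        m = make_manifest([("1", p, "A", "G") for p in range(1, 1000)])
        out = gc.cds_density(m, genes)
        assert out.loc["G1", "mean_distance"] == pytest.approx(1.0)

    def test_identity_distance_times_n_plus_one(self, rng):
        genes = [gc.GeneRegion("G1", "1", [(1, 777)]),
                 gc.GeneRegion("G2", "1", [(1000, 1499), (1600, 1999)])]
        m = make_manifest([("1", int(p), "A", "G")
                           for p in rng.choice(2000, 60, replace=False) + 1])
        out = gc.cds_density(m, genes)
        for g in genes:
            row = out.loc[g.gene]
            assert row["mean_distance"] * (row["n_snvs"] + 1) == pytest.approx(
                g.cds_length)

    def test_non_snv_probes_ignored(self):
        genes = [gc.GeneRegion("G1", "1", [(1, 100)])]
        m = make_manifest([("1", 10, "", "", "cnv_intensity")])
        out = gc.cds_density(m, genes)
        assert out.loc["G1", "n_snvs"] == 0


class TestWindowDensity:
    def test_empty_manifest(self):
        m = make_manifest([("2", 10, "A", "G")])
        m.df = m.df.iloc[:0]
        dens = gc.window_density(m, 100, {"1": 500})
        assert dens.mean == 0 and dens.sd == 0

    def test_uniform_one_per_window(self):
        m = make_manifest([("1", p, "A", "G") for p in (50, 150, 250, 350, 450)])
        dens = gc.window_density(m, 100, {"1": 500})
        assert dens.mean == 1.0 and dens.sd == 0.0

    def test_hand_computed_mean_sd(self):
        # 10 variants over 5 windows: counts 4,3,2,1,0
        positions = [1, 2, 3, 4, 101, 102, 103, 201, 202, 301]
        m = make_manifest([("1", p, "A", "G") for p in positions])
        dens = gc.window_density(m, 100, {"1": 500})
        counts = np.array([4, 3, 2, 1, 0])
        assert dens.per_window["count"].tolist() == counts.tolist()
        assert dens.mean == pytest.approx(counts.mean())
        assert dens.sd == pytest.approx(counts.std())

    def test_counts_sum_to_total(self, rng):
        pos = rng.integers(1, 10_001, size=200)
        m = make_manifest([("1", int(p), "A", "G") for p in pos])
        dens = gc.window_density(m, 1000, {"1": 10_000})
        assert dens.per_window["count"].sum() == len(m)

    def test_variant_beyond_length_errors(self):
        m = make_manifest([("1", 600, "A", "G")])
        with pytest.raises(ValueError, match="beyond"):
            gc.window_density(m, 100, {"1": 500})
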