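import itertools

import numpy as np
import pytest
from scipy.stats import chi2_contingency, fisher_exact, hypergeom

from herbiscan.association import (
    CarrierTable,
    benjamini_hochberg,
    candidate_report,
    carrier_table,
    chi_square_2x2,
    default_gene_pairs,
    fisher_one_sided,
    fisher_two_sided,
    frequency_screen,
    heterozygosity_test,
    screen_all,
)
from herbiscan.gene_models import GeneModel, Strand
from herbiscan.phenotypes import ResistanceCall


class TestFisherOneSided:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((3, 0, 0, 3), 1 / 20),          # C(3,3)C(3,0)/C(6,3)
            ((1, 1, 1, 1), 1 - 1 / 6),       # 1 - P(X = 0)
            ((0, 5, 0, 5), 1.0),             # empty carrier margin
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_hand_derived_tables(self, table, expected):
        assert fisher_one_sided(CarrierTable(*table)) == pytest.approx(expected)

    def test_matches_scipy_on_moderate_margins(self):
        """Dual route: enumeration vs scipy's Fisher exact (greater tail)."""
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if a + b == 0 or c + d == 0:
                continue
            ours = fisher_one_sided(CarrierTable(a, b, c, d))
            _, ref = fisher_exact([[a, b], [c, d]], alternative="greater")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_monotone_in_resistant_carriers(self):
        """Moving a resistant sample from non-carrier to carrier never
        increases the one-sided p."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            b = int(rng.integers(1, 10))
            a = int(rng.integers(0, 10))
            c = int(rng.integers(0, 10))
            d = int(rng.integers(0, 10))
            p0 = fisher_one_sided(CarrierTable(a, b, c, d))
            p1 = fisher_one_sided(CarrierTable(a + 1, b - 1, c, d))
            assert p1 <= p0 + 1e-12

    def test_two_sided_matches_scipy(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            ours = fisher_two_sided(CarrierTable(a, b, c, d))
            _, ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert ours == pytest.approx(ref, abs=1e-9)


class TestFrequencyScreen:
    def test_large_gap_flagged(self):
        # 21.4% vs 1.4% carriers
        assert frequency_screen(CarrierTable(3, 11, 1, 71))

    def test_below_threshold_not_flagged(self):
        # 10% vs 0%
        assert not frequency_screen(CarrierTable(1, 9, 0, 10))

    def test_exact_threshold_inclusive(self):
        # exactly 15% vs 0%
        assert frequency_screen(CarrierTable(3, 17, 0, 20))

    def test_just_below_threshold_rejected(self):
        # 14.9% gap: 149/1000 vs 0
        assert not frequency_screen(CarrierTable(149, 851, 0, 1000))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            frequency_screen(CarrierTable(0, 0, 1, 1))


class TestHeterozygosity:
    def make_inputs(self, statuses_r, statuses_s):
        """Single-locus-per-column matrix over two phenotype groups."""
        from conftest import make_matrix

        n_loci = len(statuses_r[0])
        samples = [f"r{k}" for k in range(len(statuses_r))] + \
                  [f"s{k}" for k in range(len(statuses_s))]
        loci = [("chrT", 110 + j, "A", ["G"], 20.0) for j in range(n_loci)]
        matrix = make_matrix(samples, loci, statuses_r + statuses_s)
        calls = [ResistanceCall(s, "herb", s.startswith("r"), False, s.startswith("r"))
                 for s in samples]
        gene = GeneModel(gene_id="G", chrom="chrT", start=100, end=200,
                         strand=Strand.forward, exons=[(100, 200)], flank_bp=10)
        return matrix, calls, gene

    def test_identical_rates_give_zero_statistic(self):
        matrix, calls, gene = self.make_inputs(["HA"] * 10, ["HA"] * 10)
        res = heterozygosity_test(matrix, calls, gene, "herb")
        assert res.chi_sq == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_closed_form_and_scipy(self):
        # het/hom: resistant 8/92, susceptible 1/99
        a, b, c, d = 8, 92, 1, 99
        stat, p = chi_square_2x2(a, b, c, d)
        n = a + b + c + d
        by_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(by_hand)
        ref_stat, ref_p, _, _ = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p)

    def test_all_homozygous_gene_degenerate(self):
        matrix, calls, gene = self.make_inputs(["AA"] * 5, ["AB"] * 5)
        res = heterozygosity_test(matrix, calls, gene, "herb")
        assert res.degenerate
        assert res.het_rate_resistant == 0.0

    def test_no_called_loci_degenerate_without_statistic(self):
        matrix, calls, gene = self.make_inputs(["..."] * 3, ["..."] * 3)
        res = heterozygosity_test(matrix, calls, gene, "herb")
        assert res.degenerate and res.chi_sq is None

    def test_c_and_missing_calls_excluded(self):
        matrix, calls, gene = self.make_inputs(["HC", "A."], ["CC", "AA"])
        res = heterozygosity_test(matrix, calls, gene, "herb")
        assert res.het_resistant + res.hom_resistant == 2
        assert res.het_susceptible + res.hom_susceptible == 2


class TestScreenAll:
    def make_gene(self, chrom="chrT"):
        return GeneModel(gene_id="G1", chrom=chrom, start=100, end=200,
                         strand=Strand.forward, exons=[(100, 200)],
                         acronym="GeneA", flank_bp=10)

    def test_planted_association_flagged_by_both_screens(self, matrix_factory):
        gene = self.make_gene()
        n_r, n_s = 12, 48
        samples = [f"r{k}" for k in range(n_r)] + [f"s{k}" for k in range(n_s)]
        # locus 0: causal (all resistant carry B, few susceptible); locus 1 flat
        col0 = ["B"] * n_r + ["B"] * 4 + ["A"] * (n_s - 4)
        col1 = ["A", "B"] * ((n_r + n_s) // 2)
        calls_grid = ["".join(t) for t in zip(col0, col1)]
        matrix = matrix_factory(samples,
                                [("chrT", 120, "A", ["G"], 20.0),
                                 ("chrT", 150, "C", ["T"], 20.0)],
                                calls_grid)
        rcalls = [ResistanceCall(s, "herbX", s.startswith("r"), False, False)
                  for s in samples]
        results = screen_all(matrix, rcalls, [gene], pairs={"herbX": ("GeneA",)})
        by_locus = {r.locus_id: r for r in results}
        causal = by_locus["chrT:120"]
        assert causal.fisher_flag and causal.freq_diff_flag
        assert not by_locus["chrT:150"].fisher_flag

    def test_no_resistant_samples_skips_every_locus(self, matrix_factory):
        gene = self.make_gene()
        matrix = matrix_factory(["s1", "s2"], [("chrT", 120, "A", ["G"], 20.0)],
                                ["A", "B"])
        rcalls = [ResistanceCall(s, "herbX", False, False, False)
                  for s in ("s1", "s2")]
        assert screen_all(matrix, rcalls, [gene], pairs={"herbX": ("GeneA",)}) == []

    def test_unmapped_herbicide_is_config_error(self, matrix_factory):
        gene = self.make_gene()
        matrix = matrix_factory(["s1"], [("chrT", 120, "A", ["G"], 20.0)], ["A"])
        rcalls = [ResistanceCall("s1", "mystery", True, False, False)]
        with pytest.raises(ValueError, match="no target gene"):
            screen_all(matrix, rcalls, [gene], pairs={"herbX": ("GeneA",)})

    def test_default_mapping_has_ten_pairs(self):
        pairs = default_gene_pairs()
        assert sum(len(v) for v in pairs.values()) == 10

    def test_carrier_mode_strict_excludes_c(self, matrix_factory):
        gene = self.make_gene()
        matrix = matrix_factory(["r1", "s1"], [("chrT", 120, "A", ["G"], 20.0)],
                                ["C", "A"])
        phenos = {"r1": True, "s1": False}
        loose = carrier_table(matrix, 0, phenos, "bhc")
        strict = carrier_table(matrix, 0, phenos, "bh")
        assert loose.r_carrier == 1 and strict.r_carrier == 0

    def test_bh_column_is_monotone_rearrangement(self):
        ps = [0.01, 0.2, 0.03, 0.8]
        qs = benjamini_hochberg(ps)
        assert np.all(qs >= ps)
        assert np.all(qs <= 1.0)
        # q ordering follows p ordering
        assert np.argmin(qs) == np.argmin(ps)


class TestCandidateReport:
    def test_percentages_recompute_from_counts(self, matrix_factory):
        from herbiscan.consequence import Effect, SubstitutionAnnotation
        from herbiscan.gene_models import RegionLabel

        gene = GeneModel(gene_id="G1", chrom="chrT", start=100, end=200,
                         strand=Strand.forward, exons=[(100, 200)],
                         acronym="GeneA", flank_bp=10)
        n_r, n_s = 19, 70
        samples = [f"r{k}" for k in range(n_r)] + [f"s{k}" for k in range(n_s)]
        col = ["B", "H"] + ["A"] * (n_r - 2) + ["A"] * n_s
        matrix = matrix_factory(samples, [("chrT", 120, "A", ["G"], 20.0)],
                                ["".join([c]) for c in col])
        rcalls = [ResistanceCall(s, "herbX", s.startswith("r"), False, False)
                  for s in samples]
        results = screen_all(matrix, rcalls, [gene], pairs={"herbX": ("GeneA",)})
        ann = SubstitutionAnnotation(
            locus_id="chrT:120", gene_id="G1", gene_acronym="GeneA",
            region=RegionLabel.exon, effect=Effect.missense,
            codon_index=7, ref_aa="D", alt_aa="G",
        )
        report = candidate_report(results, {"chrT:120": ann}, matrix, rcalls)
        assert len(report) == 1
        row = report.iloc[0]
        # 2 carriers among 19 called resistant -> 10.5%
        assert row.pct_resistant_with_snp == pytest.approx(100 * 2 / 19, abs=0.05)
        assert row.n_resistant_called == 19
        n_listed = len(row.resistant_carriers.split(";"))
        assert n_listed == 2
        assert row.substitution == "Asp7Gly"

    def test_zero_susceptible_carriers_report_zero_percent(self, matrix_factory):
        from herbiscan.consequence import Effect, SubstitutionAnnotation
        from herbiscan.gene_models import RegionLabel

        gene = GeneModel(gene_id="G1", chrom="chrT", start=100, end=200,
                         strand=Strand.forward, exons=[(100, 200)],
                         acronym="GeneA", flank_bp=10)
        samples = [f"r{k}" for k in range(16)] + [f"s{k}" for k in range(73)]
        col = ["B", "B"] + ["A"] * 14 + ["A"] * 73
        matrix = matrix_factory(samples, [("chrT", 120, "A", ["G"], 20.0)],
                                ["".join([c]) for c in col])
        rcalls = [ResistanceCall(s, "sethoxydim", s.startswith("r"), False, False)
                  for s in samples]
        results = screen_all(matrix, rcalls, [gene],
                             pairs={"sethoxydim": ("GeneA",)})
        ann = SubstitutionAnnotation(
            locus_id="chrT:120", gene_id="G1", gene_acronym="GeneA",
            region=RegionLabel.exon, effect=Effect.missense,
            codon_index=2096, ref_aa="G", alt_aa="A",
        )
        report = candidate_report(results, {"chrT:120": ann}, matrix, rcalls)
        assert report.iloc[0].pct_susceptible_with_snp == 0.0
        assert report.iloc[0].susceptible_carriers == ""

    def test_unflagged_locus_excluded(self, matrix_factory):
        from herbiscan.consequence import Effect, SubstitutionAnnotation
        from herbiscan.gene_models import RegionLabel

        gene = GeneModel(gene_id="G1", chrom="chrT", start=100, end=200,
                         strand=Strand.forward, exons=[(100, 200)],
                         acronym="GeneA", flank_bp=10)
        samples = ["r1", "r2", "s1", "s2"]
        matrix = matrix_factory(samples, [("chrT", 120, "A", ["G"], 20.0)],
                                ["B", "A", "B", "A"])
        rcalls = [ResistanceCall(s, "herbX", s.startswith("r"), False, False)
                  for s in samples]
        results = screen_all(matrix, rcalls, [gene], pairs={"herbX": ("GeneA",)})
        ann = SubstitutionAnnotation(
            locus_id="chrT:120", gene_id="G1", gene_acronym="GeneA",
            region=RegionLabel.exon, effect=Effect.missense,
            codon_index=1, ref_aa="D", alt_aa="G",
        )
        assert len(candidate_report(results, {"chrT:120": ann}, matrix, rcalls)) == 0
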