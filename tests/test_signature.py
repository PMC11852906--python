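import numpy as np
import pandas as pd
import pytest

from aplmeth import (
    DMR,
    GenomeInfo,
    chromosome_enrichment,
    region_beta_matrix,
    select_unique_hyper,
)

from conftest import table_from_betas


def dmr(chrom, start, end, direction, comparison, delta=None):
    if delta is None:
        delta = 0.3 if direction == "hyper" else -0.3
    return DMR(chrom, start, end, 3, 3, delta, direction, comparison)


class TestSelectUniqueHyper:
    def test_set_algebra_example(self):
        """r1 unique to A; r2 claimed by A and B -> dropped; r3 overlaps a
        lesion-vs-NAT DMR -> excluded."""
        r1 = (100, 150)
        r2 = (300, 350)
        r3 = (500, 550)
        inter = {
            "A_vs_B": [dmr("chr1", *r1, "hyper", "A_vs_B"), dmr("chr1", *r2, "hyper", "A_vs_B")],
            "B_vs_C": [dmr("chr1", *r2, "hyper", "B_vs_C"), dmr("chr1", *r3, "hyper", "B_vs_C")],
        }
        vs_nat = {"A_vs_NAT": [dmr("chr1", 540, 600, "hyper", "A_vs_NAT")]}
        sig = select_unique_hyper(inter, vs_nat)
        assert [(r.chrom, r.start, r.end) for r in sig.regions] == [("chr1", *r1)]
        assert sig.regions[0].subtype == "A"
        assert sig.n_nat_excluded == 1
        assert sig.n_ambiguous == 2

    def test_empty_vs_nat_is_pure_uniqueness_partition(self):
        inter = {
            "A_vs_B": [dmr("chr1", 100, 150, "hyper", "A_vs_B")],
            "A_vs_C": [dmr("chr1", 300, 350, "hyper", "A_vs_C")],
        }
        sig = select_unique_hyper(inter, {})
        assert len(sig.regions) == 2
        assert {r.subtype for r in sig.regions} == {"A"}

    def test_all_candidates_overlapping_nat_gives_empty_signature(self):
        inter = {"A_vs_B": [dmr("chr1", 100, 150, "hyper", "A_vs_B")]}
        vs_nat = {"A_vs_NAT": [dmr("chr1", 150, 200, "hypo", "A_vs_NAT")]}
        sig = select_unique_hyper(inter, vs_nat)
        assert sig.regions == []
        assert sig.n_nat_excluded == 1

    def test_hypo_dmr_assigned_to_second_named_subtype(self):
        inter = {"A_vs_B": [dmr("chr1", 100, 150, "hypo", "A_vs_B")]}
        sig = select_unique_hyper(inter, {})
        assert sig.regions[0].subtype == "B"

    def test_consistent_multi_comparison_claims_merge(self):
        inter = {
            "A_vs_B": [dmr("chr1", 100, 150, "hyper", "A_vs_B")],
            "A_vs_C": [dmr("chr1", 120, 170, "hyper", "A_vs_C")],
        }
        sig = select_unique_hyper(inter, {})
        (r,) = sig.regions
        assert (r.start, r.end) == (100, 170)
        assert r.comparisons == ("A_vs_B", "A_vs_C")

    def test_invariant_to_supply_order(self):
        inter = {
            "A_vs_B": [dmr("chr1", 100, 150, "hyper", "A_vs_B")],
            "B_vs_C": [dmr("chr1", 300, 350, "hyper", "B_vs_C")],
        }
        fwd = select_unique_hyper(inter, {})
        rev = select_unique_hyper(dict(reversed(list(inter.items()))), {})
        assert fwd.regions == rev.regions


class TestChromosomeEnrichment:
    def test_two_equal_chroms_counts_three_one(self):
        genome = GenomeInfo({"chr1": 1000, "chr2": 1000})
        dmrs = [dmr("chr1", i * 100, i * 100 + 10, "hyper", "c") for i in range(1, 4)]
        dmrs.append(dmr("chr2", 100, 110, "hyper", "c"))
        enr = chromosome_enrichment(dmrs, genome).set_index("chrom")
        assert enr.loc["chr1", "enrichment"] == pytest.approx(1.5)
        assert enr.loc["chr2", "enrichment"] == pytest.approx(0.5)
        assert not enr.loc["chr1", "flagged"]  # threshold is strict: > 1.5

    def test_counts_proportional_to_length_give_unit_enrichment(self):
        genome = GenomeInfo({"chr1": 2000, "chr2": 1000})
        dmrs = [dmr("chr1", i, i + 1, "hyper", "c") for i in (10, 500)] + [
            dmr("chr2", 10, 11, "hyper", "c")
        ]
        enr = chromosome_enrichment(dmrs, genome)
        np.testing.assert_allclose(enr["enrichment"], 1.0)

    def test_length_weighted_mean_is_exactly_one(self, default_cohort):
        from aplmeth import AnalysisConfig, analyze_cohort

        # reuse the default cohort's DMRs for a realistic count pattern
        genome = default_cohort.genome
        dmrs = [
            dmr(f"chr{1 + i % 4}", 100 + 200 * i, 150 + 200 * i, "hyper", "c")
            for i in range(17)
        ]
        enr = chromosome_enrichment(dmrs, genome)
        w = enr["length"] / enr["length"].sum()
        assert float((w * enr["enrichment"]).sum()) == pytest.approx(1.0)

    def test_unknown_chromosome_errors(self):
        genome = GenomeInfo({"chr1": 1000})
        with pytest.raises(ValueError, match="chrM"):
            chromosome_enrichment([dmr("chrM", 1, 5, "hyper", "c")], genome)

    def test_flagging_above_threshold(self):
        genome = GenomeInfo({"chr1": 1000, "chr2": 1000, "chr3": 1000})
        dmrs = [dmr("chr1", i * 10, i * 10 + 2, "hyper", "c") for i in range(1, 9)]
        dmrs += [dmr("chr2", 100, 110, "hyper", "c")]
        enr = chromosome_enrichment(dmrs, genome).set_index("chrom")
        assert enr.loc["chr1", "flagged"]
        assert not enr.loc["chr2", "flagged"]


class TestRegionBetaMatrix:
    def _table(self):
        idx = pd.MultiIndex.from_tuples(
            [("chr1", 100), ("chr1", 140), ("chr1", 900)], names=["chrom", "pos"]
        )
        betas = pd.DataFrame({"s1": [0.2, 0.4, 0.9], "s2": [0.6, 0.8, 0.1]}, index=idx)
        return table_from_betas(betas, depth=10)

    def test_mean_of_member_site_betas(self):
        (row,) = region_beta_matrix([dmr("chr1", 90, 150, "hyper", "c")], self._table()).to_numpy()
        assert row[0] == pytest.approx(0.3)
        assert row[1] == pytest.approx(0.7)

    def test_single_cpg_overlap_passes_through(self):
        m = region_beta_matrix([dmr("chr1", 850, 950, "hyper", "c")], self._table())
        assert m.iloc[0, 0] == pytest.approx(0.9)

    def test_region_without_cpgs_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="no tested CpGs"):
            m = region_beta_matrix([dmr("chr1", 400, 500, "hyper", "c")], self._table())
        assert m.isna().all().all()

    def test_no_coverage_yields_missing_entry(self):
        idx = pd.MultiIndex.from_tuples([("chr1", 100)], names=["chrom", "pos"])
        from aplmeth import CpGSiteTable

        meth = pd.DataFrame({"s1": [3], "s2": [0]}, index=idx)
        unmeth = pd.DataFrame({"s1": [7], "s2": [0]}, index=idx)
        m = region_beta_matrix([dmr("chr1", 90, 110, "hyper", "c")], CpGSiteTable(meth, unmeth))
        assert m.loc[:, "s2"].isna().all()
        assert m.loc[:, "s1"].iloc[0] == pytest.approx(0.3)

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            region_beta_matrix([], self._table())
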