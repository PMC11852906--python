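import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aplmeth import AnalysisConfig, adjust_bh, filter_sites
from aplmeth.sites import test_sites as run_test_sites
from aplmeth.io import write_bed_intervals

from conftest import make_table, table_from_betas


def bh_oracle(p):
    """Step-up BH by the textbook formula: sort, p(i)*n/i, enforce monotone."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.01], [0.04, 0.02]),
            ([0.5], [0.5]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected)

    def test_empty_input(self):
        assert len(adjust_bh([])) == 0

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=25), st.randoms())
    def test_elementwise_increase_and_permutation_equivariance(self, p, rnd):
        adj = adjust_bh(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        shuffled = adjust_bh([p[i] for i in perm])
        np.testing.assert_allclose(shuffled, adj[perm], atol=1e-12)


class TestFilterSites:
    def _three_sample_table(self, depths):
        return make_table(
            {
                sid: [("chr1", 100, d, 0), ("chr1", 200, 10, 0)]
                for sid, d in zip(["a", "b", "c"], depths)
            }
        )

    def test_coverage_floor_in_every_sample(self):
        cfg = AnalysisConfig()
        kept = filter_sites(self._three_sample_table([5, 5, 5]), cfg)
        assert ("chr1", 100) in kept.index
        kept = filter_sites(self._three_sample_table([5, 4, 5]), cfg)
        assert ("chr1", 100) not in kept.index
        assert ("chr1", 200) in kept.index

    def test_masked_position_dropped_regardless_of_depth(self, tmp_path):
        mask = tmp_path / "mask.bed"
        write_bed_intervals([("chr1", 100, 100)], mask)
        cfg = AnalysisConfig(maf_mask=mask)
        kept = filter_sites(self._three_sample_table([50, 50, 50]), cfg)
        assert ("chr1", 100) not in kept.index
        assert ("chr1", 200) in kept.index

    def test_no_mask_high_coverage_is_identity(self):
        table = self._three_sample_table([9, 9, 9])
        kept = filter_sites(table, AnalysisConfig())
        assert kept.index.equals(table.index)

    def test_everything_filtered_warns(self):
        with pytest.warns(UserWarning, match="no CpG sites"):
            filter_sites(self._three_sample_table([1, 1, 1]).select_rows([True, False]), AnalysisConfig())


class TestTestSites:
    def test_paired_six_pairs_all_hyper(self):
        tumor_betas = [0.45, 0.5, 0.55, 0.6, 0.65, 0.7]
        betas = pd.DataFrame(
            {f"t{i}": [b] for i, b in enumerate(tumor_betas)}
            | {f"n{i}": [0.1] for i in range(6)},
            index=pd.MultiIndex.from_tuples([("chr1", 100)], names=["chrom", "pos"]),
        )
        table = table_from_betas(betas)
        res = run_test_sites(
            table,
            [f"t{i}" for i in range(6)],
            [f"n{i}" for i in range(6)],
            paired=True,
            config=AnalysisConfig(),
        )
        assert res["p_raw"].iloc[0] == pytest.approx(0.03125)
        assert res["significant"].iloc[0]
        assert res["delta_beta"].iloc[0] == pytest.approx(np.mean(tumor_betas) - 0.1)

    def test_paired_five_pairs_never_significant(self):
        betas = pd.DataFrame(
            {f"t{i}": [0.4 + 0.05 * i] for i in range(5)}
            | {f"n{i}": [0.1] for i in range(5)},
            index=pd.MultiIndex.from_tuples([("chr1", 100)], names=["chrom", "pos"]),
        )
        res = run_test_sites(
            table_from_betas(betas),
            [f"t{i}" for i in range(5)],
            [f"n{i}" for i in range(5)],
            paired=True,
            config=AnalysisConfig(),
        )
        assert res["p_raw"].iloc[0] == pytest.approx(0.0625)
        assert not res["significant"].iloc[0]

    def test_unpaired_complete_separation(self):
        betas = pd.DataFrame(
            {f"a{i}": [0.6 + 0.05 * i] for i in range(4)}
            | {f"b{i}": [0.05 * (i + 1)] for i in range(4)},
            index=pd.MultiIndex.from_tuples([("chr1", 100)], names=["chrom", "pos"]),
        )
        res = run_test_sites(
            table_from_betas(betas),
            [f"a{i}" for i in range(4)],
            [f"b{i}" for i in range(4)],
            paired=False,
            config=AnalysisConfig(),
        )
        assert res["p_raw"].iloc[0] == pytest.approx(2 / 70)

    def test_untestable_sites_reported_not_dropped(self):
        # identical tumor/NAT betas -> all differences zero -> untestable
        betas = pd.DataFrame(
            {f"t{i}": [0.3, 0.5] for i in range(4)} | {f"n{i}": [0.3, 0.5] for i in range(4)},
            index=pd.MultiIndex.from_tuples(
                [("chr1", 100), ("chr1", 130)], names=["chrom", "pos"]
            ),
        )
        res = run_test_sites(
            table_from_betas(betas),
            [f"t{i}" for i in range(4)],
            [f"n{i}" for i in range(4)],
            paired=True,
            config=AnalysisConfig(),
        )
        assert len(res) == 2
        assert res["untestable"].all()
        assert (res["p_raw"] == 1.0).all()
        assert not res["significant"].any()

    def test_adjusted_never_below_raw_and_flag_consistent(self, default_cohort):
        samples = default_cohort.samples
        pairs = samples.pairs()
        cfg = AnalysisConfig()
        table = filter_sites(default_cohort.sites, cfg, samples.sample_ids)
        res = run_test_sites(
            table.select_rows(np.arange(table.n_sites) < 2000),
            [t for t, _ in pairs[:10]],
            [n for _, n in pairs[:10]],
            paired=True,
            config=cfg,
        )
        assert (res["p_adj"] >= res["p_raw"] - 1e-12).all()
        expected_flag = (res["p_adj"] < cfg.alpha) & (res["delta_beta"].abs() >= cfg.min_delta)
        assert (res["significant"] == (expected_flag & ~res["untestable"])).all()

    def test_small_groups_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="at least 3"):
            run_test_sites(default_cohort.sites, ["SSL_00_T"], ["SSL_00_N"], True, AnalysisConfig())


def test_null_cohort_raw_p_fraction_within_binomial_noise():
    """Wilcoxon on null paired data is conservative; the fraction of raw
    p < 0.05 must not exceed 0.05 by more than two binomial SEs."""
    from aplmeth import SimulationConfig, Tissue, generate_null_cohort

    cohort = generate_null_cohort(SimulationConfig(seed=5, n_cpgs=4000))
    cfg = AnalysisConfig()
    table = filter_sites(cohort.sites, cfg, cohort.samples.sample_ids)
    pairs = cohort.samples.pairs()
    res = run_test_sites(
        table,
        [t for t, _ in pairs],
        [n for _, n in pairs],
        paired=True,
        config=cfg,
    )
    frac = (res["p_raw"] < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / len(res))
    assert frac <= 0.05 + 2 * se
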