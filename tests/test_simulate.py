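import numpy as np
import pandas as pd
import pytest

from aplmeth import (
    SimulationConfig,
    Tissue,
    generate_cohort,
    generate_null_cohort,
    read_cov_files,
)
from aplmeth.simulate import KIND_SIGNATURE, KIND_TUMOR_VS_NAT

SMALL = dict(n_cpgs=1200, n_patients_per_subtype=4, planted_regions_per_subtype=6,
             signature_regions_per_subtype=3, n_promoter_clusters=4, chrom_length=400_000)


class TestDeterminismAndStructure:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(SimulationConfig(seed=3, **SMALL))
        b = generate_cohort(SimulationConfig(seed=3, **SMALL))
        pd.testing.assert_frame_equal(a.sites.meth, b.sites.meth)
        pd.testing.assert_frame_equal(a.sites.unmeth, b.sites.unmeth)
        assert a.truth.regions == b.truth.regions
        assert a.truth.cimp_labels == b.truth.cimp_labels

    def test_different_seed_differs(self):
        a = generate_cohort(SimulationConfig(seed=3, **SMALL))
        b = generate_cohort(SimulationConfig(seed=4, **SMALL))
        assert not a.sites.meth.equals(b.sites.meth)

    def test_adding_patients_preserves_existing_samples(self):
        small = generate_cohort(SimulationConfig(seed=3, **SMALL))
        bigger_cfg = {**SMALL, "n_patients_per_subtype": 5}
        big = generate_cohort(SimulationConfig(seed=3, **bigger_cfg))
        shared = small.sites.samples
        pd.testing.assert_frame_equal(small.sites.meth, big.sites.meth[shared])

    def test_every_patient_fully_paired(self):
        cohort = generate_cohort(SimulationConfig(seed=1, **SMALL))
        pairs = cohort.samples.pairs()
        assert len(pairs) == 3 * SMALL["n_patients_per_subtype"]
        assert len(cohort.samples.records) == 2 * len(pairs)

    def test_counts_valid_and_betas_bounded(self):
        cohort = generate_cohort(SimulationConfig(seed=1, **SMALL))
        assert (cohort.sites.meth.to_numpy() >= 0).all()
        assert (cohort.sites.unmeth.to_numpy() >= 0).all()
        beta = cohort.sites.beta().to_numpy()
        finite = beta[np.isfinite(beta)]
        assert finite.min() >= 0 and finite.max() <= 1

    def test_planted_regions_disjoint_and_well_formed(self):
        cohort = generate_cohort(SimulationConfig(seed=2, **SMALL))
        cfg = SimulationConfig(seed=2, **SMALL)
        regions = sorted(r.interval for r in cohort.truth.regions)
        for (c1, s1, e1), (c2, s2, e2) in zip(regions, regions[1:]):
            assert c1 != c2 or e1 < s2  # non-overlapping
        chroms = cohort.sites.index.get_level_values("chrom").to_numpy()
        poss = cohort.sites.index.get_level_values("pos").to_numpy()
        for r in cohort.truth.regions:
            inside = np.sort(poss[(chroms == r.chrom) & (poss >= r.start) & (poss <= r.end)])
            assert len(inside) >= cfg.region_n_cpgs
            assert np.diff(inside).max() <= cfg.intra_region_gap

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(SimulationConfig(seed=0, n_cpgs=5000, n_chroms=1, chrom_length=10_000))
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(
                SimulationConfig(seed=0, **{**SMALL, "planted_regions_per_subtype": 1000})
            )


class TestPlantedEffects:
    def test_mean_planted_delta_recovered_at_high_depth(self):
        """Monte-Carlo check of the generating model: empirical tumor-NAT
        delta beta over planted sites approximates the configured shift."""
        cfg = SimulationConfig(
            seed=8, n_cpgs=4000, n_patients_per_subtype=10, mean_depth=50,
            planted_delta=0.4, region_n_cpgs=5, planted_regions_per_subtype=40,
            signature_regions_per_subtype=0, n_promoter_clusters=0,
        )
        cohort = generate_cohort(cfg)
        beta = cohort.sites.beta()
        chroms = cohort.sites.index.get_level_values("chrom").to_numpy()
        poss = cohort.sites.index.get_level_values("pos").to_numpy()
        deltas = []
        for s in ("SSL", "TA", "VA_TVA"):
            pairs = cohort.samples.pairs()
            sub_pairs = [(t, n) for t, n in pairs if t.startswith(s)]
            for r in cohort.truth.regions_of(KIND_TUMOR_VS_NAT, subtype=s):
                mask = (chroms == r.chrom) & (poss >= r.start) & (poss <= r.end)
                d = beta.loc[mask, [t for t, _ in sub_pairs]].to_numpy() - beta.loc[
                    mask, [n for _, n in sub_pairs]
                ].to_numpy()
                sign = 1.0 if r.direction == "hyper" else -1.0
                deltas.append(sign * np.nanmean(d))
        assert np.mean(deltas) == pytest.approx(0.4, abs=0.05)

    def test_null_cohort_has_no_truth(self):
        cohort = generate_null_cohort(SimulationConfig(seed=5, **SMALL))
        assert cohort.truth.regions == []
        assert set(cohort.truth.cimp_labels.values()) <= {"CIMP-L/N"}
        assert cohort.truth.panel_sites == []

    def test_depth_mean_within_three_se_of_poisson_mean(self):
        cfg = SimulationConfig(seed=6, **SMALL)
        cohort = generate_null_cohort(cfg)
        depth = cohort.sites.depth().to_numpy().ravel()
        se = np.sqrt(cfg.mean_depth / depth.size)
        assert abs(depth.mean() - cfg.mean_depth) < 3 * se

    def test_zero_delta_cohort_is_null_despite_truth_regions(self):
        cfg = SimulationConfig(seed=7, planted_delta=0.0, **SMALL)
        cohort = generate_cohort(cfg)
        assert len(cohort.truth.regions) > 0
        beta = cohort.sites.beta()
        chroms = cohort.sites.index.get_level_values("chrom").to_numpy()
        poss = cohort.sites.index.get_level_values("pos").to_numpy()
        pairs = cohort.samples.pairs()
        diffs = []
        for r in cohort.truth.regions_of(KIND_TUMOR_VS_NAT):
            mask = (chroms == r.chrom) & (poss >= r.start) & (poss <= r.end)
            sub = [(t, n) for t, n in pairs if t.startswith(r.subtype)]
            d = beta.loc[mask, [t for t, _ in sub]].to_numpy() - beta.loc[
                mask, [n for _, n in sub]
            ].to_numpy()
            diffs.append(np.nanmean(d))
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.03)

    def test_cimp_fraction_and_panel_elevation(self):
        cfg = SimulationConfig(seed=9, **{**SMALL, "cimp_fraction": 0.5})
        cohort = generate_cohort(cfg)
        labels = cohort.truth.cimp_labels
        assert set(labels) == set(cohort.samples.samples(tissue=Tissue.tumor))
        beta = cohort.sites.beta()
        idx = pd.MultiIndex.from_tuples(cohort.truth.panel_sites, names=["chrom", "pos"])
        panel = beta.loc[idx]
        high = [s for s, l in labels.items() if l == "CIMP-H"]
        low = [s for s, l in labels.items() if l == "CIMP-L/N"]
        assert panel[high].mean().mean() > panel[low].mean().mean() + 0.3


class TestEmission:
    def test_round_trip_of_emitted_files_is_bit_exact(self, tmp_path):
        cfg = SimulationConfig(seed=4, **{**SMALL, "n_cpgs": 400, "n_patients_per_subtype": 3,
                                          "planted_regions_per_subtype": 2,
                                          "signature_regions_per_subtype": 1,
                                          "n_promoter_clusters": 1})
        cohort = generate_cohort(cfg, out_dir=tmp_path)
        paths = {sid: tmp_path / f"{sid}.cov" for sid in cohort.sites.samples}
        back = read_cov_files(paths)
        pd.testing.assert_frame_equal(back.meth, cohort.sites.meth.sort_index())
        pd.testing.assert_frame_equal(back.unmeth, cohort.sites.unmeth.sort_index())
        assert (tmp_path / "sample_sheet.tsv").exists()
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "promoters.bed").exists()

    def test_truth_json_round_trip(self, tmp_path):
        from aplmeth import SyntheticTruth

        cohort = generate_cohort(
            SimulationConfig(seed=4, **SMALL), out_dir=tmp_path
        )
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.regions == cohort.truth.regions
        assert back.cimp_labels == cohort.truth.cimp_labels
        assert back.promoters == cohort.truth.promoters
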