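import numpy as np
import pytest

from haploscan.divergence import genome_fst
from haploscan.diversity import genome_summary, make_windows, window_diversity
from haploscan.synthetic_data import (
    CNVSegment,
    SimConfig,
    SweepSpec,
    inject_sweep,
    simulate_cnv_depth,
    simulate_two_pop_snps,
)
from haploscan.variant_io import read_vcf, write_vcf


class TestSnpSimulator:
    def test_seeded_determinism(self):
        cfg = SimConfig(contig_lengths={"c1": 60_000}, seed=4)
        g1, t1 = simulate_two_pop_snps(cfg)
        g2, t2 = simulate_two_pop_snps(cfg)
        np.testing.assert_array_equal(g1.alleles, g2.alleles)
        np.testing.assert_array_equal(g1.positions, g2.positions)
        g3, _ = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 60_000}, seed=5))
        assert g3.n_sites != g1.n_sites or not np.array_equal(g3.positions, g1.positions)

    def test_sample_naming_and_groups(self):
        cfg = SimConfig(n1=3, n2=2, n3=1, contig_lengths={"c1": 30_000}, seed=0)
        g, truth = simulate_two_pop_snps(cfg)
        assert g.samples[:3] == ["G1_01", "G1_02", "G1_03"]
        assert truth.groups.sizes() == {"group1": 3, "group2": 2, "group3": 1}

    def test_every_site_segregates(self):
        g, _ = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 50_000}, seed=1))
        alt, called = g.allele_counts()
        assert ((alt > 0) & (alt < called)).all()

    def test_emitted_panel_survives_vcf_round_trip(self, tmp_path):
        g, _ = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 40_000}, seed=2))
        p = tmp_path / "sim.vcf"
        write_vcf(g, p)
        g2 = read_vcf(p)
        np.testing.assert_array_equal(g.alleles, g2.alleles)
        np.testing.assert_array_equal(g.positions, g2.positions)
        assert g.samples == g2.samples

    def test_f_zero_panmixia_fst_near_zero(self):
        cfg = SimConfig(n1=15, n2=15, n3=0, F1=0.0, F2=0.0, missing_rate=0.0,
                        ld_copy_prob=0.0, contig_lengths={"c1": 500_000}, seed=6)
        g, truth = simulate_two_pop_snps(cfg)
        assert abs(genome_fst(g, truth.groups)) <= 0.02

    def test_moderate_divergence_fst_tracks_f(self):
        cfg = SimConfig(n1=15, n2=15, n3=0, F1=0.3, F2=0.3, missing_rate=0.0,
                        ld_copy_prob=0.0, contig_lengths={"c1": 500_000}, seed=6)
        g, truth = simulate_two_pop_snps(cfg)
        assert genome_fst(g, truth.groups) == pytest.approx(0.3, abs=0.05)

    def test_high_f_group_has_lower_diversity(self):
        g, truth = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 300_000}, seed=8))
        w = make_windows(g.contigs)
        s1 = genome_summary(window_diversity(g, truth.groups.indices(g.samples, "group1"), w))
        s2 = genome_summary(window_diversity(g, truth.groups.indices(g.samples, "group2"), w))
        # F2=0.75 shrinks within-group heterozygosity far below F1=0.3's
        assert s2["theta_pi"] < s1["theta_pi"]


class TestInjectSweep:
    def test_trivial_sweep_is_identity_like(self):
        g, truth = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 100_000}, seed=9))
        spec = SweepSpec("c1", 50_000, reduction=1.0, singleton_fraction=0.0)
        g2, t2 = inject_sweep(g, truth, spec, seed=9)
        np.testing.assert_array_equal(g.alleles, g2.alleles)
        assert t2.sweep is spec

    def test_diversity_reduced_in_interval(self):
        cfg = SimConfig(ld_copy_prob=0.0, contig_lengths={"c1": 300_000}, seed=10)
        g, truth = simulate_two_pop_snps(cfg)
        idx = truth.groups.indices(g.samples, "group1")
        spec = SweepSpec("c1", 150_000)
        g2, t2 = inject_sweep(g, truth, spec, seed=10)

        def pi_in(gg, lo, hi):
            w = make_windows({"c1": 300_000}, 10_000, 10_000)
            wt = window_diversity(gg, idx, w)
            m = (wt["start"] >= lo) & (wt["end"] <= hi)
            return wt.loc[m, "theta_pi"].mean()

        before = pi_in(g, spec.start, spec.end)
        after = pi_in(g2, spec.start, spec.end)
        outside = pi_in(g2, 1, 100_000)
        assert after < before / 3           # ~10x thinning, loose bound
        assert outside == pytest.approx(pi_in(g, 1, 100_000), rel=0.05)

    def test_other_groups_untouched(self):
        g, truth = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 150_000}, seed=11))
        g2, _ = inject_sweep(g, truth, SweepSpec("c1", 75_000), seed=11)
        idx2 = truth.groups.indices(g.samples, "group2")
        kept = np.isin(g.positions, g2.positions)
        np.testing.assert_array_equal(g.alleles[kept][:, idx2], g2.alleles[:, idx2])

    def test_interval_out_of_range_errors(self):
        g, truth = simulate_two_pop_snps(SimConfig(contig_lengths={"c1": 50_000}, seed=0))
        with pytest.raises(ValueError, match="outside contig"):
            inject_sweep(g, truth, SweepSpec("c1", 49_000), seed=0)
        with pytest.raises(ValueError, match="unknown contig"):
            inject_sweep(g, truth, SweepSpec("nope", 25_000), seed=0)


class TestCnvDepthSimulator:
    def test_seeded_determinism(self):
        cfg = SimConfig(contig_lengths={"c1": 50_000}, seed=3)
        d1, _ = simulate_cnv_depth(cfg)
        d2, _ = simulate_cnv_depth(cfg)
        np.testing.assert_array_equal(d1.counts, d2.counts)

    def test_segment_means_scale_with_cn(self):
        segs = [CNVSegment("c1", 10_001, 20_000, 3, 1), CNVSegment("c1", 30_001, 40_000, 0, 1)]
        cfg = SimConfig(contig_lengths={"c1": 60_000}, cnv_segments=segs,
                        missing_rate=0.0, seed=12)
        d, truth = simulate_cnv_depth(cfg)
        i1 = truth.groups.indices(d.samples, "group1")
        bins = d.bins
        base = ((bins["start"] < 10_001) | (bins["start"] > 40_000)).to_numpy()
        gain = ((bins["start"] >= 10_001) & (bins["end"] <= 20_000)).to_numpy()
        absent = ((bins["start"] >= 30_001) & (bins["end"] <= 40_000)).to_numpy()
        m_base = d.counts[np.ix_(base, i1)].mean()
        assert d.counts[np.ix_(gain, i1)].mean() == pytest.approx(3 * m_base, rel=0.15)
        assert d.counts[np.ix_(absent, i1)].mean() < 0.15 * m_base

    def test_group3_stays_baseline(self):
        segs = [CNVSegment("c1", 10_001, 20_000, 3, 0)]
        cfg = SimConfig(contig_lengths={"c1": 40_000}, cnv_segments=segs, seed=13)
        d, truth = simulate_cnv_depth(cfg)
        i3 = truth.groups.indices(d.samples, "group3")
        bins = d.bins
        inb = ((bins["start"] >= 10_001) & (bins["end"] <= 20_000)).to_numpy()
        outb = ~inb
        for j in i3:
            assert d.counts[inb, j].mean() == pytest.approx(d.counts[outb, j].mean(), rel=0.25)

    def test_truth_table_matches_config(self):
        segs = [CNVSegment("c1", 1_001, 5_000, 2, 1)]
        _, truth = simulate_cnv_depth(SimConfig(contig_lengths={"c1": 20_000},
                                                cnv_segments=segs, seed=0))
        tab = truth.cnv_table()
        assert tab.iloc[0]["cn_group1"] == 2 and tab.iloc[0]["start"] == 1_001


class TestConfigValidation:
    def test_bad_f_rejected(self):
        with pytest.raises(ValueError, match="F parameters"):
            SimConfig(F1=1.0).validate()

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(snp_density=0.0).validate()
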