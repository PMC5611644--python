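import numpy as np
import pytest

from methdyn.simulate import (
    ConfigurationError,
    PlantedDMR,
    SimulationConfig,
    plant_truth,
    random_planted_dmrs,
    simulate_genome,
    simulate_sirnas,
    simulate_stage,
)


def flat_chh_config(p, seed=5, length=250_000):
    """A background-only genome whose CHH probability is p everywhere."""
    profiles = {
        "s1": {(c, k): (p if c == "CHH" else 0.0)
               for c in ("CG", "CHG", "CHH")
               for k in ("te_edge", "te_interior", "gene_body", "background")}
    }
    return SimulationConfig(
        seed=seed, n_chroms=1, chrom_length=length, n_tes=0, n_genes=0,
        stage_profiles=profiles, peri_chh_boost={}, n_saturated_sites=0,
    )


class TestGenome:
    def test_same_seed_gives_identical_annotations_and_sites(self, small_config):
        g1 = simulate_genome(small_config)
        g2 = simulate_genome(small_config)
        assert g1.tes == g2.tes and g1.genes == g2.genes
        assert g1.sites.equals(g2.sites)

    def test_no_tes_gives_genes_only(self):
        cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=200_000,
                               n_tes=0, n_genes=30)
        g = simulate_genome(cfg)
        assert g.tes == [] and len(g.genes) == 30

    def test_pericentromere_centered(self):
        cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=1_000_000,
                               pericentromere_fraction=0.2, n_tes=40, n_genes=20)
        g = simulate_genome(cfg)
        (peri,) = g.pericentromeres
        assert (peri.start, peri.end) == (400_000, 600_000)

    def test_te_and_gene_intervals_do_not_overlap(self, small_genome):
        ivs = sorted(small_genome.tes + small_genome.genes,
                     key=lambda i: (i.chrom, i.start))
        for a, b in zip(ivs, ivs[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_pericentromeric_te_density_at_least_3x_arms(self, small_genome,
                                                         small_config):
        (peri,) = small_genome.pericentromeres
        peri_bp = sum(t.length for t in small_genome.tes
                      if t.start >= peri.start and t.end <= peri.end)
        arm_bp = sum(t.length for t in small_genome.tes) - peri_bp
        L = small_config.chrom_length
        peri_density = peri_bp / peri.length
        arm_density = arm_bp / (L - peri.length)
        assert peri_density >= 3 * arm_density

    def test_context_frequencies_chh_heavy(self, small_genome):
        counts = small_genome.sites["context"].value_counts()
        assert counts["CHH"] / counts["CG"] == pytest.approx(5.0, rel=0.15)

    def test_sites_within_chromosome_bounds(self, small_genome, small_config):
        assert small_genome.sites["pos"].between(
            0, small_config.chrom_length - 1).all()

    def test_overfull_genome_rejected(self):
        cfg = SimulationConfig(seed=1, n_chroms=1, chrom_length=50_000,
                               n_tes=100, n_genes=100)
        with pytest.raises(ConfigurationError):
            simulate_genome(cfg)


class TestStage:
    def test_unknown_stage_rejected(self, small_config, small_genome):
        with pytest.raises(ConfigurationError):
            simulate_stage(small_config, "gametophyte", small_genome)

    def test_probability_one_gives_fully_methylated_counts(self):
        cfg = flat_chh_config(1.0, length=20_000)
        meth = simulate_stage(cfg, "s1", simulate_genome(cfg))
        chh = meth.subset_context("CHH")
        assert (chh["n_unmeth"] == 0).all() and (chh["n_meth"] >= 1).all()

    def test_probability_zero_gives_no_methylation(self):
        cfg = flat_chh_config(0.0, length=20_000)
        meth = simulate_stage(cfg, "s1", simulate_genome(cfg))
        assert (meth.subset_context("CHH")["n_meth"] == 0).all()

    def test_pooled_level_converges_to_configured_probability(self):
        # law of large numbers: >=10,000 CHH sites at 20x, p = 0.15
        cfg = flat_chh_config(0.15)
        meth = simulate_stage(cfg, "s1", simulate_genome(cfg))
        chh = meth.subset_context("CHH")
        assert len(chh) >= 10_000
        pooled = chh["n_meth"].sum() / (chh["n_meth"].sum() + chh["n_unmeth"].sum())
        assert pooled == pytest.approx(0.15, abs=0.01)

    def test_planted_dmr_overrides_interval(self):
        cfg = flat_chh_config(0.0, length=50_000)
        cfg.stage_profiles["s2"] = dict(cfg.stage_profiles["s1"])
        cfg.planted_dmrs = [
            PlantedDMR("Chr1", 10_000, 12_000, "CHH", ("s1", "s2"), 0.9)
        ]
        g = simulate_genome(cfg)
        m1 = simulate_stage(cfg, "s1", g)
        chh = m1.subset_context("CHH")
        inside = chh[chh["pos"].between(10_000, 11_999)]
        outside = chh[~chh["pos"].between(10_000, 11_999)]
        pooled = inside["n_meth"].sum() / (inside["n_meth"] + inside["n_unmeth"]).sum()
        assert pooled == pytest.approx(0.95, abs=0.05)
        assert (outside["n_meth"] == 0).all()

    def test_saturated_sites_have_no_unmethylated_reads(
            self, small_config, small_genome, small_truth, small_stages):
        meth = small_stages[small_config.saturated_stage]
        df = meth.df.set_index(["chrom", "pos", "strand"])
        sat = df.loc[list(small_truth.saturated)]
        assert (sat["n_unmeth"] == 0).all()

    def test_stage_draws_are_independent_substreams(self, small_config,
                                                    small_genome, small_truth):
        # re-simulating one stage alone reproduces it bit for bit
        again = simulate_stage(small_config, "mature_embryo", small_genome,
                               small_truth)
        ref = simulate_stage(small_config, "mature_embryo", small_genome,
                             small_truth)
        assert again.df.equals(ref.df)


class TestSirnas:
    def test_enrichment_fold_ratio(self):
        cfg = flat_chh_config(0.0, length=400_000)
        cfg.n_sirna_reads = 50_000
        cfg.sirna_enrichment_fold = 10.0
        cfg.saturated_stage = "s1"
        g = simulate_genome(cfg)
        truth = plant_truth(cfg, g)
        truth.dmrs = [PlantedDMR("Chr1", 100_000, 120_000, "CHH",
                                 ("s1", "s2"), 0.3)]
        reads, total = simulate_sirnas(cfg, g, truth)
        r24 = [r for r in reads if r.length == 24]
        n_in = sum(100_000 <= r.start < 120_000 for r in r24)
        n_out = len(r24) - n_in
        rate_in = n_in / 20_000
        rate_out = n_out / 380_000
        assert rate_in / rate_out == pytest.approx(10.0, rel=0.15)

    def test_infinite_fold_puts_all_24nt_reads_in_target(self):
        cfg = flat_chh_config(0.0, length=100_000)
        cfg.sirna_enrichment_fold = float("inf")
        cfg.sirna_frac_2122 = 0.0
        cfg.saturated_stage = "s1"
        g = simulate_genome(cfg)
        truth = plant_truth(cfg, g)
        truth.dmrs = [PlantedDMR("Chr1", 40_000, 45_000, "CHH", ("s1", "s2"), 0.3)]
        reads, _ = simulate_sirnas(cfg, g, truth)
        assert reads and all(40_000 <= r.start < 45_000 for r in reads)

    def test_fold_one_is_uniform_within_sampling_error(self):
        cfg = flat_chh_config(0.0, length=400_000)
        cfg.n_sirna_reads = 50_000
        cfg.sirna_enrichment_fold = 1.0
        cfg.saturated_stage = "s1"
        g = simulate_genome(cfg)
        truth = plant_truth(cfg, g)
        truth.dmrs = [PlantedDMR("Chr1", 100_000, 150_000, "CHH",
                                 ("s1", "s2"), 0.3)]
        reads, _ = simulate_sirnas(cfg, g, truth)
        r24 = [r for r in reads if r.length == 24]
        frac_in = sum(100_000 <= r.start < 150_000 for r in r24) / len(r24)
        assert frac_in == pytest.approx(50_000 / 400_000, abs=0.02)

    def test_reads_within_bounds_and_reproducible(self, small_config,
                                                  small_genome, small_truth):
        r1, t1 = simulate_sirnas(small_config, small_genome, small_truth)
        r2, t2 = simulate_sirnas(small_config, small_genome, small_truth)
        assert r1 == r2 and t1 == t2
        assert all(0 <= r.start and r.end <= small_config.chrom_length
                   for r in r1)


class TestPlantedDmrPlacement:
    def test_grid_aligned_and_disjoint_from_annotations(self, small_config,
                                                        small_genome):
        planted = random_planted_dmrs(small_config, small_genome, 10)
        for d in planted:
            assert d.start % 100 == 0 and d.end % 100 == 0
            assert 300 <= d.end - d.start <= 1000
            for iv in small_genome.tes + small_genome.genes:
                assert not (d.start < iv.end and iv.start < d.end)
        # pairwise disjoint
        ds = sorted(planted, key=lambda d: d.start)
        for a, b in zip(ds, ds[1:]):
            assert a.end <= b.start
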