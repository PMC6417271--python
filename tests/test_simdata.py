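"""Generator properties: seed determinism, Balding-Nichols moments,
construction-time truth, and file round-trips."""
import filecmp
import numpy as np
import pytest

from aedespop import popgen_stats as pg
from aedespop import simdata, vcf_filter
from aedespop.simdata import DepthModel, MitoConfig, SimConfig, SimConfigError


class TestConfig:
    def test_divergence_parameter_bounds(self):
        with pytest.raises(SimConfigError):
            SimConfig(n_populations=2, target_F=1.5, samples_per_population=[2, 2])
        with pytest.raises(SimConfigError):
            SimConfig(n_populations=2, target_F=0.0, samples_per_population=[2, 2])

    def test_mask_interval_bounds_checked(self):
        with pytest.raises(SimConfigError, match="out of bounds"):
            SimConfig(
                genome_layout=[("chr1", 1000)],
                mask_intervals=[("chr1", 500, 2000)],
                n_populations=2,
                samples_per_population=[2, 2],
            )

    def test_hybrid_parents_must_be_known_populations(self):
        with pytest.raises(SimConfigError, match="hybrid"):
            SimConfig(
                n_populations=2,
                samples_per_population=[2, 2],
                n_hybrids=[("pop1", "popX", 1)],
            )


class TestFrequencies:
    def test_seed_determinism(self, small_config):
        _, f1 = simdata.draw_population_frequencies(small_config)
        _, f2 = simdata.draw_population_frequencies(small_config)
        np.testing.assert_array_equal(f1, f2)

    def test_no_divergence_limit(self):
        cfg = SimConfig(
            n_populations=2, target_F=1e-6, samples_per_population=[2, 2],
            n_sites=500, seed=1,
        )
        pbar, freqs = simdata.draw_population_frequencies(cfg)
        assert np.abs(freqs - pbar[:, None]).max() < 0.01

    def test_balding_nichols_variance(self):
        """Across sites with a near-constant ancestral frequency, the
        population-frequency variance approaches F * pbar * (1-pbar)."""
        F, pbar = 0.2, 0.3
        cfg = SimConfig(
            n_populations=2, target_F=F, samples_per_population=[2, 2],
            n_sites=40_000, ancestral_freq_range=(pbar, pbar + 1e-9), seed=2,
        )
        _, freqs = simdata.draw_population_frequencies(cfg)
        expected = F * pbar * (1 - pbar)
        assert np.var(freqs[:, 0]) == pytest.approx(expected, rel=0.05)


class TestGenotypes:
    def test_fixed_site_all_reference(self):
        cfg = SimConfig(
            n_populations=2, samples_per_population=[5, 5], n_sites=100,
            missing_rate=0.0, seed=3,
        )
        freqs = np.zeros((100, 2))
        gm, _, _ = simdata.simulate_genotypes(freqs, cfg)
        assert (gm.dosage == 0).all()

    def test_missing_fraction_binomial(self):
        cfg = SimConfig(
            n_populations=2, samples_per_population=[5, 5], n_sites=1000,
            missing_rate=0.25, seed=4,
        )
        _, freqs = simdata.draw_population_frequencies(cfg)
        gm, _, _ = simdata.simulate_genotypes(freqs, cfg)
        frac = (gm.dosage == -1).mean()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_f1_hybrid_forced_heterozygosity(self):
        cfg = SimConfig(
            n_populations=2, samples_per_population=[2, 2], n_sites=200,
            missing_rate=0.0, n_hybrids=[("pop1", "pop2", 1)], seed=5,
        )
        freqs = np.column_stack([np.zeros(200), np.ones(200)])
        gm, truth, _ = simdata.simulate_genotypes(freqs, cfg)
        hybrid = next(iter(truth.hybrid_parents))
        j = gm.samples.index(hybrid)
        assert (gm.dosage[:, j] == 1).all()

    def test_depth_model_mean(self, small_bundle):
        assert small_bundle.depth.mean() == pytest.approx(
            small_bundle.config.depth.mean, rel=0.05
        )


class TestMito:
    def test_lineage_distances_by_construction(self):
        cfg = SimConfig(
            n_populations=2, samples_per_population=[3, 3], n_sites=100,
            mito=MitoConfig(n_lineages=2, defining_substitutions=30, private_rate=0.0),
            seed=6,
        )
        m = simdata.simulate_mito(cfg)
        cons = {s: m.consensus(s) for s in m.samples}
        ref = m.reference

        def hamming(a, b):
            return sum(x != y for x, y in zip(a, b))

        for s in m.samples:
            expected = 0 if m.lineage_of[s] == 0 else 30
            assert hamming(cons[s], ref) == expected
        for s1 in m.samples:
            for s2 in m.samples:
                want = 0 if m.lineage_of[s1] == m.lineage_of[s2] else 30
                assert hamming(cons[s1], cons[s2]) == want

    def test_single_lineage_no_substitutions_identical_to_reference(self):
        cfg = SimConfig(
            n_populations=2, samples_per_population=[2, 2], n_sites=50,
            mito=MitoConfig(n_lineages=1, defining_substitutions=0, private_rate=0.0),
            seed=7,
        )
        m = simdata.simulate_mito(cfg)
        assert all(m.consensus(s) == m.reference for s in m.samples)

    def test_lineages_cross_nuclear_populations(self, small_bundle):
        """Default assignment alternates lineages within populations."""
        lin = small_bundle.truth.mito_lineage
        for pop, members in [
            ("pop1", [s for s in lin if s.startswith("pop1")]),
        ]:
            assert {lin[s] for s in members} == {0, 1}

    def test_variant_positions_inside_genes(self, small_bundle):
        m = small_bundle.mito
        covered = set()
        for _, start, end, _ in m.genes:
            covered.update(range(start, end + 1))
        assert all(int(p) in covered for p in m.positions)


class TestBundleIO:
    def test_seed_determinism_byte_identical_files(self, small_config, tmp_path):
        b1 = simdata.simulate(small_config)
        b2 = simdata.simulate(small_config)
        np.testing.assert_array_equal(b1.gm.dosage, b2.gm.dosage)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simdata.write_dataset(b1, d1)
        simdata.write_dataset(b2, d2)
        for name in ("nuclear.vcf", "mito.vcf", "mito_ref.fasta", "mask.bed",
                     "samples.tsv", "genes.tsv", "truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_vcf_round_trip_exact(self, small_bundle, bundle_paths):
        vt = vcf_filter.read_vcf(bundle_paths["nuclear_vcf"], ploidy=2)
        assert vt.n_sites == small_bundle.config.n_sites
        gm, _ = vcf_filter.filter_missingness(vt, 1.0)
        np.testing.assert_array_equal(gm.dosage, small_bundle.gm.dosage)
        np.testing.assert_array_equal(gm.pos, small_bundle.gm.pos)
        np.testing.assert_array_equal(gm.chrom, small_bundle.gm.chrom)
        assert gm.samples == small_bundle.gm.samples

    def test_masked_sites_detected_by_filter(self, small_bundle, bundle_paths):
        vt = vcf_filter.read_vcf(bundle_paths["nuclear_vcf"], ploidy=2)
        mask = vcf_filter.read_bed(bundle_paths["mask_bed"])
        kept = vcf_filter.filter_mask_regions(vt, mask)
        by_chrom = {}
        for chrom, s, e in mask:
            by_chrom.setdefault(chrom, []).append((s, e))
        expected_removed = sum(
            int(simdata._in_mask(vt.pos[vt.chrom == c], ivs).sum())
            for c, ivs in by_chrom.items()
        )
        assert vt.n_sites - kept.n_sites == expected_removed
        assert expected_removed > 0  # masked regions do hold (fewer) sites

    def test_recovered_fst_on_written_bundle(self, small_bundle, bundle_paths,
                                             populations):
        """The full file round trip preserves the divergence signal."""
        vt = vcf_filter.read_vcf(bundle_paths["nuclear_vcf"], ploidy=2)
        gm, _ = vcf_filter.run_filter_pipeline(
            vt, mask=vcf_filter.read_bed(bundle_paths["mask_bed"]),
            min_depth=None,
        )
        est = pg.genome_fst(gm, populations["pop1"], populations["pop2"]).estimate
        assert est == pytest.approx(0.15, abs=0.03)


class TestTemporalBottleneck:
    def test_shapes_and_groups(self):
        gm, before, after = simdata.simulate_temporal_bottleneck(
            n_sites=2000, seed=1
        )
        assert len(before) == 3 and len(after) == 4
        assert gm.n_samples == 7 and gm.n_sites == 2000

    def test_determinism(self):
        g1, _, _ = simdata.simulate_temporal_bottleneck(n_sites=1000, seed=2)
        g2, _, _ = simdata.simulate_temporal_bottleneck(n_sites=1000, seed=2)
        np.testing.assert_array_equal(g1.dosage, g2.dosage)

    def test_diversity_loss_after_founding(self):
        gm, before, after = simdata.simulate_temporal_bottleneck(
            n_sites=20_000, seed=3
        )
        scan = pg.windowed_scan(gm, before, after)
        # pi_2 (after) below pi_1 (before) on average
        assert scan.delta_pi.mean() > 0
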