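"""Hudson F_ST, pi and window machinery against hand values and
explicit per-site loop oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aedespop import popgen_stats as pg
from aedespop.genotypes import GenotypeMatrix
from helpers import brute_pi_site, naive_hudson_sums, site_alleles


def _gm(dosage, pos=None, chrom=None, samples=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, s = dosage.shape
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(s)],
        chrom=chrom if chrom is not None else np.array(["chr1"] * n, dtype=object),
        pos=pos if pos is not None else np.arange(1, n + 1),
        dosage=dosage,
    )


class TestSiteFst:
    def test_fixed_difference_gives_unit_ratio(self):
        num, den, valid = pg.site_fst_components([10], [10], [0], [10])
        assert valid[0]
        assert num[0] == pytest.approx(1.0, abs=1e-15)
        assert den[0] == pytest.approx(1.0, abs=1e-15)

    def test_equal_frequencies_hand_value(self):
        # p1 = p2 = 0.5 with 11 alleles each: N = -0.05, D = 0.5
        num, den, _ = pg.site_fst_components([5.5], [11], [5.5], [11])
        assert num[0] == pytest.approx(-0.05, abs=1e-12)
        assert den[0] == pytest.approx(0.5, abs=1e-12)
        assert num[0] / den[0] == pytest.approx(-0.1, abs=1e-12)

    def test_no_divergence_limit_large_n(self):
        num, _, _ = pg.site_fst_components([4000], [10000], [4000], [10000])
        assert abs(num[0]) < 1e-3

    def test_undercalled_sites_excluded(self):
        num, den, valid = pg.site_fst_components([1, 1], [1, 4], [1, 1], [4, 4])
        assert not valid[0] and valid[1]
        assert num[0] == 0 and den[0] == 0

    @given(
        a1=st.integers(0, 20), n1=st.integers(2, 20),
        a2=st.integers(0, 20), n2=st.integers(2, 20),
    )
    @settings(deadline=None, derandomize=True)
    def test_numerator_never_exceeds_denominator(self, a1, n1, a2, n2):
        """Per-site N <= D, hence any ratio-of-sums F_ST <= 1."""
        a1, a2 = min(a1, n1), min(a2, n2)
        num, den, valid = pg.site_fst_components([a1], [n1], [a2], [n2])
        if valid[0]:
            assert num[0] <= den[0] + 1e-12


class TestWindows:
    def test_enumeration_1mbp_500kbp_on_3mbp(self):
        wins = pg.enumerate_windows(3_000_000, 1_000_000, 500_000)
        assert wins == [
            (0, 1_000_000),
            (500_000, 1_500_000),
            (1_000_000, 2_000_000),
            (1_500_000, 2_500_000),
            (2_000_000, 3_000_000),
        ]

    def test_single_window_chromosomes(self):
        assert pg.enumerate_windows(1_000_000, 1_000_000, 500_000) == [(0, 1_000_000)]
        assert pg.enumerate_windows(800_000, 1_000_000, 500_000) == [(0, 800_000)]

    def test_trailing_partial_window(self):
        wins = pg.enumerate_windows(3_200_000, 1_000_000, 500_000)
        assert wins[-1] == (2_500_000, 3_200_000)
        assert wins[:-1][-1] == (2_000_000, 3_000_000)

    def test_window_smaller_than_step_rejected(self):
        with pytest.raises(ValueError):
            pg.enumerate_windows(1_000_000, 100, 200)


class TestWindowedFst:
    def test_matches_naive_loop_per_window(self):
        rng = np.random.default_rng(7)
        n = 200
        dosage = rng.integers(0, 3, size=(n, 12)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = -1
        pos = np.sort(rng.choice(np.arange(1, 500_001), n, replace=False))
        gm = _gm(dosage, pos=pos)
        g1 = gm.samples[:6]
        g2 = gm.samples[6:]
        scan = pg.windowed_fst(
            gm, g1, g2, window_bp=100_000, step_bp=50_000, min_snps=1,
            chrom_lengths={"chr1": 500_000},
        )
        for row in scan.itertuples():
            sites = [
                i for i in range(n)
                if row.start <= pos[i] - 1 < row.end
            ]
            tn, td = naive_hudson_sums(gm, g1, g2, sites=sites)
            if td == 0:
                assert np.isnan(row.fst)
            else:
                assert row.fst == pytest.approx(tn / td, abs=1e-12)

    def test_min_snps_yields_missing(self):
        gm = _gm([[0, 1, 2, 1]] * 3)
        scan = pg.windowed_fst(
            gm, gm.samples[:2], gm.samples[2:], window_bp=10, step_bp=10,
            min_snps=5, chrom_lengths={"chr1": 10},
        )
        assert scan.fst.isna().all()

    def test_unknown_group_label_raises(self):
        gm = _gm([[0, 1, 2, 1]] * 3)
        with pytest.raises(KeyError):
            pg.windowed_fst(gm, ["nope"], gm.samples[2:])


class TestPi:
    def test_site_pi_equals_bruteforce_mean_pairwise_difference(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(60, 25)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.15] = -1
        gm = _gm(dosage)
        a, n = pg.allele_counts(gm, gm.samples)
        pi, valid = pg.site_pi(a, n)
        idx = gm.sample_indices(gm.samples)
        for s in range(gm.n_sites):
            alleles = site_alleles(gm, s, idx)
            if len(alleles) < 2:
                assert not valid[s]
            else:
                assert pi[s] == pytest.approx(brute_pi_site(alleles), abs=1e-12)

    def test_two_of_four_alleles_hand_value(self):
        # 2 alt of 4 alleles: (4/3) * 2 * 0.25 = 2/3 = mean pairwise 4/6
        pi, _ = pg.site_pi([2], [4])
        assert pi[0] == pytest.approx(2 / 3, abs=1e-15)
        assert pi[0] == pytest.approx(brute_pi_site([1, 1, 0, 0]), abs=1e-15)

    def test_fixed_group_and_span_normalization(self):
        gm = _gm([[0, 0], [0, 0], [2, 1]], pos=np.array([1, 2, 3]))
        fixed = pg.windowed_pi(
            gm, gm.samples, window_bp=10, step_bp=10, chrom_lengths={"chr1": 10}
        )
        only_site3 = 4 / 3 * 2 * 0.75 * 0.25
        assert fixed.pi[0] == pytest.approx(only_site3 / 10)
        doubled = pg.windowed_pi(
            gm, gm.samples, window_bp=20, step_bp=20, chrom_lengths={"chr1": 20}
        )
        assert doubled.pi[0] == pytest.approx(fixed.pi[0] / 2)

    def test_delta_pi_antisymmetry_and_grid_check(self):
        rng = np.random.default_rng(5)
        gm = _gm(rng.integers(0, 3, size=(50, 8)).astype(np.int8))
        g1, g2 = gm.samples[:4], gm.samples[4:]
        p1 = pg.windowed_pi(gm, g1, 25, 25, {"chr1": 50})
        p2 = pg.windowed_pi(gm, g2, 25, 25, {"chr1": 50})
        np.testing.assert_allclose(pg.delta_pi(p1, p2), -pg.delta_pi(p2, p1))
        bad = pg.windowed_pi(gm, g2, 50, 50, {"chr1": 50})
        with pytest.raises(ValueError, match="grids"):
            pg.delta_pi(p1, bad)


class TestGenomeFst:
    def test_self_comparison_near_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 20_000)
        dosage = rng.binomial(2, p[:, None], size=(20_000, 20)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 10_000_001), 20_000, replace=False))
        gm = _gm(dosage, pos=pos)
        g = pg.genome_fst(gm, gm.samples[:10], gm.samples[10:])
        assert abs(g.estimate) < 0.01
        assert g.se > 0
        assert g.n_blocks >= 2

    def test_matches_naive_totals(self, small_bundle, populations):
        gm = small_bundle.gm
        g1, g2 = populations["pop1"][:5], populations["pop2"][:5]
        sub = gm.take_sites(np.arange(500))
        est = pg.genome_fst(sub, g1, g2).estimate
        tn, td = naive_hudson_sums(sub, g1, g2)
        assert est == pytest.approx(tn / td, abs=1e-12)

    def test_single_block_warns_undefined_se(self):
        gm = _gm([[0, 1, 2, 1]] * 5)
        with pytest.warns(UserWarning, match="jackknife"):
            g = pg.genome_fst(gm, gm.samples[:2], gm.samples[2:], block_bp=10**9)
        assert np.isnan(g.se)

    def test_missing_data_does_not_leak_between_samples(self):
        """Per-site counts use called alleles only: masking one sample's
        genotype leaves the remaining samples' contributions unchanged."""
        rng = np.random.default_rng(9)
        dosage = rng.integers(0, 3, size=(100, 8)).astype(np.int8)
        gm = _gm(dosage)
        dropped = dosage.copy()
        dropped[:, 0] = -1
        gm_dropped = _gm(dropped)
        # compare against physically removing the sample
        gm_removed = gm.take_samples(gm.samples[1:])
        a1, n1 = pg.allele_counts(gm_dropped, gm.samples)
        a2, n2 = pg.allele_counts(gm_removed, gm_removed.samples)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(n1, n2)


class TestPairwiseMatrix:
    def test_symmetry_zero_diagonal_and_ordering(self):
        from aedespop import simdata
        from aedespop.simdata import SimConfig

        # per-population F [0.05, 0.05, 0.25] gives pairwise expectations
        # (0.05, 0.15, 0.15): the A-B pair must come out closest
        cfg = SimConfig(
            n_populations=3,
            target_F=[0.05, 0.05, 0.25],
            samples_per_population=[15, 15, 15],
            n_sites=20_000,
            missing_rate=0.0,
            n_hybrids=[],
            seed=4,
        )
        b = simdata.simulate(cfg)
        pops = {}
        for s, p in b.truth.population_of.items():
            pops.setdefault(p, []).append(s)
        m = pg.pairwise_fst_matrix(b.gm, pops)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
        assert np.all(np.diag(m.to_numpy()) == 0)
        assert m.loc["pop1", "pop2"] < m.loc["pop1", "pop3"]
        assert m.loc["pop1", "pop2"] < m.loc["pop2", "pop3"]

    def test_duplicate_population_self_comparison(self, small_bundle, populations):
        """Disjoint halves of one population give F_ST ~ 0; literally
        identical sample sets give the known small negative bias
        -1/(n_alleles - 1) of the Hudson estimator."""
        halves = {"a": populations["pop1"][:5], "b": populations["pop1"][5:]}
        m = pg.pairwise_fst_matrix(small_bundle.gm, halves)
        assert abs(m.loc["a", "b"]) < 0.05
        same = {"a": populations["pop1"], "b": populations["pop1"]}
        m2 = pg.pairwise_fst_matrix(small_bundle.gm, same)
        n_alleles = 2 * len(populations["pop1"])
        assert m2.loc["a", "b"] == pytest.approx(-1 / (n_alleles - 1), abs=0.02)

    def test_negative_estimates_clamped_for_trees_only(self):
        import pandas as pd

        df = pd.DataFrame(
            [[0.0, -0.02], [-0.02, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        clamped = pg.fst_to_distance(df)
        assert clamped.loc["a", "b"] == 0.0
        assert df.loc["a", "b"] == -0.02  # original retained
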