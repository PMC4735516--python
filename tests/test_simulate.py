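import numpy as np
import pytest

from enums_ne import (
    DemographyModel,
    full_span_block,
    partition_blocks,
    sim_recombinant_block,
    sim_sequences,
    sim_tree,
    sim_two_demes,
)


class TestDemographyModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            DemographyModel(((10.0, 100.0),))      # must start at 0
        with pytest.raises(ValueError):
            DemographyModel(((0.0, 100.0), (0.0, 50.0)))
        with pytest.raises(ValueError):
            DemographyModel(((0.0, -5.0),))

    def test_ne_lookup(self):
        demo = DemographyModel(((0.0, 100.0), (50.0, 500.0)))
        assert demo.ne_at(0) == 100.0
        assert demo.ne_at(49.9) == 100.0
        assert demo.ne_at(50.0) == 500.0


class TestSimTree:
    def test_same_seed_identical(self):
        demo = DemographyModel.constant(500)
        t1 = sim_tree(8, demo, 42)
        t2 = sim_tree(8, demo, 42)
        np.testing.assert_array_equal(t1.heights, t2.heights)
        np.testing.assert_array_equal(t1.parent, t2.parent)

    def test_pair_tmrca_expectation(self):
        ne = 800
        demo = DemographyModel.constant(ne)
        reps = 4000
        tm = np.array([sim_tree(2, demo, s).root_height for s in range(reps)])
        # E = 2Ne generations, SD = 2Ne for an exponential
        se = tm.std(ddof=1) / np.sqrt(reps)
        assert abs(tm.mean() - 2 * ne) < 3 * se

    def test_ten_tip_tmrca_expectation(self):
        ne = 500
        demo = DemographyModel.constant(ne)
        reps = 4000
        tm = np.array([sim_tree(10, demo, s).root_height for s in range(reps)])
        expect = 4 * ne * (1 - 1 / 10)
        se = tm.std(ddof=1) / np.sqrt(reps)
        assert abs(tm.mean() - expect) < 3 * se

    def test_bottleneck_epoch_shortens_deep_coalescence(self):
        """Lineages surviving into a small ancestral epoch coalesce fast."""
        reps = 1500
        big = DemographyModel.constant(10_000)
        crash = DemographyModel(((0.0, 10_000.0), (100.0, 100.0)))
        t_big = np.mean([sim_tree(6, big, s).root_height for s in range(reps)])
        t_crash = np.mean([sim_tree(6, crash, s).root_height for s in range(reps)])
        assert t_crash < 0.2 * t_big

    def test_matches_msprime_pair_tmrca(self):
        """Cross-check against an independent coalescent implementation."""
        msprime = pytest.importorskip("msprime")
        ne = 1000
        reps = 3000
        ours = np.array(
            [sim_tree(2, DemographyModel.constant(ne), s).root_height
             for s in range(reps)]
        )
        theirs = np.array([
            ts.first().time(ts.first().root)
            for ts in msprime.sim_ancestry(
                samples=1, population_size=ne, num_replicates=reps,
                random_seed=7,
            )
        ])
        se = np.sqrt(ours.var(ddof=1) / reps + theirs.var(ddof=1) / reps)
        assert abs(ours.mean() - theirs.mean()) < 3 * se


class TestSimSequences:
    demo = DemographyModel.constant(1000)

    def test_mu_zero_gives_identical_haplotypes(self):
        tree = sim_tree(6, self.demo, 0)
        mat = sim_sequences(tree, 0.0, 1000, 1)
        assert mat.n_sites == 0

    def test_watterson_segregating_sites(self):
        n, ne, mu, L = 20, 1000, 1e-6, 1000
        reps = 2000
        demo = DemographyModel.constant(ne)
        s_counts = []
        for seed in range(reps):
            tree = sim_tree(n, demo, seed)
            s_counts.append(sim_sequences(tree, mu, L, seed + 10_000).n_sites)
        s_counts = np.array(s_counts, dtype=float)
        expect = 4 * ne * mu * L * np.sum(1.0 / np.arange(1, n))
        se = s_counts.std(ddof=1) / np.sqrt(reps)
        assert abs(s_counts.mean() - expect) < 3 * se

    def test_pairwise_diversity_expectation(self):
        n, ne, mu, L = 10, 1000, 1e-6, 2000
        reps = 1200
        demo = DemographyModel.constant(ne)
        pis = []
        for seed in range(reps):
            tree = sim_tree(n, demo, seed)
            mat = sim_sequences(tree, mu, L, seed + 10_000)
            a = mat.alleles.astype(float)
            freq = a.mean(axis=0)
            # mean pairwise difference per site across the region
            pi = (2 * freq * (1 - freq) * n / (n - 1)).sum() / L
            pis.append(pi)
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(reps)
        assert abs(pis.mean() - 4 * ne * mu) < 3 * se

    def test_positions_within_span_and_sorted(self):
        tree = sim_tree(8, self.demo, 3)
        mat = sim_sequences(tree, 5e-5, 500, 4, span_bp=500)
        assert np.all(np.diff(mat.positions) > 0)
        assert mat.positions.min() >= 1 and mat.positions.max() <= 500

    def test_sites_are_polymorphic(self):
        tree = sim_tree(8, self.demo, 5)
        mat = sim_sequences(tree, 5e-5, 500, 6)
        counts = mat.alleles.sum(axis=0)
        assert np.all(counts >= 1) and np.all(counts <= 7)

    def test_full_span_block_pads_invariant(self):
        from enums_ne import BlockAlignment

        tree = sim_tree(6, self.demo, 7)
        mat = sim_sequences(tree, 1e-5, 800, 8)
        aln = BlockAlignment.from_haplotype_matrix(
            mat, full_span_block(mat, 800)
        )
        assert aln.total_sites == 800
        assert aln.n_variable_sites == mat.n_sites


class TestSimRecombinantBlock:
    def test_same_seed_identical(self):
        demo = DemographyModel.constant(2000)
        m1, _ = sim_recombinant_block(10, demo, 1e-5, 2000, 900, 11)
        m2, _ = sim_recombinant_block(10, demo, 1e-5, 2000, 900, 11)
        np.testing.assert_array_equal(m1.alleles, m2.alleles)
        np.testing.assert_array_equal(m1.positions, m2.positions)

    def test_sides_straddle_breakpoint(self):
        demo = DemographyModel.constant(2000)
        mat, bp = sim_recombinant_block(10, demo, 1e-5, 2000, 900, 1)
        assert (mat.positions <= bp).any() and (mat.positions > bp).any()

    def test_no_right_side_variants_means_single_block(self):
        # mu = 0 on the right side is emulated by a breakpoint at the far
        # end: with no variation to the right the FGT cannot see the splice
        demo = DemographyModel.constant(2000)
        rng = np.random.default_rng(2)
        tree = sim_tree(10, demo, rng)
        mat = sim_sequences(tree, 2e-5, 1000, rng)
        if mat.n_sites >= 2:
            assert len(partition_blocks(mat)) == 1

    def test_invalid_breakpoint_rejected(self):
        demo = DemographyModel.constant(100)
        with pytest.raises(ValueError):
            sim_recombinant_block(4, demo, 1e-5, 100, 0, 1)
        with pytest.raises(ValueError):
            sim_recombinant_block(4, demo, 1e-5, 100, 100, 1)


class TestSimTwoDemes:
    def test_same_seed_identical(self):
        m1, l1 = sim_two_demes(4, 500, 1000, 1e-5, 1000, 9)
        m2, l2 = sim_two_demes(4, 500, 1000, 1e-5, 1000, 9)
        np.testing.assert_array_equal(m1.alleles, m2.alleles)
        assert l1 == l2

    def test_labels_cover_all_samples(self):
        mat, labels = sim_two_demes(6, 500, 100, 1e-5, 1000, 3)
        assert mat.n_haplotypes == 12
        assert sorted(set(labels.values())) == ["deme1", "deme2"]
        assert len(labels) == 6

    def test_odd_haplotypes_per_deme_rejected(self):
        with pytest.raises(ValueError):
            sim_two_demes(3, 500, 100, 1e-5, 1000, 3)
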