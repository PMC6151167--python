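"""Closed-form, property and cross-engine checks for the coalescent simulator."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from zdiv import coalsim as cs
from zdiv.popgen_stats import dxy_from_matrices, pi_from_matrix


class TestClosedForms:
    def test_pair_tmrca_constant_size(self):
        # E[TMRCA] = 2*Ne generations for a sample of two
        ne = 1e4
        model = cs.single_size_change(ne, n_haplotypes=2, rho_site=0.0,
                                      locus_length=100.0)
        rng = np.random.default_rng(1)
        times = [cs.simulate_genealogies(model, rng).tmrca(50.0)
                 for _ in range(1500)]
        assert np.mean(times) == pytest.approx(2 * ne, rel=0.10)

    def test_total_branch_length_constant_size(self):
        # E[L] = 4*Ne * sum_{i=1}^{n-1} 1/i
        ne, n = 1e4, 10
        model = cs.single_size_change(ne, n_haplotypes=n, rho_site=0.0,
                                      locus_length=100.0)
        rng = np.random.default_rng(2)
        lengths = [cs.simulate_genealogies(model, rng).total_branch_length(50.0)
                   for _ in range(800)]
        expected = 4 * ne * sum(1 / i for i in range(1, n))
        assert np.mean(lengths) == pytest.approx(expected, rel=0.10)

    def test_pair_tmrca_size_change(self):
        # one change at t: P(T>t) = exp(-t/(2*x*ne)); beyond t rate 1/(2*ne)
        ne, x, t = 3e6, 0.01, 1.14e5
        model = cs.single_size_change(ne, x, t, n_haplotypes=2, rho_site=0.0,
                                      locus_length=100.0)
        rng = np.random.default_rng(3)
        times = np.array([cs.simulate_genealogies(model, rng).tmrca(50.0)
                          for _ in range(3000)])
        n0 = x * ne
        a = math.exp(-t / (2 * n0))
        expected = 2 * n0 * (1 - a) + a * 2 * ne
        assert np.mean(times) == pytest.approx(expected, rel=0.10)
        assert (times > t).mean() == pytest.approx(a, abs=0.03)

    def test_z_class_scales_pair_coalescence(self):
        ne = 1e4
        base = cs.single_size_change(ne, n_haplotypes=2, rho_site=0.0,
                                     locus_length=100.0)
        zmod = base.for_chrom_class("Z")
        rng = np.random.default_rng(4)
        t_a = np.mean([cs.simulate_genealogies(base, rng).tmrca(50.0)
                       for _ in range(2500)])
        t_z = np.mean([cs.simulate_genealogies(zmod, rng).tmrca(50.0)
                       for _ in range(2500)])
        assert t_z / t_a == pytest.approx(0.75, abs=0.06)

    def test_mean_pi_equals_theta(self):
        ne, mu = 3e6, 2e-9
        model = cs.single_size_change(ne, n_haplotypes=10, mu=mu,
                                      rho_site=0.01, locus_length=5000.0)
        rng = np.random.default_rng(5)
        pis = [pi_from_matrix(cs.simulate_matrix(model, rng).matrix, 5000.0)
               for _ in range(300)]
        assert np.mean(pis) == pytest.approx(4 * ne * mu, rel=0.05)

    def test_isolation_dxy_closed_form(self):
        # m = 0: E[dXY] = 2*mu*(T + 2*N_anc)
        ne, mu, T = 5e5, 2e-9, 4e6
        model = cs.two_population_split(ne, T, 0.0, mu=mu, rho_site=0.01,
                                       locus_length=5000.0)
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(200):
            m = cs.simulate_matrix(model, rng)
            m1, m2 = m.by_population()
            vals.append(dxy_from_matrices(m1, m2, m.locus_length))
        assert np.mean(vals) == pytest.approx(2 * mu * (T + 2 * ne), rel=0.05)


class TestMutations:
    def test_zero_mutation_rate_gives_no_sites(self):
        model = cs.single_size_change(1e4, n_haplotypes=4, rho_site=0.0,
                                      locus_length=1000.0, mu=0.0)
        rng = np.random.default_rng(7)
        m = cs.simulate_matrix(model, rng)
        assert m.n_sites == 0

    def test_every_site_polymorphic_and_in_bounds(self):
        model = cs.single_size_change(1e4, n_haplotypes=6, rho_site=0.01,
                                      locus_length=2000.0, mu=1e-6)
        rng = np.random.default_rng(8)
        m = cs.simulate_matrix(model, rng)
        assert m.n_sites > 0
        counts = m.matrix.sum(axis=0)
        assert ((counts >= 1) & (counts <= 5)).all()
        assert (m.positions >= 0).all() and (m.positions < 2000).all()
        assert (np.diff(m.positions) >= 0).all()

    def test_site_frequency_spectrum_neutral(self):
        # standard neutral SFS: E[xi_i] proportional to 1/i
        model = cs.single_size_change(1e5, n_haplotypes=10, rho_site=0.01,
                                      locus_length=2000.0, mu=1e-7)
        rng = np.random.default_rng(9)
        sfs = np.zeros(10)
        for _ in range(300):
            m = cs.simulate_matrix(model, rng)
            for c in m.matrix.sum(axis=0):
                sfs[c] += 1
        scaled = sfs[1:6] * np.arange(1, 6)  # should be flat
        assert scaled.max() / scaled.min() < 1.3


class TestRecombination:
    def test_mean_invariant_variance_decreases(self):
        ne, mu, L = 1e5, 1e-7, 5000.0
        means, varis = {}, {}
        for rho in (0.0, 0.01):
            model = cs.single_size_change(ne, n_haplotypes=10, mu=mu,
                                          rho_site=rho, locus_length=L)
            rng = np.random.default_rng(10)
            pis = [pi_from_matrix(cs.simulate_matrix(model, rng).matrix, L)
                   for _ in range(400)]
            means[rho], varis[rho] = np.mean(pis), np.var(pis)
        assert means[0.01] == pytest.approx(means[0.0], rel=0.10)
        assert varis[0.01] < 0.5 * varis[0.0]

    def test_breakpoints_tile_locus(self):
        model = cs.single_size_change(1e4, n_haplotypes=5, rho_site=0.01,
                                      locus_length=2000.0)
        rng = np.random.default_rng(11)
        ts = cs.simulate_genealogies(model, rng)
        bp = ts.breakpoints()
        assert bp[0] == 0.0 and bp[-1] == 2000.0
        for x in (0.0, 500.0, 1999.0):
            assert ts.tmrca(x) > 0


class TestDeterminismAndErrors:
    def test_same_seed_identical_output(self):
        model = cs.single_size_change(1e4, n_haplotypes=6, rho_site=0.01,
                                      locus_length=1000.0, mu=1e-6)
        m1 = cs.simulate_matrix(model, np.random.default_rng(42))
        m2 = cs.simulate_matrix(model, np.random.default_rng(42))
        assert np.array_equal(m1.matrix, m2.matrix)
        assert np.array_equal(m1.positions, m2.positions)

    def test_isolated_demes_without_merge_raise(self):
        model = cs.DemographicModel(sample_sizes=(2, 2), deme_sizes=(1e4, 1e4),
                                    migration=0.0, split_time=None)
        with pytest.raises(ValueError, match="never merge"):
            cs.simulate_genealogies(model, np.random.default_rng(0))

    def test_invalid_chrom_class(self):
        model = cs.single_size_change(1e4)
        with pytest.raises(ValueError):
            model.for_chrom_class("W")

    def test_exchangeable_population_labels(self):
        model = cs.two_population_split(1e5, 1e5, 1e-6, mu=1e-7,
                                       rho_site=0.01, locus_length=2000.0)
        rng = np.random.default_rng(12)
        m = cs.simulate_matrix(model, rng)
        m1, m2 = m.by_population()
        assert dxy_from_matrices(m1, m2, m.locus_length) == pytest.approx(
            dxy_from_matrices(m2, m1, m.locus_length))


class TestCrossValidationAgainstMsprime:
    """Distributional agreement with an independent coalescent engine."""

    @pytest.mark.parametrize("scenario", ["constant", "size_change", "two_pop"])
    def test_segregating_sites_and_pi_distributions(self, scenario):
        import msprime

        ne, mu, L, reps = 1e5, 1e-7, 2000.0, 300
        rec = 0.01 / (4 * ne)
        if scenario == "constant":
            model = cs.single_size_change(ne, n_haplotypes=10, mu=mu,
                                          rho_site=0.01, locus_length=L)
            dem = msprime.Demography()
            dem.add_population(initial_size=ne)
            samples = 5
        elif scenario == "size_change":
            x, t = 0.1, 5e4
            model = cs.single_size_change(ne, x, t, n_haplotypes=10, mu=mu,
                                          rho_site=0.01, locus_length=L)
            dem = msprime.Demography()
            dem.add_population(initial_size=x * ne)
            dem.add_population_parameters_change(time=t, initial_size=ne)
            samples = 5
        else:
            T, m = 2e5, 2e-6
            model = cs.two_population_split(ne, T, m, mu=mu, rho_site=0.01,
                                           locus_length=L)
            dem = msprime.Demography()
            dem.add_population(name="p0", initial_size=ne)
            dem.add_population(name="p1", initial_size=ne)
            dem.add_population(name="anc", initial_size=ne)
            dem.set_symmetric_migration_rate(["p0", "p1"], m)
            dem.add_population_split(time=T, derived=["p0", "p1"],
                                     ancestral="anc")
            samples = {"p0": 5, "p1": 5}

        rng = np.random.default_rng(13)
        mine_s, mine_pi = [], []
        for _ in range(reps):
            mat = cs.simulate_matrix(model, rng)
            mine_s.append(mat.n_sites)
            mine_pi.append(pi_from_matrix(mat.matrix, L))
        ref_s, ref_pi = [], []
        for seed in range(1, reps + 1):
            ts = msprime.sim_ancestry(samples=samples, demography=dem,
                                      sequence_length=L, recombination_rate=rec,
                                      ploidy=2, random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=seed + 10_000,
                                        discrete_genome=False)
            g = mts.genotype_matrix().T
            ref_s.append(g.shape[1])
            ref_pi.append(pi_from_matrix(g, L))
        assert ks_2samp(mine_s, ref_s).pvalue > 0.01
        assert ks_2samp(mine_pi, ref_pi).pvalue > 0.01
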