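"""Unit and property tests for the windowed diversity/divergence statistics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_pair_mean, tajima_oracle

from zdiv import popgen_stats as ps
from zdiv.genomic_io import GenotypeWindow, SampleMeta


class TestPairwiseDiff:
    def test_two_haplotypes_one_diff_in_ten(self):
        a = np.array([[0] * 10, [0] * 9 + [1]], dtype=np.int8)
        assert ps.mean_pairwise_diff(a) == pytest.approx(0.1)

    def test_identical_haplotypes_zero(self):
        a = np.zeros((3, 12), dtype=np.int8)
        assert ps.mean_pairwise_diff(a) == 0.0

    def test_all_missing_is_nan(self):
        a = np.full((2, 5), -1, dtype=np.int8)
        assert math.isnan(ps.mean_pairwise_diff(a))

    def test_per_pair_denominators_with_missing(self):
        # pair (0,1): 4 joint sites, 2 diffs; pair (0,2): 2 joint sites, 0 diff
        a = np.array([[0, 0, 1, 1, 0],
                      [1, 0, 0, 1, -1],
                      [0, 0, -1, -1, -1]], dtype=np.int8)
        pairs = [(0, 1), (0, 2)]
        expect = np.mean([2 / 4, 0 / 2])
        assert ps.mean_pairwise_diff(a, pairs) == pytest.approx(expect)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_oracle_under_missingness(self, seed):
        rng = np.random.default_rng(seed)
        n, s = rng.integers(2, 7), rng.integers(1, 25)
        a = rng.integers(0, 2, size=(n, s)).astype(np.int8)
        mask = rng.random((n, s)) < 0.3
        a[mask] = -1
        pairs = list(itertools.combinations(range(n), 2))
        got = ps.mean_pairwise_diff(a, pairs)
        want = brute_force_pair_mean(a, pairs)
        assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)

    def test_scale_to_span_extrapolates_callable_fraction(self):
        # one variant site among a 100-bp callable span, pair differs there
        a = np.array([[0], [1]], dtype=np.int8)
        assert ps.mean_pairwise_diff(a, scale_to_span=100.0) == pytest.approx(0.01)
        # a masked pair has no information but the unmasked pair is rescaled
        b = np.array([[0, 1], [1, 1], [-1, -1]], dtype=np.int8)
        got = ps.mean_pairwise_diff(b, [(0, 1), (0, 2)], scale_to_span=100.0)
        assert got == pytest.approx(1 / (2 * 100 / 2))


class TestToyOracle:
    def test_hand_enumerated_statistics(self, toy_populations):
        p1, p2 = toy_populations
        pi1 = ps.pi_within(p1)
        pi2 = ps.pi_within(p2)
        pi_s = ps.pi_s_weighted(pi1, pi2, 2, 2)
        pi_t = ps.pi_total(p1, p2)
        d = ps.dxy(p1, p2)
        assert pi1 == pytest.approx(0.1)
        assert pi2 == pytest.approx(0.1)
        assert pi_s == pytest.approx(0.1)
        assert pi_t == pytest.approx(0.2)
        assert ps.fst_hudson(pi_t, pi_s) == pytest.approx(0.5)
        assert d == pytest.approx(0.25)
        assert ps.d_a(d, pi_s) == pytest.approx(0.15)

    def test_pooled_identical_populations_undifferentiated(self, rng):
        p1 = rng.integers(0, 2, size=(4, 30)).astype(np.int8)
        p2 = p1.copy()
        pi1 = ps.pi_within(p1)
        pi_t = ps.pi_total(p1, p2)
        d = ps.dxy(p1, p2)
        # within = between for duplicated populations
        assert d == pytest.approx(ps.pi_within(np.vstack([p1, p2])), rel=0.2)
        assert ps.fst_hudson(pi_t, ps.pi_s_weighted(pi1, pi1, 4, 4)) <= 0.05

    def test_single_pair_dxy(self):
        a = np.array([[0] * 10], dtype=np.int8)
        b = np.array([[1, 1, 1] + [0] * 7], dtype=np.int8)
        assert ps.dxy(a, b) == pytest.approx(0.3)

    def test_dxy_equals_pi_when_populations_identical_haplotypes(self):
        h = np.array([[0, 1, 0, 1]], dtype=np.int8)
        p = np.vstack([h, h])
        assert ps.dxy(p, p.copy()) == pytest.approx(ps.pi_within(p), abs=1e-12)


class TestFstDa:
    def test_fst_zero_when_no_differentiation(self):
        assert ps.fst_hudson(0.2, 0.2) == 0.0

    def test_fst_nan_when_pi_t_zero(self):
        assert math.isnan(ps.fst_hudson(0.0, 0.0))

    def test_negative_da_preserved(self):
        assert ps.d_a(0.01, 0.02) == pytest.approx(-0.01)

    @pytest.mark.parametrize("seed", range(5))
    def test_identities_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        p1 = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        p2 = rng.integers(0, 2, size=(3, 40)).astype(np.int8)
        pi1, pi2 = ps.pi_within(p1), ps.pi_within(p2)
        pi_s = ps.pi_s_weighted(pi1, pi2, 5, 3)
        pi_t = ps.pi_total(p1, p2)
        d = ps.dxy(p1, p2)
        assert ps.fst_hudson(pi_t, pi_s) == pytest.approx(1 - pi_s / pi_t)
        assert ps.d_a(d, pi_s) == pytest.approx(d - pi_s)
        # symmetry under population relabeling
        assert ps.dxy(p2, p1) == pytest.approx(d)
        assert ps.pi_total(p2, p1) == pytest.approx(pi_t)
        assert ps.pi_s_weighted(pi2, pi1, 3, 5) == pytest.approx(pi_s)


class TestTajimasD:
    def test_no_segregating_sites_nan(self):
        assert math.isnan(ps.tajimas_d(np.zeros((6, 10), dtype=np.int8)))

    def test_too_few_haplotypes_nan(self):
        a = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
        assert math.isnan(ps.tajimas_d(a))

    def test_matches_independent_constants_oracle(self):
        # 50 random complete matrices against a from-scratch implementation
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            s = int(rng.integers(2, 40))
            a = rng.integers(0, 2, size=(n, s)).astype(np.int8)
            want = tajima_oracle(a)
            got = ps.tajimas_d(a)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


def _make_window(alleles, samples, start=0, span=100, chrom="chr1",
                 chrom_class="autosome", assume_callable=False,
                 positions=None, variant=None):
    alleles = np.asarray(alleles, dtype=np.int8)
    if positions is None:
        positions = np.arange(alleles.shape[1]) + start
    if variant is None:
        variant = np.ones(alleles.shape[1], dtype=bool)
    owner = [s for s in samples for _ in range(2)]
    return GenotypeWindow(chrom, start, start + span, chrom_class, alleles,
                          np.asarray(positions), np.asarray(variant), owner,
                          {s: 2 for s in samples}, assume_callable)


META = [SampleMeta(f"{p}{i}", p) for p in ("A", "B") for i in range(2)]


class TestWindowStats:
    def test_sparse_window_fails_filter(self, rng):
        # 100-bp span with only 3 genotyped positions (< 10%)
        a = rng.integers(0, 2, size=(8, 3)).astype(np.int8)
        w = _make_window(a, [m.sample_id for m in META], span=100)
        out = ps.window_stats(w, ("A", "B"), META)
        assert not out.passed_filter
        assert math.isnan(out.fst)

    def test_fully_genotyped_window_passes(self, rng):
        a = rng.integers(0, 2, size=(8, 60)).astype(np.int8)
        w = _make_window(a, [m.sample_id for m in META], span=100)
        out = ps.window_stats(w, ("A", "B"), META)
        assert out.passed_filter
        assert math.isfinite(out.dxy)
        assert out.da == pytest.approx(out.dxy - out.pi_s)

    def test_filter_is_per_population_and(self, rng):
        # population B entirely missing -> window fails even though A passes
        a = rng.integers(0, 2, size=(8, 60)).astype(np.int8)
        a[4:, :] = -1
        w = _make_window(a, [m.sample_id for m in META], span=100)
        out = ps.window_stats(w, ("A", "B"), META)
        assert not out.passed_filter


class TestThinning:
    def _windows(self, positions, alleles, span=1000):
        return [_make_window(alleles, [m.sample_id for m in META], span=span,
                             positions=positions)]

    def test_greedy_gap_rule(self, rng):
        a = rng.integers(0, 2, size=(8, 3)).astype(np.int8)
        thin = ps.thin_sites(self._windows([100, 400, 700], a), META, min_gap=500)
        assert list(thin.positions) == [100, 700]

    def test_site_without_coverage_in_one_population_dropped(self):
        a = np.zeros((8, 2), dtype=np.int8)
        a[4:, 0] = -1  # site 0 has no called individual in population B
        thin = ps.thin_sites(self._windows([10, 600], a), META, min_gap=500)
        assert list(thin.positions) == [600]

    def test_empty_input(self):
        thin = ps.thin_sites([], META)
        assert thin.n_sites == 0

    def test_individual_dxy_matches_bruteforce(self, rng):
        a = rng.integers(0, 2, size=(8, 20)).astype(np.int8)
        a[rng.random((8, 20)) < 0.15] = -1
        thin = ps.thin_sites(self._windows(np.arange(20) * 600, a, span=12000),
                             META, min_gap=500)
        mat = ps.pairwise_individual_dxy(thin)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T, equal_nan=True)
        samples = list(mat.index)
        for i, j in itertools.combinations(range(len(samples)), 2):
            ri = [2 * i, 2 * i + 1]
            rj = [2 * j, 2 * j + 1]
            pairs = [(x, y) for x in ri for y in rj]
            want = brute_force_pair_mean(thin.alleles, pairs)
            got = mat.iloc[i, j]
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_identical_homozygous_individuals_zero(self):
        a = np.zeros((8, 4), dtype=np.int8)
        thin = ps.thin_sites(self._windows(np.arange(4) * 600, a, span=3000),
                             META, min_gap=500)
        mat = ps.pairwise_individual_dxy(thin)
        assert np.allclose(mat.to_numpy(), 0.0)


class TestParameterRecovery:
    def test_mean_pi_recovers_theta(self):
        # neutral constant-size replicates: E[pi] = 4*Ne*mu
        from zdiv.coalsim import single_size_change, simulate_matrix

        ne, mu = 1e6, 5e-9
        model = single_size_change(ne, n_haplotypes=10, mu=mu,
                                   rho_site=0.01, locus_length=5000.0)
        rng = np.random.default_rng(77)
        pis = [ps.pi_from_matrix(simulate_matrix(model, rng).matrix, 5000.0)
               for _ in range(300)]
        assert np.mean(pis) == pytest.approx(4 * ne * mu, rel=0.05)
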