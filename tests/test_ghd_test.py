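import itertools

import numpy as np
import pytest
from scipy import stats

from dghd import (
    Network,
    centre_weights,
    ghd_test_asymptotic,
    ghd_test_montecarlo,
    moment_sums,
    normality_ratio,
    permutation_moments,
    topological_overlap,
)
from dghd.ghd_test import MomentSums, permuted_ghd_sample
from dghd.network import network_weights
from dghd.simulate import er_network, rg_network, sf_degree_sample

from .conftest import random_pair


def exhaustive_moments(wa, wb):
    """Mean/variance of the GHD over all N! node relabellings of A."""
    n = wa.n
    vals = []
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        va = wa.values[np.ix_(p, p)]
        vals.append(((va - wb.values) ** 2).sum() / (n * (n - 1)))
    vals = np.array(vals)
    return vals.mean(), vals.var()


class TestMomentSums:
    def test_all_zero_matrix(self):
        from dghd.network import WeightMatrix

        w = WeightMatrix(np.zeros((5, 5)), mode="adjacency", centred=True)
        s = moment_sums(w)
        assert (s.s1, s.s2, s.t, s.a, s.b, s.c) == (0, 0, 0, 0, 0, 0)

    def test_centred_s1_vanishes(self):
        net = rg_network(30, 0.3, seed=2)
        s = moment_sums(centre_weights(topological_overlap(net)))
        assert abs(s.s1) < 1e-10

    def test_against_double_loop(self, path3):
        net = Network.from_edges([("1", "2"), ("2", "3"), ("3", "4")],
                                 nodes=list("1234"))
        w = centre_weights(network_weights(net, "adjacency"))
        v = w.values
        s1 = s2 = t = 0.0
        for i in range(4):
            row = 0.0
            for j in range(4):
                if i != j:
                    s1 += v[i, j]
                    s2 += v[i, j] ** 2
                    row += v[i, j]
            t += row ** 2
        s = moment_sums(w)
        assert s.s1 == pytest.approx(s1, abs=1e-12)
        assert s.s2 == pytest.approx(s2, abs=1e-12)
        assert s.t == pytest.approx(t, abs=1e-12)


class TestPermutationMoments:
    @pytest.mark.parametrize("mode", ["adjacency", "topological_overlap"])
    def test_matches_exhaustive_enumeration(self, mode):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n = int(rng.integers(4, 7))
            a = er_network(n, p=0.5, seed=rng)
            b = er_network(n, p=0.5, seed=rng)
            wa = centre_weights(network_weights(a, mode))
            wb = centre_weights(network_weights(b, mode))
            m = permutation_moments(moment_sums(wa), moment_sums(wb), n)
            mu, var = exhaustive_moments(wa, wb)
            assert m.mu == pytest.approx(mu, rel=1e-10, abs=1e-14)
            assert m.sigma2 == pytest.approx(var, rel=1e-10, abs=1e-14)

    def test_zero_weights_degenerate(self):
        z = MomentSums(s1=0, s2=0, t=0, n=6)
        net = er_network(6, p=0.5, seed=1)
        sb = moment_sums(centre_weights(network_weights(net, "adjacency")))
        m = permutation_moments(z, sb, 6)
        assert m.sigma2 == 0.0
        assert m.mu == pytest.approx(sb.s2 / (6 * 5))

    def test_symmetric_in_arguments(self):
        a, b = random_pair(8, 0.4, 5)
        sa = moment_sums(centre_weights(network_weights(a, "adjacency")))
        sb = moment_sums(centre_weights(network_weights(b, "adjacency")))
        m1 = permutation_moments(sa, sb, 8)
        m2 = permutation_moments(sb, sa, 8)
        assert (m1.mu, m1.sigma2) == (m2.mu, m2.sigma2)

    def test_small_n_rejected(self):
        z = MomentSums(s1=0, s2=1, t=1, n=3)
        with pytest.raises(ValueError, match="montecarlo"):
            permutation_moments(z, z, 3)


class TestNormalityRatio:
    def test_regular_graph_is_zero(self, k4):
        with pytest.warns(UserWarning, match="regular"):
            r = normality_ratio(centre_weights(network_weights(k4, "adjacency")))
        assert r == 0.0

    def test_decreases_with_size_er(self):
        means = []
        for n in (100, 400, 1600):
            vals = []
            for rep in range(10):
                net = er_network(n, p=0.05, seed=1000 * n + rep)
                w = centre_weights(network_weights(net, "adjacency"))
                vals.append(normality_ratio(w))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_sf_degree_ratio_scaling(self):
        # for power-law degrees with exponent alpha the ratio decays like
        # N^(alpha-2); regress log-ratio on log-N and check the slope
        alpha = 1.5
        sizes = np.array([200, 800, 3200])
        log_ratios = []
        for n in sizes:
            vals = []
            for rep in range(20):
                deg = sf_degree_sample(n, alpha, seed=37 * n + rep).astype(float)
                c = deg - deg.mean()
                vals.append((c ** 3).sum() ** 2 / (c ** 2).sum() ** 3)
            log_ratios.append(np.log(np.mean(vals)))
        slope = np.polyfit(np.log(sizes), log_ratios, 1)[0]
        assert slope == pytest.approx(alpha - 2.0, abs=0.25)


class TestAsymptoticTest:
    def test_identical_networks_reject(self):
        net = rg_network(250, 0.3, seed=3)
        res = ghd_test_asymptotic(net, net)
        assert res.p_value < 1e-6

    def test_degenerate_empty_network(self):
        empty = Network(tuple("abcdef"), np.zeros((6, 6), dtype=np.int8))
        other = er_network(6, p=0.5, seed=2)
        other = Network(empty.node_labels, other.adjacency)
        res = ghd_test_asymptotic(empty, other)
        assert res.p_value == 1.0 and res.sigma2 == 0.0

    def test_monotone_in_statistic(self):
        # lower-tail p is non-decreasing in the observed statistic
        zs = np.linspace(-3, 3, 13)
        ps = stats.norm.cdf(zs)
        assert (np.diff(ps) >= 0).all()

    def test_two_sided_option(self, rg_pair_250):
        a, b = rg_pair_250
        lo = ghd_test_asymptotic(a, b, tail="lower")
        two = ghd_test_asymptotic(a, b, tail="two")
        assert 0 <= two.p_value <= 1
        assert two.p_value == pytest.approx(
            2 * min(stats.norm.cdf(lo.z), stats.norm.sf(lo.z)))


class TestMonteCarlo:
    def test_complete_graph_permutation_invariant(self):
        k5 = Network(tuple("abcde"),
                     (np.ones((5, 5)) - np.eye(5)).astype(np.int8))
        res = ghd_test_montecarlo(k5, k5, n_perm=199, seed=1)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_seed_determinism(self):
        a, b = random_pair(30, 0.2, 11)
        r1 = ghd_test_montecarlo(a, b, n_perm=199, seed=5)
        r2 = ghd_test_montecarlo(a, b, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value

    def test_agrees_with_asymptotic(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rg_network(100, 0.3, seed=rng)
            b = rg_network(100, 0.3, seed=rng)
            mc = ghd_test_montecarlo(a, b, n_perm=1999, seed=rng)
            asy = ghd_test_asymptotic(a, b)
            assert mc.p_value == pytest.approx(asy.p_value, abs=0.05)

    def test_addone_never_zero(self):
        net = rg_network(60, 0.3, seed=4)
        res = ghd_test_montecarlo(net, net, n_perm=99, seed=0)
        assert res.p_value >= 1 / 100


class TestPermutationSample:
    def test_standardised_sample_is_normal(self, rg_pair_250):
        # moderate version of the full 10k-permutation study
        a, b = rg_pair_250
        sample = permuted_ghd_sample(a, b, "topological_overlap", 2000, seed=0)
        from dghd.network import network_weights

        wa = centre_weights(network_weights(a, "topological_overlap"))
        wb = centre_weights(network_weights(b, "topological_overlap"))
        m = permutation_moments(moment_sums(wa), moment_sums(wb), 250)
        z = (sample - m.mu) / np.sqrt(m.sigma2)
        assert abs(z.mean()) < 0.1
        assert abs(z.std() - 1) < 0.1
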