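import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dghd import (
    Network,
    centre_weights,
    ghd,
    hamming_distance,
    read_network,
    topological_overlap,
    write_network,
)
from dghd.network import adjacency_weights, network_weights
from dghd.simulate import er_network, rg_network

from .conftest import random_pair


def adjacency_strategy(min_n=2, max_n=8):
    def build(n_and_bits):
        n, bits = n_and_bits
        a = np.zeros((n, n), dtype=np.int8)
        iu, ju = np.triu_indices(n, k=1)
        for k, (i, j) in enumerate(zip(iu, ju)):
            a[i, j] = a[j, i] = bits[k]
        return Network(tuple(str(x) for x in range(n)), a)

    return st.integers(min_n, max_n).flatmap(
        lambda n: st.tuples(
            st.just(n),
            st.lists(st.integers(0, 1), min_size=n * (n - 1) // 2,
                     max_size=n * (n - 1) // 2),
        )
    ).map(build)


class TestNetworkConstruction:
    def test_rejects_weighted(self):
        a = np.array([[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="weighted input unsupported"):
            Network(("1", "2"), a)

    def test_rejects_self_loops_and_asymmetry(self):
        with pytest.raises(ValueError, match="self-loop"):
            Network(("1", "2"), np.array([[1, 0], [0, 0]]))
        with pytest.raises(ValueError, match="symmetric"):
            Network(("1", "2", "3"),
                    np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0]]))

    def test_edgelist_universe_keeps_isolated_nodes(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("# nodes: 1,2,3,4\nnode_a\tnode_b\n1\t2\n2\t3\n")
        net = read_network(f)
        assert net.n_nodes == 4
        assert net.degrees().tolist() == [1, 2, 1, 0]

    def test_duplicate_undirected_edge_collapses(self, tmp_path):
        f = tmp_path / "net.tsv"
        f.write_text("1\t2\n2\t1\n")
        net = read_network(f)
        assert net.n_edges == 1
        assert net.degrees()[net.index_of(["1"])[0]] == 1

    def test_adjacency_file_rejects_non_binary(self, tmp_path):
        f = tmp_path / "adj.csv"
        f.write_text(",a,b\na,0,0.5\nb,0.5,0\n")
        with pytest.raises(ValueError, match="weighted input unsupported"):
            read_network(f, format="adjacency")

    @pytest.mark.parametrize("fmt", ["edgelist", "adjacency"])
    def test_round_trip(self, tmp_path, path3, empty5, fmt):
        for net in (path3, empty5, rg_network(100, 0.2, seed=3)):
            f = tmp_path / f"net.{fmt}"
            write_network(net, f, format=fmt)
            back = read_network(f, format=fmt)
            assert back.node_labels == net.node_labels
            assert (back.adjacency == net.adjacency).all()


class TestTopologicalOverlap:
    def test_complete_graph_all_ones(self, k4):
        w = topological_overlap(k4).values
        off = w[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_empty_graph_all_zero(self, empty5):
        assert not topological_overlap(empty5).values.any()

    def test_star_hand_values(self, star4):
        w = topological_overlap(star4)
        idx = {lab: i for i, lab in enumerate(star4.node_labels)}
        # two leaves share only the centre: (1+0)/(min(1,1)-0+1) = 1/2
        assert w.values[idx["x"], idx["y"]] == pytest.approx(0.5)
        # centre-leaf: (0+1)/(min(3,1)-1+1) = 1
        assert w.values[idx["c"], idx["x"]] == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None)
    @given(adjacency_strategy())
    def test_bounds_and_symmetry(self, net):
        w = topological_overlap(net).values
        assert (w >= 0).all() and (w <= 1).all()
        assert np.array_equal(w, w.T)
        assert not np.diag(w).any()

    def test_isolated_node_weight_zero(self):
        net = Network.from_edges([("1", "2")], nodes=["1", "2", "3"])
        w = topological_overlap(net).values
        assert w[2].sum() == 0


class TestCentring:
    def test_constant_matrix_centres_to_zero(self, k4):
        w = centre_weights(adjacency_weights(k4))
        assert np.allclose(w.values, 0.0)
        assert w.centred

    def test_offdiagonal_sum_vanishes(self):
        net = rg_network(50, 0.3, seed=7)
        w = centre_weights(topological_overlap(net))
        assert abs(w.values.sum()) < 1e-12 * 50 ** 2

    def test_row_sum_identity(self):
        # centred row sums equal degree minus mean degree (adjacency mode)
        net = er_network(30, p=0.2, seed=11)
        w = centre_weights(adjacency_weights(net))
        deg = net.degrees().astype(float)
        expected = deg - deg.mean()
        assert np.allclose(w.row_sums(), expected, atol=1e-10)


class TestDistances:
    def test_hd_examples(self, path3, k4, empty5):
        assert hamming_distance(path3, path3) == 0
        b = Network.from_edges([("1", "2"), ("1", "3")], nodes=["1", "2", "3"])
        assert hamming_distance(path3, b) == 2
        e4 = Network(k4.node_labels, np.zeros((4, 4), dtype=np.int8))
        assert hamming_distance(e4, k4) == 6

    def test_hd_equals_pair_count(self):
        for seed in range(10):
            a, b = random_pair(8, 0.4, seed)
            pairs = int((a.adjacency != b.adjacency).sum()) // 2
            assert hamming_distance(a, b) == pairs

    def test_ghd_zero_on_identical(self):
        net = rg_network(40, 0.3, seed=1)
        w = centre_weights(topological_overlap(net))
        assert ghd(w, w) == 0.0

    def test_uncentred_adjacency_identity_with_hd(self):
        # (1/(N(N-1))) sum (a_ij - b_ij)^2 == 2*HD/(N(N-1)) for raw 0/1 weights
        for seed in range(20):
            a, b = random_pair(int(4 + seed % 5), 0.5, seed)
            n = a.n_nodes
            raw = ((a.adjacency - b.adjacency) ** 2).sum() / (n * (n - 1))
            assert raw == pytest.approx(
                2 * hamming_distance(a, b) / (n * (n - 1)))

    def test_ghd_symmetric_in_arguments(self):
        a, b = random_pair(20, 0.3, 3)
        wa = centre_weights(topological_overlap(a))
        wb = centre_weights(topological_overlap(b))
        assert ghd(wa, wb) == ghd(wb, wa)

    def test_joint_relabelling_invariance(self):
        rng = np.random.default_rng(0)
        a, b = random_pair(25, 0.3, 9)
        base = ghd(centre_weights(topological_overlap(a)),
                   centre_weights(topological_overlap(b)))
        for _ in range(5):
            perm = rng.permutation(25)
            ap, bp = a.permuted(perm), b.permuted(perm)
            moved = ghd(centre_weights(topological_overlap(ap)),
                        centre_weights(topological_overlap(bp)))
            assert moved == pytest.approx(base, abs=1e-12)

    def test_mode_mismatch_and_uncentred_rejected(self, path3, k4):
        wa = centre_weights(topological_overlap(path3))
        raw = topological_overlap(path3)
        with pytest.raises(ValueError, match="centred"):
            ghd(wa, raw)


class TestSensitivity:
    def test_single_edge_moves_equal_hd_distinct_ghd(self):
        # one edge relocated in two different ways: HD cannot tell the
        # variants apart, the TO-weighted GHD can
        ref = Network.from_edges(
            [("1", "2"), ("2", "3"), ("3", "4"), ("4", "5"), ("2", "4")],
            nodes=["1", "2", "3", "4", "5"])
        v1 = Network.from_edges(
            [("1", "3"), ("2", "3"), ("3", "4"), ("4", "5"), ("2", "4")],
            nodes=["1", "2", "3", "4", "5"])
        v2 = Network.from_edges(
            [("1", "5"), ("2", "3"), ("3", "4"), ("4", "5"), ("2", "4")],
            nodes=["1", "2", "3", "4", "5"])
        assert hamming_distance(ref, v1) == hamming_distance(ref, v2) == 2

        def to_ghd(x, y):
            return ghd(centre_weights(topological_overlap(x)),
                       centre_weights(topological_overlap(y)))

        assert to_ghd(ref, v1) != pytest.approx(to_ghd(ref, v2), abs=1e-12)
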