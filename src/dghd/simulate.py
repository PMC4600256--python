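"""Random-network models, controlled-noise pairs and planted subnetworks.

These generators define the simulation conditions under which the GHD test
and the differential-subnetwork algorithm are studied:

* 2D random geometric (RG) graphs — N points uniform on the unit square,
  edges between points closer than a radius ``d`` (no torus wrap-around);
* Erdos-Renyi graphs — either uniform over graphs with an exact edge
  count (the conditional-uniform-graph null) or with IID edges;
* scale-free-degree graphs — IID degrees from a truncated power law
  realised by an erased configuration model;
* ``shuffle_edges`` — deletes a proportion ``gamma`` of edges and
  reinserts the same number uniformly among absent pairs, preserving the
  edge count exactly; gamma interpolates between an identical copy
  (gamma=0) and a density-matched independent graph (gamma=1);
* ``plant_differential`` — a pair of globally dependent networks whose
  induced subgraphs on a hidden node subset are replaced by two
  independent RG draws, the ground truth for subnetwork detection.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .network import Network

__all__ = [
    "rg_network",
    "er_network",
    "sf_network",
    "sf_degree_sample",
    "shuffle_edges",
    "plant_differential",
    "power_study",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _labels(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"n{idx:0{width}d}" for idx in range(n))


def _pair_index_to_edge(idx: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear upper-triangle (k=1) indices to (i, j) with i < j."""
    iu, ju = np.triu_indices(n, k=1)
    return iu[idx], ju[idx]


def rg_network(
    n: int, d: float, seed: int | np.random.Generator = 0
) -> Network:
    """2D random geometric graph on the unit square with radius ``d``.

    Points are uniform on [0,1]^2 and a pair is joined when its Euclidean
    distance is strictly smaller than ``d``.  Boundary effects are kept
    (no wrap-around), so the expected density is below pi d^2 for small d.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if d < 0:
        raise ValueError("radius must be non-negative")
    rng = _as_rng(seed)
    pts = rng.random((n, 2))
    dist = squareform(pdist(pts))
    a = (dist < d).astype(np.int8)
    np.fill_diagonal(a, 0)
    return Network(_labels(n), a)


def rg_expected_density(d: float, n_grid: int = 2000) -> float:
    """Expected edge probability of the unit-square RG model.

    P(|U - V| < d) for independent uniforms on [0,1]^2, evaluated by
    numerical integration of the known single-axis difference density
    f(t) = 2(1-t): the squared distance is the sum of two independent
    such coordinates squared.
    """
    t = (np.arange(n_grid) + 0.5) / n_grid
    fx = 2.0 * (1.0 - t)
    # joint density over the (dx, dy) grid; count mass inside the disc
    inside = (t[:, None] ** 2 + t[None, :] ** 2) < d * d
    mass = (fx[:, None] * fx[None, :] * inside).sum() / (n_grid * n_grid)
    return float(mass)


def er_network(
    n: int,
    p: float | None = None,
    edge_count: int | None = None,
    seed: int | np.random.Generator = 0,
) -> Network:
    """Erdos-Renyi graph: exact edge count (uniform G(n, m)) or IID edges."""
    if (p is None) == (edge_count is None):
        raise ValueError("give exactly one of p or edge_count")
    rng = _as_rng(seed)
    n_pairs = n * (n - 1) // 2
    a = np.zeros((n, n), dtype=np.int8)
    if edge_count is not None:
        if not 0 <= edge_count <= n_pairs:
            raise ValueError(f"edge_count must be in [0, {n_pairs}]")
        chosen = rng.choice(n_pairs, size=edge_count, replace=False)
        i, j = _pair_index_to_edge(chosen, n)
        a[i, j] = 1
        a[j, i] = 1
    else:
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        upper = rng.random((n, n)) < p
        upper = np.triu(upper, k=1)
        a = (upper | upper.T).astype(np.int8)
    return Network(_labels(n), a)


def sf_degree_sample(
    n: int,
    alpha: float,
    m: int = 1,
    k_max: int | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """IID degrees from the truncated power law P(d=k) ~ k^-alpha, k=m..K.

    The upper cutoff defaults to round(N^{1/(alpha-1)}) for alpha > 2 and
    N-1 for 1 < alpha <= 2, the conventional choices for scale-free
    degree sequences.
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    if k_max is None:
        k_max = int(round(n ** (1.0 / (alpha - 1.0)))) if alpha > 2 else n - 1
    if not (1 <= m <= k_max <= n - 1):
        raise ValueError("need 1 <= m <= K <= n-1")
    rng = _as_rng(seed)
    support = np.arange(m, k_max + 1)
    pmf = support.astype(np.float64) ** (-alpha)
    pmf /= pmf.sum()
    return rng.choice(support, size=n, p=pmf)


def sf_network(
    n: int,
    alpha: float,
    m: int = 1,
    k_max: int | None = None,
    seed: int | np.random.Generator = 0,
) -> Network:
    """Graph with power-law degrees via an erased configuration model.

    Degrees are drawn IID from the truncated power law; if their sum is
    odd one degree is incremented by 1 to make the sequence graphical as
    a multigraph.  Stub matching then realises the sequence and
    self-loops/parallel edges are erased, which perturbs the realised
    degrees slightly but preserves the degree law asymptotically.
    """
    import networkx as nx

    rng = _as_rng(seed)
    degrees = sf_degree_sample(n, alpha, m=m, k_max=k_max, seed=rng)
    if degrees.sum() % 2 == 1:
        degrees = degrees.copy()
        degrees[int(rng.integers(n))] += 1
    nx_seed = int(rng.integers(2 ** 31 - 1))
    multi = nx.configuration_model(degrees.tolist(), seed=nx_seed)
    graph = nx.Graph(multi)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    a = np.zeros((n, n), dtype=np.int8)
    for u, v in graph.edges():
        a[u, v] = 1
        a[v, u] = 1
    return Network(_labels(n), a)


def shuffle_edges(
    net: Network, gamma: float, seed: int | np.random.Generator = 0
) -> Network:
    """Randomly relocate a proportion ``gamma`` of the edges.

    ceil(gamma * |E|) edges are chosen uniformly without replacement and
    deleted, and the same number of edges is inserted uniformly among the
    pairs absent after deletion (deleted slots may be refilled).  The edge
    count is preserved exactly; gamma=0 returns an identical copy and
    gamma=1 yields a uniform density-matched graph independent of the
    input.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    rng = _as_rng(seed)
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    flat = net.adjacency[iu, ju].astype(bool)
    edge_idx = np.nonzero(flat)[0]
    k = math.ceil(gamma * edge_idx.size)
    if k == 0:
        return Network(net.node_labels, net.adjacency.copy())
    drop = rng.choice(edge_idx, size=k, replace=False)
    flat = flat.copy()
    flat[drop] = False
    absent = np.nonzero(~flat)[0]
    if absent.size < k:
        raise ValueError("not enough absent pairs to reinsert edges")
    add = rng.choice(absent, size=k, replace=False)
    flat[add] = True
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[flat], ju[flat]] = 1
    a |= a.T
    return Network(net.node_labels, a)


@dataclass(frozen=True)
class PlantedPair:
    """A dependent network pair with an independent planted subnetwork."""

    a: Network
    b: Network
    truth: tuple[str, ...]


def plant_differential(
    n: int,
    subnet_size: int,
    d: float,
    gamma: float,
    seed: int | np.random.Generator = 0,
) -> PlantedPair:
    """Plant an independent differential subnetwork in a dependent RG pair.

    Network A is an RG draw; B is A with a proportion ``gamma`` of edges
    shuffled.  A uniformly chosen node subset V* of size ``subnet_size``
    then has all its *internal* edges deleted in both networks and
    replaced by two independent RG draws of that size (same radius), so
    the induced subgraphs on V* are independent while edges from V* to
    the rest are left untouched.
    """
    if not 0 < subnet_size < n:
        raise ValueError("subnet_size must be in (0, n)")
    rng = _as_rng(seed)
    a = rg_network(n, d, seed=rng)
    b = shuffle_edges(a, gamma, seed=rng)
    idx = rng.choice(n, size=subnet_size, replace=False)
    idx.sort()
    truth = tuple(a.node_labels[i] for i in idx)

    def _replace_block(net: Network) -> Network:
        adj = net.adjacency.copy()
        block = rg_network(subnet_size, d, seed=rng).adjacency
        adj[np.ix_(idx, idx)] = block
        return Network(net.node_labels, adj)

    return PlantedPair(a=_replace_block(a), b=_replace_block(b), truth=truth)


def power_study(
    n: int,
    d: float,
    gammas,
    n_rep: int,
    level: float = 0.05,
    n_perm: int = 999,
    n_sim: int = 999,
    seed: int = 0,
    methods: tuple[str, ...] = ("ghd", "mad", "qap", "cug"),
    mode: str = "topological_overlap",
):
    """Null-acceptance proportions of each test across a noise grid.

    For each gamma, generates ``n_rep`` pairs (A, shuffle_edges(A, gamma)),
    runs the requested tests and records the proportion of replications in
    which the null hypothesis of independence is *not* rejected at
    ``level``.  Replicate seeds are master seed + a running counter.
    Returns a pandas DataFrame with one row per (gamma, method).
    """
    import pandas as pd

    from .baselines import cug_test, mad_test, qap_test
    from .ghd_test import ghd_test_asymptotic

    if n_rep < 1:
        raise ValueError("n_rep must be positive")
    rows = []
    counter = 0
    for gamma in gammas:
        accepts = {meth: 0 for meth in methods}
        for _ in range(n_rep):
            rep_seed = seed + counter
            counter += 1
            rng = np.random.default_rng(rep_seed)
            net_a = rg_network(n, d, seed=rng)
            net_b = shuffle_edges(net_a, gamma, seed=rng)
            for meth in methods:
                if meth == "ghd":
                    p = ghd_test_asymptotic(net_a, net_b, mode=mode).p_value
                elif meth == "hd":
                    p = ghd_test_asymptotic(net_a, net_b, mode="adjacency").p_value
                elif meth == "mad":
                    p = mad_test(net_a, net_b, n_perm=n_perm, seed=rng).p_value
                elif meth == "qap":
                    p = qap_test(net_a, net_b, n_perm=n_perm, seed=rng).p_value
                elif meth == "cug":
                    p = cug_test(net_a, net_b, n_sim=n_sim, seed=rng).p_value
                else:
                    raise ValueError(f"unknown method {meth!r}")
                if p >= level:
                    accepts[meth] += 1
        for meth in methods:
            rows.append({"gamma": float(gamma), "method": meth,
                         "acceptance": accepts[meth] / n_rep,
                         "n_rep": n_rep, "level": level})
    return pd.DataFrame(rows)
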