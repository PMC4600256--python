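"""Competing two-network independence tests: MAD, QAP and CUG.

* MAD — mean absolute difference of adjacency entries over distinct pairs;
  a normalised edge-difference count.  Similar networks give *small* MAD,
  so the permutation test rejects independence in the lower tail.
* QAP — mean elementwise product of adjacencies (the quadratic assignment
  procedure statistic); similar networks give a *large* product, so the
  permutation test rejects in the upper tail.
* CUG — compares an observed graph-covariance statistic (``gcor``) with
  its distribution over uniform random graphs conditioned on size and
  edge count; rejects in the upper tail.

MAD and QAP share the GHD test's permutation engine (uniform joint
relabelling of one network).  For binary networks |a - b| = a + b - 2ab,
so a single permuted cross-product sum drives both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network, _check_same_universe

__all__ = [
    "BaselineResult",
    "mad",
    "qap",
    "gcor",
    "mad_test",
    "qap_test",
    "cug_test",
]


@dataclass(frozen=True)
class BaselineResult:
    statistic: float
    p_value: float
    method: str
    tail: str
    n_resamples: int
    seed: int | None


def mad(a: Network, b: Network) -> float:
    """Mean absolute adjacency difference over distinct node pairs, in [0, 1]."""
    _check_same_universe(a, b)
    n = a.n_nodes
    diff = np.abs(a.adjacency.astype(np.int64) - b.adjacency.astype(np.int64))
    return float(diff.sum() / (n * (n - 1)))


def qap(a: Network, b: Network) -> float:
    """Mean elementwise adjacency product over distinct node pairs, in [0, 1]."""
    _check_same_universe(a, b)
    n = a.n_nodes
    prod = a.adjacency.astype(np.int64) * b.adjacency.astype(np.int64)
    return float(prod.sum() / (n * (n - 1)))


def gcor(a: Network, b: Network, normalised: bool = False) -> float:
    """Graph covariance sum between two binary networks.

    ``sum_{i != j} (a_ij - abar)(b_ij - bbar)`` with ``abar``/``bbar`` the
    off-diagonal means — an unnormalised cross product.  ``normalised=True``
    divides by the product of the centred root sums of squares (a proper
    correlation coefficient); CUG p-values are invariant to this positive
    scaling, so the raw sum is the default.
    """
    _check_same_universe(a, b)
    n = a.n_nodes
    nn1 = n * (n - 1.0)
    av = a.adjacency.astype(np.float64)
    bv = b.adjacency.astype(np.float64)
    ac = av - av.sum() / nn1
    bc = bv - bv.sum() / nn1
    np.fill_diagonal(ac, 0.0)
    np.fill_diagonal(bc, 0.0)
    raw = float((ac * bc).sum())
    if not normalised:
        return raw
    denom = float(np.sqrt((ac * ac).sum() * (bc * bc).sum()))
    return raw / denom if denom > 0 else 0.0


def _permuted_cross_products(
    a: Network, b: Network, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sum of A_perm * B over ordered pairs, for ``n_perm`` relabellings of A."""
    av = a.adjacency.astype(np.float64)
    bv = b.adjacency.astype(np.float64)
    n = a.n_nodes
    out = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        out[k] = (av[np.ix_(perm, perm)] * bv).sum()
    return out


def _addone(count: int, n_perm: int) -> float:
    return (1.0 + count) / (1.0 + n_perm)


def mad_test(
    a: Network,
    b: Network,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    tail: str = "lower",
) -> BaselineResult:
    """Permutation MAD test; rejects independence when MAD is unusually small."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    _check_same_universe(a, b)
    rng = np.random.default_rng(seed)
    n = a.n_nodes
    nn1 = n * (n - 1.0)
    observed = mad(a, b)
    s1a = float(a.adjacency.sum())
    s1b = float(b.adjacency.sum())
    cross = _permuted_cross_products(a, b, n_perm, rng)
    perm_stats = (s1a + s1b - 2.0 * cross) / nn1
    if tail == "lower":
        p = _addone(int(np.count_nonzero(perm_stats <= observed)), n_perm)
    elif tail == "upper":
        p = _addone(int(np.count_nonzero(perm_stats >= observed)), n_perm)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return BaselineResult(observed, float(p), "mad", tail, n_perm,
                          int(seed_val) if seed_val is not None else None)


def qap_test(
    a: Network,
    b: Network,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    tail: str = "upper",
) -> BaselineResult:
    """Permutation QAP test; rejects independence when the product is large."""
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    _check_same_universe(a, b)
    rng = np.random.default_rng(seed)
    n = a.n_nodes
    nn1 = n * (n - 1.0)
    observed = qap(a, b)
    perm_stats = _permuted_cross_products(a, b, n_perm, rng) / nn1
    if tail == "upper":
        p = _addone(int(np.count_nonzero(perm_stats >= observed)), n_perm)
    elif tail == "lower":
        p = _addone(int(np.count_nonzero(perm_stats <= observed)), n_perm)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return BaselineResult(observed, float(p), "qap", tail, n_perm,
                          int(seed_val) if seed_val is not None else None)


def cug_test(
    a: Network,
    b: Network,
    n_sim: int = 999,
    seed: int | np.random.Generator = 0,
    tail: str = "upper",
    normalised: bool = False,
) -> BaselineResult:
    """Conditional uniform graph test on the gcor statistic.

    The null draws pairs of uniform random graphs conditioned on the node
    count and the exact edge counts of the two observed networks, and
    compares the observed gcor with the simulated distribution (upper
    tail: dependent networks show unusually large graph covariance).
    """
    if n_sim < 99:
        raise ValueError("n_sim must be at least 99")
    _check_same_universe(a, b)
    from .simulate import er_network  # deferred: avoids an import cycle

    rng = np.random.default_rng(seed)
    n = a.n_nodes
    observed = gcor(a, b, normalised=normalised)
    ea, eb = a.n_edges, b.n_edges
    sims = np.empty(n_sim)
    for k in range(n_sim):
        ra = er_network(n, edge_count=ea, seed=rng)
        rb = er_network(n, edge_count=eb, seed=rng)
        sims[k] = gcor(ra, rb, normalised=normalised)
    if tail == "upper":
        p = _addone(int(np.count_nonzero(sims >= observed)), n_sim)
    elif tail == "lower":
        p = _addone(int(np.count_nonzero(sims <= observed)), n_sim)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return BaselineResult(observed, float(p), "cug", tail, n_sim,
                          int(seed_val) if seed_val is not None else None)
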