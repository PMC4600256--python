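"""Iterative differential-subnetwork detection (dGHD / dHD).

The algorithm compares two labelled networks on a shrinking sequence of
node sets.  At each step it evaluates the centred GHD statistic

    Delta_VK = GHD(A(V_K), B(V_K)) - mu_VK ,

with weights *recomputed on the induced subgraphs* (topological overlap
depends on the retained neighbourhood) and mu_VK the closed-form
permutation mean, together with the asymptotic p-value of the
independence test.  The influence of node i,

    delta_i = Delta_{V_K minus i} - Delta_VK ,

measures how much removing i moves the pair towards independence; the
node with the largest delta is removed and the process repeats down to a
minimum size.  After the full trace is produced the raw p-values are
Benjamini-Hochberg adjusted and the differential subnetwork is the node
set at the *largest* size whose adjusted p-value exceeds the significance
level.  With adjacency weights the same procedure is the dHD variant.

Because the centred weights make the permutation mean absorb both squared
terms of the GHD, the centred statistic reduces to a scaled centred
cross-product,

    Delta = -2/(K(K-1)) * [ P - S1a*S1b/(K(K-1)) ] ,

with P the raw cross-product sum and S1 the raw weight sums.  The
accelerated influence path exploits this: removing node i changes a TO
weight only through the shared-neighbour count (when i neighbours both
endpoints) and through the min-degree denominator (when the smaller-degree
endpoint neighbours i), so all N candidate removals reduce to a fixed set
of dense matrix products instead of N full weight recomputations.  The
exact recomputation path is kept as the reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ghd_test import MomentSums, permutation_moments
from .network import (
    MODE_ADJ,
    MODE_TO,
    Network,
    _check_same_universe,
    centre_weights,
    ghd,
    network_weights,
)

__all__ = [
    "RemovalStep",
    "DetectionResult",
    "bh_adjust",
    "centred_ghd",
    "node_influences",
    "dghd_run",
    "confusion",
]


# ---------------------------------------------------------------------------
# Small utilities
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, clipped to [0, 1]."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def _to_weights_raw(a: np.ndarray, common: np.ndarray | None = None):
    """Raw TO weights plus intermediates from a 0/1 float adjacency.

    ``common`` may supply the precomputed shared-neighbour count matrix
    (A @ A); the backward-elimination driver maintains it incrementally.
    """
    deg = a.sum(axis=1)
    if common is None:
        common = a @ a
    numer = common + a
    denom = np.minimum.outer(deg, deg) + 1.0 - a
    w = numer / denom
    np.fill_diagonal(w, 0.0)
    return w, numer, denom, deg


def _raw_weights(a: np.ndarray, mode: str):
    if mode == MODE_TO:
        return _to_weights_raw(a)[0]
    if mode == MODE_ADJ:
        return a
    raise ValueError(f"unknown weight mode {mode!r}")


def _centred_stats(wa: np.ndarray, wb: np.ndarray, k: int):
    """GHD, permutation moments and Delta from *raw* weights.

    Centring is carried out analytically (the centred weight sum is zero
    by construction), which keeps the step loop in simple sums.
    """
    norm = k * (k - 1.0)
    s1a = float(wa.sum())
    s1b = float(wb.sum())
    s2a = float((wa * wa).sum()) - s1a * s1a / norm
    s2b = float((wb * wb).sum()) - s1b * s1b / norm
    ra = wa.sum(axis=1) - s1a / k
    rb = wb.sum(axis=1) - s1b / k
    ta = float((ra * ra).sum())
    tb = float((rb * rb).sum())
    cross = float((wa * wb).sum()) - s1a * s1b / norm
    statistic = (s2a + s2b - 2.0 * cross) / norm
    moments = permutation_moments(
        MomentSums(s1=0.0, s2=s2a, t=ta, n=k),
        MomentSums(s1=0.0, s2=s2b, t=tb, n=k),
        k,
    )
    delta = statistic - moments.mu  # equals -2*cross/norm analytically
    return statistic, moments, delta


def _p_lower(statistic: float, mu: float, sigma2: float) -> tuple[float, float]:
    from scipy.stats import norm as _norm

    if sigma2 <= 0.0:
        return float("nan"), 1.0
    z = (statistic - mu) / np.sqrt(sigma2)
    return float(z), float(_norm.cdf(z))


# ---------------------------------------------------------------------------
# Centred statistic and node influences
# ---------------------------------------------------------------------------

def centred_ghd(
    a: Network,
    b: Network,
    nodes: Sequence[str] | None = None,
    mode: str = MODE_TO,
) -> float:
    """Centred GHD statistic on the induced subnetworks of ``nodes``.

    Weights are recomputed on the induced subgraphs and the closed-form
    permutation mean is subtracted; negative values indicate dependence
    (observed distance below its permutation expectation).
    """
    _check_same_universe(a, b)
    if nodes is not None:
        a = a.subgraph(list(nodes))
        b = b.subgraph(list(nodes))
    if a.n_nodes < 4:
        raise ValueError("centred GHD needs at least 4 nodes")
    wa = centre_weights(network_weights(a, mode))
    wb = centre_weights(network_weights(b, mode))
    from .ghd_test import moment_sums

    m = permutation_moments(moment_sums(wa), moment_sums(wb), wa.n)
    return ghd(wa, wb) - m.mu


def _influences_exact(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    """delta_i by full recomputation on every leave-one-out subgraph."""
    k = a.shape[0]
    _, _, base = _centred_stats(_raw_weights(a, mode), _raw_weights(b, mode), k)
    deltas = np.empty(k)
    for i in range(k):
        keep = np.r_[0:i, i + 1:k]
        sub_a = a[np.ix_(keep, keep)]
        sub_b = b[np.ix_(keep, keep)]
        _, _, d = _centred_stats(_raw_weights(sub_a, mode),
                                 _raw_weights(sub_b, mode), k - 1)
        deltas[i] = d - base
    return deltas


def _diag_xmy(x: np.ndarray, m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """diag(X @ M @ Y^T) for symmetric Y, one matmul per call."""
    return ((x @ m) * y).sum(axis=1)


def _to_update_factors(numer, denom, deg):
    """Pairwise factors describing how a TO weight reacts to a removal.

    For candidate removal i and pair (j, k) with j, k != i the weight
    change is (N*dD - D*dN) / ((D - dD) * D) with dN = A_ij A_ik (lost
    shared neighbour) and dD in {0, 1} (min-degree drop).  Whenever
    dD = 1 the denominator satisfies D >= 2, so the two reusable factors

        H = (N - D) / ((D-1) D)   (both endpoints neighbour i)
        G = N / ((D-1) D) * [d_j <= d_k]   (only endpoint j neighbours i)

    are finite on every pair where they are actually used; entries with
    D = 1 are masked to zero and never contribute.
    """
    less_eq = (deg[:, None] <= deg[None, :]).astype(np.float64)
    safe = denom > 1.5
    inv = np.zeros_like(denom)
    np.divide(1.0, (denom - 1.0) * denom, out=inv, where=safe)
    g = numer * inv * less_eq
    h = (numer - denom) * inv
    np.fill_diagonal(g, 0.0)
    np.fill_diagonal(h, 0.0)
    return g, h


def _influence_sums_to(a, b, wa, wb, na, da, deg_a, nb, db, deg_b):
    """Leave-one-out corrections to (S1a, S1b, P) for all candidates at once.

    Returns (d_s1a, d_s1b, d_p): for each node i, the correction beyond
    simply dropping row/column i, accounting for TO weights that change
    on the remaining pairs.  All terms are diag(X @ M @ Y) contractions
    with X, Y built from the adjacency indicators of the two networks.
    """
    ga, ha = _to_update_factors(na, da, deg_a)
    gb, hb = _to_update_factors(nb, db, deg_b)
    ca = 1.0 - a
    np.fill_diagonal(ca, 0.0)
    cb = 1.0 - b
    np.fill_diagonal(cb, 0.0)

    d_s1a = _diag_xmy(a, ha, a) + 2.0 * _diag_xmy(a, ga, ca)
    d_s1b = _diag_xmy(b, hb, b) + 2.0 * _diag_xmy(b, gb, cb)

    # linear cross terms: changed-A weights against unchanged B and vice versa
    d_p = (
        _diag_xmy(a, ha * wb, a) + 2.0 * _diag_xmy(a, ga * wb, ca)
        + _diag_xmy(b, hb * wa, b) + 2.0 * _diag_xmy(b, gb * wa, cb)
    )

    # quadratic terms: pairs whose weight changes in both networks.  The
    # nine index combinations collapse to five contractions because each
    # mixed term equals the transpose-swapped one (H symmetric, W symmetric).
    r = a * b
    ar = a - r
    br = b - r
    cc = ca * cb
    d_p += (
        _diag_xmy(r, ha * hb, r)
        + 2.0 * _diag_xmy(r, ha * gb, ar)
        + 2.0 * _diag_xmy(r, ga * hb, br)
        + 2.0 * _diag_xmy(r, ga * gb, cc)
        + 2.0 * _diag_xmy(ar, ga * gb.T, br)
    )
    return d_s1a, d_s1b, d_p


def _influences_fast(
    a: np.ndarray,
    b: np.ndarray,
    mode: str,
    pack_a: tuple | None = None,
    pack_b: tuple | None = None,
) -> np.ndarray:
    """delta_i for every node without per-candidate weight recomputation.

    ``pack_a``/``pack_b`` may pass the (weights, numerator, denominator,
    degrees) tuples already computed for the p-value of the current step.
    """
    k = a.shape[0]
    if mode == MODE_ADJ:
        wa, wb = a, b
        d_s1a = d_s1b = d_p = 0.0
    else:
        wa, na, da, deg_a = pack_a if pack_a is not None else _to_weights_raw(a)
        wb, nb, db, deg_b = pack_b if pack_b is not None else _to_weights_raw(b)
        d_s1a, d_s1b, d_p = _influence_sums_to(
            a, b, wa, wb, na, da, deg_a, nb, db, deg_b)

    norm = k * (k - 1.0)
    s1a = float(wa.sum())
    s1b = float(wb.sum())
    p_full = float((wa * wb).sum())
    base = -2.0 * (p_full - s1a * s1b / norm) / norm

    s1a_i = s1a - 2.0 * wa.sum(axis=1) + d_s1a
    s1b_i = s1b - 2.0 * wb.sum(axis=1) + d_s1b
    p_i = p_full - 2.0 * (wa * wb).sum(axis=1) + d_p
    norm_i = (k - 1.0) * (k - 2.0)
    delta_loo = -2.0 * (p_i - s1a_i * s1b_i / norm_i) / norm_i
    return delta_loo - base


def node_influences(
    a: Network,
    b: Network,
    nodes: Sequence[str] | None = None,
    mode: str = MODE_TO,
    method: str = "fast",
) -> np.ndarray:
    """Influence delta_i of every node of the (sub)network pair.

    ``method="exact"`` recomputes the centred statistic on each
    leave-one-out subgraph; ``method="fast"`` uses the closed-form update
    of the TO weights and matches the exact path to numerical precision.
    """
    _check_same_universe(a, b)
    if nodes is not None:
        a = a.subgraph(list(nodes))
        b = b.subgraph(list(nodes))
    if a.n_nodes < 5:
        raise ValueError("node influences need at least 5 nodes")
    av = a.adjacency.astype(np.float64)
    bv = b.adjacency.astype(np.float64)
    if method == "exact":
        return _influences_exact(av, bv, mode)
    if method == "fast":
        return _influences_fast(av, bv, mode)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# The dGHD / dHD driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RemovalStep:
    """One step of the backward-elimination trace."""

    size: int
    statistic: float          # GHD on the current node set
    centred_stat: float       # Delta_VK = GHD - mu_VK
    z: float
    p_raw: float
    p_adjusted: float | None
    removed: tuple[str, ...]  # nodes removed to reach the next step
    delta: float | None       # influence of the removed node (largest)
    all_deltas_nonpositive: bool


@dataclass(frozen=True)
class DetectionResult:
    trace: tuple[RemovalStep, ...]
    selected_size: int | None
    differential_nodes: tuple[str, ...] | None
    alpha: float
    mode: str
    n_min: int
    batch: int
    node_labels: tuple[str, ...]

    def nodes_at(self, size: int) -> tuple[str, ...]:
        """Node set of the trace step with the given size."""
        current = set(self.node_labels)
        for step in self.trace:
            if step.size == size:
                return tuple(x for x in self.node_labels if x in current)
            current.difference_update(step.removed)
        raise ValueError(f"no trace step of size {size}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "size": [s.size for s in self.trace],
                "removed_node": [",".join(s.removed) for s in self.trace],
                "delta": [s.delta for s in self.trace],
                "statistic": [s.statistic for s in self.trace],
                "centred_stat": [s.centred_stat for s in self.trace],
                "p_raw": [s.p_raw for s in self.trace],
                "p_adjusted": [s.p_adjusted for s in self.trace],
            }
        )


def default_n_min(n: int) -> int:
    """Smallest allowed subnetwork size: max(20, ceil(0.02 n))."""
    return max(20, int(np.ceil(0.02 * n)))


def dghd_run(
    a: Network,
    b: Network,
    n_min: int | None = None,
    alpha: float = 0.05,
    mode: str = MODE_TO,
    batch: int = 1,
) -> DetectionResult:
    """Run the backward-elimination differential-subnetwork algorithm.

    At every size from N down to ``n_min`` the asymptotic GHD p-value is
    computed on the current induced subgraphs and the ``batch`` nodes with
    the largest influences are removed (ties broken by smallest label; if
    no influence is positive the largest one is still removed so the full
    trace exists).  Raw p-values are then BH-adjusted across the whole
    trace and the selected differential subnetwork is the node set at the
    largest size with adjusted p-value above ``alpha``; ``None`` when every
    step rejects independence.  ``mode="adjacency"`` gives the dHD variant.
    """
    _check_same_universe(a, b)
    n = a.n_nodes
    if n_min is None:
        n_min = default_n_min(n)
    if not 5 <= n_min < n:
        raise ValueError("need 5 <= n_min < n")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if batch < 1:
        raise ValueError("batch must be >= 1")

    labels = list(a.node_labels)
    av = a.adjacency.astype(np.float64)
    bv = b.adjacency.astype(np.float64)

    steps: list[dict] = []
    k = n
    common_a = common_b = None  # maintained by rank-1 downdates in TO mode
    while k >= n_min:
        if mode == MODE_TO:
            pack_a = _to_weights_raw(av, common=common_a)
            pack_b = _to_weights_raw(bv, common=common_b)
            wa, wb = pack_a[0], pack_b[0]
        else:
            pack_a = pack_b = None
            wa, wb = av, bv
        statistic, moments, delta_stat = _centred_stats(wa, wb, k)
        z, p_raw = _p_lower(statistic, moments.mu, moments.sigma2)
        record = {
            "size": k,
            "statistic": statistic,
            "centred_stat": delta_stat,
            "z": z,
            "p_raw": p_raw,
            "removed": (),
            "delta": None,
            "all_deltas_nonpositive": False,
        }
        if k > n_min:
            deltas = _influences_fast(av, bv, mode, pack_a, pack_b)
            n_remove = min(batch, k - n_min)
            # sort by (-delta, label) for deterministic tie-breaking
            order = sorted(range(k), key=lambda i: (-deltas[i], labels[i]))
            drop = order[:n_remove]
            record["removed"] = tuple(labels[i] for i in drop)
            record["delta"] = float(deltas[drop[0]])
            record["all_deltas_nonpositive"] = bool(deltas.max() <= 0.0)
            keep = np.setdiff1d(np.arange(k), np.array(drop))
            if mode == MODE_TO:
                # dropping node r removes one shared neighbour from every
                # pair of its neighbours: an exact integer rank-1 downdate
                common_a = pack_a[1] - av  # back to A @ A
                common_b = pack_b[1] - bv
                for r in drop:
                    common_a -= np.outer(av[:, r], av[:, r])
                    common_b -= np.outer(bv[:, r], bv[:, r])
                common_a = common_a[np.ix_(keep, keep)]
                common_b = common_b[np.ix_(keep, keep)]
            av = av[np.ix_(keep, keep)]
            bv = bv[np.ix_(keep, keep)]
            labels = [labels[i] for i in keep]
            k -= n_remove
        else:
            steps.append(record)
            break
        steps.append(record)

    p_adj = bh_adjust([s["p_raw"] for s in steps])
    trace = tuple(
        RemovalStep(
            size=s["size"],
            statistic=s["statistic"],
            centred_stat=s["centred_stat"],
            z=s["z"],
            p_raw=s["p_raw"],
            p_adjusted=float(q),
            removed=s["removed"],
            delta=s["delta"],
            all_deltas_nonpositive=s["all_deltas_nonpositive"],
        )
        for s, q in zip(steps, p_adj)
    )

    result = DetectionResult(
        trace=trace,
        selected_size=None,
        differential_nodes=None,
        alpha=alpha,
        mode=mode,
        n_min=n_min,
        batch=batch,
        node_labels=a.node_labels,
    )
    for step in trace:  # sizes are strictly decreasing
        if step.p_adjusted is not None and step.p_adjusted > alpha:
            nodes = result.nodes_at(step.size)
            return DetectionResult(
                trace=trace, selected_size=step.size,
                differential_nodes=nodes, alpha=alpha, mode=mode,
                n_min=n_min, batch=batch, node_labels=a.node_labels)
    return result


def confusion(
    result: DetectionResult, truth: Sequence[str]
) -> tuple[float, float]:
    """(TPR, SPC) of the detected node set against the planted truth."""
    truth_set = set(map(str, truth))
    universe = set(result.node_labels)
    if not truth_set <= universe:
        raise ValueError("truth contains labels outside the node universe")
    detected = set(result.differential_nodes or ())
    tp = len(detected & truth_set)
    fn = len(truth_set - detected)
    fp = len(detected - truth_set)
    tn = len(universe - truth_set - detected)
    tpr = tp / (tp + fn) if (tp + fn) else float("nan")
    spc = tn / (fp + tn) if (fp + tn) else float("nan")
    return tpr, spc
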