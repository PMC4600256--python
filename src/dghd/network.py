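"""Labelled binary networks, edge weighting, and network distances.

A :class:`Network` is an undirected, unweighted graph on a fixed, ordered
node universe, stored as a dense symmetric 0/1 adjacency matrix with zero
diagonal.  Isolated nodes are first-class citizens: subnetwork extraction
can isolate nodes, and all distances are defined on the full node set.

Two edge-weighting schemes are supported and wrapped in a
:class:`WeightMatrix`:

* ``adjacency`` — the raw 0/1 adjacency entries;
* ``topological_overlap`` — the one-step topological overlap (TO), which
  scores a node pair by the size of its shared neighbourhood relative to
  the smaller of the two degrees, normalised to [0, 1].

The Generalised Hamming Distance (GHD) between two networks is the mean
squared difference of *mean-centred* edge weights over all ordered pairs
of distinct nodes,

    GHD(A, B) = 1/(N(N-1)) * sum_{i != j} (a'_ij - b'_ij)^2 ,

where a'_ij = a_ij - mean(a) and the mean runs over distinct pairs.  With
adjacency weights GHD is a (centred) relative of the classical Hamming
distance; with TO weights it is sensitive to neighbourhood rearrangements
that leave the raw edge-difference count unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "WeightMatrix",
    "DegreeVector",
    "read_network",
    "write_network",
    "topological_overlap",
    "adjacency_weights",
    "centre_weights",
    "hamming_distance",
    "ghd",
]

MODE_TO = "topological_overlap"
MODE_ADJ = "adjacency"


@dataclass(frozen=True)
class Network:
    """Undirected binary graph on an ordered node universe.

    Parameters
    ----------
    node_labels
        Unique string identifiers; their order defines matrix index order.
    adjacency
        ``(N, N)`` symmetric 0/1 matrix with zero diagonal.
    """

    node_labels: tuple[str, ...]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.node_labels)
        object.__setattr__(self, "node_labels", labels)
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if a.shape[0] != len(labels):
            raise ValueError("adjacency size does not match node_labels")
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if len(labels) < 2:
            raise ValueError("a network needs at least 2 nodes")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("weighted input unsupported: entries must be 0 or 1")
        a = a.astype(np.int8)
        if np.diag(a).any():
            raise ValueError("self-loops are not allowed")
        if (a != a.T).any():
            raise ValueError("adjacency must be symmetric")
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        """Node degrees in label order."""
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edges(self) -> list[tuple[str, str]]:
        """Sorted list of undirected edges as label pairs (i < j by index)."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return [(self.node_labels[i], self.node_labels[j]) for i, j in zip(iu, ju)]

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        lookup = {lab: k for k, lab in enumerate(self.node_labels)}
        try:
            return np.array([lookup[str(x)] for x in labels], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"unknown node label {e.args[0]!r}") from None

    def subgraph(self, labels: Sequence[str]) -> "Network":
        """Induced subgraph on ``labels`` (order preserved as given)."""
        idx = self.index_of(labels)
        return Network(tuple(str(x) for x in labels),
                       self.adjacency[np.ix_(idx, idx)].copy())

    def permuted(self, perm: np.ndarray) -> "Network":
        """Relabelled copy: node at position ``k`` takes position ``perm[k]``.

        Rows and columns of the adjacency are shuffled jointly while labels
        keep their positions, which is the permutation used by the
        permutation null of the GHD test.
        """
        perm = np.asarray(perm)
        a = self.adjacency[np.ix_(perm, perm)]
        return Network(self.node_labels, a.copy())

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from(self.edges())
        return g

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
    ) -> "Network":
        """Build a network from an edge list, optionally over a node universe."""
        edges = [(str(u), str(v)) for u, v in edges]
        if nodes is None:
            seen: dict[str, None] = {}
            for u, v in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = list(seen)
        labels = tuple(str(x) for x in nodes)
        lookup = {lab: k for k, lab in enumerate(labels)}
        a = np.zeros((len(labels), len(labels)), dtype=np.int8)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} rejected")
            i, j = lookup[u], lookup[v]
            a[i, j] = a[j, i] = 1
        return cls(labels, a)


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric real edge-weight matrix with zero diagonal.

    ``mode`` records the weighting scheme; ``centred`` whether the
    off-diagonal mean has been subtracted.  All GHD-related sums run over
    distinct node pairs, so the diagonal is stored as zero throughout.
    """

    values: np.ndarray
    mode: str
    centred: bool = False

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("weight matrix must be square")
        np.fill_diagonal(v, 0.0)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if self.mode not in (MODE_TO, MODE_ADJ):
            raise ValueError(f"unknown weight mode {self.mode!r}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass(frozen=True)
class DegreeVector:
    """Degrees and weight row sums of one network, used by the normality check."""

    degrees: np.ndarray
    row_sums: np.ndarray
    mean_row_sum: float


def degree_vector(w: WeightMatrix) -> DegreeVector:
    rs = w.row_sums()
    deg = (np.abs(w.values) > 0).sum(axis=1).astype(np.int64)
    return DegreeVector(degrees=deg, row_sums=rs, mean_row_sum=float(rs.mean()))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NODES_HEADER = re.compile(r"^#\s*nodes\s*:\s*(.*)$")


def read_network(
    path: str | Path,
    format: str = "edgelist",
    nodes: Sequence[str] | None = None,
) -> Network:
    """Read a network from an edge-list TSV or a labelled adjacency CSV.

    Edge-list files hold two whitespace-separated labels per row and may
    declare the node universe on a ``# nodes: n1,n2,...`` header line, so
    isolated nodes survive round trips.  An explicit ``nodes`` argument
    overrides any header.  Adjacency CSVs must be square, labelled on both
    axes, symmetric and strictly 0/1.
    """
    path = Path(path)
    if format == "edgelist":
        universe: list[str] | None = list(nodes) if nodes is not None else None
        edges: list[tuple[str, str]] = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                m = _NODES_HEADER.match(line)
                if m:
                    if universe is None and m.group(1).strip():
                        universe = [s.strip() for s in m.group(1).split(",")]
                    continue
                if line.startswith("#") or line.lower().startswith("node_a"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"malformed edge-list row: {line!r}")
                if parts[0] == parts[1]:
                    raise ValueError(f"self-loop row rejected: {line!r}")
                edges.append((parts[0], parts[1]))
        return Network.from_edges(edges, nodes=universe)
    if format == "adjacency":
        df = pd.read_csv(path, index_col=0)
        labels = [str(x) for x in df.columns]
        if [str(x) for x in df.index] != labels:
            raise ValueError("adjacency row and column labels disagree")
        a = df.to_numpy()
        if not np.isin(a, (0, 1)).all():
            raise ValueError("weighted input unsupported")
        if nodes is not None and list(map(str, nodes)) != labels:
            raise ValueError("adjacency labels do not match the supplied universe")
        return Network(tuple(labels), a.astype(np.int8))
    raise ValueError(f"unknown format {format!r}")


def write_network(net: Network, path: str | Path, format: str = "edgelist") -> None:
    """Write a network; ``read_network(write_network(...))`` round-trips."""
    path = Path(path)
    if format == "edgelist":
        with path.open("w") as fh:
            fh.write("# nodes: " + ",".join(net.node_labels) + "\n")
            fh.write("node_a\tnode_b\n")
            for u, v in net.edges():
                fh.write(f"{u}\t{v}\n")
        return
    if format == "adjacency":
        df = pd.DataFrame(net.adjacency, index=net.node_labels,
                          columns=net.node_labels)
        df.to_csv(path)
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Weights and distances
# ---------------------------------------------------------------------------

def topological_overlap(net: Network) -> WeightMatrix:
    """One-step topological overlap weights of a binary network.

    For ``i != j``::

        w_ij = (#common neighbours of i and j + A_ij)
               / (min(d_i, d_j) + 1 - A_ij)

    The denominator is always >= 1 (isolated nodes give weight 0), and
    every off-diagonal weight lies in [0, 1].
    """
    a = net.adjacency.astype(np.float64)
    deg = a.sum(axis=1)
    common = a @ a  # common[i, j] = number of shared neighbours (i != j)
    numer = common + a
    denom = np.minimum.outer(deg, deg) + 1.0 - a
    w = numer / denom
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(values=w, mode=MODE_TO, centred=False)


def adjacency_weights(net: Network) -> WeightMatrix:
    """Raw 0/1 adjacency entries wrapped as a weight matrix."""
    return WeightMatrix(values=net.adjacency.astype(np.float64),
                        mode=MODE_ADJ, centred=False)


def network_weights(net: Network, mode: str) -> WeightMatrix:
    if mode == MODE_TO:
        return topological_overlap(net)
    if mode == MODE_ADJ:
        return adjacency_weights(net)
    raise ValueError(f"unknown weight mode {mode!r}")


def centre_weights(w: WeightMatrix) -> WeightMatrix:
    """Subtract the mean over distinct pairs from every off-diagonal entry."""
    if w.centred:
        raise ValueError("weights are already centred")
    n = w.n
    if n < 2:
        raise ValueError("need at least 2 nodes to centre")
    mean = w.values.sum() / (n * (n - 1))
    v = w.values - mean
    np.fill_diagonal(v, 0.0)
    return WeightMatrix(values=v, mode=w.mode, centred=True)


def _check_same_universe(a: Network, b: Network) -> None:
    if a.node_labels != b.node_labels:
        raise ValueError("networks must share the same node universe and order")


def hamming_distance(a: Network, b: Network) -> int:
    """Number of node pairs whose edge status differs: (1/2) tr[(A-B)^2]."""
    _check_same_universe(a, b)
    d = a.adjacency.astype(np.int64) - b.adjacency.astype(np.int64)
    return int(np.trace(d @ d)) // 2


def ghd(wa: WeightMatrix, wb: WeightMatrix) -> float:
    """Generalised Hamming Distance between two centred weight matrices."""
    if not (wa.centred and wb.centred):
        raise ValueError("ghd requires centred weight matrices")
    if wa.mode != wb.mode:
        raise ValueError("weight modes differ")
    n = wa.n
    if wb.n != n:
        raise ValueError("weight matrices differ in size")
    d = wa.values - wb.values
    return float((d * d).sum() / (n * (n - 1)))
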