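"""Co-methylation network construction from a probe matrix.

Nodes are probes (e.g. CpG sites); the soft-threshold adjacency

    omega_ij = ((1 + r_ij) / 2) ** b

maps the Pearson correlation r_ij of two probe columns to [0, 1],
emphasising strong positive correlations for large ``b``, and an edge is
drawn when omega_ij exceeds a hard threshold ``tau``.  With the defaults
b = 12 and tau = 0.2 this is equivalent to requiring
r > 2 * 0.2**(1/12) - 1 ~= 0.7487.

A synthetic probe-matrix generator with correlated probe blocks stands in
for real methylation array data, so case/control network comparisons can
be exercised end to end without any download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "ProbeMatrix",
    "read_probe_matrix",
    "correlation_threshold",
    "infer_network",
    "synth_probe_matrix",
]


@dataclass(frozen=True)
class ProbeMatrix:
    """Samples x probes numeric matrix with identifiers."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("probe matrix must be 2-dimensional")
        if v.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError("matrix shape does not match identifiers")
        if np.isnan(v).any():
            raise ValueError("probe matrix contains missing values")
        if v.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids",
                           tuple(str(x) for x in self.sample_ids))
        object.__setattr__(self, "probe_ids",
                           tuple(str(x) for x in self.probe_ids))


def read_probe_matrix(path: str | Path, sep: str | None = None) -> ProbeMatrix:
    """Load a samples x probes CSV/TSV; first column holds sample ids."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ProbeMatrix(df.to_numpy(dtype=np.float64),
                       tuple(map(str, df.index)), tuple(map(str, df.columns)))


def correlation_threshold(b: float = 12.0, tau: float = 0.2) -> float:
    """Pearson correlation above which the soft-thresholded weight exceeds tau."""
    return 2.0 * tau ** (1.0 / b) - 1.0


def infer_network(
    m: ProbeMatrix,
    b: float = 12.0,
    tau: float = 0.2,
    chunk_size: int = 2000,
) -> Network:
    """Binary co-methylation network from pairwise probe correlations.

    Probe pairs with soft-thresholded adjacency ((1 + r)/2)**b strictly
    greater than ``tau`` are linked; ties at exactly tau are non-edges.
    Constant probe columns carry no correlation signal and are dropped
    with a warning.  Correlations are computed in column chunks so probe
    counts well beyond the sample count stay within memory.
    """
    values = m.values
    keep = values.std(axis=0) > 0
    if not keep.all():
        dropped = [p for p, k in zip(m.probe_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant probe column(s)",
                      stacklevel=2)
        values = values[:, keep]
    probe_ids = tuple(p for p, k in zip(m.probe_ids, keep) if k)
    n_probes = values.shape[1]
    if n_probes < 2:
        raise ValueError("need at least 2 non-constant probes")
    z = (values - values.mean(axis=0)) / values.std(axis=0)
    n_samples = values.shape[0]
    adj = np.zeros((n_probes, n_probes), dtype=np.int8)
    r_min = correlation_threshold(b, tau)
    for start in range(0, n_probes, chunk_size):
        stop = min(start + chunk_size, n_probes)
        r_block = (z[:, start:stop].T @ z) / n_samples
        np.clip(r_block, -1.0, 1.0, out=r_block)
        # edge iff omega > tau, equivalently r > 2*tau**(1/b) - 1
        adj[start:stop, :] = (r_block > r_min).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.minimum(adj, adj.T)  # guard against asymmetric float ties
    return Network(probe_ids, adj)


def synth_probe_matrix(
    n_samples: int,
    n_probes: int,
    block_sizes: Sequence[int] = (),
    within_block_r: float = 0.8,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> ProbeMatrix:
    """Synthetic probe matrix with latent-factor correlation blocks.

    Probes inside each block share one latent factor scaled so the
    pairwise correlation within the block is approximately
    ``within_block_r``; all remaining probes are independent noise.  The
    blocks occupy the leading columns in order.
    """
    if sum(block_sizes) > n_probes:
        raise ValueError("blocks exceed the number of probes")
    if not -1.0 < within_block_r < 1.0:
        raise ValueError("within_block_r must lie in (-1, 1)")
    if within_block_r < 0:
        raise ValueError("negative within-block correlation is not supported")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = rng.normal(0.0, 1.0, size=(n_samples, n_probes))
    start = 0
    for size in block_sizes:
        factor = rng.normal(0.0, 1.0, size=n_samples)
        lam = np.sqrt(within_block_r)
        x[:, start:start + size] = (
            lam * factor[:, None]
            + np.sqrt(1.0 - within_block_r) * x[:, start:start + size]
        )
        start += size
    x *= noise_sd
    samples = tuple(f"s{idx}" for idx in range(n_samples))
    probes = tuple(f"cg{idx:05d}" for idx in range(n_probes))
    return ProbeMatrix(x, samples, probes)
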