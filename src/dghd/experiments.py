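"""Reproduction harness for the simulation studies.

Three studies are packaged:

* ``null_qq_study`` — calibration of the asymptotic GHD test under
  independence: p-values over independently generated RG pairs, with a
  Kolmogorov-Smirnov comparison against U(0, 1) and a QQ table;
* ``power_study`` — null-acceptance proportion of each test along a grid
  of edge-shuffling noise levels (delegates to :func:`dghd.simulate.power_study`);
* ``benchmark_study`` — sensitivity/specificity of dGHD and dHD on
  planted differential subnetworks across noise levels.

Each run is fully described by its config; replicate seeds are derived
from the master seed by adding a running counter, so results are exactly
reproducible from a saved manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .detection import confusion, dghd_run
from .ghd_test import ghd_test_asymptotic
from .simulate import plant_differential, power_study, rg_network

__all__ = [
    "NullQQConfig",
    "BenchmarkConfig",
    "null_qq_study",
    "benchmark_study",
    "write_manifest",
]


@dataclass(frozen=True)
class NullQQConfig:
    n_rep: int = 2000
    n: int = 250
    d: float = 0.3
    mode: str = "topological_overlap"
    seed: int = 0
    n_quantiles: int = 99


@dataclass(frozen=True)
class BenchmarkConfig:
    gammas: tuple[float, ...] = (0.055, 0.11, 0.23, 0.54, 0.79, 0.95)
    n: int = 1000
    subnet_size: int = 200
    d: float = 0.3
    n_rep: int = 100
    alpha: float = 0.05
    n_min: int | None = None
    batch: int = 1
    seed: int = 0
    methods: tuple[str, ...] = ("dghd", "dhd")


def null_qq_study(cfg: NullQQConfig):
    """p-values of the asymptotic GHD test over independent RG pairs.

    Returns ``(p_values, summary, qq_table)``: the raw p-value sample, a
    dict with the KS statistic/p-value against U(0,1) and the empirical
    rejection rate at the 5% level, and a QQ table of empirical versus
    theoretical uniform quantiles.
    """
    ps = np.empty(cfg.n_rep)
    for rep in range(cfg.n_rep):
        rng = np.random.default_rng(cfg.seed + rep)
        net_a = rg_network(cfg.n, cfg.d, seed=rng)
        net_b = rg_network(cfg.n, cfg.d, seed=rng)
        ps[rep] = ghd_test_asymptotic(net_a, net_b, mode=cfg.mode).p_value
    if cfg.n_rep < 2:
        return ps, {}, pd.DataFrame()
    ks_stat, ks_p = stats.kstest(ps, "uniform")
    summary = {
        "ks_statistic": float(ks_stat),
        "ks_p_value": float(ks_p),
        "rejection_rate_5pct": float(np.mean(ps < 0.05)),
        "n_rep": cfg.n_rep,
    }
    grid = (np.arange(cfg.n_quantiles) + 1) / (cfg.n_quantiles + 1)
    qq = pd.DataFrame({
        "theoretical": grid,
        "empirical": np.quantile(ps, grid),
    })
    return ps, summary, qq


def benchmark_study(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Mean TPR/SPC of the detection algorithms on planted subnetworks.

    One planted instance is generated per (gamma, replicate); both the
    TO-weighted (dGHD) and adjacency-weighted (dHD) algorithms run on the
    same instance so their comparison is paired.
    """
    mode_of = {"dghd": "topological_overlap", "dhd": "adjacency"}
    rows = []
    counter = 0
    for gamma in cfg.gammas:
        scores: dict[str, list[tuple[float, float]]] = {
            m: [] for m in cfg.methods}
        for _ in range(cfg.n_rep):
            pair = plant_differential(cfg.n, cfg.subnet_size, cfg.d, gamma,
                                      seed=cfg.seed + counter)
            counter += 1
            for meth in cfg.methods:
                res = dghd_run(pair.a, pair.b, n_min=cfg.n_min,
                               alpha=cfg.alpha, mode=mode_of[meth],
                               batch=cfg.batch)
                scores[meth].append(confusion(res, pair.truth))
        for meth in cfg.methods:
            arr = np.array(scores[meth])
            rows.append({"gamma": float(gamma), "method": meth,
                         "tpr": float(arr[:, 0].mean()),
                         "spc": float(arr[:, 1].mean()),
                         "n_rep": cfg.n_rep})
    return pd.DataFrame(rows)


def write_manifest(cfg, out_dir: str | Path, name: str = "manifest.json") -> Path:
    """Record every parameter and seed of a study next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = dataclasses.asdict(cfg) if dataclasses.is_dataclass(cfg) else dict(cfg)
    payload["config_class"] = type(cfg).__name__
    path = out_dir / name
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
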