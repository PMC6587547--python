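"""Factorial benchmark orchestration.

A sweep crosses QTN counts x heritabilities x replicates (the default
10 x 10 x 10 design yields exactly 1000 phenotype datasets per population)
over a subset of engines, evaluating each scan with the increasing-rank
metrics.  Per-cell seeds are derived from the base seed by a 64-bit
splitmix-style mix of the cell coordinates, so grids are reproducible,
collision-free, and extendable.  Also provides the population-size
subsampling experiment and plotting/aggregation helpers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayescpi import BayesChainConfig, run_bayescpi
from .evaluate import compute_metrics, match_positives, metrics_curve
from .farmcpu import run_farmcpu
from .genotypes import GenotypeMatrix
from .mlm import bonferroni_calls, scan_mlm
from .phenotype import sample_architecture, simulate_trait
from .structure import compute_kinship, compute_pca

__all__ = ["SweepConfig", "enumerate_design", "run_sweep",
           "subsample_experiment", "summarize_report", "cell_seed"]

log = logging.getLogger("gwasbench")

DEFAULT_N_QTN_GRID = tuple(2 ** k for k in range(1, 11))          # 2..1024
DEFAULT_H2_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))  # 0.1..1.0


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def cell_seed(base_seed: int, n_qtn: int, h2: float, replicate: int) -> int:
    """Deterministic, collision-resistant per-cell seed below 2^31."""
    h = _splitmix64(base_seed)
    h = _splitmix64(h ^ n_qtn)
    h = _splitmix64(h ^ int(round(h2 * 1000)))
    h = _splitmix64(h ^ replicate)
    return int(h % (2 ** 31 - 1))


@dataclass
class SweepConfig:
    """Design of a factorial benchmark sweep."""

    n_qtn_grid: tuple = DEFAULT_N_QTN_GRID
    h2_grid: tuple = DEFAULT_H2_GRID
    replicates: int = 10
    engines: tuple = ("mlm", "farmcpu", "bayescpi")
    base_seed: int = 0
    K_grid: tuple | None = None        # None: 1..2*n_qtn, log-thinned above 100
    bayes_config: BayesChainConfig | None = None
    out_dir: str | None = None         # enables resumable per-cell artifacts

    def validate(self) -> None:
        if not self.n_qtn_grid or not self.h2_grid or self.replicates < 1:
            raise ValueError("sweep grids must be non-empty")
        bad = set(self.engines) - {"mlm", "farmcpu", "bayescpi"}
        if bad:
            raise ValueError(f"unknown engines: {sorted(bad)}")


def enumerate_design(config: SweepConfig) -> pd.DataFrame:
    """All (n_qtn, h2, replicate, seed) cells of the design; one row per
    phenotype dataset."""
    config.validate()
    rows = [(n, h, r, cell_seed(config.base_seed, n, h, r))
            for n in config.n_qtn_grid
            for h in config.h2_grid
            for r in range(config.replicates)]
    return pd.DataFrame(rows, columns=["n_qtn", "h2", "replicate", "seed"])


def _k_grid(n_qtn: int, config: SweepConfig, M: int):
    if config.K_grid is not None:
        return [k for k in config.K_grid if k <= M]
    top = min(2 * n_qtn, M)
    if top <= 100:
        return list(range(1, top + 1))
    dense = list(range(1, 101))
    sparse = np.unique(np.geomspace(100, top, num=25).astype(int)).tolist()
    return sorted(set(dense + sparse))


def _run_engine(engine: str, G: GenotypeMatrix, y, Q, K, config: SweepConfig,
                seed: int):
    if engine == "mlm":
        return scan_mlm(G, y, Q, K, mode="approx")
    if engine == "farmcpu":
        return run_farmcpu(G, y, Q)
    bc = config.bayes_config or BayesChainConfig()
    from dataclasses import replace
    return run_bayescpi(G, y, replace(bc, seed=seed)).to_result(G)


def run_sweep(G: GenotypeMatrix, config: SweepConfig) -> pd.DataFrame:
    """Run the full factorial benchmark on one genotype matrix.

    Returns the tidy metrics table (engine, n_qtn, h2, replicate, K, counts,
    power, fdr, type1).  With ``config.out_dir`` set, finished cells are
    written to disk and skipped on re-run; an engine failure flags the cell
    and the sweep continues.
    """
    config.validate()
    if not G.is_complete:
        raise ValueError("genotype matrix must be complete (impute first)")
    design = enumerate_design(config)
    Q = compute_pca(G, n_components=min(10, G.n_individuals - 1,
                                        G.n_markers))
    K = compute_kinship(G, estimator="centered")
    frames = []
    for cell in design.itertuples(index=False):
        tag = f"n{cell.n_qtn}_h{cell.h2}_r{cell.replicate}"
        path = (os.path.join(config.out_dir, f"{tag}.tsv")
                if config.out_dir else None)
        if path and os.path.exists(path):
            log.info("cell %s: cached, skipping", tag)
            frames.append(pd.read_csv(path, sep="\t"))
            continue
        arch = sample_architecture(G, cell.n_qtn, h2=cell.h2, seed=cell.seed)
        pheno = simulate_trait(G, arch)
        cell_frames = []
        for engine in config.engines:
            try:
                result = _run_engine(engine, G, pheno, Q, K, config, cell.seed)
                m = metrics_curve(result, arch, G,
                                  K_grid=_k_grid(cell.n_qtn, config,
                                                 G.n_markers))
            except Exception as exc:  # engine failure: flag, keep sweeping
                log.warning("cell %s engine %s failed: %s", tag, engine, exc)
                m = pd.DataFrame([{"K": np.nan, "failed": True}])
            m.insert(0, "engine", engine)
            cell_frames.append(m)
        out = pd.concat(cell_frames, ignore_index=True)
        out.insert(1, "n_qtn", cell.n_qtn)
        out.insert(2, "h2", cell.h2)
        out.insert(3, "replicate", cell.replicate)
        if path:
            os.makedirs(config.out_dir, exist_ok=True)
            out.to_csv(path, sep="\t", index=False)
        log.info("cell %s: done", tag)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def subsample_experiment(G: GenotypeMatrix, sizes, n_qtn: int, h2: float,
                         replicates: int = 10, base_seed: int = 0
                         ) -> pd.DataFrame:
    """Bonferroni power of the MLM engine as population size grows.

    Individuals are sampled without replacement per replicate and the trait
    is re-simulated on the subsample; power follows the LD-linked
    true-positive definition at the Bonferroni call set.
    """
    rows = []
    for size in sizes:
        if size > G.n_individuals:
            raise ValueError(f"subsample size {size} exceeds population "
                             f"size {G.n_individuals}")
        for rep in range(replicates):
            seed = cell_seed(base_seed, n_qtn + size, h2, rep)
            rng = np.random.default_rng(seed)
            sub = (G if size == G.n_individuals else
                   G.take_individuals(np.sort(rng.choice(
                       G.n_individuals, size=size, replace=False))))
            arch = sample_architecture(sub, n_qtn, h2=h2, seed=seed)
            pheno = simulate_trait(sub, arch)
            Q = compute_pca(sub, n_components=min(10, size - 1))
            K = compute_kinship(sub)
            result = scan_mlm(sub, pheno, Q, K)
            called = bonferroni_calls(result)
            ids = result.table["id"]
            idx = np.flatnonzero(ids.isin(called).to_numpy())
            # order the call set by p so merging is deterministic
            p = result.table["p"].to_numpy()
            idx = idx[np.argsort(p[idx])]
            tp, eff, fp = match_positives(idx, arch, sub)
            m = compute_metrics(tp, eff, fp, n_qtn, sub.n_markers)
            rows.append({"size": size, "replicate": rep, "n_qtn": n_qtn,
                         "h2": h2, "n_calls": len(idx), **m})
    return pd.DataFrame(rows)


def summarize_report(results: pd.DataFrame, out_dir: str | None = None
                     ) -> pd.DataFrame:
    """Aggregate the tidy sweep table to per-cell means with standard
    errors; optionally render power/FDR-vs-K and power-vs-architecture
    plots into ``out_dir``."""
    if results.empty:
        raise ValueError("empty results table")
    res = results.dropna(subset=["K"]) if "K" in results.columns else results
    keys = ["engine", "n_qtn", "h2", "K"]
    agg = (res.groupby(keys, as_index=False)
           .agg(power_mean=("power", "mean"), power_se=("power", "sem"),
                fdr_mean=("fdr", "mean"), fdr_se=("fdr", "sem"),
                type1_mean=("type1", "mean"), type1_se=("type1", "sem"),
                n_rep=("replicate", "nunique")))
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        agg.to_csv(os.path.join(out_dir, "aggregate.tsv"), sep="\t",
                   index=False)
        _render_plots(agg, out_dir)
    return agg


def _render_plots(agg: pd.DataFrame, out_dir: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for h2, sub in agg.groupby("h2"):
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for (engine, n_qtn), grp in sub.groupby(["engine", "n_qtn"]):
            grp = grp.sort_values("K")
            axes[0].plot(grp["K"], grp["power_mean"],
                         label=f"{engine} n={n_qtn}")
            axes[1].plot(grp["K"], grp["fdr_mean"])
        axes[0].set_xlabel("accepted positives K")
        axes[0].set_ylabel("power")
        axes[1].set_xlabel("accepted positives K")
        axes[1].set_ylabel("FDR")
        axes[0].legend(fontsize=6)
        fig.suptitle(f"h2 = {h2}")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"power_fdr_h2_{h2}.png"), dpi=120)
        plt.close(fig)
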