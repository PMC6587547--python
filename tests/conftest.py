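import numpy as np
import pandas as pd
import pytest

import gwasbench as gb


def make_population(n_individuals=200, n_markers=800, seed=11,
                    maf_spec="common-filtered", **kw):
    spec = gb.PopulationSpec(n_individuals=n_individuals, n_markers=n_markers,
                             maf_spec=maf_spec, seed=seed, **kw)
    return gb.generate_population(spec)


def toy_matrix(dosages, positions=None, chrom=None, samples=None):
    """Small hand-built GenotypeMatrix from an M x N array."""
    D = np.asarray(dosages, float)
    M = D.shape[0]
    positions = positions if positions is not None else 100 * (np.arange(M) + 1)
    chrom = chrom if chrom is not None else ["1"] * M
    markers = pd.DataFrame({
        "id": [f"m{i}" for i in range(M)],
        "chrom": chrom, "pos": positions,
        "counted": "A", "other": "T",
    })
    samples = samples or [f"s{j}" for j in range(D.shape[1])]
    return gb.GenotypeMatrix(D, markers, samples)


@pytest.fixture(scope="session")
def small_pop():
    """200 x 800 structured population for engine unit tests."""
    G, truth = make_population(seed=11)
    return gb.filter_markers(G, min_maf=0.05), truth


@pytest.fixture(scope="session")
def bench_pop():
    """The 500 x 5000 benchmark population (complete, unfiltered)."""
    G, truth = make_population(n_individuals=500, n_markers=5000, seed=101)
    return G, truth


@pytest.fixture(scope="session")
def bench_filtered(bench_pop):
    G, _ = bench_pop
    return gb.filter_markers(G, min_maf=0.05)


@pytest.fixture(scope="session")
def bench_qk(bench_filtered):
    Q = gb.compute_pca(bench_filtered)
    K = gb.compute_kinship(bench_filtered)
    return Q, K
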