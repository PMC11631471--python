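"""Shared fixtures: small synthetic libraries, mixture bulks, benchmark runs."""

from __future__ import annotations

import numpy as np
import pytest

from vtissue.containers import ExpressionMatrix, SingleCellLibrary
from vtissue.fit import BootstrapConfig, bootstrap_fit, harmonize
from vtissue.simulate import SimulationConfig, generate_library, run_benchmark

MIXTURE_GRID = [
    (0.6, 0.3, 0.1),
    (1 / 3, 1 / 3, 1 / 3),
    (0.2, 0.5, 0.3),
    (0.1, 0.1, 0.8),
    (0.5, 0.25, 0.25),
]


def random_instance(seed: int, n_genes: int = 20, n_cells: int = 10):
    """One random non-negative regression instance (y, X)."""
    rng = np.random.default_rng(seed)
    X = rng.lognormal(1.0, 1.0, (n_genes, n_cells))
    y = rng.lognormal(1.0, 1.0, n_genes)
    return y, X


@pytest.fixture(scope="session")
def small_library():
    """A 3-type synthetic library with ground-truth model, desk scale."""
    config = SimulationConfig(
        n_genes=80,
        cell_types=("alpha", "beta", "gamma"),
        cells_per_type=100,
        n_donors=4,
        seed=11,
        dispersion=1.0,
    )
    library, model = generate_library(config)
    return config, library, model


@pytest.fixture(scope="session")
def mixture_fit(small_library):
    """Bulks built as known 3-type mixtures of the library's type means, fitted.

    Ground truth: because every cell column is scaled to the same total,
    a label's share of fitted weight equals its share of explained
    expression, which the mixture construction fixes exactly.
    """
    _, library, _ = small_library
    assert library.labels is not None
    types = sorted(set(library.labels))
    means = np.column_stack(
        [library.values[:, library.labels == t].mean(axis=1) for t in types]
    )
    bulk_values = np.column_stack([means @ np.asarray(p) for p in MIXTURE_GRID])
    bulk = ExpressionMatrix(
        bulk_values, library.gene_ids, [f"mix_{i}" for i in range(len(MIXTURE_GRID))]
    )
    bulk_h, lib_h = harmonize(bulk, library)
    config = BootstrapConfig(n_runs=10, cell_fraction=0.3, seed=5)
    fit = bootstrap_fit(bulk_h, lib_h, config)
    return bulk_h, lib_h, fit, types, np.asarray(MIXTURE_GRID).T  # truth: types x samples


@pytest.fixture(scope="session")
def random_fit():
    """Random bulks fitted against a random library (no mixture structure)."""
    rng = np.random.default_rng(42)
    library = SingleCellLibrary(
        rng.lognormal(1.0, 1.0, (60, 80)),
        [f"g{i}" for i in range(60)],
        [f"c{i}" for i in range(80)],
        labels=rng.choice(["A", "B", "C", "D"], size=80),
    )
    bulk = ExpressionMatrix(
        rng.lognormal(1.0, 1.0, (60, 6)), library.gene_ids, [f"s{i}" for i in range(6)]
    )
    bulk_h, lib_h = harmonize(bulk, library)
    fit = bootstrap_fit(bulk_h, lib_h, BootstrapConfig(n_runs=4, cell_fraction=0.4, seed=3))
    return bulk_h, lib_h, fit


def benchmark_config(seed: int) -> SimulationConfig:
    """The scaled-down attribution benchmark conditions."""
    return SimulationConfig(n_bulks=40, cells_per_bulk=200, seed=seed)


@pytest.fixture(scope="session")
def benchmark_table():
    cfg = benchmark_config(seed=1)
    bs = BootstrapConfig(n_runs=10, cell_fraction=0.10, seed=1)
    return run_benchmark(cfg, bootstrap=bs), cfg


@pytest.fixture(scope="session")
def null_benchmark_table():
    cfg = benchmark_config(seed=1)
    bs = BootstrapConfig(n_runs=10, cell_fraction=0.10, seed=1)
    return run_benchmark(cfg, bootstrap=bs, log2fc_grid=[0.0]), cfg
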