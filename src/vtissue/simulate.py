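"""Synthetic single-cell libraries and pseudo-bulks for benchmarking.

The generator emulates the structure the benchmark relies on: several
donors contribute cells of a few discrete cell types; each type has a
distinct expression archetype built from a shared baseline plus
type-specific marker genes, so types are separable but share most of
their transcriptome (perturbed genes are therefore not exclusive to one
type).  Per-cell counts follow a negative-binomial model around the
archetype with per-cell depth variation, then each cell is scaled to a
common CPM-like column sum.

The benchmark itself perturbs a random half of one cell type's cells by
multiplying a random gene set by a fold factor, sums random cell draws
into pseudo-bulk profiles of two classes (class I contains perturbed
cells, class II does not), fits the bulks against cells from *held-out*
donors, and asks whether the perturbed genes surface in the perturbed
type's differential table — and only there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SingleCellLibrary
from .decompose import decompose
from .evaluate import permutation_null_auc, rank_differential, roc_auc
from .fit import BootstrapConfig, bootstrap_fit, harmonize

__all__ = [
    "SimulationConfig",
    "LibraryModel",
    "BenchmarkTruth",
    "generate_library",
    "split_by_donor",
    "apply_modification",
    "build_pseudobulks",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population and the benchmark design.

    ``cells_per_type`` counts the whole population; donors split evenly
    into a library half and a bulk-pool half, so the fitting library
    holds about half of the cells.  Dispersion parameterises the
    negative binomial as ``var = m + dispersion * m^2`` (0 = noiseless).
    """

    n_genes: int = 500
    cell_types: tuple[str, ...] = ("type_0", "type_1", "type_2", "type_3")
    cells_per_type: int = 1000
    n_donors: int = 8
    shared_gene_fraction: float = 0.4
    marker_gene_fraction: float = 0.2
    marker_strength: float = 8.0
    type_effect_sd: float = 1.25
    n_substates: int = 2
    substate_effect_sd: float = 0.4
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.3
    library_size_sd: float = 0.3
    donor_effect_sd: float = 0.1
    target_sum: float = 1e6
    modified_type: str | None = None
    modified_cell_fraction: float = 0.5
    n_modified_genes: int = 38
    log2_fold_change: float = 2.0
    n_bulks: int = 100
    cells_per_bulk: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cell_types) < 2:
            raise ValueError("at least two cell types are required (spill-over needs targets)")
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValueError("duplicate cell type names")
        if not (0.0 < self.modified_cell_fraction <= 1.0):
            raise ValueError("modified_cell_fraction must lie in (0, 1]")
        if self.n_modified_genes > self.n_genes:
            raise ValueError("n_modified_genes exceeds n_genes")
        if self.n_bulks % 2:
            raise ValueError("n_bulks must be even (half per class)")
        if self.n_donors < 2:
            raise ValueError("need at least two donors for the library/bulk split")
        if self.shared_gene_fraction + self.marker_gene_fraction > 1.0:
            raise ValueError("shared_gene_fraction + marker_gene_fraction must not exceed 1")
        if self.n_substates < 1:
            raise ValueError("n_substates must be >= 1")

    @property
    def target_type(self) -> str:
        return self.modified_type if self.modified_type is not None else self.cell_types[0]


@dataclass(frozen=True)
class LibraryModel:
    """Ground truth of the generator: archetypes, markers, sub-state labels."""

    archetypes: pd.DataFrame  # genes x types, linear mean expression
    marker_genes: dict[str, list[str]]  # type -> genes strongly elevated in that type
    cell_substates: np.ndarray  # per-cell sub-state label, e.g. "type_0/state_1"


@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth of one benchmark instance."""

    modified_gene_ids: tuple[str, ...]
    modified_cell_ids: tuple[str, ...]
    class_assignment: dict[str, str]  # sample id -> "I" | "II"


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return mean.copy()
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def generate_library(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SingleCellLibrary, LibraryModel]:
    """Draw a synthetic single-cell population.

    Returns the library (with type labels and donor ids) and the
    generating model (archetypes, marker genes) for use as ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_types = len(config.cell_types)
    genes = np.asarray([f"gene_{i:04d}" for i in range(config.n_genes)], dtype=object)

    # Three gene regimes: identical across types, hard markers of one type,
    # and graded genes whose level differs across types by lognormal factors.
    # Graded genes give each type a distinctive quantitative profile even
    # where expression is not exclusive, which mirrors real transcriptomes.
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    archetypes = np.tile(baseline[:, np.newaxis], (1, n_types))
    regime = rng.random(config.n_genes)
    marker_cut = config.shared_gene_fraction + config.marker_gene_fraction
    marker_of = rng.integers(0, n_types, size=config.n_genes)
    markers: dict[str, list[str]] = {t: [] for t in config.cell_types}
    for g in range(config.n_genes):
        if regime[g] < config.shared_gene_fraction:
            continue
        if regime[g] < marker_cut:
            t = int(marker_of[g])
            archetypes[g, t] *= config.marker_strength
            markers[config.cell_types[t]].append(genes[g])
        elif config.type_effect_sd > 0:
            archetypes[g, :] *= rng.lognormal(0.0, config.type_effect_sd, n_types)

    # Within-type sub-states: correlated expression shifts shared by all
    # cells of a (type, state) pair, emulating activation/differentiation
    # states inside a discrete cell type.
    substate_factors = (
        rng.lognormal(0.0, config.substate_effect_sd, (n_types, config.n_substates, config.n_genes))
        if config.substate_effect_sd > 0 and config.n_substates > 1
        else np.ones((n_types, config.n_substates, config.n_genes))
    )

    donor_names = np.asarray([f"donor_{d}" for d in range(config.n_donors)], dtype=object)
    donor_factors = (
        rng.lognormal(0.0, config.donor_effect_sd, (config.n_donors, config.n_genes))
        if config.donor_effect_sd > 0
        else np.ones((config.n_donors, config.n_genes))
    )

    n_cells = n_types * config.cells_per_type
    values = np.empty((config.n_genes, n_cells))
    labels = np.empty(n_cells, dtype=object)
    donors = np.empty(n_cells, dtype=object)
    substates = np.empty(n_cells, dtype=object)
    cell_ids = np.asarray([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)

    col = 0
    for t, type_name in enumerate(config.cell_types):
        donor_idx = rng.integers(0, config.n_donors, size=config.cells_per_type)
        state_idx = rng.integers(0, config.n_substates, size=config.cells_per_type)
        depth = (
            rng.lognormal(0.0, config.library_size_sd, config.cells_per_type)
            if config.library_size_sd > 0
            else np.ones(config.cells_per_type)
        )
        for j in range(config.cells_per_type):
            mean = (
                archetypes[:, t]
                * substate_factors[t, state_idx[j]]
                * donor_factors[donor_idx[j]]
                * depth[j]
            )
            values[:, col] = _nb_sample(rng, mean, config.dispersion)
            labels[col] = type_name
            donors[col] = donor_names[donor_idx[j]]
            substates[col] = f"{type_name}/state_{state_idx[j]}"
            col += 1

    totals = values.sum(axis=0)
    scale = np.where(totals > 0, config.target_sum / np.where(totals > 0, totals, 1.0), 1.0)
    values *= scale[np.newaxis, :]

    library = SingleCellLibrary(values, genes, cell_ids, labels=labels, donor_ids=donors)
    model = LibraryModel(
        archetypes=pd.DataFrame(archetypes, index=genes, columns=list(config.cell_types)),
        marker_genes=markers,
        cell_substates=substates,
    )
    return library, model


def split_by_donor(
    library: SingleCellLibrary,
    donors: Sequence[str],
) -> tuple[SingleCellLibrary, SingleCellLibrary]:
    """Split cells into (cells of ``donors``, cells of all other donors)."""
    if library.donor_ids is None:
        raise ValueError("library carries no donor ids")
    chosen = set(donors)
    mask = np.asarray([d in chosen for d in library.donor_ids])
    if not mask.any() or mask.all():
        raise ValueError("donor split must leave cells on both sides")
    return library.subset_cells(np.flatnonzero(mask)), library.subset_cells(np.flatnonzero(~mask))


def apply_modification(
    cells: SingleCellLibrary,
    cell_type: str,
    fraction: float,
    gene_ids: Sequence[str],
    log2fc: float,
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
) -> tuple[SingleCellLibrary, tuple[str, ...]]:
    """Multiply selected genes by ``2**log2fc`` in a random cell subset.

    A uniformly random ``fraction`` of the cells labeled ``cell_type``
    is modified; every other entry is untouched.  Returns the modified
    library and the ids of the modified cells.
    """
    if cells.labels is None:
        raise ValueError("cells carry no type labels")
    rng = rng if rng is not None else np.random.default_rng(seed)
    type_idx = np.flatnonzero(cells.labels == cell_type)
    if len(type_idx) == 0:
        raise ValueError(f"cell type {cell_type!r} not present")
    n_mod = int(round(fraction * len(type_idx)))
    if n_mod < 1:
        raise ValueError(
            f"fraction {fraction} of {len(type_idx)} {cell_type!r} cells rounds to zero"
        )
    chosen = np.sort(rng.choice(type_idx, size=n_mod, replace=False))
    gene_rows = cells.gene_index(gene_ids)
    values = cells.values.copy()
    values[np.ix_(gene_rows, chosen)] *= 2.0 ** log2fc
    modified = dc_replace(cells, values=values)
    return modified, tuple(cells.cell_ids[chosen])


def build_pseudobulks(
    class1_pool: SingleCellLibrary,
    class2_pool: SingleCellLibrary,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    modified_gene_ids: Sequence[str] = (),
    modified_cell_ids: Sequence[str] = (),
) -> tuple[ExpressionMatrix, BenchmarkTruth]:
    """Sum random cell draws into two classes of pseudo-bulk profiles.

    Each bulk is the elementwise sum of ``cells_per_bulk`` cell profiles
    drawn without replacement from its class pool (class I: the pool
    containing modified cells at their natural frequency; class II: the
    purely unmodified pool).  Half of ``n_bulks`` go to each class.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if list(class1_pool.gene_ids) != list(class2_pool.gene_ids):
        raise ValueError("pools must share the same gene ids in the same order")
    for pool, name in ((class1_pool, "class I"), (class2_pool, "class II")):
        if config.cells_per_bulk > pool.n_cells:
            raise ValueError(
                f"cells_per_bulk {config.cells_per_bulk} exceeds the {name} pool "
                f"({pool.n_cells} cells)"
            )
    half = config.n_bulks // 2
    values = np.empty((class1_pool.n_genes, config.n_bulks))
    sample_ids, classes = [], {}
    for b in range(config.n_bulks):
        pool = class1_pool if b < half else class2_pool
        cls = "I" if b < half else "II"
        idx = rng.choice(pool.n_cells, size=config.cells_per_bulk, replace=False)
        values[:, b] = pool.values[:, idx].sum(axis=1)
        sid = f"bulk_{b:03d}"
        sample_ids.append(sid)
        classes[sid] = cls
    bulks = ExpressionMatrix(values, class1_pool.gene_ids, sample_ids)
    truth = BenchmarkTruth(
        modified_gene_ids=tuple(modified_gene_ids),
        modified_cell_ids=tuple(modified_cell_ids),
        class_assignment=classes,
    )
    return bulks, truth


def _benchmark_point(
    config: SimulationConfig,
    log2fc: float,
    n_modified: int,
    bootstrap: BootstrapConfig,
    n_permutations: int,
    solver: str,
    seed: int,
) -> list[dict]:
    rng = np.random.default_rng(seed)
    population, _ = generate_library(config, rng)

    # Modify a random half of the target type's cells across the WHOLE
    # population, then split donors.  The library therefore contains both
    # sub-states of the target type (no individual cell is shared with
    # the bulk pools); class-I bulks draw from the modified bulk-donor
    # pool, class-II bulks from the same donors' unmodified cells.
    mod_genes = sorted(rng.choice(population.gene_ids, size=n_modified, replace=False))
    modified_population, mod_cells = apply_modification(
        population, config.target_type, config.modified_cell_fraction, mod_genes, log2fc, rng
    )
    library_donors = [f"donor_{d}" for d in range(config.n_donors // 2)]
    library_half, class1_pool = split_by_donor(modified_population, library_donors)
    _, class2_pool = split_by_donor(population, library_donors)

    bulks, truth = build_pseudobulks(
        class1_pool, class2_pool, config, rng,
        modified_gene_ids=mod_genes, modified_cell_ids=mod_cells,
    )

    bulk_h, lib_h = harmonize(bulks, library_half)
    fit = bootstrap_fit(bulk_h, lib_h, bootstrap, solver=solver)
    dec = decompose(fit)
    table = rank_differential(dec.per_label_expression, truth.class_assignment)

    rows = []
    for label in sorted(dec.per_label_expression):
        sub = table[table["label"] == label].set_index("gene")["statistic"]
        auc, _ = roc_auc(sub, truth.modified_gene_ids)
        null = permutation_null_auc(
            dec.per_label_expression[label],
            truth.class_assignment,
            truth.modified_gene_ids,
            n_permutations=n_permutations,
            seed=seed + 1,
        )
        p_greater = (1 + int((null >= auc).sum())) / (len(null) + 1)
        lo, hi = np.quantile(null, [0.025, 0.975])
        rows.append(
            {
                "label": label,
                "modified": label == config.target_type,
                "log2fc": log2fc,
                "n_modified_genes": n_modified,
                "auc": auc,
                "p_greater": p_greater,
                "null_low": float(lo),
                "null_high": float(hi),
            }
        )
    return rows


def run_benchmark(
    config: SimulationConfig,
    *,
    bootstrap: BootstrapConfig | None = None,
    log2fc_grid: Sequence[float] | None = None,
    n_modified_grid: Sequence[int] | None = None,
    n_permutations: int = 200,
    solver: str = "lbfgsb",
) -> pd.DataFrame:
    """Full benchmark pipeline over a grid of effect sizes.

    For each (log2 fold change, number of modified genes) grid point:
    generate the population, split donors into library and bulk pool,
    perturb the target type's cells, build the two pseudo-bulk classes,
    fit against the library donors only, decompose per cell type, rank
    genes per type, and score recovery of the perturbed genes by AUC
    with a label-permutation null.

    Returns a tidy table with one row per (grid point, cell type).
    """
    bootstrap = bootstrap or BootstrapConfig(n_runs=10, cell_fraction=0.10, seed=config.seed)
    fcs = list(log2fc_grid) if log2fc_grid is not None else [config.log2_fold_change]
    mods = list(n_modified_grid) if n_modified_grid is not None else [config.n_modified_genes]
    rows: list[dict] = []
    for i, fc in enumerate(fcs):
        for j, nm in enumerate(mods):
            point_seed = int(
                np.random.SeedSequence([config.seed, i, j]).generate_state(1)[0] % (2**31)
            )
            rows.extend(
                _benchmark_point(config, fc, nm, bootstrap, n_permutations, solver, point_seed)
            )
    return pd.DataFrame(rows)
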