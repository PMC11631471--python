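"""Synthetic library generator, perturbation, pseudo-bulks and benchmark wiring."""

import numpy as np
import pytest

from vtissue.containers import ExpressionMatrix
from vtissue.decompose import mean_cell_weights
from vtissue.fit import BootstrapConfig, bootstrap_fit, harmonize
from vtissue.simulate import (
    SimulationConfig,
    apply_modification,
    build_pseudobulks,
    generate_library,
    split_by_donor,
)


def tiny_config(**overrides):
    defaults = dict(
        n_genes=50,
        cell_types=("t0", "t1"),
        cells_per_type=10,
        n_donors=2,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestGenerateLibrary:
    def test_shape_and_balanced_labels(self):
        lib, _ = generate_library(tiny_config())
        assert lib.values.shape == (50, 20)
        assert (np.asarray(lib.labels) == "t0").sum() == 10
        assert (np.asarray(lib.labels) == "t1").sum() == 10
        assert lib.donor_ids is not None

    def test_zero_noise_limit_reproduces_archetypes(self):
        config = tiny_config(
            dispersion=0.0, library_size_sd=0.0, donor_effect_sd=0.0,
            substate_effect_sd=0.0, n_substates=1,
        )
        lib, model = generate_library(config)
        for t, name in enumerate(config.cell_types):
            arch = model.archetypes[name].to_numpy()
            arch_scaled = arch / arch.sum() * config.target_sum
            for col in np.flatnonzero(np.asarray(lib.labels) == name):
                np.testing.assert_allclose(lib.values[:, col], arch_scaled, rtol=1e-12)

    def test_type_profiles_are_distinguishable(self, small_library):
        _, lib, _ = small_library
        types = sorted(set(lib.labels))
        means = {t: lib.values[:, lib.labels == t].mean(axis=1) for t in types}
        for i, a in enumerate(types):
            for b in types[i + 1:]:
                cos = means[a] @ means[b] / (
                    np.linalg.norm(means[a]) * np.linalg.norm(means[b])
                )
                assert cos < 0.95

    def test_determinism_under_seed(self):
        lib1, _ = generate_library(tiny_config())
        lib2, _ = generate_library(tiny_config())
        np.testing.assert_array_equal(lib1.values, lib2.values)
        np.testing.assert_array_equal(lib1.donor_ids, lib2.donor_ids)

    def test_single_type_rejected(self):
        with pytest.raises(ValueError, match="at least two cell types"):
            tiny_config(cell_types=("only",))


class TestApplyModification:
    def test_zero_fold_change_is_identity(self):
        lib, _ = generate_library(tiny_config())
        modified, cells = apply_modification(lib, "t0", 0.5, ["gene_0001"], 0.0, seed=1)
        np.testing.assert_array_equal(modified.values, lib.values)
        assert len(cells) == 5

    def test_fold_factor_arithmetic(self):
        lib, _ = generate_library(tiny_config())
        modified, cells = apply_modification(lib, "t0", 0.1, ["gene_0002"], 2.0, seed=1)
        assert len(cells) == 1
        col = list(lib.cell_ids).index(cells[0])
        row = list(lib.gene_ids).index("gene_0002")
        assert modified.values[row, col] == pytest.approx(4.0 * lib.values[row, col])

    def test_touches_exactly_the_selected_entries(self):
        lib, _ = generate_library(tiny_config(dispersion=0.5))
        genes = ["gene_0003", "gene_0010", "gene_0030"]
        modified, cells = apply_modification(lib, "t1", 0.5, genes, 1.0, seed=2)
        changed = np.argwhere(modified.values != lib.values)
        gene_rows = {list(lib.gene_ids).index(g) for g in genes}
        cell_cols = {list(lib.cell_ids).index(c) for c in cells}
        assert {r for r, _ in changed} <= gene_rows
        assert {c for _, c in changed} <= cell_cols
        # every targeted entry with nonzero expression changed
        for r in gene_rows:
            for c in cell_cols:
                if lib.values[r, c] > 0:
                    assert modified.values[r, c] != lib.values[r, c]

    def test_mean_ratio_matches_fold_change(self, small_library):
        _, lib, _ = small_library
        rng = np.random.default_rng(4)
        genes = sorted(rng.choice(lib.gene_ids, size=10, replace=False))
        modified, cells = apply_modification(lib, "alpha", 0.5, genes, 1.5, seed=4)
        rows = lib.gene_index(genes)
        mod_cols = [list(lib.cell_ids).index(c) for c in cells]
        unmod_cols = [
            i for i, (l, c) in enumerate(zip(lib.labels, lib.cell_ids))
            if l == "alpha" and c not in set(cells)
        ]
        ratio = modified.values[np.ix_(rows, mod_cols)].mean() / (
            lib.values[np.ix_(rows, unmod_cols)].mean()
        )
        assert np.log2(ratio) == pytest.approx(1.5, abs=0.3)

    def test_empty_target_fraction_errors(self):
        lib, _ = generate_library(tiny_config())
        with pytest.raises(ValueError, match="rounds to zero"):
            apply_modification(lib, "t0", 0.01, ["gene_0001"], 1.0, seed=0)


class TestBuildPseudobulks:
    def test_single_cell_bulks_equal_cell_profiles(self):
        config = tiny_config(n_bulks=4, cells_per_bulk=1)
        lib, _ = generate_library(config)
        bulks, truth = build_pseudobulks(lib, lib, config)
        for s in range(bulks.n_samples):
            diffs = np.abs(lib.values - bulks.values[:, [s]]).sum(axis=0)
            assert diffs.min() == pytest.approx(0.0)
        assert sum(c == "I" for c in truth.class_assignment.values()) == 2

    def test_constant_pool_gives_scaled_profile(self):
        config = tiny_config(n_bulks=2, cells_per_bulk=3)
        lib, _ = generate_library(
            tiny_config(dispersion=0.0, library_size_sd=0.0, donor_effect_sd=0.0,
                        substate_effect_sd=0.0, n_substates=1,
                        cell_types=("t0", "t1"))
        )
        t0 = lib.subset_cells(np.flatnonzero(np.asarray(lib.labels) == "t0"))
        bulks, _ = build_pseudobulks(t0, t0, config)
        np.testing.assert_allclose(bulks.values[:, 0], 3 * t0.values[:, 0], rtol=1e-12)

    def test_column_sums_match_draw_size(self, small_library):
        _, lib, _ = small_library
        config = SimulationConfig(
            n_genes=80, cell_types=("alpha", "beta", "gamma"), cells_per_type=100,
            n_donors=4, seed=11, n_bulks=10, cells_per_bulk=50,
        )
        bulks, _ = build_pseudobulks(lib, lib, config, np.random.default_rng(0))
        cell_sums = lib.values.sum(axis=0)
        expected = 50 * cell_sums.mean()
        sd = 50 ** 0.5 * cell_sums.std()
        # CPM scaling makes cell totals (near-)constant, so allow float slack
        assert np.all(
            np.abs(bulks.values.sum(axis=0) - expected) <= 3 * sd + 1e-6 * expected
        )

    def test_oversized_draw_errors(self):
        config = tiny_config(n_bulks=2, cells_per_bulk=100)
        lib, _ = generate_library(tiny_config())
        with pytest.raises(ValueError, match="exceeds"):
            build_pseudobulks(lib, lib, config)


class TestDonorSplit:
    def test_partition_is_disjoint_and_complete(self, small_library):
        _, lib, _ = small_library
        first, second = split_by_donor(lib, ["donor_0", "donor_1"])
        assert first.n_cells + second.n_cells == lib.n_cells
        assert not set(first.cell_ids) & set(second.cell_ids)
        assert set(first.donor_ids) == {"donor_0", "donor_1"}
        assert not set(second.donor_ids) & {"donor_0", "donor_1"}

    def test_degenerate_split_errors(self, small_library):
        _, lib, _ = small_library
        with pytest.raises(ValueError, match="both sides"):
            split_by_donor(lib, ["donor_0", "donor_1", "donor_2", "donor_3"])


class TestBenchmarkWiring:
    def test_class_two_bulks_contain_no_modified_cell(self, small_library):
        config, lib, _ = small_library
        rng = np.random.default_rng(1)
        genes = sorted(rng.choice(lib.gene_ids, size=5, replace=False))
        modified, cells = apply_modification(lib, "beta", 0.5, genes, 2.0, rng)
        cfg = SimulationConfig(
            n_genes=80, cell_types=("alpha", "beta", "gamma"), cells_per_type=100,
            n_donors=4, seed=11, n_bulks=6, cells_per_bulk=20,
        )
        bulks, truth = build_pseudobulks(
            modified, lib, cfg, rng, modified_gene_ids=genes, modified_cell_ids=cells
        )
        # class II columns are reproducible from the unmodified pool alone:
        # every class II bulk must be expressible without touching modified values
        assert set(truth.class_assignment.values()) == {"I", "II"}
        n_I = sum(v == "I" for v in truth.class_assignment.values())
        assert n_I == 3

    def test_substate_enrichment_shows_in_weight_ratios(self):
        """Bulks built from one sub-state only pull that sub-state's cells."""
        config = SimulationConfig(
            n_genes=60, cell_types=("t0", "t1"), cells_per_type=80, n_donors=2,
            seed=21, n_substates=2, substate_effect_sd=0.8, dispersion=0.5,
        )
        lib, model = generate_library(config)
        states = model.cell_substates
        m_s0 = lib.values[:, states == "t0/state_0"].mean(axis=1)
        m_s1 = lib.values[:, states == "t0/state_1"].mean(axis=1)
        m_t1 = lib.values[:, np.asarray(lib.labels) == "t1"].mean(axis=1)
        bulk_values = np.column_stack(
            [0.5 * m_s0 + 0.5 * m_t1] * 3 + [0.5 * m_s1 + 0.5 * m_t1] * 3
        )
        bulk = ExpressionMatrix(bulk_values, lib.gene_ids, [f"s{i}" for i in range(6)])
        relabeled = type(lib)(
            lib.values, lib.gene_ids, lib.cell_ids, labels=states, donor_ids=lib.donor_ids
        )
        bulk_h, lib_h = harmonize(bulk, relabeled)
        fit = bootstrap_fit(bulk_h, lib_h, BootstrapConfig(n_runs=6, cell_fraction=0.5, seed=2))
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        _, labels = mean_cell_weights(fit, groups)
        table = labels.set_index("label")["ratio"]
        assert table["t0/state_0"] > 1.0
        assert table["t0/state_1"] < 1.0
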