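"""Readers, writers and gene pre-filtering.

All matrices live on disk as plain text: dense TSV for bulk matrices
(genes x samples, first column gene ids), Matrix-Market plus two
metadata tables for sparse single-cell libraries, long-format TSV for
fitted weights, and JSON sidecars for configuration and provenance.
Validation is eager: duplicate identifiers, negative values and ragged
rows abort with the offending location before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ExpressionMatrix, SingleCellLibrary
from .fit import BootstrapConfig, BootstrapRun, FitResult

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_library_tsv",
    "read_library_mtx",
    "write_library_mtx",
    "write_fit",
    "read_fit",
    "select_variable_genes",
    "file_checksum",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from None
    dup = df.index[df.index.duplicated()]
    if len(dup):
        line = int(np.flatnonzero(df.index == dup[0])[1]) + 2  # +1 header, +1 one-based
        raise ValueError(f"{path}: duplicate row id {dup[0]!r} (line {line})")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric column(s) {non_numeric[:3]}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing value in row {gene!r}")
    neg = df.lt(0).any(axis=1)
    if neg.any():
        gene = df.index[neg][0]
        line = int(np.flatnonzero(neg)[0]) + 2
        raise ValueError(f"{path}: negative value in row {gene!r} (line {line})")
    return df


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a dense genes x samples TSV (header = sample ids, col 1 = gene ids)."""
    return ExpressionMatrix.from_frame(_read_table(path))


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def _attach_metadata(
    values: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    cells_path: str | Path | None,
) -> SingleCellLibrary:
    labels = donors = None
    if cells_path is not None:
        meta = pd.read_csv(cells_path, sep="\t", dtype=str)
        if "cell_id" not in meta.columns:
            raise ValueError(f"{cells_path}: missing required column 'cell_id'")
        meta = meta.set_index("cell_id")
        missing = [c for c in cell_ids if c not in meta.index]
        if missing:
            raise ValueError(f"{cells_path}: no metadata for cell(s) {missing[:5]}")
        meta = meta.loc[list(cell_ids)]
        if "label" in meta.columns:
            labels = meta["label"].to_numpy(dtype=object)
        if "donor_id" in meta.columns:
            donors = meta["donor_id"].to_numpy(dtype=object)
    return SingleCellLibrary(values, gene_ids, cell_ids, labels=labels, donor_ids=donors)


def read_library_tsv(path: str | Path, cells_path: str | Path | None = None) -> SingleCellLibrary:
    """Read a dense genes x cells TSV, optionally with a cell metadata table."""
    df = _read_table(path)
    return _attach_metadata(df.to_numpy(dtype=float), df.index, df.columns, cells_path)


def read_library_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> SingleCellLibrary:
    """Read a sparse library: Matrix-Market genes x cells + genes.tsv + cells.tsv.

    ``genes.tsv`` is a headerless single-column list of gene ids;
    ``cells.tsv`` has a header with ``cell_id`` and optional ``label``
    and ``donor_id`` columns.  Explicit zeros in the MTX are
    canonicalized away.
    """
    matrix = scipy.io.mmread(str(mtx_path))
    dense = np.asarray(scipy.sparse.csc_matrix(matrix).todense(), dtype=float)
    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)[0].tolist()
    meta = pd.read_csv(cells_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValueError(f"{cells_path}: missing required column 'cell_id'")
    if dense.shape != (len(genes), len(meta)):
        raise ValueError(
            f"{mtx_path}: shape {dense.shape} does not match {len(genes)} genes x {len(meta)} cells"
        )
    return _attach_metadata(dense, genes, meta["cell_id"].tolist(), cells_path)


def write_library_mtx(
    library: SingleCellLibrary,
    mtx_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csc_matrix(library.values))
    pd.Series(library.gene_ids).to_csv(genes_path, sep="\t", header=False, index=False)
    library.cell_metadata().to_csv(cells_path, sep="\t", index=False)


def write_fit(fit: FitResult, weights_path: str | Path, sidecar_path: str | Path) -> None:
    """Write weights as long-format TSV (run, cell_id, sample_id, weight > 0)
    plus a JSON sidecar holding the config, seed and per-run cell subsets."""
    rows = []
    for k, run in enumerate(fit.runs):
        cell_ids = fit.library.cell_ids[run.cell_indices]
        nz = np.argwhere(run.weights > 0)
        for i, s in nz:
            rows.append((k, cell_ids[i], fit.sample_ids[s], run.weights[i, s]))
    pd.DataFrame(rows, columns=["run", "cell_id", "sample_id", "weight"]).to_csv(
        weights_path, sep="\t", index=False, float_format="%.17g"
    )
    sidecar = {
        "config": dataclasses.asdict(fit.config),
        "sample_ids": list(fit.sample_ids),
        "subsets": [[str(c) for c in fit.library.cell_ids[r.cell_indices]] for r in fit.runs],
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_fit(
    weights_path: str | Path,
    sidecar_path: str | Path,
    library: SingleCellLibrary,
) -> FitResult:
    """Reconstruct a FitResult from its TSV/JSON pair and the library it used."""
    sidecar = json.loads(Path(sidecar_path).read_text())
    config = BootstrapConfig(**sidecar["config"])
    sample_ids = sidecar["sample_ids"]
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    cell_pos = {c: i for i, c in enumerate(library.cell_ids)}
    table = pd.read_csv(weights_path, sep="\t", float_precision="round_trip")

    runs = []
    for k, subset in enumerate(sidecar["subsets"]):
        try:
            idx = np.asarray([cell_pos[c] for c in subset], dtype=int)
        except KeyError as err:
            raise ValueError(f"fit references cell {err.args[0]!r} absent from the library") from None
        local = {c: i for i, c in enumerate(subset)}
        weights = np.zeros((len(subset), len(sample_ids)))
        chunk = table[table["run"] == k]
        for cell, sample, w in zip(chunk["cell_id"], chunk["sample_id"], chunk["weight"]):
            weights[local[cell], sample_pos[sample]] = w
        runs.append(BootstrapRun(cell_indices=idx, weights=weights))
    return FitResult(
        runs=runs,
        sample_ids=np.asarray(sample_ids, dtype=object),
        library=library,
        config=config,
    )


def select_variable_genes(
    bulk: ExpressionMatrix,
    library: SingleCellLibrary,
    n: int,
) -> list[str]:
    """Pick the genes most variable across *both* datasets.

    Per gene, the variance of log2(1+x) is computed separately across
    bulk samples and across library cells; genes are ranked in each
    dataset (rank 1 = most variable) and ordered by the better of their
    two ranks, ties broken by gene id.  The top ``n`` gene ids are
    returned in that order.
    """
    if list(bulk.gene_ids) != list(library.gene_ids):
        raise ValueError("gene sets must be harmonized before variable-gene selection")
    if n < 1:
        raise ValueError("n must be >= 1")
    genes = list(bulk.gene_ids)
    if n >= len(genes):
        if n > len(genes):
            warnings.warn(
                f"requested {n} variable genes but only {len(genes)} available; returning all",
                stacklevel=2,
            )
        return genes

    def _ranks(values: np.ndarray) -> np.ndarray:
        var = np.log2(1.0 + values).var(axis=1, ddof=1)
        order = sorted(range(len(genes)), key=lambda i: (-var[i], genes[i]))
        rank = np.empty(len(genes), dtype=int)
        rank[order] = np.arange(1, len(genes) + 1)
        return rank

    best = np.minimum(_ranks(bulk.values), _ranks(library.values))
    chosen = sorted(range(len(genes)), key=lambda i: (best[i], genes[i]))[:n]
    return [genes[i] for i in chosen]


def file_checksum(path: str | Path) -> str:
    """SHA-256 of a file, for run provenance logs."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()
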