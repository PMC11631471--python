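"""In-memory containers for bulk and single-cell expression matrices.

Both containers hold dense genes-by-columns matrices on a linear scale
(CPM/TPM-like units).  Validation is strict and happens at construction:
negative or non-finite entries and duplicate identifiers are rejected
before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SingleCellLibrary"]


def _as_id_array(ids: Iterable, name: str) -> np.ndarray:
    arr = np.asarray([str(x) for x in ids], dtype=object)
    if arr.size == 0:
        raise ValueError(f"{name}: at least one identifier required")
    seen: set = set()
    for i, x in enumerate(arr):
        if x in seen:
            raise ValueError(f"{name}: duplicate identifier {x!r} (position {i})")
        seen.add(x)
    return arr


def _check_values(values: np.ndarray, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{what}: expected a 2-D matrix, got ndim={values.ndim}")
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{what}: shape {values.shape} does not match identifiers "
            f"({n_rows} genes x {n_cols} columns)"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: non-finite entries are not allowed")
    if values.min(initial=0.0) < 0:
        g, c = np.argwhere(values < 0)[0]
        raise ValueError(f"{what}: negative entry at row {g}, column {c}")
    return values


@dataclass(frozen=True)
class ExpressionMatrix:
    """Non-negative genes x samples matrix with identifiers.

    Parameters
    ----------
    values
        Dense non-negative matrix of shape ``(n_genes, n_samples)`` in
        linear expression units.
    gene_ids, sample_ids
        Unique, ordered string identifiers for rows and columns.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _as_id_array(self.gene_ids, "gene_ids"))
        object.__setattr__(self, "sample_ids", _as_id_array(self.sample_ids, "sample_ids"))
        object.__setattr__(
            self,
            "values",
            _check_values(self.values, len(self.gene_ids), len(self.sample_ids), "bulk matrix"),
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a genes x samples DataFrame (index = gene ids)."""
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([lookup[g] for g in genes], dtype=int)
        except KeyError as err:
            raise KeyError(f"gene {err.args[0]!r} not present") from None

    def restrict_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes``, in the given order."""
        idx = self.gene_index(genes)
        return ExpressionMatrix(self.values[idx, :], np.asarray(list(genes), dtype=object), self.sample_ids)


@dataclass(frozen=True)
class SingleCellLibrary:
    """Non-negative genes x cells reference matrix with optional metadata.

    ``labels`` (cell-type / cluster / state annotation) and ``donor_ids``
    are optional per-cell vectors; when present they must have one entry
    per cell.  Missing annotations are represented as ``None`` entries.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray | None = None
    donor_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", _as_id_array(self.gene_ids, "gene_ids"))
        object.__setattr__(self, "cell_ids", _as_id_array(self.cell_ids, "cell_ids"))
        object.__setattr__(
            self,
            "values",
            _check_values(self.values, len(self.gene_ids), len(self.cell_ids), "single-cell library"),
        )
        for attr in ("labels", "donor_ids"):
            vec = getattr(self, attr)
            if vec is not None:
                vec = np.asarray(list(vec), dtype=object)
                if vec.shape != (self.n_cells,):
                    raise ValueError(f"{attr}: expected one entry per cell ({self.n_cells}), got {vec.shape}")
                object.__setattr__(self, attr, vec)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def cell_metadata(self) -> pd.DataFrame:
        meta = pd.DataFrame({"cell_id": self.cell_ids})
        if self.labels is not None:
            meta["label"] = self.labels
        if self.donor_ids is not None:
            meta["donor_id"] = self.donor_ids
        return meta

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.asarray([lookup[g] for g in genes], dtype=int)
        except KeyError as err:
            raise KeyError(f"gene {err.args[0]!r} not present") from None

    def restrict_genes(self, genes: Sequence[str]) -> "SingleCellLibrary":
        idx = self.gene_index(genes)
        return replace(
            self,
            values=self.values[idx, :],
            gene_ids=np.asarray(list(genes), dtype=object),
        )

    def subset_cells(self, indices: Sequence[int]) -> "SingleCellLibrary":
        """Return a copy containing only the cells at ``indices`` (in order)."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=self.cell_ids[idx],
            labels=None if self.labels is None else self.labels[idx],
            donor_ids=None if self.donor_ids is None else self.donor_ids[idx],
        )
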