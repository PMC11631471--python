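"""Sparse non-negative reconstruction of bulk profiles from a single-cell library.

Every bulk sample ``y`` is approximated as ``X @ beta`` with ``beta >= 0``,
where the columns of ``X`` are individual single-cell profiles.  The
non-negativity constraint alone yields a sparse weight vector: only cells
that genuinely contribute expression mass to the bulk receive non-zero
weight, so the fitted sample can be read as a "virtual tissue" — a small,
weighted selection of library cells.

To stabilise the selection, the fit is repeated over random subsamples of
the library (by default 10% of the cells per run); downstream quantities
(cell-type frequencies, per-type expression, residual diagnostics) are
averaged across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .containers import ExpressionMatrix, SingleCellLibrary

__all__ = [
    "BootstrapConfig",
    "BootstrapRun",
    "FitResult",
    "harmonize",
    "fit_weights_single",
    "bootstrap_fit",
]

logger = logging.getLogger(__name__)

#: convergence tolerance on the projected gradient of the (rescaled) objective
DEFAULT_GTOL = 1e-9
#: iteration cap for the box-constrained quasi-Newton solver
DEFAULT_MAXITER = 15_000
#: weights below this fraction of the per-sample maximum are zeroed
DEFAULT_ZERO_THRESHOLD = 1e-8


@dataclass(frozen=True)
class BootstrapConfig:
    """Configuration of the subsampling scheme.

    ``n_runs`` independent fits are performed, each against a uniformly
    random subset of ``round(cell_fraction * n_cells)`` cells drawn
    without replacement.  ``zero_threshold`` is relative to the largest
    weight of each fitted sample and defines the support of the virtual
    tissue (which cells count as "selected").
    """

    n_runs: int = 50
    cell_fraction: float = 0.10
    seed: int = 0
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not (0.0 < self.cell_fraction <= 1.0):
            raise ValueError("cell_fraction must lie in (0, 1]")
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be non-negative")


@dataclass(frozen=True)
class BootstrapRun:
    """One subsample fit: the drawn cell indices and their weight matrix."""

    cell_indices: np.ndarray  # indices into the library, shape (m,)
    weights: np.ndarray  # shape (m, n_samples), non-negative

    @property
    def n_cells(self) -> int:
        return len(self.cell_indices)


@dataclass(frozen=True)
class FitResult:
    """Weights of all bootstrap runs plus the inputs needed to interpret them."""

    runs: list[BootstrapRun]
    sample_ids: np.ndarray
    library: SingleCellLibrary
    config: BootstrapConfig

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.library.gene_ids


def harmonize(
    bulk: ExpressionMatrix,
    library: SingleCellLibrary,
    *,
    rescale: bool = True,
    target_sum: float = 1e6,
    drop_zero_cells: bool = True,
) -> tuple[ExpressionMatrix, SingleCellLibrary]:
    """Restrict bulk and library to their shared genes and align row order.

    The shared genes are ordered lexicographically so that the output is
    independent of the input row order.  With ``rescale`` (default), every
    column of both matrices is scaled to sum to ``target_sum``, putting
    bulks and cells on a common CPM-like scale; columns with zero total
    are left untouched.  Library cells that are all-zero on the shared
    gene set are dropped with a warning rather than fitted.
    """
    shared = sorted(set(bulk.gene_ids) & set(library.gene_ids))
    if not shared:
        raise ValueError(
            "no shared genes between bulk and library "
            f"({bulk.n_genes} bulk gene ids vs {library.n_genes} library gene ids)"
        )
    bulk_h = bulk.restrict_genes(shared)
    lib_h = library.restrict_genes(shared)

    if rescale:
        bulk_h = ExpressionMatrix(
            _rescale_columns(bulk_h.values, target_sum), bulk_h.gene_ids, bulk_h.sample_ids
        )
        lib_values = _rescale_columns(lib_h.values, target_sum)
    else:
        lib_values = lib_h.values

    keep = np.flatnonzero(lib_values.sum(axis=0) > 0)
    if drop_zero_cells and len(keep) < lib_h.n_cells:
        dropped = lib_h.n_cells - len(keep)
        warnings.warn(
            f"dropping {dropped} library cell(s) with zero expression on the shared gene set",
            stacklevel=2,
        )
        lib_h = SingleCellLibrary(
            lib_values[:, keep],
            lib_h.gene_ids,
            lib_h.cell_ids[keep],
            None if lib_h.labels is None else lib_h.labels[keep],
            None if lib_h.donor_ids is None else lib_h.donor_ids[keep],
        )
    else:
        lib_h = SingleCellLibrary(
            lib_values, lib_h.gene_ids, lib_h.cell_ids, lib_h.labels, lib_h.donor_ids
        )
    return bulk_h, lib_h


def _rescale_columns(values: np.ndarray, target_sum: float) -> np.ndarray:
    totals = values.sum(axis=0)
    scale = np.where(totals > 0, target_sum / np.where(totals > 0, totals, 1.0), 1.0)
    return values * scale[np.newaxis, :]


def _solve_nnls(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, _ = scipy.optimize.nnls(X, y)
    return beta


def _solve_lbfgsb(
    y: np.ndarray,
    X: np.ndarray,
    gram: np.ndarray | None,
    gtol: float,
    maxiter: int,
) -> np.ndarray:
    # Work on the Gram form: 0.5 b'Gb - h'b + 0.5 y'y, rescaled so the
    # projected-gradient tolerance is meaningful regardless of data units.
    scale = max(float(X.max(initial=0.0)), float(y.max(initial=0.0)))
    if scale <= 0:
        return np.zeros(X.shape[1])
    G = (X.T @ X) if gram is None else gram
    s2 = scale * scale
    Gs = G / s2
    hs = (X.T @ y) / s2
    const = 0.5 * float(y @ y) / s2

    def objective(b: np.ndarray) -> tuple[float, np.ndarray]:
        Gb = Gs @ b
        return 0.5 * float(b @ Gb) - float(hs @ b) + const, Gb - hs

    res = scipy.optimize.minimize(
        objective,
        x0=np.zeros(X.shape[1]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * X.shape[1],
        options={"gtol": gtol, "ftol": 1e-15, "maxiter": maxiter, "maxfun": 10 * maxiter},
    )
    return np.maximum(res.x, 0.0)


def fit_weights_single(
    y: np.ndarray,
    X: np.ndarray,
    *,
    solver: str = "lbfgsb",
    gtol: float = DEFAULT_GTOL,
    maxiter: int = DEFAULT_MAXITER,
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD,
    gram: np.ndarray | None = None,
) -> np.ndarray:
    """Solve ``min ||y - X beta||`` subject to ``beta >= 0`` for one sample.

    Parameters
    ----------
    y
        Non-negative bulk profile, length ``n_genes``.
    X
        Non-negative library matrix, shape ``(n_genes, n_cells)``.
    solver
        ``"lbfgsb"`` (box-constrained quasi-Newton, default) or ``"nnls"``
        (exact Lawson–Hanson active set).
    gram
        Optional precomputed ``X.T @ X`` (reused across samples fitted
        against the same sub-library).

    Returns
    -------
    numpy.ndarray
        Non-negative weights, with entries below
        ``zero_threshold * max(beta)`` set to exact zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"dimension mismatch: y has {y.shape}, X has {X.shape}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X))):
        raise ValueError("non-finite entries in fit inputs")
    if y.min(initial=0.0) < 0 or X.min(initial=0.0) < 0:
        raise ValueError("negative entries in fit inputs")
    if not np.any(X.sum(axis=0) > 0):
        raise ValueError("degenerate library: all cells have zero expression")

    if solver == "lbfgsb":
        beta = _solve_lbfgsb(y, X, gram, gtol, maxiter)
    elif solver == "nnls":
        beta = _solve_nnls(y, X)
    else:
        raise ValueError(f"unknown solver {solver!r}; choose 'lbfgsb' or 'nnls'")

    peak = beta.max(initial=0.0)
    if peak > 0:
        beta[beta < zero_threshold * peak] = 0.0
    return beta


def bootstrap_fit(
    bulk: ExpressionMatrix,
    library: SingleCellLibrary,
    config: BootstrapConfig | None = None,
    *,
    solver: str = "lbfgsb",
) -> FitResult:
    """Fit every bulk sample against ``n_runs`` random library subsamples.

    Inputs must already be harmonized (identical gene ids in identical
    order; see :func:`harmonize`).  Each run draws
    ``round(cell_fraction * n_cells)`` cells uniformly without
    replacement and fits all samples against that sub-library.  The whole
    procedure is deterministic given ``config.seed``.
    """
    config = config or BootstrapConfig()
    if list(bulk.gene_ids) != list(library.gene_ids):
        raise ValueError("bulk and library gene ids differ; call harmonize() first")
    n_cells = library.n_cells
    m = int(round(config.cell_fraction * n_cells))
    if m < 1:
        raise ValueError(
            f"cell_fraction {config.cell_fraction} of {n_cells} cells rounds to an empty subset"
        )

    rng = np.random.default_rng(config.seed)
    runs: list[BootstrapRun] = []
    for k in range(config.n_runs):
        idx = np.sort(rng.choice(n_cells, size=m, replace=False))
        Xk = library.values[:, idx]
        gram = Xk.T @ Xk
        weights = np.empty((m, bulk.n_samples))
        for s in range(bulk.n_samples):
            try:
                weights[:, s] = fit_weights_single(
                    bulk.values[:, s],
                    Xk,
                    solver=solver,
                    zero_threshold=config.zero_threshold,
                    gram=gram if solver == "lbfgsb" else None,
                )
            except Exception as err:
                raise RuntimeError(
                    f"fit failed in bootstrap run {k} for sample {bulk.sample_ids[s]!r}: {err}"
                ) from err
        runs.append(BootstrapRun(cell_indices=idx, weights=weights))
        logger.debug("bootstrap run %d/%d: %d cells", k + 1, config.n_runs, m)

    return FitResult(runs=runs, sample_ids=bulk.sample_ids, library=library, config=config)


def explained_expression(fit: FitResult, run: int) -> np.ndarray:
    """Reconstructed bulk ``X^(k) @ beta^(k)`` for one run (genes x samples)."""
    r = fit.runs[run]
    return fit.library.values[:, r.cell_indices] @ r.weights
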