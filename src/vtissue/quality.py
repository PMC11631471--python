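"""Fit-quality diagnostics for virtual tissues.

A bounded relative residual is computed for every gene, sample and
bootstrap run:

    r = |Y - Yhat| / (Y + Yhat)   in [0, 1],

with the convention r = 0 when Y = Yhat = 0 (a gene silent in both bulk
and reconstruction is perfectly fitted).  Averaging the tensor along
different axes yields a per-gene score g (how well a gene is
reconstructed across all tissues), a per-sample score b (how well one
virtual tissue explains its bulk), and a per-gene mean bootstrap
variance v (how sensitive a gene's fit is to the cell subsample).  Genes
poorly covered by the library — e.g. because a cell identity is missing
— show large g and are excluded before downstream interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .fit import FitResult, explained_expression

__all__ = [
    "QualityReport",
    "relative_residuals",
    "gene_score",
    "tissue_score",
    "gene_variance",
    "quality_report",
    "apply_quality_filter",
    "write_residuals_hdf5",
]

logger = logging.getLogger(__name__)

DEFAULT_GENE_SCORE_MAX = 0.5
DEFAULT_TISSUE_SCORE_MAX = 0.5
#: default variance cutoff is this multiple of the mean gene variance
DEFAULT_VARIANCE_FOLD = 10.0


@dataclass(frozen=True)
class QualityReport:
    """Residual tensor and derived quality scores."""

    residuals: np.ndarray  # genes x samples x runs, each in [0, 1]
    gene_score: np.ndarray  # per gene, mean residual over samples and runs
    tissue_score: np.ndarray  # per sample, mean residual over genes and runs
    gene_variance: np.ndarray | None  # per gene, mean across-sample bootstrap variance
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def gene_table(self) -> pd.DataFrame:
        table = pd.DataFrame({"gene": self.gene_ids, "g": self.gene_score})
        if self.gene_variance is not None:
            table["v"] = self.gene_variance
        return table

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame({"sample": self.sample_ids, "b": self.tissue_score})


def relative_residuals(bulk: ExpressionMatrix, fit: FitResult) -> np.ndarray:
    """Residual tensor of shape (genes, samples, runs)."""
    if list(bulk.gene_ids) != list(fit.gene_ids):
        raise ValueError("bulk gene ids do not match the fitted library")
    if list(bulk.sample_ids) != list(fit.sample_ids):
        raise ValueError("bulk sample ids do not match the fit result")
    Y = bulk.values
    out = np.empty((bulk.n_genes, bulk.n_samples, fit.n_runs))
    for k in range(fit.n_runs):
        Yhat = explained_expression(fit, k)
        denom = Y + Yhat
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.abs(Y - Yhat) / denom
        out[:, :, k] = np.where(denom > 0, r, 0.0)
    return out


def gene_score(residuals: np.ndarray) -> np.ndarray:
    """Per-gene mean residual over samples and runs."""
    return np.asarray(residuals).mean(axis=(1, 2))


def tissue_score(residuals: np.ndarray) -> np.ndarray:
    """Per-sample mean residual over genes and runs."""
    return np.asarray(residuals).mean(axis=(0, 2))


def gene_variance(residuals: np.ndarray) -> np.ndarray:
    """Per-gene mean (over samples) of the across-run residual variance.

    Uses the (n-1) denominator across runs; requires at least two runs.
    """
    residuals = np.asarray(residuals)
    if residuals.shape[2] < 2:
        raise ValueError("variance undefined: at least two bootstrap runs required")
    return residuals.var(axis=2, ddof=1).mean(axis=1)


def quality_report(bulk: ExpressionMatrix, fit: FitResult) -> QualityReport:
    """Compute the residual tensor and all derived scores in one pass."""
    res = relative_residuals(bulk, fit)
    return QualityReport(
        residuals=res,
        gene_score=gene_score(res),
        tissue_score=tissue_score(res),
        gene_variance=gene_variance(res) if res.shape[2] >= 2 else None,
        gene_ids=bulk.gene_ids,
        sample_ids=bulk.sample_ids,
    )


def apply_quality_filter(
    report: QualityReport,
    gene_score_max: float = DEFAULT_GENE_SCORE_MAX,
    variance_max: float | None = None,
    tissue_score_max: float = DEFAULT_TISSUE_SCORE_MAX,
) -> tuple[list[str], list[str]]:
    """Select genes and samples passing the quality thresholds.

    Genes are kept iff ``g <= gene_score_max`` and ``v <= variance_max``;
    samples iff ``b <= tissue_score_max``.  ``variance_max=None`` uses
    ``10 x mean(v)`` (flagging genes whose bootstrap variance is very
    large relative to its mean); when the variance is unavailable
    (single run) only the gene score applies.
    """
    keep_genes = report.gene_score <= gene_score_max
    if report.gene_variance is not None:
        if variance_max is None:
            variance_max = DEFAULT_VARIANCE_FOLD * float(report.gene_variance.mean())
        keep_genes &= report.gene_variance <= variance_max
    keep_samples = report.tissue_score <= tissue_score_max

    genes = [g for g, k in zip(report.gene_ids, keep_genes) if k]
    samples = [s for s, k in zip(report.sample_ids, keep_samples) if k]
    logger.info(
        "quality filter: kept %d/%d genes, %d/%d samples",
        len(genes), len(report.gene_ids), len(samples), len(report.sample_ids),
    )
    if not genes:
        raise ValueError(
            "quality filter removed every gene; revise gene_score_max/variance_max thresholds"
        )
    return genes, samples


def write_residuals_hdf5(report: QualityReport, path) -> None:
    """Optionally persist the full residual tensor (requires h5py)."""
    import h5py

    with h5py.File(path, "w") as handle:
        handle.create_dataset("residuals", data=report.residuals, compression="gzip")
        handle.create_dataset("gene_ids", data=np.asarray(report.gene_ids, dtype="S"))
        handle.create_dataset("sample_ids", data=np.asarray(report.sample_ids, dtype="S"))

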