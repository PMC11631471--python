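"""Cell-type frequencies and cell-type-specific expression from fitted weights.

Given a labeling of the library cells (cell type, cluster, activation
state, ...), each fitted sample decomposes into per-label quantities:

* the effective frequency of label ``a`` in sample ``s`` is the share of
  the sample's total fitted weight carried by cells with that label,
  ``c_s^a = sum_{i: l_i = a} beta_{i,s} / sum_i beta_{i,s}``;
* the label-specific expression is the portion of the reconstructed bulk
  contributed by those cells, ``Ytilde^a_{.,s} = sum_{i: l_i = a} X_{.,i} beta_{i,s}``.

Summing label-specific expression over all labels recovers the full
reconstruction ``X beta``.  All quantities are computed per bootstrap run
and then averaged across runs; the labeling can be swapped at any time
without refitting (the weights do not depend on labels).

Effective frequencies are comparable across samples for the *same* label
only — cell types differ in total mRNA content, so comparing different
labels within one sample is not meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SingleCellLibrary
from .fit import FitResult

__all__ = [
    "CellTypeDecomposition",
    "effective_frequencies",
    "per_run_frequencies",
    "summarize_frequencies",
    "cell_type_expression",
    "decompose",
    "relabel",
    "mean_cell_weights",
]


@dataclass(frozen=True)
class CellTypeDecomposition:
    """Bootstrap-averaged per-label view of a set of virtual tissues."""

    frequencies: pd.DataFrame  # labels x samples, bootstrap mean
    frequency_sd: pd.DataFrame  # labels x samples, bootstrap sd (ddof=1)
    per_label_expression: dict[str, pd.DataFrame]  # label -> genes x samples
    total_explained: pd.DataFrame  # genes x samples, bootstrap mean of X beta

    @property
    def labels(self) -> list[str]:
        return list(self.frequencies.index)


def _resolve_labels(fit_or_library, labels) -> np.ndarray:
    library = fit_or_library.library if isinstance(fit_or_library, FitResult) else fit_or_library
    if labels is None:
        labels = library.labels
        if labels is None:
            raise ValueError("no labels supplied and the library carries none")
    labels = np.asarray(list(labels), dtype=object)
    if labels.shape != (library.n_cells,):
        raise ValueError(
            f"labels must have one entry per cell ({library.n_cells}), got {labels.shape}"
        )
    return labels


def _check_labeled(labels_subset: np.ndarray, cell_ids_subset: np.ndarray) -> None:
    missing = [
        cid
        for lab, cid in zip(labels_subset, cell_ids_subset)
        if lab is None or (isinstance(lab, float) and np.isnan(lab))
    ]
    if missing:
        raise ValueError(f"unlabeled cell(s) in fitted subset: {missing[:5]}")


def effective_frequencies(
    weights: np.ndarray,
    labels: Sequence,
    label_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-label weight shares for one run's weight matrix.

    ``weights`` has shape (cells, samples); ``labels`` one label per row.
    Samples whose total weight is zero get NaN frequencies (flagged
    missing rather than reported as zeros).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim == 1:
        weights = weights[:, np.newaxis]
    labels = np.asarray(list(labels), dtype=object)
    if labels.shape[0] != weights.shape[0]:
        raise ValueError("one label per weight row required")
    _check_labeled(labels, labels)
    order = list(label_order) if label_order is not None else sorted(set(labels))
    totals = weights.sum(axis=0)
    freq = np.full((len(order), weights.shape[1]), np.nan)
    ok = totals > 0
    for j, lab in enumerate(order):
        mask = labels == lab
        if ok.any():
            freq[j, ok] = weights[mask, :].sum(axis=0)[ok] / totals[ok]
        if not mask.any():
            freq[j, ok] = 0.0
    return pd.DataFrame(freq, index=order)


def per_run_frequencies(
    fit: FitResult,
    labels: Sequence | None = None,
    label_order: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Frequency tensor of shape (runs, labels, samples).

    Labels absent from a run's subset contribute frequency 0 for that
    run; samples with zero total weight are NaN.
    """
    labels = _resolve_labels(fit, labels)
    order = list(label_order) if label_order is not None else sorted(set(labels))
    tensor = np.full((fit.n_runs, len(order), fit.n_samples), np.nan)
    for k, run in enumerate(fit.runs):
        sub_labels = labels[run.cell_indices]
        _check_labeled(sub_labels, fit.library.cell_ids[run.cell_indices])
        frame = effective_frequencies(run.weights, sub_labels, label_order=order)
        tensor[k] = frame.to_numpy()
    return tensor, order


def summarize_frequencies(
    fit: FitResult,
    labels: Sequence | None = None,
    label_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrap mean and standard deviation of the per-run frequencies.

    The standard deviation uses the (n-1) denominator over the runs in
    which the sample had positive total weight; with a single run the sd
    is reported as 0 with a warning.
    """
    tensor, order = per_run_frequencies(fit, labels, label_order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean = np.nanmean(tensor, axis=0)
        counts = np.sum(~np.isnan(tensor), axis=0)
        sd = np.where(counts >= 2, np.nanstd(tensor, axis=0, ddof=1), 0.0)
        sd = np.where(counts == 0, np.nan, sd)
    if fit.n_runs == 1:
        warnings.warn("single bootstrap run: standard deviations reported as 0", stacklevel=2)
    cols = list(fit.sample_ids)
    return (
        pd.DataFrame(mean, index=order, columns=cols),
        pd.DataFrame(sd, index=order, columns=cols),
    )


def cell_type_expression(
    X_subset: np.ndarray,
    weights: np.ndarray,
    labels: Sequence,
    label_order: Sequence[str] | None = None,
) -> dict[str, np.ndarray]:
    """Per-label explained expression for one run: label -> genes x samples."""
    X_subset = np.asarray(X_subset, dtype=float)
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    if X_subset.shape[1] != weights.shape[0] or labels.shape[0] != weights.shape[0]:
        raise ValueError("cells axis of X_subset, weights and labels must agree")
    _check_labeled(labels, labels)
    order = list(label_order) if label_order is not None else sorted(set(labels))
    out: dict[str, np.ndarray] = {}
    for lab in order:
        mask = labels == lab
        out[lab] = X_subset[:, mask] @ weights[mask, :]
    return out


def decompose(
    fit: FitResult,
    labels: Sequence | None = None,
    label_order: Sequence[str] | None = None,
) -> CellTypeDecomposition:
    """Full bootstrap-averaged decomposition under a labeling.

    Per-run frequencies and per-label expression are computed run by run
    and averaged; labels missing from a run's subset contribute zeros to
    that run's per-label expression.
    """
    labels = _resolve_labels(fit, labels)
    order = list(label_order) if label_order is not None else sorted(set(labels))
    freq_mean, freq_sd = summarize_frequencies(fit, labels, order)

    n_genes, n_samples = fit.library.n_genes, fit.n_samples
    expr_sum = {lab: np.zeros((n_genes, n_samples)) for lab in order}
    total_sum = np.zeros((n_genes, n_samples))
    for run in fit.runs:
        sub_labels = labels[run.cell_indices]
        per_run = cell_type_expression(
            fit.library.values[:, run.cell_indices], run.weights, sub_labels, order
        )
        for lab in order:
            expr_sum[lab] += per_run[lab]
            total_sum += per_run[lab]

    genes, cols = list(fit.gene_ids), list(fit.sample_ids)
    k = fit.n_runs
    return CellTypeDecomposition(
        frequencies=freq_mean,
        frequency_sd=freq_sd,
        per_label_expression={
            lab: pd.DataFrame(expr_sum[lab] / k, index=genes, columns=cols) for lab in order
        },
        total_explained=pd.DataFrame(total_sum / k, index=genes, columns=cols),
    )


def relabel(fit: FitResult, new_labels: Sequence) -> CellTypeDecomposition:
    """Re-analyze the same virtual tissues under a different labeling (no refit)."""
    return decompose(fit, new_labels)


def mean_cell_weights(
    fit: FitResult,
    sample_groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-wise mean weight per cell and group ratio per cell and label.

    ``sample_groups`` maps every fitted sample id to one of exactly two
    group names.  For each cell, the weight is averaged over the samples
    of each group within each run that drew the cell, then over those
    runs; cells never drawn are reported as missing (NaN).  The per-label
    table aggregates the per-cell group means and their ratio
    (first group / second group, groups in sorted name order).
    """
    groups = sorted(set(sample_groups.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two sample groups required, got {groups}")
    sample_ids = list(fit.sample_ids)
    missing = [s for s in sample_ids if s not in sample_groups]
    if missing:
        raise ValueError(f"samples without group assignment: {missing[:5]}")
    masks = {g: np.asarray([sample_groups[s] == g for s in sample_ids]) for g in groups}
    for g in groups:
        if not masks[g].any():
            raise ValueError(f"group {g!r} has zero samples")

    n_cells = fit.library.n_cells
    sums = {g: np.zeros(n_cells) for g in groups}
    counts = np.zeros(n_cells)
    for run in fit.runs:
        for g in groups:
            sums[g][run.cell_indices] += run.weights[:, masks[g]].mean(axis=1)
        counts[run.cell_indices] += 1

    drawn = counts > 0
    cells = pd.DataFrame({"cell_id": fit.library.cell_ids})
    if fit.library.labels is not None:
        cells["label"] = fit.library.labels
    for g in groups:
        cells[f"mean_weight_{g}"] = np.where(drawn, sums[g] / np.maximum(counts, 1), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["ratio"] = cells[f"mean_weight_{groups[0]}"] / cells[f"mean_weight_{groups[1]}"]

    if fit.library.labels is None:
        return cells, pd.DataFrame()
    rows = []
    for lab, sub in cells.groupby("label", sort=True):
        m = {g: float(np.nanmean(sub[f"mean_weight_{g}"])) for g in groups}
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = m[groups[0]] / m[groups[1]] if m[groups[1]] != 0 else np.inf
        rows.append({"label": lab, **{f"mean_weight_{g}": m[g] for g in groups}, "ratio": ratio})
    return cells, pd.DataFrame(rows)
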