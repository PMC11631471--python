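# Methods

## The reconstruction model

Each bulk sample `y` is approximated by a non-negative combination of
individual single-cell profiles, `min ‖y − Xβ‖, β ≥ 0`. Two properties of
non-negative least squares carry the method:

* the solution is *sparse* without a tuning parameter — at an optimum the
  active cells are at most as numerous as the genes, and in practice far
  fewer, so each fitted sample reads as a small weighted selection of cells;
* similar cells cannot cancel each other (no negative weights), so among
  redundant cells a few representatives absorb the shared signal.

The model assumes the library is *comprehensive* (contains cells of most
types and states present in the bulk) and that bulk and library are on a
common linear scale. There is no batch-effect correction between the two
modalities; genes distorted by technical disparities are meant to be caught
by the residual diagnostics, not repaired.

### Solver

The default solver is a box-constrained quasi-Newton method (L-BFGS-B, lower
bound 0) run on the Gram form of the least-squares objective
(½βᵀXᵀXβ − (Xᵀy)ᵀβ + ½yᵀy), with the Gram matrix shared across the samples
fitted against one sub-library. Inputs are rescaled internally by the matrix
maximum so that the projected-gradient tolerance (1e-9, max 15 000
iterations) is meaningful regardless of expression units. An exact
Lawson–Hanson active-set NNLS is available as an alternative
(`solver="nnls"`) and serves as the independent oracle in the test suite:
on random instances the quasi-Newton objective agrees with the active-set
optimum to 1e-6 relative.

Weights below 1e-8 × the sample's largest weight are set to exact zero. This
hard support definition is what makes "number of cells in a virtual tissue"
well defined; the threshold is configurable (`BootstrapConfig.zero_threshold`).

### Subsampling

The fit is repeated `n_runs` times (default 50), each against a uniformly
random `cell_fraction` (default 10%) of the library drawn *without*
replacement — a subsampling scheme rather than a classical resample, chosen
because a fraction-of-cells draw is the natural way to perturb a cell
library. Aggregation happens at the level of derived quantities
(frequencies, per-label expression, residuals), not raw weights, because
each run sees a different cell subset; per-cell summaries average only over
the runs in which the cell was drawn. Standard deviations use the (n−1)
denominator. Per-run frequencies are normalized first and then averaged
across runs; samples with zero total weight yield missing (not zero)
frequencies.

### Harmonization

Bulk and library are restricted to their shared genes, rows ordered
lexicographically, and by default every column of both matrices is rescaled
to a common total (1e6, CPM-like). The rescaling is exposed as a flag
because fitting unscaled data is occasionally wanted (e.g. when bulk columns
are already calibrated); all downstream quantities are scale-free ratios
except the per-label expression, which inherits the working scale. Library
cells that are all-zero on the shared gene set are dropped with a warning.

## Quality scores

Per gene, sample and run the relative residual is
`r = |Y − Ỹ| / (Y + Ỹ) ∈ [0, 1]`, with `r = 0` when `Y = Ỹ = 0`: a gene
silent in both bulk and reconstruction is treated as perfectly fitted rather
than penalized. Scores: `g_g` = mean over samples and runs (gene coverage),
`b_s` = mean over genes and runs (per-tissue fit), `v_g` = across-run
variance per (gene, sample), (n−1) denominator, averaged over samples
(robustness to the cell subsample). Default filter thresholds are
`g ≤ 0.5`, `b ≤ 0.5` and `v ≤ 10 × mean(v)` — conservative, configurable,
and intended as a starting point since no universal numeric cutoffs exist
for these scores; filtering that removes every gene aborts with an error
rather than returning an empty analysis.

## Differential ranking and AUC

Per cell label, genes are ranked between two sample classes by the absolute
Welch t statistic on `log2(1 + x)` of the bootstrap-mean label-specific
expression (plain log-fold-change and signed variants are available). The
log transform is used for ranking only; all decomposition outputs stay
linear. Genes with zero variance in both classes get statistic 0; ties break
by gene id. Recovery of a known positive gene set is scored by ROC/AUC
(pair-counting with ties at ½, which equals the threshold-sweep area);
significance and null bands come from permuting the sample class labels
while holding the decomposition fixed — the weights do not depend on class
labels, so refitting under permutation would change nothing but cost.

## The synthetic-data generator

The generator emulates the structure the method's validation needs, at desk
scale rather than atlas scale:

* **Archetypes.** Each gene gets a lognormal baseline (log-mean 2, log-sd 1,
  arbitrary linear units before per-cell scaling). Genes fall into three
  regimes: a shared fraction (default 0.4) identical across types; hard
  markers (default 0.2) elevated `marker_strength`-fold (default 8) in one
  random type; and graded genes (the remainder) whose level varies across
  types by lognormal factors (log-sd 1.25). The graded regime matters: real
  cell types differ quantitatively in most expressed genes, and it is this
  per-gene level structure that lets the fit attribute expression surpluses
  to the right compartment. A benchmark perturbation drawn uniformly over
  genes therefore hits mostly non-exclusive genes, as intended.
* **Sub-states.** Each type carries `n_substates` (default 2) within-type
  states, each a lognormal per-gene shift (log-sd 0.4) shared by the state's
  cells — correlated within-type heterogeneity of the kind cell labels hide.
* **Cells.** Each cell belongs to one of `n_donors` (default 8) donors
  (per-donor lognormal gene factors, log-sd 0.1) and has a lognormal depth
  factor (log-sd 0.3). Counts are negative-binomial around the cell's mean
  with `var = m + φ m²`, φ = `dispersion` (default 0.3; 0 gives the
  noiseless limit in which every cell equals its archetype after scaling).
  Columns are scaled to a common total (1e6).

What the generator does **not** emulate: ambient RNA, doublets, dropout
beyond NB sampling, batch/platform effects between bulk and library, or
mRNA-content differences between types. Passing benchmarks on this data
therefore demonstrates the statistical mechanics of the method — sparse
selection, attribution, diagnostics — not robustness to every real-data
artifact.

## The attribution benchmark

A random half of one type's cells have a random gene set (default 38 genes)
multiplied by `2^log2fc` — *across the whole population, before the donor
split*. Donors then split into a library half and a bulk half, so the
library contains both sub-states of the perturbed type while no individual
cell appears on both sides. Class-I pseudo-bulks sum `cells_per_bulk` random
cells (without replacement within a bulk) from the modified bulk-donor pool;
class-II bulks draw from the same donors' unmodified cells. This mirrors the
benchmark's logic: the perturbation creates within-type heterogeneity, and
the method must pick the modified-state library cells for class-I tissues —
which is exactly what the per-type differential tables then reveal. (An
alternative design that leaves the library entirely unmodified removes every
cell matching the perturbed state; the fit then has nothing to select and
attribution collapses toward chance — verified, and the reason the
population-level modification is the implemented design.)

Default benchmark scale in tests and in `scripts/acceptance.py`: 4 types ×
1000 cells (≈2000 library cells after the donor split), 500 genes,
38 modified genes at log2fc = 2, 40 pseudo-bulks of 200 cells, 10 bootstrap
runs at 10% cells, 200 label permutations. On this scale the modified type's
AUC is at ceiling with permutation p < 0.05 while the unmodified types stay
inside the null band — the no-spill-over property. The full default
(100 bulks of 500 cells) is configuration away; the reduced sizes keep a
complete run in tens of seconds on one CPU.

## Numerical and design choices

* Mixture-recovery ground truth relies on every library column having the
  same total: a label's share of fitted weight then equals its share of
  explained expression, so constructed mixture proportions are recoverable
  as frequencies.
* Variable-gene selection ranks genes by variance of `log2(1 + x)`
  separately in bulk (across samples) and library (across cells) and keeps
  the best-of-two rank, ties by gene id — a gene strongly variable in either
  modality survives. Union, intersection or combined-matrix variants would
  be reasonable; best-rank-of-two is the default because it is symmetric and
  cannot be starved by one low-variance modality.
* Frequencies are comparable across samples for the same label only;
  comparing different labels within one sample conflates mRNA content with
  abundance and is deliberately not supported by any output.
* Effect sizes in `mean_cell_weights` are ratios of group means computed per
  cell over the runs that drew the cell; cells never drawn are missing, not
  zero.

## Known limitations

* No GPU or parallel solver; fits are sequential and deterministic given the
  seed (bitwise reproducibility is only promised within one platform).
* The quality thresholds are heuristics; the scores themselves are the
  stable interface.
* With very small libraries (tens of cells) the 10% default subsample can
  round to a handful of cells; raise `cell_fraction` in that regime, or the
  fit degenerates by construction.
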