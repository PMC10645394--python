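# Methods

## Model and assumptions

The package assumes a case/control single-cell cohort in which

- expression is quality-controlled, normalized and **log-scaled** upstream
  (validated only structurally: finite values; a warning fires above a
  heuristic ceiling of 50, which log-scaled data should never reach);
- every cell carries a sample ID and a cell-type label produced outside the
  package (no cell clustering or annotation is performed here);
- controls are reasonably homogeneous, so a single aggregate reference per
  cell type (and batch) is meaningful;
- disease effects of interest are *programs*: coherent log-fold shifts of a
  gene set, present in a subset of (sample, cell type) pseudobulks;
- clinical covariates are binary (thresholded by the user; the package never
  thresholds continuous measurements).

Batches are honored throughout: a disease sample is normalized against the
control reference of its own batch label, unlabeled samples map to batch
`"default"`, and every batch containing disease samples must contain at
least one control.

## Pseudobulks, references and folds

A pseudobulk is the arithmetic mean of the log-scaled expression of all
cells of one (sample, cell type) pair; pairs with fewer than `min_cells`
(default 10) cells are dropped and reported. The aggregate control
reference supports two estimators:

- `mean_of_sample_pseudobulks` (default) — the unweighted mean of
  per-control-sample pseudobulks, so one deeply sampled control cannot
  dominate;
- `pooled_cells` — the mean over all pooled control cells, weighting
  controls by cell count.

With a single control the two coincide. Fold profiles are differences of
log-scale means (not ratios of linear means). Control *self-folds* — each
control against the all-controls aggregate — support cohorts where healthy
donors themselves are profiled; they require at least two controls because
a single control's self-fold is identically zero.

Before factorization every gene row is shifted by its own minimum so the
matrix is nonnegative. The shift is computed **once over all columns of the
matrix being analyzed**; `combine_folds` exists so that pooling disease
folds with control self-folds recomputes a single shared shift rather than
concatenating per-set shifts. Correlation-based steps (marker finding,
projection templates) are unaffected by per-gene constants, so raw and
shifted folds give identical marker tables.

## Clustering

1. **Guide genes.** A gene qualifies when |raw fold| ≥ log2(`fold_diff`)
   (default `fold_diff` = 2, i.e. one log2 unit; a natural-log mode is
   provided for cohorts stored on that scale) in at least `min_columns`
   (default 2) columns, and it correlates at Pearson ≥ 0.4 with at least one
   other qualifying gene; capped at 5000 genes by dynamic range. Fewer than
   10 survivors is an error suggesting threshold relaxation — on null data
   this gate is the first line of defense and typically fires before any
   clustering happens.
2. **Sparse NMF.** The shifted fold matrix restricted to guide genes is
   factorized with multiplicative-update NMF (Frobenius loss) carrying an L1
   penalty ρ = 0.3 on the coefficient factor H, via scikit-learn. The first
   restart uses the deterministic nonnegative-double-SVD initialization, the
   remaining `n_restarts − 1` (default 9) use seeded random initializations;
   the fit with the lowest reconstruction error wins. After the penalized
   fit, H is refit by unpenalized nonnegative least squares against the
   fixed basis: the penalty decides the basis and the support, but its
   shrinkage bias is removed from the reported factors (an exactly rank-k
   matrix is then reconstructed to machine precision). Column labels are the
   argmax of the *penalized* coefficients — sparsity is what assigns a
   column to one dominant program — with ties to the lowest component index.
3. **Unassigned columns.** Multiplicative updates never produce exact
   zeros, so "all coefficients ≈ 0" needs a numeric reading: a column whose
   largest penalized coefficient falls below `unassigned_coef_frac`
   (default 0.05) of the largest coefficient in H is considered unexplained
   by every component and left unassigned. On planted-program cohorts the
   separation is wide (member columns sit at ~0.7–1.0 of the maximum,
   background columns at ~0.03).
4. **Marker validation.** Each remaining cluster is tested for unique
   markers: every guide gene is assigned to the cluster whose 1/0
   membership indicator its fold row best correlates with (Pearson), and
   retained at r ≥ `marker_pearson_cutoff` (default 0.2). Marker scans run
   on the guide-gene matrix the clustering operated on — at ~10²–10³
   columns a full-transcriptome scan would admit roughly 1% chance markers
   per cluster at the 0.2 cutoff and defeat the validation. Clusters with
   zero markers are dropped; their columns are reassigned to the surviving
   component with the highest penalized coefficient (or unassigned under
   the same ≈0 rule). Survivors are renumbered U1..Un in component order
   and the marker table is recomputed on the final labels. Ties in the
   marker argmax go to the smaller cluster ID; within-cluster marker ranks
   order by descending r, then gene ID.
5. **Resolution sweep.** Ranks {10, 15, 20, 30} by default. The chosen k is
   the smallest whose validated cluster count is within `stability_margin`
   (default 2) of the next larger rank's count, else the largest tested; a
   fixed k can be forced. The per-k report is retained in the model.

Pathway annotation is a one-sided hypergeometric over-representation test
of each cluster's markers against a GMT collection, background = analyzed
genes ∩ collection universe, BH-adjusted within cluster.

## Association testing

For every (cluster, cell type, covariate) a 2×2 table counts
covariate-positive/negative samples in and out of the cluster. Counts are
**nonredundant**: a sample contributes at most one pseudobulk per
membership cell (configurable to raw pseudobulk counts). Unassigned
columns count as out-of-cluster pseudobulks of their cell type — they are
part of the tested universe, not a cluster. Missing covariate values drop
the sample from that covariate's tables only.

- **Fisher** (default): one-sided upper-tail p (positive enrichment),
  gated at Q ≥ 4 positive samples in the cluster; odds ratio QT/RS with
  0/0 undefined and x/0 infinite.
- **CMH** (when a confounder column is supplied): per-stratum tables gated
  at ≥ 2 samples each; Mantel–Haenszel pooled odds ratio; the chi-square
  test (continuity correction off by default) made one-sided by halving
  the p when the MH OR exceeds 1 and reflecting it otherwise. When every
  stratum is degenerate (e.g. a covariate constant within each stratum —
  the fully confounded case) the statistic has zero variance and the
  result is reported *untestable* rather than significant: stratification
  has explained the association away.
- **BH adjustment** runs separately within each covariate family, so adding
  a covariate never changes another covariate's adjusted values. Flags:
  raw p < 0.1 and FDR-adjusted p < 0.1 by default.

## Projection and embedding

Each final cluster's centroid is the mean shifted-fold vector of its
member columns over the model's marker genes. A new cohort's folds —
computed against the *new* cohort's own controls, never the reference
cohort's — are assigned to the best-correlated centroid over the shared
marker genes (≥ 20 required), or left unassigned below r = 0.2. The joint
2-D embedding (UMAP, fitted on the reference set, transforming the
others) is visualization-only; byte-identical columns are embedded once
and share coordinates, since the optimizer would otherwise jitter exact
duplicates apart.

## Synthetic cohorts

The generator simulates directly on the log scale: per-cell expression =
per-gene lognormal baseline + per-(gene, cell type) Gaussian offset
(sd 0.5) + planted program effect + Gaussian noise (sd 0.4). Defaults are
the study conditions: 16 disease and 5 control samples, 8 cell types,
30–200 cells per (sample, cell type), 2000 genes, five disjoint 40-gene
programs with mean log-fold effect 1.5, each confined to one cell type and
a random 5-sample subset, and one linked binary covariate per program with
5% label-flip noise. The null scenario plants nothing and draws covariates
independently; the confounded scenario makes the covariate a pure stratum
indicator whose stratum also contains all program members.

What the generator does **not** emulate: count-level sampling (dropout,
library-size variation), batch effects, correlated programs, or ambient
contamination. Passing tests therefore demonstrate the pipeline's
behavior under its own stated assumptions (log-scale additive effects,
annotated cells, homogeneous controls), not robustness to upstream
artifacts. Simulated log values may dip slightly below zero in low-baseline
genes; values are left unclipped so that planted effects are recovered
without truncation bias.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.SeedSequence` with explicit
  spawn keys, so identical seeds give byte-identical artifacts (verified
  across library and CLI runs).
- NMF: `max_iter` 600, `tol` 1e-6; non-convergent restarts keep the best
  iterate and emit a single summary warning.
- Statistical backends: scipy for the Fisher exact test and hypergeometric
  tails, statsmodels for the CMH chi-square and BH; the test suite checks
  each against independently coded enumeration/formula oracles
  (agreement to 1e-12 on 500 random tables for Fisher).
- Exact integer arithmetic is used for the single-stratum MH odds ratio so
  it equals QT/RS without floating error.
- Test and acceptance runs scale simulations to the statistics they
  measure: full default cohorts (128 disease pseudobulk columns) for
  recovery across 10–20 seeds, reduced cohorts (400 genes, 10–30 cells per
  pair) for null-safety sweeps and determinism, label-level designs for
  the 50–200-replicate association rate estimates.

## Known limitations

- The coefficient-floor rule for unassigned columns is a scale heuristic;
  cohorts where every column carries strong signal will simply assign
  everything, which matches the intended behavior on real disease data.
- The marker scan's 1/0 indicator templates treat clusters as flat
  membership sets; graded (median-centered) templates are not implemented.
- CMH handles a single categorical confounder; multi-way stratification
  and non-binary covariates are out of scope.
- The projection classifier is a transparent nearest-marker-centroid rule;
  a k-NN in embedding space would be a drop-in alternative but is not
  provided.
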