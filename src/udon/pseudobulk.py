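"""Pseudobulk construction and control-normalized fold matrices.

The first stage of the workflow collapses each (sample, cell type) group of
cells into a single mean expression vector (a *pseudobulk*), builds an
aggregate control reference per cell type (optionally per batch), and
subtracts it to obtain per-patient, per-cell-type differential profiles on
the log scale.  Because downstream factorization requires nonnegative
input, each gene row of the fold matrix is additionally shifted by its own
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONTROL, DISEASE, CellCohort
from .errors import InputError

COLUMN_SEP = "|"

MODE_POOLED = "pooled_cells"
MODE_MEAN_OF_SAMPLES = "mean_of_sample_pseudobulks"


def column_name(sample: str, cell_type: str) -> str:
    return f"{sample}{COLUMN_SEP}{cell_type}"


@dataclass
class PseudobulkSet:
    """genes x (sample, cell type) mean-expression matrix.

    ``values`` columns are named ``"sample|celltype"``; ``meta`` is indexed
    identically with columns sample, cell_type, n_cells, condition, batch.
    ``dropped`` records (sample, cell type) pairs excluded by the
    ``min_cells`` floor, with their cell counts.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.meta.index):
            raise InputError("pseudobulk values and metadata columns are out of sync")
        if len(self.meta) and (self.meta["n_cells"] < 1).any():
            raise InputError("pseudobulk columns must contain at least one cell")

    @property
    def columns(self) -> pd.Index:
        return self.values.columns


@dataclass
class ControlReference:
    """Aggregate control pseudobulk per (cell type, batch).

    ``values`` columns are a MultiIndex (cell_type, batch);
    ``n_control_samples`` counts the contributing control samples per column.
    ``missing_cell_types`` flags cell types seen in controls but below the
    cell floor everywhere.
    """

    values: pd.DataFrame
    n_control_samples: pd.Series
    mode: str
    missing_cell_types: list = field(default_factory=list)

    def lookup(self, cell_type: str, batch: str) -> np.ndarray | None:
        key = (cell_type, batch)
        if key not in self.values.columns:
            return None
        return self.values[key].to_numpy()


@dataclass
class FoldMatrix:
    """Control-normalized differential profiles.

    ``raw`` holds pseudobulk minus matched control reference (log scale);
    ``shifted`` is ``raw`` minus the per-gene minimum ``gene_min`` so every
    entry is nonnegative with a zero minimum per gene row.
    """

    raw: pd.DataFrame
    shifted: pd.DataFrame
    gene_min: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.raw.columns.equals(self.meta.index):
            raise InputError("fold matrix values and metadata columns are out of sync")

    @property
    def columns(self) -> pd.Index:
        return self.raw.columns

    @property
    def genes(self) -> pd.Index:
        return self.raw.index


def _shift_nonnegative(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    gene_min = raw.min(axis=1)
    shifted = raw.sub(gene_min, axis=0)
    return shifted, gene_min


def fold_matrix_from_raw(raw: pd.DataFrame, meta: pd.DataFrame) -> FoldMatrix:
    """Build a :class:`FoldMatrix`, computing the nonnegative shift."""
    shifted, gene_min = _shift_nonnegative(raw)
    return FoldMatrix(raw=raw, shifted=shifted, gene_min=gene_min, meta=meta)


# ----------------------------------------------------------------------
def compute_pseudobulks(cohort: CellCohort, min_cells: int = 10,
                        conditions: tuple[str, ...] = (DISEASE,)) -> PseudobulkSet:
    """Mean expression per (sample, cell type) pair with >= ``min_cells`` cells.

    Pairs below the floor are not silently lost: they are listed in the
    result's ``dropped`` table together with their cell counts.
    """
    if min_cells < 1:
        raise InputError("min_cells must be a positive integer")
    keep_samples = set(
        cohort.sample_meta.index[cohort.sample_meta["condition"].isin(conditions)]
    )
    obs = cohort.obs[cohort.obs["sample"].isin(keep_samples)]
    if obs.empty:
        raise InputError(f"no cells from samples with condition in {sorted(conditions)}")

    X = cohort.expression.to_numpy()
    cols, meta_rows, dropped_rows = [], [], []
    groups = obs.groupby(["sample", "cell_type"], sort=True).groups
    col_pos = {c: i for i, c in enumerate(cohort.cells)}
    blocks = []
    for (sample, cell_type), cell_ids in groups.items():
        n = len(cell_ids)
        if n < min_cells:
            dropped_rows.append({"sample": sample, "cell_type": cell_type, "n_cells": n})
            continue
        idx = np.fromiter((col_pos[c] for c in cell_ids), dtype=np.intp, count=n)
        blocks.append(X[:, idx].mean(axis=1))
        cols.append(column_name(sample, cell_type))
        meta_rows.append({
            "sample": sample, "cell_type": cell_type, "n_cells": n,
            "condition": cohort.condition_of(sample), "batch": cohort.batch_of(sample),
        })
    if not cols:
        raise InputError(
            f"no pseudobulks: every (sample, cell type) pair has fewer than {min_cells} cells"
        )
    values = pd.DataFrame(np.column_stack(blocks), index=cohort.genes, columns=cols)
    meta = pd.DataFrame(meta_rows, index=pd.Index(cols))
    dropped = pd.DataFrame(dropped_rows, columns=["sample", "cell_type", "n_cells"])
    return PseudobulkSet(values=values, meta=meta, dropped=dropped)


def aggregate_control_reference(cohort: CellCohort, min_cells: int = 10,
                                mode: str = MODE_MEAN_OF_SAMPLES) -> ControlReference:
    """Aggregate control pseudobulk per (cell type, batch).

    ``mean_of_sample_pseudobulks`` (default) averages per-control-sample
    pseudobulks with equal weight, so a single deeply sampled control cannot
    dominate the reference; ``pooled_cells`` averages over all pooled
    control cells, weighting samples by their cell counts.
    """
    if mode not in (MODE_POOLED, MODE_MEAN_OF_SAMPLES):
        raise InputError(f"unknown aggregation mode '{mode}'")
    meta = cohort.sample_meta
    controls = meta.index[meta["condition"] == CONTROL]
    if len(controls) == 0:
        raise InputError("no control samples in cohort")
    obs = cohort.obs[cohort.obs["sample"].isin(set(controls))].copy()
    obs["batch"] = obs["sample"].map(meta["batch"])

    X = cohort.expression.to_numpy()
    col_pos = {c: i for i, c in enumerate(cohort.cells)}
    ref_cols, counts, blocks, missing = [], [], [], []

    for (cell_type, batch), grp in obs.groupby(["cell_type", "batch"], sort=True):
        per_sample = []
        for sample, cell_ids in grp.groupby("sample").groups.items():
            if len(cell_ids) < min_cells and mode == MODE_MEAN_OF_SAMPLES:
                continue
            idx = np.fromiter((col_pos[c] for c in cell_ids), dtype=np.intp)
            per_sample.append((sample, idx))
        if mode == MODE_POOLED:
            idx_all = np.fromiter((col_pos[c] for c in grp.index), dtype=np.intp)
            if len(idx_all) < min_cells:
                missing.append((cell_type, batch))
                continue
            blocks.append(X[:, idx_all].mean(axis=1))
            counts.append(grp["sample"].nunique())
        else:
            if not per_sample:
                missing.append((cell_type, batch))
                continue
            blocks.append(np.mean([X[:, idx].mean(axis=1) for _, idx in per_sample], axis=0))
            counts.append(len(per_sample))
        ref_cols.append((cell_type, batch))

    if not ref_cols:
        raise InputError(
            f"no control reference columns: no (cell type, batch) reached {min_cells} cells "
            f"(batches: {sorted(meta.loc[controls, 'batch'].unique())})"
        )
    columns = pd.MultiIndex.from_tuples(ref_cols, names=["cell_type", "batch"])
    values = pd.DataFrame(np.column_stack(blocks), index=cohort.genes, columns=columns)
    n_ctrl = pd.Series(counts, index=columns)
    return ControlReference(values=values, n_control_samples=n_ctrl, mode=mode,
                            missing_cell_types=missing)


def fold_differentials(pseudobulks: PseudobulkSet, reference: ControlReference) -> FoldMatrix:
    """Subtract the matched control reference from every pseudobulk column.

    Log-scale inputs make this difference a log fold change.  Every
    column's (cell type, batch) must exist in the reference; orphans are an
    error so that silent drop-outs cannot skew clustering.
    """
    raw_cols = []
    orphans = []
    for col in pseudobulks.columns:
        cell_type = pseudobulks.meta.at[col, "cell_type"]
        batch = pseudobulks.meta.at[col, "batch"]
        ref = reference.lookup(cell_type, batch)
        if ref is None:
            orphans.append(col)
            continue
        raw_cols.append(pseudobulks.values[col].to_numpy() - ref)
    if orphans:
        raise InputError(f"pseudobulk columns lack a control reference: {orphans}")
    raw = pd.DataFrame(np.column_stack(raw_cols), index=pseudobulks.values.index,
                       columns=pseudobulks.columns)
    return fold_matrix_from_raw(raw, pseudobulks.meta.copy())


def control_self_folds(cohort: CellCohort, min_cells: int = 10,
                       mode: str = MODE_MEAN_OF_SAMPLES) -> FoldMatrix:
    """Per-control-sample pseudobulk minus the all-controls aggregate.

    Used when healthy donors themselves are profiled against their
    collective average (pan-immune scenarios).  Requires >= 2 controls; a
    single control's self-fold is identically zero and carries no signal.
    """
    controls = cohort.samples(CONTROL)
    if len(controls) < 2:
        raise InputError("control self-folds need at least 2 control samples")
    pb = compute_pseudobulks(cohort, min_cells=min_cells, conditions=(CONTROL,))
    ref = aggregate_control_reference(cohort, min_cells=min_cells, mode=mode)
    folds = fold_differentials(pb, ref)
    folds.meta["condition"] = CONTROL
    return folds


def combine_folds(fold_sets: list[FoldMatrix]) -> FoldMatrix:
    """Concatenate fold matrices column-wise and recompute one shared shift.

    The per-gene nonnegative shift must span every column analyzed in a
    run, so pooling disease folds with control self-folds goes through this
    helper rather than concatenating ``shifted`` blocks.
    """
    if not fold_sets:
        raise InputError("no fold matrices to combine")
    genes = fold_sets[0].genes
    for fm in fold_sets[1:]:
        if not fm.genes.equals(genes):
            raise InputError("fold matrices have mismatched gene indexes")
    raw = pd.concat([fm.raw for fm in fold_sets], axis=1)
    if raw.columns.duplicated().any():
        raise InputError("duplicate pseudobulk column names across fold matrices")
    meta = pd.concat([fm.meta for fm in fold_sets], axis=0)
    return fold_matrix_from_raw(raw, meta)
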