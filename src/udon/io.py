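"""Readers and writers for the package's on-disk formats.

Expression comes in either as MatrixMarket coordinate format with the 10x
``features.tsv``/``barcodes.tsv`` sidecars (genes as rows) or as a dense
genes x cells TSV with cell IDs in the header.  Annotations, covariates,
pseudobulk/fold matrices and column metadata are all plain TSV; gene-set
collections use the MSigDB GMT convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cohort import CellCohort
from .errors import InputError
from .pseudobulk import FoldMatrix, PseudobulkSet, fold_matrix_from_raw
from .satay import CovariateTable

ANNOTATION_COLUMNS = ("cell_id", "sample_id", "cell_type", "condition")


# -- expression ---------------------------------------------------------
def read_expression_mtx(matrix_path, features_path=None, barcodes_path=None) -> pd.DataFrame:
    """Read a genes x cells matrix in 10x MTX + features/barcodes layout.

    ``matrix_path`` may be a directory holding ``matrix.mtx``,
    ``features.tsv`` (or ``genes.tsv``) and ``barcodes.tsv``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.is_dir():
        d = matrix_path
        matrix_path = d / "matrix.mtx"
        features_path = features_path or next(
            (p for p in (d / "features.tsv", d / "genes.tsv") if p.exists()), None)
        barcodes_path = barcodes_path or d / "barcodes.tsv"
    if features_path is None or barcodes_path is None:
        raise InputError("MTX input needs features and barcodes files")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise InputError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    features = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    genes = features.iloc[:, 0].astype(str)
    if features.shape[1] >= 2:  # 10x: (id, symbol, ...); prefer symbols when unique
        symbols = features.iloc[:, 1].astype(str)
        if symbols.nunique() == len(symbols):
            genes = symbols
    dense = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(barcodes)):
        raise InputError(
            f"matrix shape {dense.shape} does not match features x barcodes "
            f"({len(genes)} x {len(barcodes)})"
        )
    return pd.DataFrame(dense, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(barcodes.iloc[:, 0].astype(str), name="cell"))


def read_expression_tsv(path) -> pd.DataFrame:
    """Dense genes x cells TSV, header row = cell IDs, first column = genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise InputError(f"expression file {path} is empty")
    try:
        return df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric values in expression file {path}: {exc}") from exc


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"annotation file {path} is missing columns: {missing}")
    return df


def load_cohort(expression_path, annotation_path) -> CellCohort:
    """Assemble a :class:`CellCohort` from expression + annotation files."""
    expression_path = Path(expression_path)
    if expression_path.is_dir() or expression_path.suffix == ".mtx":
        expr = read_expression_mtx(expression_path)
    else:
        expr = read_expression_tsv(expression_path)
    ann = read_annotation_tsv(annotation_path)
    ann = ann.set_index("cell_id")
    missing_cells = expr.columns.difference(ann.index)
    if len(missing_cells):
        raise InputError(f"{len(missing_cells)} cells lack annotation rows "
                         f"(first: {list(missing_cells[:5])})")
    ann = ann.loc[expr.columns]
    obs = pd.DataFrame({"sample": ann["sample_id"], "cell_type": ann["cell_type"]},
                       index=expr.columns)
    per_sample = ann.groupby("sample_id").agg({
        "condition": "first", **({"batch": "first"} if "batch" in ann.columns else {})})
    consistency = ann.groupby("sample_id")["condition"].nunique()
    if (consistency > 1).any():
        raise InputError("condition must be constant within each sample")
    return CellCohort(expression=expr, obs=obs, sample_meta=per_sample)


def write_cohort_tsv(cohort: CellCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    ann = pd.DataFrame({
        "cell_id": cohort.cells,
        "sample_id": cohort.obs["sample"].values,
        "cell_type": cohort.obs["cell_type"].values,
        "condition": cohort.obs["sample"].map(cohort.sample_meta["condition"]).values,
        "batch": cohort.obs["sample"].map(cohort.sample_meta["batch"]).values,
    })
    ann.to_csv(out / "annotation.tsv", sep="\t", index=False)


# -- matrices -----------------------------------------------------------
def write_matrix_tsv(values: pd.DataFrame, meta: pd.DataFrame, prefix) -> None:
    """A genes x columns matrix plus its column-metadata sidecar."""
    prefix = Path(prefix)
    values.to_csv(prefix.with_suffix(".tsv"), sep="\t", index_label="gene")
    meta.to_csv(prefix.parent / (prefix.name + "_columns.tsv"), sep="\t",
                index_label="column")


def write_pseudobulks(pb: PseudobulkSet, prefix) -> None:
    write_matrix_tsv(pb.values, pb.meta, prefix)


def write_folds(folds: FoldMatrix, prefix) -> None:
    prefix = Path(prefix)
    write_matrix_tsv(folds.raw, folds.meta, prefix.parent / (prefix.name + "_raw"))
    write_matrix_tsv(folds.shifted, folds.meta, prefix.parent / (prefix.name + "_shifted"))


def read_folds(prefix) -> FoldMatrix:
    """Rebuild a fold matrix from its ``*_raw`` TSV pair (shift recomputed)."""
    prefix = Path(prefix)
    raw = pd.read_csv(prefix.parent / (prefix.name + "_raw.tsv"), sep="\t", index_col="gene")
    meta = pd.read_csv(prefix.parent / (prefix.name + "_raw_columns.tsv"), sep="\t",
                       index_col="column")
    return fold_matrix_from_raw(raw, meta)


# -- covariates ---------------------------------------------------------
def read_covariates_tsv(path, stratum_column: str = "stratum") -> CovariateTable:
    """Sample-level binary covariates: sample_id, one column per covariate.

    An optional ``stratum`` column carries confounder labels for CMH.
    Values must be 1, 0 or NA; continuous measures are thresholded by the
    user before this point.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise InputError(f"covariate file {path} needs a 'sample_id' column")
    df = df.set_index("sample_id")
    strata = None
    if stratum_column in df.columns:
        strata = df[stratum_column].astype(str)
        df = df.drop(columns=[stratum_column])
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise InputError(f"non-numeric covariate values in {path}: {exc}") from exc
    return CovariateTable(values=values, strata=strata)


def write_covariates_tsv(covariates: CovariateTable, path) -> None:
    df = covariates.values.copy()
    if covariates.strata is not None:
        df["stratum"] = covariates.strata.reindex(df.index)
    df.to_csv(path, sep="\t", index_label="sample_id")


# -- gene sets ----------------------------------------------------------
def read_gmt(path) -> dict:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise InputError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
        name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name in sets:
            raise InputError(f"{path}:{lineno}: duplicate gene set name '{name}'")
        sets[name] = set(genes)
    if not sets:
        raise InputError(f"GMT file {path} contains no gene sets")
    return sets
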