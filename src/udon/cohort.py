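"""Annotated single-cell cohort container.

A :class:`CellCohort` couples a log-scaled genes x cells expression matrix
with the per-cell annotations (sample of origin, cell-type label) and the
per-sample annotations (disease/control condition, optional batch) that the
pseudobulk machinery needs.  Expression values are assumed to be quality
controlled, normalized and log-scaled upstream; this container only
validates structural consistency, not biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

DISEASE = "disease"
CONTROL = "control"
DEFAULT_BATCH = "default"

#: heuristic ceiling for log-scaled data; larger values suggest raw counts
LOG_SCALE_MAX = 50.0


@dataclass
class CellCohort:
    """Log-scaled expression joined to cell- and sample-level annotation.

    Parameters
    ----------
    expression
        genes x cells matrix of finite, log-scaled values.  The column
        index must equal ``obs.index`` (cell identifiers).
    obs
        Per-cell table with columns ``sample`` and ``cell_type``.
    sample_meta
        Per-sample table with column ``condition`` (``"disease"`` or
        ``"control"``) and optional ``batch`` (missing -> ``"default"``).
    """

    expression: pd.DataFrame
    obs: pd.DataFrame
    sample_meta: pd.DataFrame
    _warnings: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self._validate()

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        if self.expression.shape[0] < 1 or self.expression.shape[1] < 1:
            raise InputError("empty cohort: expression matrix has no genes or no cells")
        if not self.expression.columns.equals(self.obs.index):
            raise InputError("expression columns and annotation index (cell IDs) differ")
        for col in ("sample", "cell_type"):
            if col not in self.obs.columns:
                raise InputError(f"cell annotation is missing required column '{col}'")
            if self.obs[col].isna().any():
                raise InputError(f"cell annotation column '{col}' contains missing values")
        if "condition" not in self.sample_meta.columns:
            raise InputError("sample metadata is missing required column 'condition'")
        if "batch" not in self.sample_meta.columns:
            self.sample_meta = self.sample_meta.assign(batch=DEFAULT_BATCH)
        self.sample_meta["batch"] = self.sample_meta["batch"].fillna(DEFAULT_BATCH)

        unknown = set(self.obs["sample"]) - set(self.sample_meta.index)
        if unknown:
            raise InputError(f"cells reference samples absent from sample metadata: {sorted(unknown)}")
        bad = set(self.sample_meta["condition"]) - {DISEASE, CONTROL}
        if bad:
            raise InputError(f"sample condition must be 'disease' or 'control', got {sorted(bad)}")

        values = self.expression.to_numpy()
        if not np.isfinite(values).all():
            raise InputError("expression contains NaN or infinite values; inputs must be finite")
        if values.max(initial=0.0) >= LOG_SCALE_MAX:
            self._warnings.append(
                f"max expression value {values.max():.1f} >= {LOG_SCALE_MAX}; "
                "inputs are expected to be log-scaled"
            )

        # every batch holding disease samples must also hold a control
        meta = self.sample_meta
        for batch, grp in meta.groupby("batch"):
            if (grp["condition"] == DISEASE).any() and not (grp["condition"] == CONTROL).any():
                raise InputError(f"batch '{batch}' has disease samples but no control sample")

    # ------------------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    @property
    def cells(self) -> pd.Index:
        return self.expression.columns

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def samples(self, condition: str | None = None) -> pd.Index:
        meta = self.sample_meta
        if condition is not None:
            meta = meta[meta["condition"] == condition]
        return meta.index

    def condition_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "condition"])

    def batch_of(self, sample: str) -> str:
        return str(self.sample_meta.loc[sample, "batch"])

    # ------------------------------------------------------------------
    @classmethod
    def from_anndata(cls, adata, *, sample_key: str = "sample_id",
                     cell_type_key: str = "cell_type", condition_key: str = "condition",
                     batch_key: str | None = "batch") -> "CellCohort":
        """Build a cohort from an AnnData object (cells x genes).

        Sample-level condition/batch are taken from the per-cell ``.obs``
        columns and must be constant within each sample.
        """
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        expr = pd.DataFrame(np.asarray(X).T, index=adata.var_names, columns=adata.obs_names)
        obs = pd.DataFrame(
            {"sample": adata.obs[sample_key].astype(str).values,
             "cell_type": adata.obs[cell_type_key].astype(str).values},
            index=adata.obs_names,
        )
        cols = {"condition": adata.obs[condition_key].astype(str).values}
        if batch_key is not None and batch_key in adata.obs:
            cols["batch"] = adata.obs[batch_key].astype(str).values
        per_cell = pd.DataFrame(cols, index=adata.obs_names).assign(sample=obs["sample"])
        grouped = per_cell.groupby("sample").nunique()
        if (grouped > 1).any().any():
            raise InputError("condition/batch must be constant within each sample")
        sample_meta = per_cell.groupby("sample").first()
        return cls(expression=expr, obs=obs, sample_meta=sample_meta)

    def to_anndata(self):
        """Export as AnnData (cells x genes) with annotations in ``.obs``."""
        import anndata as ad

        obs = self.obs.copy()
        obs["condition"] = self.obs["sample"].map(self.sample_meta["condition"]).values
        obs["batch"] = self.obs["sample"].map(self.sample_meta["batch"]).values
        return ad.AnnData(X=self.expression.to_numpy().T, obs=obs,
                          var=pd.DataFrame(index=self.genes))
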