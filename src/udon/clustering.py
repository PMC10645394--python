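"""Cluster discovery on shifted fold matrices via sparse NMF.

The pipeline mirrors iterative guide-gene clustering at pseudobulk scale:

1. guide-gene selection — keep genes with a large fold change in at least a
   few columns that co-vary with at least one other selected gene;
2. sparse nonnegative matrix factorization of the shifted fold matrix
   restricted to guide genes, columns labeled by their dominant component;
3. marker validation — components without at least one unique marker gene
   above the correlation cutoff are dropped and their columns reassigned;
4. a resolution sweep that picks the smallest rank k whose number of
   marker-validated clusters is stable against the next larger rank.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from .errors import InputError, UdonError
from .markers import MarkerTable, marker_finder
from .pseudobulk import FoldMatrix

logger = logging.getLogger(__name__)

#: coefficient below which a column is considered unexplained by a component
COEF_EPS = 1e-12


@dataclass(frozen=True)
class UdonParams:
    """Tunable knobs of the clustering stage.

    Defaults follow the published protocol: sparsity ``rho`` 0.3 on the
    coefficient factor, marker Pearson cutoff 0.2, feature fold threshold 2
    (interpreted on the log2 scale), rank sweep over {10, 15, 20, 30}.
    """

    rho: float = 0.3
    marker_pearson_cutoff: float = 0.2
    fold_diff: float = 2.0
    fold_scale: str = "log2"          # "log2" or "ln": scale of the input folds
    k_values: tuple = (10, 15, 20, 30)
    seed: int = 0
    n_restarts: int = 10
    min_columns: int = 2              # columns a guide gene must exceed the fold threshold in
    gene_corr_min: float = 0.4        # guide gene must correlate with >=1 other at this level
    max_genes: int = 5000
    min_guide_genes: int = 10
    stability_margin: int = 2
    max_iter: int = 600
    tol: float = 1e-6
    #: a column whose largest sparse coefficient falls below this fraction of
    #: the largest coefficient overall is considered unexplained (unassigned)
    unassigned_coef_frac: float = 0.05

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise InputError("rho must be in (0, 1)")
        if self.fold_diff <= 1:
            raise InputError("fold_diff must exceed 1")
        if any(k < 2 for k in self.k_values):
            raise InputError("all k values must be >= 2")
        if self.fold_scale not in ("log2", "ln"):
            raise InputError("fold_scale must be 'log2' or 'ln'")

    @property
    def fold_threshold(self) -> float:
        """|raw fold| threshold implied by ``fold_diff`` on the input scale."""
        if self.fold_scale == "log2":
            return float(np.log2(self.fold_diff))
        return float(np.log(self.fold_diff))


@dataclass
class NMFResult:
    basis: pd.DataFrame               # guide genes x k, nonnegative
    coefficients: pd.DataFrame        # k x columns, NNLS-refit (unbiased)
    coefficients_sparse: pd.DataFrame  # k x columns, L1-penalized fit
    labels: pd.Series                 # column -> provisional component index (int)
    k: int
    reconstruction_error: float


@dataclass
class UdonModel:
    """A finalized clustering of pseudobulk fold profiles.

    ``labels`` maps each column to a final cluster ID ("U1", "U2", ...)
    or ``"unassigned"``.  ``centroids`` holds per-cluster mean shifted-fold
    vectors over the marker genes, used for projecting new cohorts.
    """

    k_used: int
    labels: pd.Series
    basis: pd.DataFrame
    coefficients: pd.DataFrame
    guide_genes: list
    marker_table: MarkerTable
    dropped_clusters: list
    meta: pd.DataFrame
    centroids: pd.DataFrame
    params: UdonParams
    per_k_report: pd.DataFrame | None = None
    pathway_report: pd.DataFrame | None = None

    def clusters(self) -> list[str]:
        return sorted((c for c in pd.unique(self.labels) if c != "unassigned"),
                      key=lambda u: int(u[1:]))

    def assignments(self) -> pd.DataFrame:
        out = self.meta.loc[self.labels.index, ["sample", "cell_type"]].copy()
        out["cluster"] = self.labels
        return out

    # -- serialization --------------------------------------------------
    def to_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.assignments().to_csv(p / "labels.tsv", sep="\t", index_label="column")
        self.marker_table.df.to_csv(p / "markers.tsv", sep="\t", index=False)
        self.basis.to_csv(p / "basis.tsv", sep="\t", index_label="gene")
        self.coefficients.to_csv(p / "coefficients.tsv", sep="\t", index_label="component")
        self.centroids.to_csv(p / "centroids.tsv", sep="\t", index_label="gene")
        self.meta.to_csv(p / "column_meta.tsv", sep="\t", index_label="column")
        if self.per_k_report is not None:
            self.per_k_report.to_csv(p / "per_k_report.tsv", sep="\t", index=False)
        if self.pathway_report is not None:
            self.pathway_report.to_csv(p / "pathways.tsv", sep="\t", index=False)
        manifest = {
            "k_used": int(self.k_used),
            "guide_genes": list(map(str, self.guide_genes)),
            "dropped_clusters": [int(c) for c in self.dropped_clusters],
            "marker_cutoff": float(self.marker_table.cutoff),
            "params": asdict(self.params),
        }
        (p / "model.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_dir(cls, path) -> "UdonModel":
        from pathlib import Path

        p = Path(path)
        manifest = json.loads((p / "model.json").read_text())
        labels_df = pd.read_csv(p / "labels.tsv", sep="\t", index_col="column")
        markers = pd.read_csv(p / "markers.tsv", sep="\t")
        params_d = manifest["params"]
        params_d["k_values"] = tuple(params_d["k_values"])
        per_k = p / "per_k_report.tsv"
        pathways = p / "pathways.tsv"
        return cls(
            k_used=manifest["k_used"],
            labels=labels_df["cluster"],
            basis=pd.read_csv(p / "basis.tsv", sep="\t", index_col="gene"),
            coefficients=pd.read_csv(p / "coefficients.tsv", sep="\t", index_col="component"),
            guide_genes=manifest["guide_genes"],
            marker_table=MarkerTable(df=markers, cutoff=manifest["marker_cutoff"]),
            dropped_clusters=manifest["dropped_clusters"],
            meta=pd.read_csv(p / "column_meta.tsv", sep="\t", index_col="column"),
            centroids=pd.read_csv(p / "centroids.tsv", sep="\t", index_col="gene"),
            params=UdonParams(**params_d),
            per_k_report=pd.read_csv(per_k, sep="\t") if per_k.exists() else None,
            pathway_report=pd.read_csv(pathways, sep="\t") if pathways.exists() else None,
        )


# ----------------------------------------------------------------------
def select_guide_genes(folds: FoldMatrix, params: UdonParams = UdonParams()) -> list:
    """High-dynamic-range, mutually correlated feature genes.

    A gene qualifies when its |raw fold| exceeds the fold threshold in at
    least ``min_columns`` columns and it correlates (Pearson >=
    ``gene_corr_min``) with at least one other qualifying gene; capped at
    ``max_genes`` by dynamic range.  Deterministic given inputs.
    """
    raw = folds.raw
    if raw.empty:
        raise InputError("fold matrix is empty")
    thr = params.fold_threshold
    hits = (raw.abs() >= thr).sum(axis=1)
    survivors = raw.index[hits >= params.min_columns]
    if len(survivors) < params.min_guide_genes:
        raise InputError(
            f"only {len(survivors)} genes exceed |fold| >= {thr:.3g} in >= "
            f"{params.min_columns} columns; relax fold_diff or min_columns"
        )
    sub = raw.loc[survivors].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    variable = sd > 0
    sub = sub[variable]
    survivors = survivors[variable]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    np.fill_diagonal(corr, -np.inf)
    partnered = np.nanmax(corr, axis=1) >= params.gene_corr_min
    selected = survivors[partnered]
    if len(selected) < params.min_guide_genes:
        raise InputError(
            f"only {len(selected)} guide genes survive the correlation gate "
            f"(>= {params.gene_corr_min}); relax thresholds"
        )
    if len(selected) > params.max_genes:
        dyn = (raw.loc[selected].max(axis=1) - raw.loc[selected].min(axis=1))
        selected = dyn.sort_values(ascending=False, kind="mergesort").index[: params.max_genes]
        selected = raw.index[raw.index.isin(selected)]  # restore gene order
    return list(selected)


def _nmf_seed(base_seed: int, k: int, restart: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(k, restart))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _nnls_refit(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Unpenalized NNLS refit of the coefficient matrix given a fixed basis."""
    from scipy.optimize import nnls

    out = np.empty_like(H)
    for j in range(X.shape[1]):
        out[:, j] = nnls(W, X[:, j])[0]
    return out


def snmf_factorize(matrix: pd.DataFrame, k: int, params: UdonParams = UdonParams()) -> NMFResult:
    """Sparse NMF (L1 penalty ``rho`` on coefficients), best of restarts.

    ``matrix`` is the shifted fold matrix restricted to guide genes
    (genes x columns, nonnegative).  Each column's provisional label is the
    argmax of its coefficient vector, ties resolved to the lowest component
    index.  The first restart uses a deterministic nonnegative-double-SVD
    initialization; the rest use seeded random initializations, and the fit
    with the smallest reconstruction error wins.  After the penalized fit,
    coefficients are refit by unpenalized nonnegative least squares against
    the fixed basis — the L1 penalty shapes the basis and the support but
    its shrinkage bias is removed from the reported factors.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise InputError("sparse NMF input must be nonnegative; apply the fold shift first")
    if k >= X.shape[1]:
        raise InputError(f"k={k} must be smaller than the number of columns ({X.shape[1]})")

    best = None
    n_unconverged = 0
    for r in range(max(1, params.n_restarts)):
        init = "nndsvda" if r == 0 else "random"
        model = NMF(
            n_components=k, init=init, solver="mu", beta_loss="frobenius",
            alpha_W=0.0, alpha_H=params.rho, l1_ratio=1.0,
            max_iter=params.max_iter, tol=params.tol,
            random_state=_nmf_seed(params.seed, k, r),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            W = model.fit_transform(X)
        if model.n_iter_ >= params.max_iter:
            n_unconverged += 1
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, model.components_)
    if n_unconverged:
        warnings.warn(
            f"sparse NMF (k={k}): {n_unconverged}/{params.n_restarts} restarts hit "
            f"max_iter={params.max_iter} before tol={params.tol}; best iterate kept",
            ConvergenceWarning, stacklevel=2,
        )
    _, W, H_sparse = best
    H = _nnls_refit(X, W, H_sparse)
    err = float(np.linalg.norm(X - W @ H))
    # labels come from the penalized coefficients: sparsity is what assigns
    # each column to one dominant program (or to none)
    labels = pd.Series(np.argmax(H_sparse, axis=0), index=matrix.columns, name="component")
    basis = pd.DataFrame(W, index=matrix.index, columns=range(k))
    coeff = pd.DataFrame(H, index=range(k), columns=matrix.columns)
    coeff_sparse = pd.DataFrame(H_sparse, index=range(k), columns=matrix.columns)
    return NMFResult(basis=basis, coefficients=coeff, coefficients_sparse=coeff_sparse,
                     labels=labels, k=k, reconstruction_error=err)


def finalize_clusters(factors: NMFResult, folds: FoldMatrix,
                      params: UdonParams = UdonParams(),
                      guide_genes: list | None = None) -> UdonModel:
    """Marker-validate NMF components into final clusters.

    Columns whose sparse coefficients are all ~0 (below
    ``unassigned_coef_frac`` of the largest coefficient) are unexplained by
    every component and left unassigned.  Components with no unique marker
    gene reaching the Pearson cutoff are dropped; their columns are
    reassigned to the surviving component with the highest sparse
    coefficient, or left unassigned when all surviving coefficients are ~0.
    Surviving components are renumbered U1..Un in component order and the
    marker table is recomputed on the final labels.
    """
    guide_genes = list(factors.basis.index) if guide_genes is None else guide_genes
    guide_matrix = folds.raw.loc[guide_genes]
    H_sparse = factors.coefficients_sparse
    coef_floor = max(float(H_sparse.to_numpy().max()) * params.unassigned_coef_frac, COEF_EPS)
    explained = H_sparse.max(axis=0) >= coef_floor

    labels = factors.labels.copy().astype(object)
    labels[~explained] = "unassigned"
    assigned = labels[labels != "unassigned"]
    occupied = sorted(pd.unique(assigned))
    empty = [c for c in range(factors.k) if c not in occupied]
    if len(occupied) < 2:
        raise UdonError("no marker-supported structure: factorization collapsed to one component")

    table = marker_finder(guide_matrix[assigned.index], assigned,
                          cutoff=params.marker_pearson_cutoff)
    supported = [c for c in occupied if c in set(table.df["cluster"])]
    dropped = sorted(set(empty) | (set(occupied) - set(supported)))
    if not supported:
        raise UdonError("no marker-supported structure: every component lacks unique markers")

    unsupported = set(occupied) - set(supported)
    if unsupported:
        coeff_sub = H_sparse.loc[supported]
        for col in labels.index[labels.isin(list(unsupported))]:
            col_coeff = coeff_sub[col]
            if float(col_coeff.max()) < coef_floor:
                labels.at[col] = "unassigned"
            else:
                labels.at[col] = int(col_coeff.idxmax())

    rename = {c: f"U{i + 1}" for i, c in enumerate(supported)}
    final = labels.map(lambda c: rename.get(c, "unassigned"))

    # marker table on final labels (falls back to the provisional table
    # when a single cluster survives: templates need >= 2 clusters)
    assigned = final[final != "unassigned"]
    if assigned.nunique() >= 2:
        table_final = marker_finder(guide_matrix[assigned.index], assigned,
                                    cutoff=params.marker_pearson_cutoff)
    else:
        table_final = table.relabel(rename)
        table_final.df = table_final.df[table_final.df["cluster"].isin(rename.values())]

    shifted = folds.shifted
    cent = {}
    for cluster in sorted(rename.values(), key=lambda u: int(u[1:])):
        cols = final.index[final == cluster]
        cent[cluster] = shifted.loc[:, cols].mean(axis=1)
    marker_genes = list(dict.fromkeys(g for c in cent for g in table_final.markers_of(c)))
    centroids = pd.DataFrame(cent).loc[marker_genes] if marker_genes else pd.DataFrame(cent)

    return UdonModel(
        k_used=factors.k,
        labels=final,
        basis=factors.basis,
        coefficients=factors.coefficients,
        guide_genes=guide_genes,
        marker_table=table_final,
        dropped_clusters=dropped,
        meta=folds.meta,
        centroids=centroids,
        params=params,
    )


def fit_udon(folds: FoldMatrix, k: int, params: UdonParams = UdonParams(),
             guide_genes: list | None = None) -> UdonModel:
    """Guide-gene selection + sparse NMF + marker validation at a fixed k."""
    if guide_genes is None:
        guide_genes = select_guide_genes(folds, params)
    factors = snmf_factorize(folds.shifted.loc[guide_genes], k, params)
    return finalize_clusters(factors, folds, params, guide_genes=guide_genes)


def sweep_resolution(folds: FoldMatrix, params: UdonParams = UdonParams()) -> UdonModel:
    """Fit every k in ``params.k_values`` and keep the stable resolution.

    Chosen k: the smallest whose marker-validated cluster count is within
    ``stability_margin`` of the next larger k's count; if no k qualifies,
    the largest tested k.  The per-k report is attached to the model.
    """
    ks = sorted(set(params.k_values))
    if len(ks) < 2:
        raise InputError("resolution sweep needs >= 2 k values")
    if ks[-1] >= folds.raw.shape[1]:
        raise InputError(
            f"largest k ({ks[-1]}) must be below the number of pseudobulk columns "
            f"({folds.raw.shape[1]})"
        )
    guide_genes = select_guide_genes(folds, params)
    models: dict[int, UdonModel | None] = {}
    counts: dict[int, int] = {}
    for k in ks:
        try:
            model = fit_udon(folds, k, params, guide_genes=guide_genes)
            models[k] = model
            counts[k] = len(model.clusters())
        except UdonError as exc:
            logger.warning("k=%d produced no marker-supported clusters (%s)", k, exc)
            models[k] = None
            counts[k] = 0

    chosen = ks[-1]
    for a, b in zip(ks, ks[1:]):
        if models[a] is not None and abs(counts[a] - counts[b]) <= params.stability_margin:
            chosen = a
            break
    if models[chosen] is None:
        candidates = [k for k in ks if models[k] is not None]
        if not candidates:
            raise UdonError("no marker-supported structure at any tested resolution")
        chosen = candidates[0]
    report = pd.DataFrame({
        "k": ks,
        "final_clusters": [counts[k] for k in ks],
        "chosen": [k == chosen for k in ks],
    })
    model = models[chosen]
    model.per_k_report = report
    return model


# ----------------------------------------------------------------------
def annotate_cluster_pathways(model: UdonModel, gene_sets: dict,
                              background_genes=None, top_n: int = 10) -> pd.DataFrame:
    """One-sided over-representation of cluster markers in gene sets.

    Hypergeometric upper-tail test of each cluster's marker genes against
    each gene set, over the background of analyzed genes that appear in the
    collection's universe; BH adjustment within each cluster.  Returns the
    ``top_n`` sets per cluster by p-value.
    """
    if not gene_sets:
        raise InputError("gene set collection is empty")
    if background_genes is None:
        background_genes = model.basis.index
    universe = set().union(*gene_sets.values())
    bg = [g for g in background_genes if g in universe]
    N = len(bg)
    if N == 0:
        raise InputError("no overlap between analyzed genes and the gene-set universe")
    bg_set = set(bg)

    rows = []
    for cluster in model.clusters():
        markers = [g for g in model.marker_table.markers_of(cluster) if g in bg_set]
        n_mark = len(markers)
        if n_mark == 0:
            continue
        mset = set(markers)
        for name, members in gene_sets.items():
            K = len(members & bg_set)
            if K == 0:
                continue
            x = len(mset & members)
            p = float(stats.hypergeom.sf(x - 1, N, K, n_mark))
            rows.append({"cluster": cluster, "gene_set": name, "overlap": x,
                         "set_size": K, "n_markers": n_mark, "p_value": p})
    report = pd.DataFrame(rows, columns=["cluster", "gene_set", "overlap", "set_size",
                                         "n_markers", "p_value"])
    if report.empty:
        return report.assign(fdr_adjusted_p=pd.Series(dtype=float))
    report["fdr_adjusted_p"] = np.nan
    for cluster, idx in report.groupby("cluster").groups.items():
        report.loc[idx, "fdr_adjusted_p"] = multipletests(
            report.loc[idx, "p_value"], method="fdr_bh")[1]
    report = report.sort_values(["cluster", "p_value", "gene_set"], kind="mergesort")
    return report.groupby("cluster", group_keys=False).head(top_n).reset_index(drop=True)
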