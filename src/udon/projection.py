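"""Projection of new cohorts onto an existing cluster model.

Each final cluster is summarized by the mean shifted-fold vector of its
member columns over the model's marker genes (a centroid).  A new cohort's
fold profiles — computed against the new cohort's OWN controls — are then
assigned to the best-correlated centroid, or left unassigned below a
correlation floor.  A joint 2-D embedding is provided for visualization
only; nothing downstream consumes its coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import UdonModel
from .errors import InputError
from .pseudobulk import FoldMatrix

MIN_SHARED_DEFAULT = 20


@dataclass
class ClusterCentroids:
    """Per-cluster mean shifted-fold vectors over marker genes."""

    values: pd.DataFrame  # marker genes x clusters

    @classmethod
    def from_model(cls, model: UdonModel) -> "ClusterCentroids":
        if model.centroids.empty:
            raise InputError("model has no centroids (no marker genes retained)")
        return cls(values=model.centroids)

    @property
    def marker_genes(self) -> pd.Index:
        return self.values.index

    @property
    def clusters(self) -> list:
        return list(self.values.columns)


def project_labels(model: UdonModel, new_folds: FoldMatrix, min_r: float = 0.2,
                   min_shared: int = MIN_SHARED_DEFAULT) -> pd.DataFrame:
    """Assign new fold columns to the model's clusters by centroid correlation.

    Returns a table (indexed by new column) with ``projected_cluster``
    ("unassigned" when the best Pearson r over shared marker genes falls
    below ``min_r``) and ``correlation``.  Deterministic and independent of
    column order.
    """
    centroids = ClusterCentroids.from_model(model)
    shared = centroids.marker_genes.intersection(new_folds.genes)
    if len(shared) < min_shared:
        raise InputError(
            f"only {len(shared)} marker genes shared with the new cohort "
            f"(need >= {min_shared}); check gene identifier conventions"
        )
    C = centroids.values.loc[shared].to_numpy(dtype=float)   # genes x clusters
    X = new_folds.shifted.loc[shared].to_numpy(dtype=float)  # genes x new columns

    def _standardize(A):
        mu = A.mean(axis=0, keepdims=True)
        sd = A.std(axis=0, keepdims=True)
        sd[sd == 0] = np.nan
        return (A - mu) / sd

    R = _standardize(X).T @ _standardize(C) / len(shared)  # columns x clusters
    R = np.nan_to_num(R, nan=-np.inf)
    best = np.argmax(R, axis=1)
    best_r = R[np.arange(R.shape[0]), best]
    assigned = np.where(best_r >= min_r,
                        np.asarray(centroids.clusters, dtype=object)[best], "unassigned")
    return pd.DataFrame(
        {"projected_cluster": assigned, "correlation": np.where(np.isfinite(best_r), best_r, np.nan)},
        index=new_folds.columns,
    )


def joint_embed(fold_sets: list[FoldMatrix], gene_space, seed: int = 0,
                n_neighbors: int = 15, min_dist: float = 0.1) -> pd.DataFrame:
    """2-D neighbor embedding of several cohorts in a shared gene space.

    The first fold matrix is the reference: the embedding is fitted on it
    and the remaining cohorts are transformed into the same coordinates.
    Byte-identical columns are embedded once and share coordinates (the
    optimizer would otherwise jitter exact duplicates apart).
    Visualization plumbing only.
    """
    import umap  # deferred: slow import

    gene_space = pd.Index(gene_space)
    if len(gene_space) == 0:
        raise InputError("gene space for the joint embedding is empty")
    for fm in fold_sets:
        missing = gene_space.difference(fm.genes)
        if len(missing):
            raise InputError(f"fold matrix lacks {len(missing)} genes of the embedding space")

    def _embed_unique(fit_or_transform, data):
        uniq, inverse = np.unique(data, axis=0, return_inverse=True)
        return fit_or_transform(uniq)[inverse]

    reference = fold_sets[0].shifted.loc[gene_space].to_numpy(dtype=float).T
    n_uniq_ref = np.unique(reference, axis=0).shape[0]
    n_neighbors = min(n_neighbors, max(2, n_uniq_ref - 1))
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
                        random_state=seed)
    coords = [_embed_unique(reducer.fit_transform, reference)]
    for fm in fold_sets[1:]:
        coords.append(_embed_unique(reducer.transform,
                                    fm.shifted.loc[gene_space].to_numpy(dtype=float).T))
    frames = []
    for i, (fm, xy) in enumerate(zip(fold_sets, coords)):
        frames.append(pd.DataFrame({"cohort": i, "x": xy[:, 0], "y": xy[:, 1]},
                                   index=fm.columns))
    return pd.concat(frames)
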