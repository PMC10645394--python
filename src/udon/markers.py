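"""Marker gene assignment by cluster-template correlation (MarkerFinder).

Each cluster is encoded as a 1/0 membership indicator over the matrix
columns.  A gene is assigned to the cluster whose indicator its expression
row best correlates with (Pearson), and retained as a *unique* marker when
that best correlation reaches the cutoff.  Because a gene is assigned to at
most one cluster, the per-cluster marker sets are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass
class MarkerTable:
    """Ranked unique markers per cluster.

    ``df`` has columns gene, cluster, pearson_r, rank (1-based, descending
    r within cluster, ties broken by gene identifier).
    """

    df: pd.DataFrame
    cutoff: float

    def markers_of(self, cluster) -> list[str]:
        sub = self.df[self.df["cluster"] == cluster]
        return list(sub.sort_values("rank")["gene"])

    def clusters(self) -> list:
        return sorted(self.df["cluster"].unique())

    def relabel(self, mapping: dict) -> "MarkerTable":
        df = self.df.copy()
        df["cluster"] = df["cluster"].map(lambda c: mapping.get(c, c))
        return MarkerTable(df=df, cutoff=self.cutoff)


def marker_finder(matrix: pd.DataFrame, labels: pd.Series, cutoff: float = 0.2) -> MarkerTable:
    """Assign genes to clusters by indicator-template correlation.

    Parameters
    ----------
    matrix
        genes x columns matrix (fold profiles).  Correlation with a fixed
        template is invariant to adding a per-gene constant, so raw and
        nonnegative-shifted folds give identical results.
    labels
        column -> cluster label; every matrix column must be labeled.
    cutoff
        minimum best-template Pearson r for a gene to be retained.
    """
    if not set(matrix.columns) <= set(labels.index):
        raise InputError("every matrix column must have a cluster label")
    labels = labels.loc[matrix.columns]
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise InputError("marker finding needs >= 2 clusters (templates are degenerate otherwise)")

    X = matrix.to_numpy(dtype=float)
    n = X.shape[1]
    # standardize gene rows; zero-variance rows are excluded (their
    # correlation with any template is undefined)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    nonconst = sd[:, 0] > 0
    n_dropped = int((~nonconst).sum())
    if n_dropped:
        logger.info("marker_finder: excluded %d constant gene rows", n_dropped)
    Z = (X[nonconst] - mu[nonconst]) / sd[nonconst]

    T = np.stack([(labels.to_numpy() == c).astype(float) for c in clusters])  # k x n
    tmu = T.mean(axis=1, keepdims=True)
    tsd = T.std(axis=1, keepdims=True)
    if (tsd == 0).any():
        raise InputError("a cluster spans all or none of the columns; templates are constant")
    Tz = (T - tmu) / tsd

    R = Z @ Tz.T / n  # genes x k Pearson correlations
    best = np.argmax(R, axis=1)  # ties -> first (smaller cluster label, sorted order)
    best_r = R[np.arange(R.shape[0]), best]

    genes = matrix.index[nonconst]
    keep = best_r >= cutoff
    df = pd.DataFrame({
        "gene": genes[keep],
        "cluster": [clusters[i] for i in best[keep]],
        "pearson_r": best_r[keep],
    })
    df = df.sort_values(["cluster", "pearson_r", "gene"],
                        ascending=[True, False, True], kind="mergesort")
    df["rank"] = df.groupby("cluster").cumcount() + 1
    return MarkerTable(df=df.reset_index(drop=True), cutoff=cutoff)


def top_markers(table: MarkerTable, n: int = 10) -> dict:
    """First ``min(n, available)`` markers per cluster, by rank."""
    if n < 0:
        raise InputError("n must be nonnegative")
    out: dict = {}
    for cluster in table.clusters():
        out[cluster] = table.markers_of(cluster)[:n]
    return out
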