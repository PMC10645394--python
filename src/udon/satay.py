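"""Association of clusters with binary clinical covariates (SATAY-UDON).

For every (cluster, cell type, covariate) triple a 2x2 contingency table of
nonredundant sample/cell-type memberships is assembled and tested for
positive enrichment: a one-sided Fisher exact test by default, or a
Cochran–Mantel–Haenszel test stratified on a user-named confounder.
P-values are Benjamini–Hochberg adjusted within each covariate family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CovariateTable:
    """Per-sample binary covariates, thresholded upstream by the user.

    ``values``: samples x covariates with entries 1, 0 or NaN (missing).
    ``strata``: optional sample -> stratum label for confounder-adjusted
    testing (e.g. age group, sex).
    """

    values: pd.DataFrame
    strata: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise InputError("covariate table needs at least one covariate column")
        arr = self.values.to_numpy(dtype=float)
        ok = np.isnan(arr) | (arr == 0) | (arr == 1)
        if not ok.all():
            bad = self.values.columns[(~ok).any(axis=0)]
            raise InputError(
                f"covariates must be binary (1/0/NA); non-binary values in {list(bad)} — "
                "threshold continuous measurements before loading"
            )

    @property
    def covariates(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class Contingency2x2:
    """Counts for one (cluster, cell type, covariate) table.

    q: covariate-positive members of the cluster; r: positive non-members;
    s: negative members; t: negative non-members.
    """

    q: int
    r: int
    s: int
    t: int

    def __post_init__(self):
        if min(self.q, self.r, self.s, self.t) < 0:
            raise InputError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.q + self.r + self.s + self.t

    def as_array(self) -> np.ndarray:
        return np.array([[self.q, self.r], [self.s, self.t]], dtype=int)

    def odds_ratio(self) -> float:
        num, den = self.q * self.t, self.r * self.s
        if den == 0:
            return float("nan") if num == 0 else float("inf")
        return num / den


@dataclass
class AssociationResult:
    cluster: str
    cell_type: str
    covariate: str
    test: str                      # "fisher" or "cmh"
    p_value: float
    odds_ratio: float
    contingency: object            # Contingency2x2 or list of (stratum, Contingency2x2)
    fdr_adjusted_p: float = float("nan")
    significant_raw: bool = False
    significant_fdr: bool = False
    untestable: bool = False
    note: str = ""


# ----------------------------------------------------------------------
def fisher_one_sided(t: Contingency2x2) -> tuple[float, float]:
    """Upper-tail Fisher exact p (positive enrichment) and odds ratio.

    p = P(X >= q) for hypergeometric X with the table's margins fixed;
    OR = qt/rs with 0/0 undefined (NaN) and x/0 infinite.
    """
    if t.n == 0:
        return 1.0, float("nan")
    p = float(stats.fisher_exact(t.as_array(), alternative="greater")[1])
    return min(p, 1.0), t.odds_ratio()


def cmh_test(strata: list[Contingency2x2], *, min_stratum_n: int = 2,
             correction: bool = False) -> tuple[float, float, list[Contingency2x2]]:
    """One-sided CMH p and Mantel–Haenszel odds ratio across strata.

    Strata with fewer than ``min_stratum_n`` samples are dropped (logged).
    The chi-square p is halved in the positive direction (MH OR > 1), else
    reflected, matching the one-sided enrichment alternative.  Returns
    (p, MH odds ratio, retained strata); p is NaN when untestable.
    """
    if not strata:
        raise InputError("CMH needs at least one stratum")
    kept = [t for t in strata if t.n >= min_stratum_n]
    if len(kept) < len(strata):
        logger.info("cmh_test: dropped %d strata below %d samples",
                    len(strata) - len(kept), min_stratum_n)
    if not kept:
        return float("nan"), float("nan"), kept

    if len(kept) == 1:  # /n cancels; keep integer arithmetic exact
        num, den = kept[0].q * kept[0].t, kept[0].r * kept[0].s
    else:
        num = sum(t.q * t.t / t.n for t in kept)
        den = sum(t.r * t.s / t.n for t in kept)
    if den == 0:
        mh_or = float("nan") if num == 0 else float("inf")
    else:
        mh_or = num / den

    tables = np.stack([t.as_array() for t in kept], axis=-1)
    st = StratifiedTable(tables.astype(float))
    try:
        res = st.test_null_odds(correction=correction)
        p_two = float(res.pvalue)
    except Exception:  # degenerate margins (zero variance in every stratum)
        return float("nan"), mh_or, kept
    if not np.isfinite(p_two):
        return float("nan"), mh_or, kept
    p_one = p_two / 2 if (np.isinf(mh_or) or (np.isfinite(mh_or) and mh_or > 1)) else 1 - p_two / 2
    return float(min(max(p_one, 0.0), 1.0)), mh_or, kept


def bh_adjust(p_values: pd.Series, families: pd.Series) -> pd.Series:
    """Step-up Benjamini–Hochberg applied separately within each family.

    ``families`` gives the covariate name per p-value; adding a covariate
    therefore never changes the adjusted values of existing covariates.
    """
    if not p_values.index.equals(families.index):
        raise InputError("p-values and family labels must share an index")
    adjusted = pd.Series(np.nan, index=p_values.index, dtype=float)
    for _, idx in families.groupby(families).groups.items():
        ps = p_values.loc[idx]
        valid = ps.index[ps.notna()]
        if len(valid):
            adjusted.loc[valid] = multipletests(ps.loc[valid], method="fdr_bh")[1]
    return adjusted


# ----------------------------------------------------------------------
def _scored_labels(labels: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "cell_type", "cluster"}
    if not required <= set(labels.columns):
        raise InputError(f"label table must have columns {sorted(required)}")
    return labels


def build_contingencies(labels: pd.DataFrame, covariates: CovariateTable,
                        dedup: bool = True) -> list[tuple[str, str, str, Contingency2x2]]:
    """One 2x2 table per (cluster, cell type, covariate).

    ``labels`` is the model's assignment table (pseudobulk column ->
    sample, cell_type, cluster).  Counts are pseudobulks of the given cell
    type, split by cluster membership and covariate status.  With ``dedup``
    (the default) each sample contributes at most one pseudobulk to each
    membership cell, the nonredundant-donor convention.  Samples with a
    missing covariate value are excluded from that covariate's tables only.
    Unassigned columns never form a cluster of their own but do count as
    out-of-cluster pseudobulks of their cell type.
    """
    scored = _scored_labels(labels)
    unknown = set(scored["sample"]) - set(covariates.values.index)
    if unknown:
        raise InputError(f"samples missing from covariate table: {sorted(unknown)}")

    out = []
    for cell_type, ct_rows in scored.groupby("cell_type", sort=True):
        clusters = [c for c in ct_rows["cluster"].unique() if c != UNASSIGNED]
        for cluster in sorted(clusters, key=str):
            in_rows = ct_rows[ct_rows["cluster"] == cluster]
            out_rows = ct_rows[ct_rows["cluster"] != cluster]
            for cov in covariates.covariates:
                status = covariates.values[cov]
                q = _count(in_rows, status, 1, dedup)
                s = _count(in_rows, status, 0, dedup)
                r = _count(out_rows, status, 1, dedup)
                t = _count(out_rows, status, 0, dedup)
                out.append((cluster, cell_type, cov, Contingency2x2(q=q, r=r, s=s, t=t)))
    return out


def _count(rows: pd.DataFrame, status: pd.Series, value: int, dedup: bool) -> int:
    samples = rows["sample"]
    mask = samples.map(status) == value
    if dedup:
        return int(samples[mask].nunique())
    return int(mask.sum())


def run_satay(labels: pd.DataFrame, covariates: CovariateTable, *,
              min_positive: int = 4, alpha: float = 0.1, fdr_alpha: float = 0.1,
              confounder: bool = False, min_stratum_n: int = 2,
              dedup: bool = True, correction: bool = False) -> pd.DataFrame:
    """Full association scan of clusters against binary covariates.

    Fisher tests require q >= ``min_positive`` covariate-positive samples
    in the cluster; with ``confounder=True`` the covariate table's
    ``strata`` drive per-stratum CMH tables gated at ``min_stratum_n``
    samples each.  Returns a tidy table with raw p, per-covariate
    BH-adjusted p and both significance flags.
    """
    if not 0 < alpha <= 1 or not 0 < fdr_alpha <= 1:
        raise InputError("alpha and fdr_alpha must lie in (0, 1]")
    if confounder and covariates.strata is None:
        raise InputError("confounder-adjusted testing requires a strata column")

    results: list[AssociationResult] = []
    if confounder:
        strata_labels = covariates.strata
        scored = _scored_labels(labels)
        missing = set(scored["sample"]) - set(strata_labels.index)
        if missing:
            raise InputError(f"samples missing a stratum label: {sorted(missing)}")
        triples: dict[tuple, list] = {}
        for stratum in sorted(strata_labels.dropna().unique(), key=str):
            sub_samples = set(strata_labels.index[strata_labels == stratum])
            sub_labels = labels[labels["sample"].isin(sub_samples)]
            if sub_labels.empty:
                continue
            sub_cov = CovariateTable(
                values=covariates.values.loc[covariates.values.index.isin(sub_samples)])
            for cluster, cell_type, cov, tab in build_contingencies(sub_labels, sub_cov, dedup):
                triples.setdefault((cluster, cell_type, cov), []).append((stratum, tab))
        for (cluster, cell_type, cov), strata in sorted(triples.items(), key=str):
            p, mh_or, kept = cmh_test([t for _, t in strata],
                                      min_stratum_n=min_stratum_n, correction=correction)
            res = AssociationResult(
                cluster=cluster, cell_type=cell_type, covariate=cov, test="cmh",
                p_value=p, odds_ratio=mh_or, contingency=strata,
                untestable=not (p == p),  # NaN p -> untestable
            )
            if not kept:
                res.note = "all strata below the per-stratum sample floor"
            results.append(res)
    else:
        for cluster, cell_type, cov, tab in build_contingencies(labels, covariates, dedup):
            if tab.q < min_positive:
                continue
            p, odds = fisher_one_sided(tab)
            results.append(AssociationResult(
                cluster=cluster, cell_type=cell_type, covariate=cov, test="fisher",
                p_value=p, odds_ratio=odds, contingency=tab,
            ))

    df = results_frame(results)
    if df.empty:
        return df
    df["fdr_adjusted_p"] = bh_adjust(df["p_value"], df["covariate"])
    df["significant_raw"] = df["p_value"] < alpha
    df["significant_fdr"] = df["fdr_adjusted_p"] < fdr_alpha
    return df


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = ["cluster", "cell_type", "covariate", "test", "p_value", "odds_ratio",
            "fdr_adjusted_p", "significant_raw", "significant_fdr", "untestable",
            "q", "r", "s", "t", "note"]
    rows = []
    for res in results:
        if isinstance(res.contingency, Contingency2x2):
            q, r, s, t = (res.contingency.q, res.contingency.r,
                          res.contingency.s, res.contingency.t)
        else:
            tabs = [tab for _, tab in res.contingency]
            q, r, s, t = (sum(x.q for x in tabs), sum(x.r for x in tabs),
                          sum(x.s for x in tabs), sum(x.t for x in tabs))
        rows.append({
            "cluster": res.cluster, "cell_type": res.cell_type, "covariate": res.covariate,
            "test": res.test, "p_value": res.p_value, "odds_ratio": res.odds_ratio,
            "fdr_adjusted_p": res.fdr_adjusted_p, "significant_raw": res.significant_raw,
            "significant_fdr": res.significant_fdr, "untestable": res.untestable,
            "q": q, "r": r, "s": s, "t": t, "note": res.note,
        })
    return pd.DataFrame(rows, columns=cols)


def dot_plot_export(results: pd.DataFrame) -> pd.DataFrame:
    """Tidy (cluster x covariate) export for dot-plot visualization."""
    if results.empty:
        return pd.DataFrame(columns=["cluster", "covariate", "min_p", "min_fdr_p",
                                     "best_odds_ratio", "cell_types"])
    rows = []
    for (cluster, cov), grp in results.groupby(["cluster", "covariate"], sort=True):
        best = grp.loc[grp["p_value"].idxmin()] if grp["p_value"].notna().any() else None
        rows.append({
            "cluster": cluster, "covariate": cov,
            "min_p": grp["p_value"].min(),
            "min_fdr_p": grp["fdr_adjusted_p"].min(),
            "best_odds_ratio": best["odds_ratio"] if best is not None else float("nan"),
            "cell_types": ",".join(sorted(grp.loc[grp["significant_raw"], "cell_type"])),
        })
    return pd.DataFrame(rows)
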