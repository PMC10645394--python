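"""Shared fixtures: tiny hand-built cohorts and a small recovered model.

Everything is generated programmatically; statistical fixtures use reduced
gene/cell counts so the whole suite stays fast, while full-scale study
conditions are exercised in the acceptance tests.
"""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.exceptions import ConvergenceWarning

from udon.cohort import CellCohort
from udon.clustering import UdonParams, sweep_resolution
from udon.pseudobulk import (aggregate_control_reference, compute_pseudobulks,
                             fold_differentials)
from udon.simulate import default_spec, simulate_cohort

warnings.filterwarnings("ignore", category=ConvergenceWarning)

SMALL_COHORT_KW = dict(n_genes=400, cells_per_type_per_sample=(15, 30))


def build_cohort(expr: dict, cell_meta: list, sample_meta: dict) -> CellCohort:
    """Hand-rolled cohort from explicit dicts.

    expr: gene -> list of per-cell values; cell_meta: list of (sample,
    cell_type) per cell; sample_meta: sample -> (condition[, batch]).
    """
    n_cells = len(cell_meta)
    cells = pd.Index([f"c{i}" for i in range(n_cells)])
    expression = pd.DataFrame({g: vals for g, vals in expr.items()}, index=cells).T
    expression.columns = cells
    obs = pd.DataFrame(
        {"sample": [m[0] for m in cell_meta], "cell_type": [m[1] for m in cell_meta]},
        index=cells)
    rows = {}
    for s, meta in sample_meta.items():
        if isinstance(meta, str):
            rows[s] = {"condition": meta}
        else:
            rows[s] = {"condition": meta[0], "batch": meta[1]}
    return CellCohort(expression=expression, obs=obs,
                      sample_meta=pd.DataFrame(rows).T)


@pytest.fixture(scope="session")
def small_separated():
    """A reduced well-separated 5-program cohort, its folds and fitted model."""
    spec = default_spec(seed=101, **SMALL_COHORT_KW)
    cohort, covariates, truth = simulate_cohort(spec)
    pb = compute_pseudobulks(cohort)
    ref = aggregate_control_reference(cohort)
    folds = fold_differentials(pb, ref)
    model = sweep_resolution(folds, UdonParams(seed=101))
    return {"spec": spec, "cohort": cohort, "covariates": covariates,
            "truth": truth, "pseudobulks": pb, "reference": ref,
            "folds": folds, "model": model}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
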