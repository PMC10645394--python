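"""Pseudobulk construction, control references and fold matrices."""

import numpy as np
import pandas as pd
import pytest

from udon.cohort import CellCohort
from udon.errors import InputError
from udon.pseudobulk import (MODE_MEAN_OF_SAMPLES, MODE_POOLED,
                             aggregate_control_reference, combine_folds,
                             compute_pseudobulks, control_self_folds,
                             fold_differentials, fold_matrix_from_raw)
from udon.simulate import default_spec, simulate_cohort

from conftest import build_cohort


def two_sample_cohort():
    # d1: 1 cell of ctA; d2: 2 cells of ctA with values 1 and 3; ctrl: 2 cells
    expr = {"gA": [5.0, 1.0, 3.0, 2.0, 2.0], "gB": [0.5, 0.0, 1.0, 0.0, 1.0]}
    cells = [("d1", "ctA"), ("d2", "ctA"), ("d2", "ctA"), ("h1", "ctA"), ("h1", "ctA")]
    samples = {"d1": "disease", "d2": "disease", "h1": "control"}
    return build_cohort(expr, cells, samples)


class TestComputePseudobulks:
    def test_single_cell_pair_equals_cell_vector(self):
        pb = compute_pseudobulks(two_sample_cohort(), min_cells=1)
        assert pb.values.loc["gA", "d1|ctA"] == 5.0
        assert pb.values.loc["gB", "d1|ctA"] == 0.5

    def test_two_cell_mean(self):
        pb = compute_pseudobulks(two_sample_cohort(), min_cells=1)
        assert pb.values.loc["gA", "d2|ctA"] == 2.0

    def test_min_cells_drops_and_reports(self):
        pb = compute_pseudobulks(two_sample_cohort(), min_cells=2)
        assert "d1|ctA" not in pb.columns
        assert pb.dropped.iloc[0].tolist() == ["d1", "ctA", 1]

    def test_all_below_floor_errors(self):
        with pytest.raises(InputError, match="no pseudobulks"):
            compute_pseudobulks(two_sample_cohort(), min_cells=10)

    def test_matches_loop_and_average_oracle(self, rng):
        # 100 cells per pair, compared against a naive per-gene python loop
        genes = [f"g{i}" for i in range(20)]
        cells, values = [], []
        for s in ("dA", "dB"):
            for ct in ("x", "y"):
                for _ in range(100):
                    cells.append((s, ct))
                    values.append(rng.normal(size=20))
        cells.append(("h", "x"))
        values.append(rng.normal(size=20))
        cohort = build_cohort(
            {g: [v[i] for v in values] for i, g in enumerate(genes)},
            cells, {"dA": "disease", "dB": "disease", "h": "control"})
        pb = compute_pseudobulks(cohort, min_cells=1)
        for col in pb.columns:
            s, ct = col.split("|")
            members = [v for (cs, cct), v in zip(cells, values) if cs == s and cct == ct]
            for i, g in enumerate(genes):
                total = 0.0
                for v in members:
                    total += v[i]
                assert abs(pb.values.loc[g, col] - total / len(members)) < 1e-10

    def test_conservation_sum_equals_n_times_mean(self, small_separated):
        cohort = small_separated["cohort"]
        pb = small_separated["pseudobulks"]
        col = pb.columns[0]
        s, ct = pb.meta.loc[col, ["sample", "cell_type"]]
        mask = (cohort.obs["sample"] == s) & (cohort.obs["cell_type"] == ct)
        total = cohort.expression.loc[:, mask.values].sum(axis=1)
        n = pb.meta.loc[col, "n_cells"]
        assert np.allclose(total, n * pb.values[col], atol=1e-8)

    def test_cell_order_invariance(self):
        cohort = two_sample_cohort()
        perm = np.array([3, 1, 4, 0, 2])
        shuffled = CellCohort(
            expression=cohort.expression.iloc[:, perm],
            obs=cohort.obs.iloc[perm],
            sample_meta=cohort.sample_meta.copy())
        a = compute_pseudobulks(cohort, min_cells=1)
        b = compute_pseudobulks(shuffled, min_cells=1)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestControlReference:
    def weighted_cohort(self):
        # h1: 1 cell all zeros; h2: 3 cells all 4.0
        expr = {"g": [0.0, 4.0, 4.0, 4.0, 1.0]}
        cells = [("h1", "ctA")] + [("h2", "ctA")] * 3 + [("d", "ctA")]
        return build_cohort(expr, cells, {"h1": "control", "h2": "control", "d": "disease"})

    def test_pooled_vs_mean_of_samples(self):
        cohort = self.weighted_cohort()
        pooled = aggregate_control_reference(cohort, min_cells=1, mode=MODE_POOLED)
        mean = aggregate_control_reference(cohort, min_cells=1, mode=MODE_MEAN_OF_SAMPLES)
        assert pooled.values[("ctA", "default")].iloc[0] == 3.0
        assert mean.values[("ctA", "default")].iloc[0] == 2.0

    def test_single_control_modes_coincide(self):
        cohort = two_sample_cohort()
        a = aggregate_control_reference(cohort, min_cells=1, mode=MODE_POOLED)
        b = aggregate_control_reference(cohort, min_cells=1, mode=MODE_MEAN_OF_SAMPLES)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_pooled_equals_total_sum_over_total_count(self, rng):
        genes = [f"g{i}" for i in range(5)]
        cells, vals = [], []
        for s, n in (("h1", 3), ("h2", 7), ("h3", 2), ("h4", 5), ("h5", 4)):
            for _ in range(n):
                cells.append((s, "ctA"))
                vals.append(rng.normal(size=5))
        cells.append(("d", "ctA"))
        vals.append(rng.normal(size=5))
        meta = {f"h{i}": "control" for i in range(1, 6)}
        meta["d"] = "disease"
        cohort = build_cohort({g: [v[i] for v in vals] for i, g in enumerate(genes)},
                              cells, meta)
        ref = aggregate_control_reference(cohort, min_cells=1, mode=MODE_POOLED)
        ctrl_vals = np.array(vals[:-1])
        assert np.allclose(ref.values[("ctA", "default")],
                           ctrl_vals.sum(axis=0) / len(ctrl_vals))

    def test_no_controls_errors(self):
        expr = {"g": [1.0, 1.0]}
        with pytest.raises(InputError, match="batch"):
            build_cohort(expr, [("d", "ctA"), ("d", "ctA")], {"d": "disease"})


class TestFoldDifferentials:
    def test_self_fold_is_zero(self):
        cohort = two_sample_cohort()
        pb = compute_pseudobulks(cohort, min_cells=1, conditions=("control",))
        ref = aggregate_control_reference(cohort, min_cells=1)
        folds = fold_differentials(pb, ref)
        assert np.allclose(folds.raw.to_numpy(), 0.0)

    def test_shift_per_gene_minimum(self):
        raw = pd.DataFrame([[-2.0, 1.0], [0.0, 3.0], [1.0, 2.0]],
                           index=["a", "b", "c"], columns=["x|ct", "y|ct"])
        meta = pd.DataFrame({"sample": ["x", "y"], "cell_type": "ct"}, index=raw.columns)
        fm = fold_matrix_from_raw(raw, meta)
        assert fm.gene_min.tolist() == [-2.0, 0.0, 1.0]
        assert np.allclose(fm.shifted.min(axis=1), 0.0)
        assert (fm.shifted.to_numpy() >= 0).all()

    def test_shift_matches_row_min_oracle(self, rng):
        raw = pd.DataFrame(rng.normal(size=(50, 8)),
                           index=[f"g{i}" for i in range(50)],
                           columns=[f"s{j}|ct" for j in range(8)])
        meta = pd.DataFrame({"sample": [f"s{j}" for j in range(8)], "cell_type": "ct"},
                            index=raw.columns)
        fm = fold_matrix_from_raw(raw, meta)
        for i in range(raw.shape[0]):
            row_min = min(raw.iloc[i])  # independent per-row scan
            assert np.allclose(fm.shifted.iloc[i], raw.iloc[i] - row_min)

    def test_shift_idempotent(self, small_separated):
        folds = small_separated["folds"]
        again = fold_matrix_from_raw(folds.shifted, folds.meta)
        assert np.allclose(again.shifted.to_numpy(), folds.shifted.to_numpy(), atol=1e-12)

    def test_orphan_cell_type_errors(self):
        cohort = two_sample_cohort()
        pb = compute_pseudobulks(cohort, min_cells=1)
        ref = aggregate_control_reference(cohort, min_cells=1)
        pb.meta.loc[:, "cell_type"] = "ctMissing"
        with pytest.raises(InputError, match="reference"):
            fold_differentials(pb, ref)

    def test_scale_equivariance(self):
        # adding kappa to all disease cells of one gene moves its folds by kappa
        cohort = two_sample_cohort()
        pb = compute_pseudobulks(cohort, min_cells=1)
        ref = aggregate_control_reference(cohort, min_cells=1)
        base = fold_differentials(pb, ref)

        kappa = 1.7
        expr = cohort.expression.copy()
        disease_cells = cohort.obs["sample"].isin(["d1", "d2"]).values
        expr.loc["gA", disease_cells] += kappa
        shifted_cohort = CellCohort(expression=expr, obs=cohort.obs,
                                    sample_meta=cohort.sample_meta.copy())
        pb2 = compute_pseudobulks(shifted_cohort, min_cells=1)
        folds2 = fold_differentials(pb2, aggregate_control_reference(shifted_cohort, min_cells=1))
        assert np.allclose(folds2.raw.loc["gA"], base.raw.loc["gA"] + kappa)
        assert np.allclose(folds2.raw.loc["gB"], base.raw.loc["gB"])


class TestBatchHandling:
    def batch_cohort(self, ctrl_b_value=0.0):
        expr = {"g": [1.0, 2.0, 0.0, ctrl_b_value]}
        cells = [("dA", "ct"), ("dB", "ct"), ("hA", "ct"), ("hB", "ct")]
        samples = {"dA": ("disease", "A"), "dB": ("disease", "B"),
                   "hA": ("control", "A"), "hB": ("control", "B")}
        return build_cohort(expr, cells, samples)

    def test_disease_sample_uses_own_batch_reference(self):
        cohort = self.batch_cohort(ctrl_b_value=10.0)
        pb = compute_pseudobulks(cohort, min_cells=1)
        folds = fold_differentials(pb, aggregate_control_reference(cohort, min_cells=1))
        assert folds.raw.loc["g", "dA|ct"] == 1.0      # 1 - 0
        assert folds.raw.loc["g", "dB|ct"] == -8.0     # 2 - 10

    def test_batch_isolation(self):
        # changing batch-B control cells leaves batch-A folds untouched
        a = self.batch_cohort(ctrl_b_value=0.0)
        b = self.batch_cohort(ctrl_b_value=99.0)
        for cohort in (a, b):
            pb = compute_pseudobulks(cohort, min_cells=1)
            ref = aggregate_control_reference(cohort, min_cells=1)
            fold = fold_differentials(pb, ref)
            assert fold.raw.loc["g", "dA|ct"] == 1.0


class TestControlSelfFolds:
    def test_identical_controls_give_zero(self):
        expr = {"g": [2.0, 2.0, 1.0]}
        cells = [("h1", "ct"), ("h2", "ct"), ("d", "ct")]
        cohort = build_cohort(expr, cells,
                              {"h1": "control", "h2": "control", "d": "disease"})
        folds = control_self_folds(cohort, min_cells=1)
        assert np.allclose(folds.raw.to_numpy(), 0.0)
        assert (folds.meta["condition"] == "control").all()

    def test_single_control_errors(self):
        cohort = two_sample_cohort()
        with pytest.raises(InputError, match="2 control"):
            control_self_folds(cohort, min_cells=1)

    def test_pooled_mode_self_folds_mean_zero(self, rng):
        # equal cell counts: deviations from the pooled average sum to zero
        genes = ["g1", "g2"]
        cells, vals = [], []
        for s in [f"h{i}" for i in range(10)]:
            for _ in range(3):
                cells.append((s, "ct"))
                vals.append(rng.normal(size=2))
        cells.append(("d", "ct"))
        vals.append(rng.normal(size=2))
        meta = {f"h{i}": "control" for i in range(10)}
        meta["d"] = "disease"
        cohort = build_cohort({g: [v[i] for v in vals] for i, g in enumerate(genes)},
                              cells, meta)
        folds = control_self_folds(cohort, min_cells=1, mode=MODE_POOLED)
        assert np.allclose(folds.raw.mean(axis=1), 0.0, atol=1e-10)

    def test_matches_two_step_oracle(self, rng):
        genes = [f"g{i}" for i in range(4)]
        cells, vals = [], []
        counts = {f"h{i}": int(rng.integers(2, 6)) for i in range(10)}
        for s, n in counts.items():
            for _ in range(n):
                cells.append((s, "ct"))
                vals.append(rng.normal(size=4))
        cells.append(("d", "ct"))
        vals.append(rng.normal(size=4))
        meta = {s: "control" for s in counts}
        meta["d"] = "disease"
        cohort = build_cohort({g: [v[i] for v in vals] for i, g in enumerate(genes)},
                              cells, meta)
        folds = control_self_folds(cohort, min_cells=1, mode=MODE_POOLED)
        # oracle: per-sample mean minus pooled mean, via explicit loops
        ctrl_vals = np.array(vals[:-1])
        pooled = ctrl_vals.mean(axis=0)
        start = 0
        for s, n in counts.items():
            sample_mean = ctrl_vals[start:start + n].mean(axis=0)
            start += n
            assert np.allclose(folds.raw[f"{s}|ct"], sample_mean - pooled, atol=1e-10)


def test_combined_folds_share_one_shift(small_separated):
    cohort = small_separated["cohort"]
    folds = small_separated["folds"]
    ctrl = control_self_folds(cohort)
    both = combine_folds([folds, ctrl])
    assert both.raw.shape[1] == folds.raw.shape[1] + ctrl.raw.shape[1]
    assert np.allclose(both.shifted.min(axis=1), 0.0, atol=1e-12)
    assert (both.shifted.to_numpy() >= 0).all()


def test_simulated_effect_recovered_through_pipeline():
    # planted log-fold of 1.5 comes back through pseudobulk -> fold
    spec = default_spec(seed=7, n_genes=300)
    cohort, _, truth = simulate_cohort(spec)
    pb = compute_pseudobulks(cohort)
    folds = fold_differentials(pb, aggregate_control_reference(cohort))
    effects = []
    for p, genes in truth.program_genes.items():
        cols = [c for c in truth.program_columns[p] if c in folds.raw.columns]
        effects.append(folds.raw.loc[genes, cols].to_numpy().mean())
    assert abs(np.mean(effects) - 1.5) < 0.15
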