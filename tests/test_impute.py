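import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cranioshift.impute import (RegressionFormula, enumerate_formulae,
                                fit_all_formulae, fit_formula, formula_weights,
                                impute_cell, impute_table, resample_imputations)

import oracles
from conftest import make_table


class TestEnumerate:
    def test_three_variables(self):
        subsets = enumerate_formulae(["A", "B", "C"], "A")
        assert subsets == [("B",), ("C",), ("B", "C")]

    def test_seven_variables_gives_63(self):
        codes = [f"V{i}" for i in range(7)]
        assert len(enumerate_formulae(codes, "V0")) == 63

    def test_two_variables_single_subset(self):
        assert enumerate_formulae(["A", "B"], "A") == [("B",)]

    def test_ordering_by_size_then_position(self):
        subsets = enumerate_formulae(["A", "B", "C", "D"], "C")
        assert subsets[:3] == [("A",), ("B",), ("D",)]
        assert subsets[3:6] == [("A", "B"), ("A", "D"), ("B", "D")]
        assert subsets[-1] == ("A", "B", "D")

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            enumerate_formulae(["A", "B"], "Z")


class TestFitFormula:
    def test_exact_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = np.column_stack([2 * x + 1, x])
        f = fit_formula(vals, ["Y", "X"], "Y", ["X"], sigma_floor=1e-8)
        assert f.intercept == pytest.approx(1.0, abs=1e-9)
        assert f.coefficients[0] == pytest.approx(2.0, abs=1e-9)
        assert f.residual_sd == 1e-8  # perfect fit hits the floor
        assert f.n_cases == 5

    def test_matches_normal_equations_oracle(self, rng):
        vals = rng.normal(50, 5, size=(8, 3))
        f = fit_formula(vals, ["A", "B", "C"], "A", ["B", "C"], sigma_floor=1e-12)
        beta = oracles.ols_normal_equations(vals[:, 1:], vals[:, 0])
        assert f.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(f.coefficients, beta[1:], atol=1e-8)

    def test_residual_sd_unbiased_df(self, rng):
        vals = rng.normal(50, 5, size=(10, 2))
        f = fit_formula(vals, ["A", "B"], "A", ["B"], sigma_floor=1e-12)
        beta = oracles.ols_normal_equations(vals[:, 1:], vals[:, 0])
        resid = vals[:, 0] - (beta[0] + vals[:, 1] * beta[1])
        assert f.residual_sd == pytest.approx(np.sqrt(resid @ resid / 8), rel=1e-10)

    def test_too_few_cases_rejected(self, rng):
        vals = rng.normal(50, 5, size=(4, 4))  # 3 predictors need >= 5 rows
        assert fit_formula(vals, list("ABCD"), "A", ["B", "C", "D"], 1e-8) is None

    def test_rank_deficient_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        vals = np.column_stack([x * 3 + 1, x, 2 * x])  # collinear predictors
        assert fit_formula(vals, ["A", "B", "C"], "A", ["B", "C"], 1e-8) is None

    def test_missing_rows_excluded(self, rng):
        vals = rng.normal(50, 5, size=(10, 2))
        vals_missing = vals.copy()
        vals_missing[7:, 1] = np.nan
        f = fit_formula(vals_missing, ["A", "B"], "A", ["B"], 1e-12)
        g = fit_formula(vals[:7], ["A", "B"], "A", ["B"], 1e-12)
        assert f.n_cases == 7
        assert f.intercept == pytest.approx(g.intercept)


def _formula(sd, target="A", predictors=("B",), intercept=0.0, coefs=(1.0,),
             pidx=(1,)):
    return RegressionFormula(target=target, predictors=predictors,
                             intercept=intercept,
                             coefficients=np.array(coefs, dtype=float),
                             residual_sd=sd, n_cases=10, target_idx=0,
                             predictor_idx=pidx)


class TestWeights:
    def test_single_formula_weight_one(self):
        assert formula_weights([_formula(2.0)]) == pytest.approx([1.0])

    def test_equal_sds_split_evenly(self):
        w = formula_weights([_formula(1.5), _formula(1.5)])
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_sd_one_and_two_gives_two_thirds(self):
        w = formula_weights([_formula(1.0), _formula(2.0)])
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            formula_weights([])

    def test_weights_sum_to_one(self, rng):
        w = formula_weights([_formula(s) for s in rng.uniform(0.1, 5, size=20)])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()

    def test_scale_invariance(self, rng):
        sds = rng.uniform(0.5, 4.0, size=6)
        w_mm = formula_weights([_formula(s) for s in sds])
        w_cm = formula_weights([_formula(s / 10) for s in sds])
        np.testing.assert_allclose(w_mm, w_cm, atol=1e-12)


class TestImputeCell:
    def test_weighted_average_arithmetic(self):
        # two applicable formulae predicting 10 and 12 with weights 3:1
        f1 = _formula(1.0, intercept=10.0, coefs=(0.0,))
        f2 = _formula(3.0, intercept=12.0, coefs=(0.0,))
        row = np.array([np.nan, 5.0])
        mask = np.array([True, False])
        est, sd, prov = impute_cell(row, mask, [f1, f2])
        assert est == pytest.approx(0.75 * 10 + 0.25 * 12)
        assert sd == pytest.approx(0.75 * 1.0 + 0.25 * 3.0)
        assert [w for _, w in prov] == pytest.approx([0.75, 0.25])

    def test_inapplicable_formulae_skipped(self):
        f_ok = _formula(1.0, intercept=7.0, coefs=(0.0,), pidx=(1,))
        f_bad = _formula(0.5, predictors=("C",), pidx=(2,))
        row = np.array([np.nan, 5.0, np.nan])
        mask = np.array([True, False, True])
        est, _, prov = impute_cell(row, mask, [f_ok, f_bad])
        assert est == pytest.approx(7.0)
        assert len(prov) == 1

    def test_no_applicable_formula_names_specimen(self):
        f = _formula(1.0, pidx=(1,))
        row = np.array([np.nan, np.nan])
        mask = np.array([True, True])
        with pytest.raises(ValueError, match="SPEC-9"):
            impute_cell(row, mask, [f], specimen_id="SPEC-9")

    def test_infinite_sd_formula_negligible(self):
        f1 = _formula(1.0, intercept=10.0, coefs=(0.0,))
        f_inf = _formula(1e15, intercept=1e6, coefs=(0.0,))
        row = np.array([np.nan, 5.0])
        mask = np.array([True, False])
        est_with, _, _ = impute_cell(row, mask, [f1, f_inf])
        est_without, _, _ = impute_cell(row, mask, [f1])
        assert abs(est_with - est_without) < 1e-6


class TestImputeTable:
    def test_complete_table_untouched(self, small_complete_table):
        out = impute_table(small_complete_table)
        np.testing.assert_array_equal(out.values, small_complete_table.values)
        assert (out.cell_sd == 0).all()
        assert out.n_imputed() == 0

    def test_observed_cells_bitwise_identical(self, rng):
        vals = np.abs(rng.normal(120, 8, size=(15, 4))) + 1
        mask = rng.random((15, 4)) < 0.15
        mask[:, 0] = False  # keep one anchor column complete
        t = make_table(vals, mask=mask)
        out = impute_table(t)
        obs = ~t.missing_mask
        np.testing.assert_array_equal(out.values[obs], t.values[obs])
        assert (out.cell_sd[obs] == 0).all()

    def test_noiseless_linear_system_recovered(self, rng):
        # columns are exact affine functions of a latent factor
        z = rng.uniform(10, 20, size=12)
        vals = np.column_stack([2 * z + 5, 3 * z + 1, z + 40])
        truth = vals.copy()
        mask = np.zeros_like(vals, dtype=bool)
        mask[2, 0] = mask[7, 2] = True
        t = make_table(vals, mask=mask)
        out = impute_table(t)
        assert out.values[2, 0] == pytest.approx(truth[2, 0], abs=1e-6)
        assert out.values[7, 2] == pytest.approx(truth[7, 2], abs=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(5):
            vals = np.abs(rng.normal(100, 10, size=(12, 4))) + 1
            mask = rng.random((12, 4)) < 0.2
            mask[mask.sum(axis=1) > 2] = False
            t = make_table(vals, mask=mask)
            out = impute_table(t)
            expected, expected_sd = oracles.brute_force_impute(t.values)
            np.testing.assert_allclose(out.values, expected, atol=1e-8)
            np.testing.assert_allclose(out.cell_sd, expected_sd, atol=1e-8)

    def test_row_order_invariance(self, rng):
        vals = np.abs(rng.normal(100, 10, size=(10, 3))) + 1
        mask = rng.random((10, 3)) < 0.2
        t = make_table(vals, mask=mask)
        out1 = impute_table(t)
        perm = rng.permutation(10)
        out2 = impute_table(t.subset_rows(perm))
        inv = np.argsort(perm)
        np.testing.assert_array_equal(out1.values, out2.values[inv])
        np.testing.assert_array_equal(out1.cell_sd, out2.cell_sd[inv])

    def test_unit_rescaling_scales_estimates_not_weights(self, rng):
        vals = np.abs(rng.normal(100, 10, size=(10, 3))) + 1
        mask = np.zeros_like(vals, dtype=bool)
        mask[3, 1] = True
        t_mm = make_table(vals, mask=mask)
        t_cm = make_table(vals / 10.0, mask=mask)
        out_mm = impute_table(t_mm)
        out_cm = impute_table(t_cm)
        assert out_cm.values[3, 1] == pytest.approx(out_mm.values[3, 1] / 10, rel=1e-9)
        sid = str(t_mm.specimen_id[3])
        code = t_mm.variable_codes[1]
        w_mm = [w for _, w in out_mm.provenance[(sid, code)]]
        w_cm = [w for _, w in out_cm.provenance[(sid, code)]]
        np.testing.assert_allclose(w_mm, w_cm, atol=1e-10)

    def test_provenance_weights_sum_to_one(self, rng):
        vals = np.abs(rng.normal(100, 10, size=(12, 4))) + 1
        mask = rng.random((12, 4)) < 0.15
        mask[mask.sum(axis=1) > 2] = False
        out = impute_table(make_table(vals, mask=mask))
        for prov in out.provenance.values():
            assert sum(w for _, w in prov) == pytest.approx(1.0, abs=1e-12)


class TestResample:
    def _imputed(self, rng, n=8, p=3, rate=0.2):
        vals = np.abs(rng.normal(100, 10, size=(n, p))) + 1
        mask = rng.random((n, p)) < rate
        mask[mask.sum(axis=1) > 1] = False
        return impute_table(make_table(vals, mask=mask))

    def test_zero_sd_draws_identical(self, small_complete_table):
        out = impute_table(small_complete_table)
        draws = resample_imputations(out, 5, seed=0)
        for d in draws:
            np.testing.assert_array_equal(d, out.values)

    def test_observed_cells_bitwise_identical_across_draws(self, rng):
        imp = self._imputed(rng)
        draws = resample_imputations(imp, 100, seed=1)
        obs = ~imp.imputed_mask
        for d in draws:
            np.testing.assert_array_equal(d[obs], imp.values[obs])

    def test_empirical_sd_matches_cell_sd(self, rng):
        imp = self._imputed(rng, n=12, rate=0.3)
        cells = np.argwhere(imp.imputed_mask)
        assert len(cells) > 0
        draws = resample_imputations(imp, 10_000, seed=2)
        for i, j in cells:
            emp = draws[:, i, j].std(ddof=1)
            assert emp == pytest.approx(imp.cell_sd[i, j], rel=0.03)

    def test_reproducible_from_seed(self, rng):
        imp = self._imputed(rng)
        d1 = resample_imputations(imp, 10, seed=3)
        d2 = resample_imputations(imp, 10, seed=3)
        np.testing.assert_array_equal(d1, d2)

    def test_mixture_mode_runs_and_centres(self, rng):
        imp = self._imputed(rng, n=20, rate=0.2)
        draws = resample_imputations(imp, 4000, seed=4, mode="mixture")
        cells = np.argwhere(imp.imputed_mask)
        i, j = cells[0]
        # mixture mean approaches the weighted-average point estimate
        assert draws[:, i, j].mean() == pytest.approx(
            imp.values[i, j], abs=4 * imp.cell_sd[i, j] / np.sqrt(4000) + 1e-9)

    def test_bad_draw_count(self, rng):
        with pytest.raises(ValueError):
            resample_imputations(self._imputed(rng), 0, seed=0)
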