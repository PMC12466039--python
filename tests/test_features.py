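"""Feature blocks, variance/correlation selection, scaling."""

import numpy as np
import pytest

from pkcascade.features import (
    FeatureMatrix,
    FeatureRecipe,
    apply_scaler,
    correlation_filter,
    fit_scaler,
    morgan_fingerprint,
    morgan_matrix,
    physchem_block,
    variance_filter,
)


def fm(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"c{i}" for i in range(matrix.shape[1])]
    return FeatureMatrix("test", matrix, names)


class TestMorgan:
    def test_methane_single_environment(self):
        # one heavy atom: only the radius-0 environment exists
        assert morgan_fingerprint("C").GetNumOnBits() == 1

    def test_deterministic_and_canonical_invariant(self):
        a = morgan_fingerprint("CCO")
        b = morgan_fingerprint("OCC")
        assert list(a.GetOnBits()) == list(b.GetOnBits())

    def test_matrix_shape_and_binary(self):
        m = morgan_matrix(["CCO", "CCN", "c1ccccc1"])
        assert m.matrix.shape == (3, 2048)
        assert set(np.unique(m.matrix)) <= {0.0, 1.0}


class TestPhyschem:
    def test_duplicate_rows_identical(self):
        blk = physchem_block(["CCO", "CCO"])
        np.testing.assert_array_equal(blk.matrix[0], blk.matrix[1])

    def test_column_count_matches_descriptor_set(self):
        from rdkit.Chem import Descriptors
        from rdkit import Chem

        expected = len(Descriptors.CalcMolDescriptors(Chem.MolFromSmiles("CCO")))
        assert physchem_block(["CCO"]).matrix.shape[1] == expected


class TestVarianceFilter:
    def test_constant_removed_balanced_bit_retained(self):
        m = fm(np.column_stack([np.ones(10), np.r_[np.zeros(5), np.ones(5)]]))
        out = variance_filter(m, 0.05)
        assert out.feature_names == ["c1"]  # variance 0.25 >= 0.05

    def test_boundary_inclusive(self):
        # variance exactly at the threshold is retained
        col = np.r_[np.zeros(19), np.ones(1)]  # var = 0.0475 < 0.05
        col2 = np.r_[np.zeros(18), np.ones(2)]  # var = 0.09
        out = variance_filter(fm(np.column_stack([col, col2])), 0.05)
        assert out.feature_names == ["c1"]

    def test_idempotent(self, rng):
        m = fm(rng.normal(size=(30, 8)) * rng.uniform(0, 2, 8))
        once = variance_filter(m, 0.5)
        twice = variance_filter(once, 0.5)
        np.testing.assert_array_equal(once.matrix, twice.matrix)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            variance_filter(FeatureMatrix("x", np.empty((0, 0)), []))


class TestCorrelationFilter:
    def test_identical_columns_second_removed(self, rng):
        x = rng.normal(size=20)
        out = correlation_filter(fm(np.column_stack([x, x, rng.normal(size=20)])))
        assert out.feature_names == ["c0", "c2"]

    def test_anticorrelated_retained_with_signed_r(self, rng):
        x = rng.normal(size=50)
        out = correlation_filter(fm(np.column_stack([x, -x])))
        assert out.feature_names == ["c0", "c1"]  # r = -1 <= 0.95
        out_abs = correlation_filter(fm(np.column_stack([x, -x])), use_abs=True)
        assert out_abs.feature_names == ["c0"]

    def test_no_retained_pair_above_threshold_brute_force(self, rng):
        # correlated blocks: verify the output property by enumeration
        base = rng.normal(size=(60, 3))
        X = np.column_stack(
            [base[:, 0], base[:, 0] + 0.01 * rng.normal(size=60), base[:, 1], base[:, 2]]
        )
        out = correlation_filter(fm(X), 0.95)
        corr = np.corrcoef(out.matrix, rowvar=False)
        off_diag = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.all(off_diag <= 0.95)

    def test_independent_columns_all_retained(self, rng):
        out = correlation_filter(fm(rng.normal(size=(1000, 6))), 0.95)
        assert out.matrix.shape[1] == 6


class TestScaler:
    def test_closed_form(self):
        out = fit_scaler(fm(np.array([[1.0], [2.0], [3.0]])))
        np.testing.assert_allclose(out.matrix[:, 0], [-1.2247448, 0, 1.2247448], atol=1e-6)

    def test_apply_to_new_row(self):
        fitted = fit_scaler(fm(np.array([[1.0, 10.0], [3.0, 30.0]])))
        new = apply_scaler(fm(np.array([[2.0, 20.0]])), fitted.scaler_state)
        np.testing.assert_allclose(new.matrix, [[0.0, 0.0]], atol=1e-12)

    def test_fitting_set_standardized(self, rng):
        out = fit_scaler(fm(rng.normal(3, 2, size=(40, 5))))
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0, atol=1e-8)
        np.testing.assert_allclose(out.matrix.std(axis=0), 1, atol=1e-8)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            fit_scaler(fm(np.ones((5, 1))))

    def test_column_mismatch_errors(self, rng):
        fitted = fit_scaler(fm(rng.normal(size=(10, 3))))
        with pytest.raises(ValueError):
            apply_scaler(fm(rng.normal(size=(2, 4))), fitted.scaler_state)


class TestRecipe:
    def test_selection_reused_and_imputation(self, human_ds):
        smiles = human_ds.std_smiles[:40]
        recipe = FeatureRecipe().fit(smiles)
        assert 0 < len(recipe.morgan_names) < 2048
        assert len(recipe.physchem_names) > 0
        out = recipe.transform(smiles[:5])
        assert out.matrix.shape == (5, len(recipe.morgan_names) + len(recipe.physchem_names))
        assert np.all(np.isfinite(out.matrix))
        # transforming unseen chemistry still yields finite features
        exotic = recipe.transform(["C1CC1", "c1ccc2c(c1)cccc2"])
        assert np.all(np.isfinite(exotic.matrix))

    def test_selected_physchem_has_no_pair_above_threshold(self, human_ds):
        smiles = human_ds.std_smiles[:60]
        recipe = FeatureRecipe().fit(smiles)
        _, phys = recipe.transform_blocks(smiles)
        corr = np.corrcoef(phys.matrix, rowvar=False)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.nanmax(off) <= 0.95 + 1e-9
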