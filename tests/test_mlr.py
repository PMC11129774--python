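import numpy as np
import pandas as pd
import pytest

from oracles import ols_normal_equations
from qualinear import (
    CollinearityError,
    DataError,
    Dataset,
    LinearModel,
    SyntheticConfig,
    encode_dummies,
    generate,
    mse,
)


def _worked_example_design(n=40, seed=0):
    """Noiseless data from the worked example's fitted coefficients."""
    ds = generate(SyntheticConfig(n=n, noise_sd=0.0, seed=seed))
    encoded, _ = encode_dummies(ds, "treatment")
    return encoded


class TestFit:
    def test_noiseless_recovery_of_known_coefficients(self):
        # y = 7.948 + 0.919*age + 25.075*A + 8.013*B exactly
        res = LinearModel.from_dataset(_worked_example_design()).fit()
        assert res.params == pytest.approx([7.948, 0.919, 25.075, 8.013], abs=1e-9)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_exact_line_through_three_points(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        res = LinearModel([1.0, 3.0, 5.0], X, ["Intercept", "x"]).fit()
        assert res.params == pytest.approx([1.0, 2.0], abs=1e-12)
        assert res.resid == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=20)
        res = LinearModel(y, X).fit()
        assert res.params == pytest.approx(ols_normal_equations(X, y), abs=1e-10)

    def test_inference_identities(self, synthetic_noisy):
        ds, _ = synthetic_noisy
        res = LinearModel.from_dataset(ds).fit()
        assert res.tvalues == pytest.approx(res.params / res.bse)
        assert res.rsquared_adj <= res.rsquared
        assert res.df_resid == res.nobs - len(res.params)
        assert ((res.pvalues >= 0) & (res.pvalues <= 1)).all()

    def test_inference_matches_statsmodels(self, synthetic_noisy):
        # cross-check SEs/t/p and R2 against an independent implementation
        sm = pytest.importorskip("statsmodels.api")
        ds, _ = synthetic_noisy
        from qualinear.data import design_matrix
        X, _ = design_matrix(ds)
        y = ds.response_values
        ref = sm.OLS(y, X).fit()
        res = LinearModel.from_dataset(ds).fit()
        assert res.params == pytest.approx(ref.params, rel=1e-10)
        assert res.bse == pytest.approx(ref.bse, rel=1e-8)
        assert res.pvalues == pytest.approx(ref.pvalues, abs=1e-10)
        assert res.rsquared == pytest.approx(ref.rsquared, rel=1e-10)
        assert res.rsquared_adj == pytest.approx(ref.rsquared_adj, rel=1e-10)

    def test_residuals_orthogonal_to_design(self, synthetic_noisy):
        ds, _ = synthetic_noisy
        model = LinearModel.from_dataset(ds)
        res = model.fit()
        scale = np.abs(model.exog).sum(axis=0) * np.abs(res.resid).max()
        assert (np.abs(model.exog.T @ res.resid) / np.maximum(scale, 1.0) < 1e-8).all()

    def test_noise_column_never_decreases_rsquared(self, synthetic_noisy, rng):
        ds, _ = synthetic_noisy
        base = LinearModel.from_dataset(ds).fit()
        from qualinear.data import design_matrix
        X, names = design_matrix(ds)
        X2 = np.column_stack([X, rng.normal(size=len(X))])
        aug = LinearModel(ds.response_values, X2, names + ["noise"]).fit()
        assert aug.rsquared >= base.rsquared - 1e-12

    def test_collinear_dummies_rejected_with_names(self):
        # intercept + all three indicators is the classic dummy trap
        n = 30
        g = np.arange(n) % 3
        X = np.column_stack([np.ones(n), g == 0, g == 1, g == 2]).astype(float)
        y = np.arange(n, dtype=float)
        with pytest.raises(CollinearityError) as exc:
            LinearModel(y, X, ["Intercept", "A", "B", "C"]).fit()
        assert exc.value.columns

    def test_underdetermined_rejected(self):
        X = np.eye(3)
        with pytest.raises(DataError):
            LinearModel([1.0, 2.0, 3.0], X).fit()


class TestPredict:
    def test_printed_equation_arithmetic(self):
        # full-precision evaluation of the published point estimates
        res = _fit_with_fixed_params([7.948, 0.919, 25.075, 8.013])
        assert res.predict([[1, 21, 1, 0]])[0] == pytest.approx(52.322)
        assert res.predict([[1, 19, 0, 0]])[0] == pytest.approx(25.409)

    def test_zero_row_returns_intercept(self):
        res = _fit_with_fixed_params([7.948, 0.919, 25.075, 8.013])
        assert res.predict([[1, 0, 0, 0]])[0] == pytest.approx(7.948)

    def test_column_mismatch_rejected(self, synthetic_noisy):
        ds, _ = synthetic_noisy
        res = LinearModel.from_dataset(ds).fit()
        with pytest.raises(DataError):
            res.predict([[1.0, 2.0]])


def _fit_with_fixed_params(beta):
    """A fit whose coefficients are exactly ``beta`` (noiseless generated data)."""
    rng = np.random.default_rng(0)
    X = np.column_stack([
        np.ones(20), rng.integers(18, 70, 20),
        rng.integers(0, 2, 20), rng.integers(0, 2, 20),
    ]).astype(float)
    y = X @ np.asarray(beta, dtype=float)
    return LinearModel(y, X, ["Intercept", "age", "A", "B"]).fit()


class TestMSE:
    def test_identical_vectors_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_small_arithmetic(self):
        assert mse([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_published_rows_arithmetic(self):
        # (3.683^2 + 3.812^2)/2 on the first two comparison rows
        assert mse([56.0, 41.0], [52.317, 37.188]) == pytest.approx(14.0479165)

    def test_errors(self):
        with pytest.raises(DataError):
            mse([1.0], [1.0, 2.0])
        with pytest.raises(DataError):
            mse([], [])


class TestParameterRecovery:
    def test_estimates_within_four_ses_of_truth(self):
        # moderate-n version; the acceptance suite runs the full study size
        truth = np.array([7.948, 0.919, 25.075, 8.013])
        hits = 0
        reps = 50
        for r in range(reps):
            ds = generate(SyntheticConfig(n=400, noise_sd=2.0, seed=1000 + r))
            encoded, _ = encode_dummies(ds, "treatment")
            res = LinearModel.from_dataset(encoded).fit()
            if np.all(np.abs(res.params - truth) < 4 * res.bse):
                hits += 1
        assert hits / reps >= 0.95


class TestSummary:
    def test_summary_table_layout(self, synthetic_noisy):
        ds, _ = synthetic_noisy
        text = LinearModel.from_dataset(ds).fit().summary()
        for token in ("Estimated", "Std. error", "t-value", "p-values",
                      "Intercept", "R-squared"):
            assert token in text

    def test_json_roundtrip(self, synthetic_noisy):
        import json
        ds, _ = synthetic_noisy
        d = json.loads(LinearModel.from_dataset(ds).fit().to_json())
        assert {c["name"] for c in d["coefficients"]} == {
            "Intercept", "age", "treatment_A", "treatment_B"}
        assert 0.0 <= d["r_squared"] <= 1.0
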