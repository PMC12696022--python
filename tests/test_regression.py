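import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfaopt import (
    ObservationTable,
    SingularDesignError,
    TreatmentKey,
    UnderDeterminedError,
    build_design_matrix,
    compare_degrees,
    default_truth_surface,
    fit,
    pareto_rank,
    predict,
)
from vfaopt.regression import TERM_NAMES, CubicSurfaceModel


def _table(key, t, d, y):
    import pandas as pd

    df = pd.DataFrame(
        {
            "sludge_type": key.sludge_type,
            "organic_load": key.organic_load,
            "initial_ph": key.initial_ph,
            "temperature": np.asarray(t, dtype=float),
            "day": np.asarray(d, dtype=float),
            "replicate": np.arange(1, len(t) + 1),
            "vfa_mg_cod_per_l": np.asarray(y, dtype=float),
        }
    )
    return ObservationTable(df)


def normal_equations_ols(X, y):
    """Independent brute-force oracle: explicit (X'X)^-1 X'y on raw monomials."""
    return np.linalg.solve(X.T @ X, X.T @ y)


KEY = TreatmentKey("PS", 14.0, 10.5)


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "t, d, expected",
        [
            (1.0, 1.0, [1] * 10),
            (0.0, 2.0, [1, 0, 2, 0, 0, 4, 0, 0, 0, 8]),
        ],
    )
    def test_hand_evaluated_rows(self, t, d, expected):
        np.testing.assert_array_equal(build_design_matrix([t], [d])[0], expected)

    def test_cubic_temperature_column(self):
        row = build_design_matrix([25.0], [9.0])[0]
        assert row[TERM_NAMES.index("t^3")] == 25.0**3 == 15625.0


class TestFit:
    def test_zero_noise_exact_recovery(self, zero_noise_obs, best_key):
        truth = default_truth_surface(best_key, seed=0)
        model = fit(zero_noise_obs, best_key)
        scale = np.linalg.norm(truth.coefficients)
        np.testing.assert_allclose(
            model.coefficients, truth.coefficients, rtol=1e-6, atol=1e-6 * scale
        )
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        # modest variable magnitudes keep the explicit normal equations stable
        rng = np.random.default_rng(42)
        t = rng.uniform(0.5, 3.0, size=40)
        d = rng.uniform(0.5, 3.0, size=40)
        y = rng.normal(5.0, 1.0, size=40)
        model = fit(_table(KEY, t, d, y), KEY)
        oracle = normal_equations_ols(build_design_matrix(t, d), y)
        np.testing.assert_allclose(
            model.coefficients, oracle, rtol=1e-8, atol=1e-8 * np.linalg.norm(oracle)
        )

    def test_residuals_orthogonal_to_design(self, study_obs, best_key):
        rows = study_obs.subset(best_key)
        X = build_design_matrix(rows["temperature"].to_numpy(), rows["day"].to_numpy())
        model = fit(study_obs, best_key)
        resid = rows["vfa_mg_cod_per_l"].to_numpy() - X @ model.coefficients
        scale = np.linalg.norm(X, axis=0) * np.linalg.norm(resid)
        assert np.all(np.abs(X.T @ resid) <= 1e-6 * np.maximum(scale, 1.0))

    def test_model_has_ten_coefficients_and_correct_df(self, study_obs, best_key):
        model = fit(study_obs, best_key)
        assert model.coefficients.shape == (10,)
        assert model.residual_df == model.n_rows - 10 == 45 - 10

    def test_under_determined(self):
        t = np.linspace(25, 55, 10)
        d = np.linspace(3, 12, 10)
        with pytest.raises(UnderDeterminedError):
            fit(_table(KEY, t, d, np.ones(10)), KEY)

    def test_singular_design_names_columns(self):
        t = np.full(20, 25.0)  # one temperature: t-columns collinear with intercept
        d = np.tile(np.linspace(3, 12, 5), 4)
        with pytest.raises(SingularDesignError, match="t"):
            fit(_table(KEY, t, d, np.arange(20.0)), KEY)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        shift=st.floats(0.0, 1e4),  # table schema forbids negative concentrations
        scale=st.floats(0.01, 100.0),
    )
    def test_shift_scale_equivariance(self, shift, scale, study_obs, best_key):
        rows = study_obs.subset(best_key)
        base = fit(study_obs, best_key)
        t, d = rows["temperature"].to_numpy(), rows["day"].to_numpy()
        y = rows["vfa_mg_cod_per_l"].to_numpy()

        shifted = fit(_table(KEY, t, d, y + shift), KEY)
        assert shifted.coefficients[0] == pytest.approx(base.coefficients[0] + shift, rel=1e-6, abs=1e-6)
        np.testing.assert_allclose(shifted.coefficients[1:], base.coefficients[1:], rtol=1e-6, atol=1e-8)

        scaled = fit(_table(KEY, t, d, y * scale), KEY)
        np.testing.assert_allclose(scaled.coefficients, base.coefficients * scale, rtol=1e-6)
        assert scaled.residual_sd == pytest.approx(base.residual_sd * scale, rel=1e-6)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-9)
        np.testing.assert_allclose(scaled.coef_t_values, base.coef_t_values, rtol=1e-6)


class TestPredict:
    def test_constant_and_zero_models(self, best_key):
        zero = CubicSurfaceModel(best_key, np.zeros(10), 0.0, np.zeros(10), np.zeros(10), 1, 0.0, 11)
        assert predict(zero, 37.5, 4.2) == 0.0
        five = CubicSurfaceModel(best_key, np.r_[5.0, np.zeros(9)], 0.0, np.zeros(10), np.zeros(10), 1, 0.0, 11)
        assert predict(five, 55.0, 12.0) == 5.0

    def test_matches_direct_monomial_evaluation(self, best_key):
        truth = default_truth_surface(best_key, seed=2)
        model = CubicSurfaceModel(best_key, truth.coefficients, 1.0, np.zeros(10), np.zeros(10), 1, 0.0, 11)
        t, d = np.meshgrid(np.linspace(25, 55, 7), np.linspace(0, 12, 7))
        b = truth.coefficients
        direct = sum(
            b[i] * t**p * d**q
            for i, (p, q) in enumerate(
                [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2), (3, 0), (2, 1), (1, 2), (0, 3)]
            )
        )
        got = predict(model, t.ravel(), d.ravel())
        np.testing.assert_allclose(got, direct.ravel(), rtol=1e-10)


class TestParetoRank:
    def test_sorted_and_thresholded_at_df27(self, best_key):
        tvals = np.array([0.5, -3.0, 2.1, 1.0, -2.0, 4.0, 0.1, 2.052, -0.3, 2.06])
        model = CubicSurfaceModel(best_key, np.ones(10), 0.9, tvals, np.ones(10), 27, 1.0, 37)
        ranked = pareto_rank(model, alpha=0.05)
        mags = [r[1] for r in ranked]
        assert mags == sorted(mags, reverse=True)
        # two-sided critical t at df 27 is 2.052 (3 dp); strict inequality at the boundary
        flags = {name: sig for name, _, sig in ranked}
        assert flags[TERM_NAMES[5]] is True  # |t| = 4.0
        assert flags[TERM_NAMES[1]] is True  # |t| = 3.0
        assert flags[TERM_NAMES[0]] is False  # |t| = 0.5
        assert flags[TERM_NAMES[3]] is False  # |t| = 1.0

    def test_dominant_generated_term_ranks_first(self):
        rng = np.random.default_rng(5)
        t = rng.uniform(25, 55, 200)
        d = rng.uniform(0, 12, 200)
        y = 1000.0 + 500.0 * d**2 + rng.normal(0, 10.0, 200)  # huge d^2 effect
        model = fit(_table(KEY, t, d, y), KEY)
        ranked = pareto_rank(model)
        assert ranked[0][0] == "d^2"
        assert ranked[0][2] is True


class TestCompareDegrees:
    def test_r2_monotone_in_degree(self, study_obs, best_key):
        cmp = compare_degrees(study_obs, best_key)
        assert cmp[2].r_squared <= cmp[3].r_squared <= cmp[4].r_squared
        assert (cmp[2].n_terms, cmp[3].n_terms, cmp[4].n_terms) == (6, 10, 15)

    def test_exact_quadratic_truth_fits_all_degrees(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(25, 55, 60)
        d = rng.uniform(0, 12, 60)
        y = 100.0 + 2.0 * t - 3.0 * d + 0.05 * t * d - 0.4 * d**2
        cmp = compare_degrees(_table(KEY, t, d, y), KEY)
        for degree in (2, 3, 4):
            assert cmp[degree].r_squared == pytest.approx(1.0, abs=1e-9)

    def test_strong_cubic_truth_rejects_quadratic(self):
        rng = np.random.default_rng(4)
        t = rng.uniform(25, 55, 90)
        d = rng.uniform(0, 12, 90)
        y = 5000.0 + 0.5 * (d - 6.0) ** 3 * (t / 10.0) + rng.normal(0, 1.0, 90)
        cmp = compare_degrees(_table(KEY, t, d, y), KEY)
        assert cmp[3].adj_r_squared > cmp[2].adj_r_squared + 0.15
        # the quartic spends 5 more parameters for almost nothing
        assert cmp[4].adj_r_squared < cmp[3].adj_r_squared + 0.01
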