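"""PLS fitting and the validation battery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from qsarmix.fields import DescriptorMatrix, FieldGridSpec
from qsarmix.qsar import (
    ComfaPLS,
    contour_regions,
    field_contributions,
    fit_pls,
    loo_q2,
    overfit_ratio,
    r2_pred,
    regression_stats,
    scramble_validate,
    select_optimal_components,
    train_test_split_ids,
)
from qsarmix.synthetic import SyntheticQsarSpec, gen_qsar_set


def toy_descriptor(values: np.ndarray, fields=None) -> DescriptorMatrix:
    p = values.shape[1]
    fields = fields or ["steric"] * p
    grid = FieldGridSpec(origin=(0, 0, 0), spacing=1.0, dims=(p, 1, 1))
    cols = pd.DataFrame({
        "ix": range(p), "iy": 0, "iz": 0,
        "x": np.arange(p, dtype=float), "y": 0.0, "z": 0.0,
        "field": fields,
    }, index=pd.Index([f"c{i}" for i in range(p)], name="column"))
    vals = pd.DataFrame(values, index=[f"m{i}" for i in range(len(values))],
                        columns=cols.index)
    return DescriptorMatrix(values=vals, columns=cols, grid=grid)


class TestFit:
    def test_noiseless_linear_single_component_r2_one(self, rng):
        X = rng.normal(0, 1, (10, 1))
        y = 3.0 * X[:, 0] - 1.0
        m = fit_pls(X, y, 1)
        stats = regression_stats(m, X, y)
        assert stats["r2"] == pytest.approx(1.0, abs=1e-8)

    def test_full_rank_pls_equals_ols_normal_equations(self, rng):
        X = rng.normal(0, 1, (12, 3))
        y = rng.normal(0, 1, 12)
        m = fit_pls(X, y, 3)
        Xc = np.column_stack([np.ones(12), X])
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
        np.testing.assert_allclose(
            m.predict(X).ravel(), Xc @ beta, atol=1e-8
        )

    def test_degenerate_inputs_raise(self, rng):
        X = rng.normal(0, 1, (8, 2))
        with pytest.raises(ValueError, match="constant activity"):
            fit_pls(X, np.ones(8), 1)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, rng.normal(0, 1, 8), 8)


class TestLooQ2:
    def test_equals_explicit_left_out_loop_oracle(self, rng):
        """Hand-rolled LOO loop over <=10 points, independent PLS calls."""
        X = rng.normal(0, 1, (8, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.3, 8)
        press = 0.0
        for i in range(8):
            keep = [j for j in range(8) if j != i]
            oracle = PLSRegression(n_components=2, scale=False)
            oracle.fit(X[keep], y[keep])
            press += float(oracle.predict(X[i:i + 1]).ravel()[0] - y[i]) ** 2
        expected = 1 - press / float(((y - y.mean()) ** 2).sum())
        assert loo_q2(X, y, 2) == pytest.approx(expected, abs=1e-12)

    def test_noiseless_linear_data_approaches_one(self, rng):
        X = rng.normal(0, 1, (12, 2))
        y = X @ np.array([2.0, -1.0])
        assert loo_q2(X, y, 2) >= 0.999

    def test_pure_noise_high_dimension_stays_low(self):
        """q2 on pure noise with p >> n should essentially never look predictive."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (12, 100))
            y = r.normal(0, 1, 12)
            assert loo_q2(X, y, 2) < 0.3

    def test_optimal_component_selection_tie_breaks_small(self, rng):
        X = rng.normal(0, 1, (10, 2))
        y = X @ np.array([1.0, 0.5])
        n_opt, scan = select_optimal_components(X, y, 5)
        assert n_opt == min(c for c, v in scan.items() if v == max(scan.values()))


class TestRegressionStats:
    def test_printed_overfit_ratio(self):
        """The published q2/R2 pair gives the printed 22.992% screen value."""
        assert overfit_ratio(0.767, 0.996) == pytest.approx(22.992, abs=5e-4)

    def test_see_matches_direct_residual_computation(self, rng):
        X = rng.normal(0, 1, (5, 1))
        y = 2 * X[:, 0] + rng.normal(0, 0.5, 5)
        m = fit_pls(X, y, 1)
        resid = y - m.predict(X).ravel()
        expected = np.sqrt((resid**2).sum() / (5 - 1 - 1))
        stats = regression_stats(m, X, y)
        assert stats["see"] == pytest.approx(expected, abs=1e-12)
        r2 = stats["r2"]
        assert stats["f"] == pytest.approx((r2 / 1) / ((1 - r2) / 3), abs=1e-9)

    def test_perfect_fit_reports_zero_see_infinite_f(self, rng):
        X = rng.normal(0, 1, (6, 1))
        y = 4.0 * X[:, 0]
        stats = regression_stats(fit_pls(X, y, 1), X, y)
        assert stats["see"] == pytest.approx(0.0, abs=1e-10)
        assert stats["f"] > 1e10 or np.isinf(stats["f"])

    def test_insufficient_dof_raises(self, rng):
        X = rng.normal(0, 1, (3, 4))
        y = rng.normal(0, 1, 3)
        with pytest.raises(ValueError, match="n - c - 1"):
            regression_stats(fit_pls(X, y, 2), X, y)


class TestR2Pred:
    def test_perfect_prediction(self):
        assert r2_pred([1.0, 2.0], [1.0, 2.0], 5.0) == 1.0

    def test_mean_predictor_scores_zero(self):
        assert r2_pred([1.0, 3.0], [2.0, 2.0], 2.0) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        assert r2_pred([1.0, 2.0], [1.5, 2.5], 0.0) == pytest.approx(0.9)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(ValueError, match="training mean"):
            r2_pred([2.0, 2.0], [1.0, 3.0], 2.0)


class TestFieldContributions:
    def test_all_mass_on_one_field(self, rng):
        X = np.column_stack([rng.normal(0, 1, 10), np.zeros(10)])
        X[:, 1] = rng.normal(0, 1e-9, 10)
        y = 2 * X[:, 0]
        m = fit_pls(X, y, 1)
        c = field_contributions(m, X, ["steric", "electrostatic"])
        assert c["steric"] == pytest.approx(1.0, abs=1e-4)
        assert c["steric"] + c["electrostatic"] == pytest.approx(1.0)

    def test_mirrored_duplicate_columns_split_evenly(self, rng):
        a = rng.normal(0, 1, 10)
        X = np.column_stack([a, a])
        y = a * 3
        c = field_contributions(fit_pls(X, y, 1), X, ["steric", "electrostatic"])
        assert c["steric"] == pytest.approx(0.5, abs=1e-9)

    def test_hand_computed_two_column_model(self, rng):
        X = np.column_stack([rng.normal(0, 2, 12), rng.normal(0, 1, 12)])
        y = X @ np.array([1.0, -3.0]) + rng.normal(0, 0.1, 12)
        m = fit_pls(X, y, 2)
        coef = np.asarray(m.coef_).ravel()
        mass = np.abs(coef) * X.std(axis=0, ddof=1)
        c = field_contributions(m, X, ["steric", "electrostatic"])
        assert c["steric"] == pytest.approx(mass[0] / mass.sum(), abs=1e-12)


@pytest.fixture(scope="module")
def signal_data():
    _, y, info = gen_qsar_set(SyntheticQsarSpec(), seed=3)
    model = ComfaPLS(info["X"], y)
    return model.exog, np.asarray(y)


class TestScrambling:
    def test_intact_level_reproduces_loo_q2(self, signal_data):
        X, y = signal_data
        rep = scramble_validate(X, y, 2, seed=0)
        intact = rep.levels.iloc[0]
        assert intact["r2yy"] == pytest.approx(1.0)
        assert intact["q2"] == pytest.approx(loo_q2(X, y, 2), abs=1e-12)

    def test_signal_data_has_positive_slope(self, signal_data):
        X, y = signal_data
        rep = scramble_validate(X, y, 2, seed=0)
        assert rep.dq2_dr2yy > 0

    def test_fully_scrambled_noise_is_not_predictive(self):
        vals = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (10, 20))
            y = r.normal(0, 1, 10)
            rep = scramble_validate(X, y, 2, seed=seed)
            full = rep.levels[rep.levels["r2yy"] < 0.5]["q2"]
            vals.extend(full.tolist())
        assert np.mean(vals) <= 0.1

    def test_determinism_and_level_validation(self, signal_data):
        X, y = signal_data
        a = scramble_validate(X, y, 2, seed=42)
        b = scramble_validate(X, y, 2, seed=42)
        assert a.q2_scrambled == b.q2_scrambled
        with pytest.raises(ValueError, match="levels"):
            scramble_validate(X, y, 2, levels=(0.0, 1.0))


class TestContours:
    def test_uniform_coefficients_yield_single_color(self, rng):
        vals = rng.normal(0, 3, (10, 4))
        X = toy_descriptor(vals)
        y = vals.sum(axis=1)
        res = contour_regions(fit_pls(X, y, 2), X)
        assert set(res["color"]) == {"green"}

    def test_dominant_column_ranks_first(self, rng):
        vals = np.column_stack([rng.normal(0, 10, 12), rng.normal(0, 0.5, 12),
                                rng.normal(0, 0.5, 12)])
        X = toy_descriptor(vals)
        y = 5 * vals[:, 0] + 0.01 * vals[:, 1]
        res = contour_regions(fit_pls(X, y, 2), X)
        assert res.index[0] == "c0" and bool(res.loc["c0", "support"])

    def test_support_frac_one_labels_everything_supportive(self, rng):
        vals = rng.normal(0, 3, (10, 3))
        X = toy_descriptor(vals)
        y = vals @ np.array([1.0, -1.0, 0.5])
        res = contour_regions(fit_pls(X, y, 2), X, support_frac=1.0)
        assert res["support"].all()

    def test_sign_semantics_map_to_field_colors(self, rng):
        vals = rng.normal(0, 3, (12, 2))
        X = toy_descriptor(vals, fields=["steric", "electrostatic"])
        y = 2 * vals[:, 0] - 2 * vals[:, 1]
        res = contour_regions(fit_pls(X, y, 2), X)
        assert res.loc["c0", "color"] == "green"
        assert res.loc["c1", "color"] == "red"


class TestModelFacade:
    def test_results_invariants_and_summary(self):
        _, y, info = gen_qsar_set(SyntheticQsarSpec(), seed=5)
        res = ComfaPLS(info["X"], y).fit()
        assert res.r2 <= 1
        assert sum(res.contributions.values()) == pytest.approx(1.0)
        assert 1 <= res.n_components < len(y)
        text = res.summary()
        assert "q2 (LOO)" in text and "SEE" in text

    def test_bit_identical_reports_for_identical_inputs(self):
        _, y, info = gen_qsar_set(SyntheticQsarSpec(), seed=6)
        r1 = ComfaPLS(info["X"], y).fit(n_components=3)
        r2 = ComfaPLS(info["X"], y).fit(n_components=3)
        assert r1.q2 == r2.q2 and r1.see == r2.see and r1.f_stat == r2.f_stat
        np.testing.assert_array_equal(r1.coef, r2.coef)

    def test_all_columns_filtered_raises(self):
        vals = np.full((6, 4), 1.0) + np.random.default_rng(0).normal(0, 1e-6, (6, 4))
        X = toy_descriptor(vals)
        with pytest.raises(ValueError, match="column filter"):
            ComfaPLS(X, np.arange(6.0))

    def test_split_is_seeded_and_partitions(self):
        ids = [f"m{i}" for i in range(15)]
        tr1, te1 = train_test_split_ids(ids, 4, seed=9)
        tr2, te2 = train_test_split_ids(ids, 4, seed=9)
        assert (tr1, te1) == (tr2, te2)
        assert sorted(tr1 + te1) == sorted(ids) and len(te1) == 4
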