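"""Re-parameterized Mitscherlich model: ω arithmetic, VIF, stepwise, fitting."""

import numpy as np
import pytest

from firgrowth.datamodel import CovariateVector, split_train_test
from firgrowth.rp_model import (DEFAULT_RP_VARIABLES, RPCoefficients, fit_rp,
                                load_coefficients, omega_pair, rp_predict,
                                rp_predict_dataset, stepwise_aic, vif_screen,
                                vif_table)
from firgrowth.synthetic import GeneratorConfig, generate_dataset

TABLE1 = load_coefficients("table1_dbh")
TABLE4 = load_coefficients("table4_h")

EXAMPLE_COV = CovariateVector(TABLE1.variable_names,
                              (121, 3, 423, 98, 4, 1500, 900))


class TestOmegaPair:
    def test_published_dbh_coefficients_hand_example(self):
        w0, w1, valid = omega_pair(TABLE1, EXAMPLE_COV)
        assert w0 == pytest.approx(16.59, abs=1e-9)
        assert w1 == pytest.approx(0.0410, abs=5e-5)
        assert valid

    def test_zero_covariates_return_intercepts(self):
        zeros = CovariateVector(TABLE1.variable_names, (0.0,) * 7)
        assert omega_pair(TABLE1, zeros)[:2] == (-20.041, 0.039)
        w0, w1, valid = omega_pair(TABLE4, zeros)
        assert (w0, w1) == (-2.301, 0.063)
        assert not valid          # negative asymptote is flagged

    def test_name_mismatch_rejected(self):
        cov = CovariateVector(("N", "PW"), (1.0, 2.0))
        with pytest.raises(ValueError, match="do not match"):
            omega_pair(TABLE1, cov)


class TestRpPredict:
    def test_hand_example_at_age_23(self):
        # 16.59 * (1 - exp(-0.0410 * 23)) ~ 10.13 cm
        assert rp_predict(TABLE1, EXAMPLE_COV, 23) == pytest.approx(10.13,
                                                                    abs=0.01)

    def test_zero_age_gives_zero(self):
        assert rp_predict(TABLE1, EXAMPLE_COV, 0) == 0.0

    def test_asymptote(self):
        w0 = omega_pair(TABLE1, EXAMPLE_COV).omega0
        assert rp_predict(TABLE1, EXAMPLE_COV, 1e5) == pytest.approx(
            w0, abs=1e-6 * w0)

    def test_monotone_and_bounded_for_valid_omegas(self):
        t = np.linspace(0, 300, 400)
        v = rp_predict(TABLE1, EXAMPLE_COV, t)
        w0 = omega_pair(TABLE1, EXAMPLE_COV).omega0
        assert np.all(np.diff(v) >= -1e-12) and np.all(v <= w0 + 1e-12)


class TestVif:
    def test_orthogonal_columns_give_unit_vif(self, rng):
        n = 200
        # QR against a leading constant column: mutually orthogonal AND
        # mean-centered columns
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n),
                                             rng.normal(size=(n, 3))]))
        table = vif_table(Q[:, 1:])
        assert all(v == pytest.approx(1.0, abs=1e-6) for v in table.values())

    def test_duplicate_column_is_infinite(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        table = vif_table(X, ["a", "b", "c"])
        assert np.isinf(table["a"]) and np.isinf(table["b"])

    def test_two_columns_closed_form(self, rng):
        # VIF = 1/(1-r^2) for a correlated pair, against the brute-force
        # regression R^2 route
        x = rng.normal(size=500)
        y = 0.8 * x + 0.6 * rng.normal(size=500)
        X = np.column_stack([x, y])
        r = np.corrcoef(x, y)[0, 1]
        expected = 1.0 / (1.0 - r ** 2)
        table = vif_table(X)
        assert table["x0"] == pytest.approx(expected, rel=1e-9)
        assert table["x1"] == pytest.approx(expected, rel=1e-9)

    def test_screen_keeps_orthogonal_input(self, rng):
        Q, _ = np.linalg.qr(np.column_stack([np.ones(100),
                                             rng.normal(size=(100, 4))]))
        assert vif_screen(Q[:, 1:], list("abcd")) == list("abcd")

    def test_screen_drops_one_of_duplicate_pair(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        survivors = vif_screen(X, ["a", "b", "c"])
        assert survivors == ["a", "c"]     # later-listed duplicate dropped

    def test_screen_postcondition_all_below_threshold(self, rng):
        z = rng.normal(size=300)
        X = np.column_stack([z + 0.05 * rng.normal(size=300),
                             z + 0.05 * rng.normal(size=300),
                             z + 0.05 * rng.normal(size=300),
                             rng.normal(size=300), rng.normal(size=300)])
        survivors = vif_screen(X, list("abcde"))
        idx = [list("abcde").index(s) for s in survivors]
        assert max(vif_table(X[:, idx]).values()) < 5


class TestFitRp:
    def test_noiseless_recovery_of_published_coefficients(self):
        cfg = GeneratorConfig(seed=3, coefficients=TABLE1, noise_sd=0.0,
                              n_plots=150, trees_per_plot=2)
        ds = generate_dataset(cfg)
        fit = fit_rp(ds, list(TABLE1.variable_names), seed=0)
        assert fit.converged
        for est, true in zip(fit.coefficients.alpha + fit.coefficients.beta,
                             TABLE1.alpha + TABLE1.beta):
            if abs(true) > 1e-5:
                assert est == pytest.approx(true, rel=1e-3)

    def test_empty_variable_list_reduces_to_base_fit(self, small_inventory):
        from firgrowth.base_growth import fit_curve
        base = fit_curve("Mitscherlich", small_inventory, seed=0)
        fit = fit_rp(small_inventory, [], seed=0)
        assert fit.coefficients.alpha[0] == pytest.approx(base.curve.a,
                                                          rel=1e-6)
        assert fit.coefficients.beta[0] == pytest.approx(base.curve.b,
                                                         rel=1e-6)

    def test_nesting_larger_set_fits_no_worse(self, small_inventory):
        small = fit_rp(small_inventory, ["N", "DD18"], seed=0)
        large = fit_rp(small_inventory, ["N", "DD18", "PW", "HB"], seed=0)
        assert large.sse <= small.sse * (1 + 1e-6)

    def test_covariates_improve_on_base_under_noise(self):
        ds = generate_dataset(GeneratorConfig(seed=9, n_plots=250,
                                              trees_per_plot=2))
        train, test = split_train_test(ds, 0.8, seed=0)
        from firgrowth.base_growth import curve_value, fit_curve
        from firgrowth.evaluation import compute_metrics
        base = fit_curve("Mitscherlich", train, seed=0)
        base_r2 = compute_metrics(test.responses,
                                  curve_value(base.curve, test.ages)).r2
        fit = fit_rp(train, list(DEFAULT_RP_VARIABLES), seed=0)
        rp_r2 = compute_metrics(test.responses,
                                rp_predict_dataset(fit.coefficients,
                                                   test)).r2
        assert rp_r2 > base_r2

    def test_too_few_observations_rejected(self):
        from conftest import make_dataset
        ds = make_dataset({"p1": [10.0, 11.0, 12.0]})
        with pytest.raises(ValueError, match="at least"):
            fit_rp(ds, ["N", "PW"], seed=0)


class TestStepwiseAic:
    NULL = RPCoefficients(TABLE1.variable_names, (22.0,) + (0.0,) * 7,
                          (0.045,) + (0.0,) * 7, "DBH")

    def test_empty_candidates_select_nothing(self, small_inventory):
        assert stepwise_aic(small_inventory, [], seed=0) == []

    def test_pure_noise_candidates_rarely_enter(self):
        picked = 0
        total = 0
        for seed in range(4):
            ds = generate_dataset(GeneratorConfig(
                seed=seed, coefficients=self.NULL, n_plots=100,
                trees_per_plot=2, surveys_per_tree=2))
            sel = stepwise_aic(ds, ["PD", "TRMC", "MAP"], seed=seed)
            picked += len(sel)
            total += 3
        assert picked / total < 0.3

    def test_strong_effect_is_selected(self):
        strong = RPCoefficients(TABLE1.variable_names,
                                (8.0, 0, 0, 0, 0, 0, 0.01, 0),
                                (0.045,) + (0.0,) * 7, "DBH")
        hits = 0
        for seed in range(3):
            ds = generate_dataset(GeneratorConfig(
                seed=seed, coefficients=strong, n_plots=100,
                trees_per_plot=2, surveys_per_tree=2))
            if "DD18" in stepwise_aic(ds, ["DD18", "PD", "TRMC"], seed=seed):
                hits += 1
        assert hits == 3


class TestCoefficientsIO:
    def test_fixture_round_trip(self, tmp_path):
        import json
        path = tmp_path / "coef.json"
        path.write_text(json.dumps(TABLE1.as_dict()))
        back = load_coefficients(str(path))
        assert back == TABLE1
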