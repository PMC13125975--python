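import numpy as np
import pandas as pd
import pytest

from ordisp import (
    FitControl,
    ModelSpec,
    Parameters,
    encode_covariates,
    fit_unpenalized,
    information_criteria,
    predictive_deviance,
    predictive_log_likelihood,
    ranked_probability_score,
    selection_rates,
    tune_grid,
)
from ordisp.evaluation import TruthPattern, coefficient_path
from ordisp.penalized import FitResult, SelectionSets, adaptive_weights
from ordisp.data import ColumnInfo

FAST = FitControl(fd_scheme="forward", maxiter=150)


def _dummy_fit(deviance, n_parameters, n_obs, params=None, spec=None):
    return FitResult(
        spec=spec or ModelSpec("cumulative_re", 3),
        params=params or Parameters([-1, 1], [], [], [[0.1]]),
        theta=np.zeros(1), loglik=-deviance / 2, penalized_loglik=-deviance / 2,
        deviance=deviance, aic=np.nan, bic=np.nan, n_parameters=n_parameters,
        n_obs=n_obs, n_clusters=5, x_columns=(), z_columns=(), convergence={"success": True},
    )


class TestInformationCriteria:
    def test_hand_example(self):
        aic, bic = information_criteria(_dummy_fit(100.0, 5, 100))
        assert aic == pytest.approx(110.0)
        assert bic == pytest.approx(100 + 5 * np.log(100), abs=1e-3)  # 123.026

    def test_zero_parameters_gives_deviance(self):
        aic, bic = information_criteria(_dummy_fit(42.0, 0, 10))
        assert aic == 42.0 and bic == 42.0


class TestRankedProbabilityScore:
    def test_hand_example_middle_category(self):
        # cumulative forecast (0.2689, 0.7311), observed y=2
        params = Parameters([-1.0, 1.0], [0.0], [], [[0.0]])
        spec = ModelSpec("cumulative_re", 3)
        data = encode_covariates(
            pd.DataFrame({"cluster": [1], "y": [2], "x": [0.0]}),
            [__import__("ordisp").CovariateSchema("x", "continuous")], k=3)
        fit = _dummy_fit(0.0, 0, 1, params=params, spec=spec)
        rps = ranked_probability_score(fit, data)
        assert rps == pytest.approx(0.2689**2 + (0.7311 - 1) ** 2, abs=1e-4)  # 0.1446

    def test_uniform_forecast_first_category(self):
        thr = [np.log(1 / 2), np.log(2)]  # F(thr) = 1/3, 2/3
        params = Parameters(thr, [0.0], [], [[0.0]])
        data = encode_covariates(
            pd.DataFrame({"cluster": [1], "y": [1], "x": [0.0]}),
            [__import__("ordisp").CovariateSchema("x", "continuous")], k=3)
        fit = _dummy_fit(0.0, 0, 1, params=params, spec=ModelSpec("cumulative_re", 3))
        assert ranked_probability_score(fit, data) == pytest.approx(
            (1 / 3 - 1) ** 2 + (2 / 3 - 1) ** 2, abs=1e-6)  # 0.5556

    def test_degenerate_correct_forecast_scores_zero(self):
        params = Parameters([-40.0, 40.0], [0.0], [], [[0.0]])
        data = encode_covariates(
            pd.DataFrame({"cluster": [1, 1], "y": [2, 2], "x": [0.0, 0.0]}),
            [__import__("ordisp").CovariateSchema("x", "continuous")], k=3)
        fit = _dummy_fit(0.0, 0, 2, params=params, spec=ModelSpec("cumulative_re", 3))
        assert ranked_probability_score(fit, data) == pytest.approx(0.0, abs=1e-12)

    def test_rps_bounded_by_k_minus_one(self, small_dataset, bench_params):
        fit = _dummy_fit(0.0, 0, small_dataset.n_obs, params=bench_params,
                         spec=ModelSpec("location_shift", 3))
        rps = ranked_probability_score(fit, small_dataset)
        assert 0.0 <= rps <= 2.0


class TestPredictiveLikelihood:
    @pytest.fixture(scope="class")
    def fit(self, small_standardized):
        return fit_unpenalized(small_standardized, ModelSpec("location_shift", 3),
                               control=FAST, compute_se=False)

    def test_training_data_reproduces_in_sample_loglik(self, fit, small_standardized):
        assert predictive_log_likelihood(fit, small_standardized) == pytest.approx(
            fit.loglik, abs=1e-6)

    def test_deviance_is_minus_two_predictive(self, fit, small_standardized):
        pll = predictive_log_likelihood(fit, small_standardized)
        assert predictive_deviance(fit, small_standardized) == pytest.approx(-2 * pll)

    def test_additive_over_concatenated_samples(self, fit, small_standardized, schemas3):
        raw = small_standardized.raw
        a = encode_covariates(raw.iloc[:60], schemas3,
                              standardization=small_standardized.standardization, k=3)
        b = encode_covariates(raw.iloc[60:], schemas3,
                              standardization=small_standardized.standardization, k=3)
        total = predictive_log_likelihood(fit, small_standardized)
        assert predictive_log_likelihood(fit, a) + predictive_log_likelihood(fit, b) == \
            pytest.approx(total, abs=1e-6)


class TestTuning:
    def test_single_point_grid_is_chosen(self, small_standardized):
        res = tune_grid(small_standardized, small_standardized, ModelSpec("location_shift", 3),
                        log_lambda_grid=[(-8, -8)], control=FAST)
        assert res.best_pair == (pytest.approx(np.exp(-8)), pytest.approx(np.exp(-8)))

    def test_negligible_penalty_matches_unpenalized(self, small_standardized):
        res = tune_grid(small_standardized, small_standardized, ModelSpec("location_shift", 3),
                        log_lambda_grid=[(-30, -30)], control=FAST)
        np.testing.assert_allclose(res.best_fit.params.beta, res.unpenalized.params.beta,
                                   atol=1e-4)

    def test_determinism(self, small_standardized):
        grid = [(-8, -8), (-8, -4), (-4, -8), (-4, -4)]
        spec = ModelSpec("location_shift", 3)
        a = tune_grid(small_standardized, small_standardized, spec, log_lambda_grid=grid,
                      control=FAST)
        b = tune_grid(small_standardized, small_standardized, spec, log_lambda_grid=grid,
                      control=FAST)
        assert a.best_pair == b.best_pair
        np.testing.assert_allclose(a.predictive_loglik, b.predictive_loglik, atol=1e-6)


class TestCoefficientPath:
    def test_path_ends_fully_shrunk_and_starts_unpenalized(self, small_standardized):
        spec = ModelSpec("location_shift", 3)
        unpen = fit_unpenalized(small_standardized, spec, control=FAST, compute_se=False)
        path = coefficient_path(small_standardized, spec, vary="location",
                                grid=np.exp(np.arange(-30.0, 4.0, 1.0)[np.r_[0, 15:34]]),
                                unpenalized=unpen, control=FAST)
        first = path[path["lambda"] == np.exp(-30.0)]
        loc_first = first[first.component == "location"].set_index("term").estimate
        for col, val in zip(unpen.x_columns, unpen.params.beta):
            assert loc_first[col.name] == pytest.approx(val, abs=1e-3)
        last = path[(path["lambda"] == np.exp(3.0)) & (path.component == "location")]
        assert last.estimate.abs().max() < 1e-3
        # continuity on the standardized scale
        wide = path[path.component == "location"].pivot(index="lambda", columns="term",
                                                        values="estimate").sort_index()
        assert np.abs(np.diff(wide.to_numpy(), axis=0)).max() < 0.5


class TestSelectionRates:
    X_COLS = [ColumnInfo("x1", "x1", "continuous"), ColumnInfo("f[2]", "f", "ordinal", 2),
              ColumnInfo("f[3]", "f", "ordinal", 3)]

    def _sel(self, excluded_loc=(), excluded_disp=(), fused=None):
        return SelectionSets(frozenset(excluded_loc), frozenset(excluded_disp),
                             fused or {"f": (("<ref>",), (2,), (3,))}, {})

    def test_everything_selected(self):
        truth = TruthPattern(location_nonzero=frozenset({"x1"}),
                             dispersion_nonzero=frozenset(),
                             dispersion_zero=frozenset({"x1"}))
        sels = [self._sel() for _ in range(4)]
        rates = selection_rates(sels, truth, self.X_COLS, self.X_COLS)
        assert rates.rate("x1", "location", "TPR") == 1.0
        assert rates.rate("x1", "dispersion", "TNR") == 0.0

    def test_hand_counted_rates(self):
        truth = TruthPattern(location_nonzero=frozenset({"x1"}),
                             dispersion_nonzero=frozenset(),
                             dispersion_zero=frozenset({"x1"}),
                             fused_pair=("f", 2, 3))
        sels = [
            self._sel(excluded_disp=("x1",), fused={"f": (("<ref>",), (2, 3))}),
            self._sel(excluded_disp=("x1",)),
            self._sel(excluded_disp=("x1",), fused={"f": (("<ref>", 2, 3),)}),
            self._sel(excluded_loc=("x1",)),
        ]
        rates = selection_rates(sels, truth, self.X_COLS, self.X_COLS)
        assert rates.rate("x1", "location", "TPR") == 0.75
        assert rates.rate("x1", "location", "FNR") == 0.25
        assert rates.rate("x1", "dispersion", "TNR") == 0.75
        # only the first replication fuses exactly {2,3} (the third over-fuses)
        assert rates.fusion_recovery == 0.25

    def test_rates_sum_to_one(self):
        truth = TruthPattern(location_nonzero=frozenset({"x1", "f"}),
                             dispersion_nonzero=frozenset(),
                             dispersion_zero=frozenset({"f"}))
        sels = [self._sel(excluded_loc=("x1",)), self._sel(),
                self._sel(excluded_disp=("f[2]", "f[3]"))]
        rates = selection_rates(sels, truth, self.X_COLS, self.X_COLS)
        t = rates.table
        for cov, comp in {("x1", "location"), ("f", "location"), ("f", "dispersion")}:
            sub = t[(t.covariate == cov) & (t.component == comp)]
            assert sub.rate.sum() == pytest.approx(1.0)
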