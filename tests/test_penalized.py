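import numpy as np
import pandas as pd
import pytest

from ordisp import (
    CovariateSchema,
    FitControl,
    ModelSpec,
    Parameters,
    adaptive_weights,
    apply_selection,
    empirical_bayes_intercepts,
    encode_covariates,
    fit_penalized,
    fit_unpenalized,
    penalty_structure,
    penalty_value,
    refit_selected,
    smoothed_penalty_value,
)
from ordisp.data import ColumnInfo
from ordisp.likelihood import cluster_log_marginal_likelihood
from ordisp.penalized import ParameterTransform, selection_design_map

FAST = FitControl(fd_scheme="forward", maxiter=150)


def _cols(*specs):
    """ColumnInfo list from (name, covariate, kind, level) tuples."""
    return [ColumnInfo(*s) for s in specs]


SIMPLE_X = _cols(("x1", "x1", "continuous", None))
SIMPLE_Z = _cols(("z1", "z1", "continuous", None))
ORDINAL_X = _cols(
    ("x1", "x1", "continuous", None),
    ("f[2]", "f", "ordinal", 2), ("f[3]", "f", "ordinal", 3), ("f[4]", "f", "ordinal", 4),
)


class TestPenaltyValues:
    def test_zero_lambdas_give_zero_penalty(self):
        config = penalty_structure(ORDINAL_X, SIMPLE_Z)
        assert penalty_value([1.0, 2, 3, 4], [5.0], config) == 0.0

    def test_worked_example(self):
        # lambda_l * w * |beta| + lambda_d * w * |alpha| = 1*2*0.5 + 2*4*0.25 = 3
        config = penalty_structure(SIMPLE_X, SIMPLE_Z).with_lambdas(1.0, 2.0)
        config.location.l1_weights[:] = 2.0
        config.dispersion.l1_weights[:] = 4.0
        assert penalty_value([0.5], [-0.25], config) == pytest.approx(3.0)

    def test_equal_ordinal_levels_have_zero_fusion_terms(self):
        config = penalty_structure(ORDINAL_X, SIMPLE_Z).with_lambdas(1.0, 0.0)
        # x1 zero, all levels equal to each other but not to the reference
        val = penalty_value([0.0, 0.7, 0.7, 0.7], [0.0], config)
        # only the three (reference, level) pairs contribute
        assert val == pytest.approx(3 * 0.7)

    def test_smoothed_upper_bounds_exact_and_converges(self):
        config = penalty_structure(SIMPLE_X, SIMPLE_Z).with_lambdas(1.0, 2.0)
        config.location.l1_weights[:] = 2.0
        config.dispersion.l1_weights[:] = 4.0
        exact = penalty_value([0.5], [-0.25], config)
        smooth = smoothed_penalty_value([0.5], [-0.25], config)
        assert smooth >= exact
        loose = penalty_structure(SIMPLE_X, SIMPLE_Z, epsilon=1e-14).with_lambdas(1.0, 2.0)
        loose.location.l1_weights[:] = 2.0
        loose.dispersion.l1_weights[:] = 4.0
        assert smoothed_penalty_value([0.5], [-0.25], loose) == pytest.approx(exact, abs=1e-6)

    def test_zero_coefficient_contributes_sqrt_epsilon(self):
        config = penalty_structure(SIMPLE_X, SIMPLE_Z, epsilon=1e-6).with_lambdas(1.0, 0.0)
        assert smoothed_penalty_value([0.0], [0.0], config) == pytest.approx(1e-3)


class TestAdaptiveWeights:
    @pytest.fixture(scope="class")
    def unpen(self, small_standardized):
        return fit_unpenalized(small_standardized, ModelSpec("location_shift", 3),
                               control=FAST, compute_se=False)

    def test_weights_are_inverse_estimates(self, unpen):
        config = adaptive_weights(unpen)
        np.testing.assert_allclose(
            config.location.l1_weights, 1.0 / np.abs(unpen.params.beta[:2]))
        np.testing.assert_allclose(
            config.dispersion.l1_weights, 1.0 / np.abs(unpen.params.alpha[:2]))

    def test_fusion_weights_enumerate_all_pairs_with_reference(self, unpen):
        config = adaptive_weights(unpen)
        # 4-level ordinal: pairs (ref,2),(ref,3),(ref,4),(2,3),(2,4),(3,4)
        assert len(config.location.fusion_pairs) == 6
        est = np.concatenate([[0.0], unpen.params.beta[2:]])
        expect = [1 / abs(est[u] - est[v]) for u in range(4) for v in range(u + 1, 4)]
        np.testing.assert_allclose(sorted(config.location.fusion_weights), sorted(expect))

    def test_exactly_equal_estimates_hit_the_cap(self):
        class Fake:
            convergence = {"success": True}
            x_columns = ORDINAL_X
            z_columns = SIMPLE_Z
            params = Parameters([-1, 1], [0.5, 0.0, 0.25, 0.25], [0.5], [[0.1, 0], [0, 0.1]])

        config = adaptive_weights(Fake(), weight_cap=1e6)
        # level 2 equals the reference and level 3 equals level 4 -> capped weights
        assert sorted(config.location.fusion_weights)[-2:] == [1e6, 1e6]
        assert 4.0 in np.round(config.location.fusion_weights, 10)

    def test_unconverged_fit_rejected(self):
        class Bad:
            convergence = {"success": False}

        with pytest.raises(ValueError, match="converged"):
            adaptive_weights(Bad())


class TestApplySelection:
    def test_small_coefficients_excluded(self):
        params = Parameters([-1, 1], [0.0004, 0.8], [0.0], [[0.1, 0], [0, 0.1]])
        cols = _cols(("a", "a", "continuous", None), ("b", "b", "continuous", None))
        sel = apply_selection(params, cols, SIMPLE_Z, zero_tolerance=1e-3)
        assert sel.excluded_location == {"a"}
        assert "z1" in sel.excluded_dispersion

    def test_transitive_fusion_of_close_levels(self):
        params = Parameters([-1, 1], [0.0, 0.5002, 0.5008, 0.9], [0.0], [[0.1, 0], [0, 0.1]])
        sel = apply_selection(params, ORDINAL_X, SIMPLE_Z, fuse_tolerance=1e-3)
        groups = {frozenset(g) for g in sel.fused_groups_location["f"]}
        assert frozenset({2, 3}) in groups
        assert frozenset({"<ref>"}) in groups
        assert frozenset({4}) in groups

    def test_all_levels_near_zero_excludes_whole_covariate(self):
        params = Parameters([-1, 1], [0.5, 1e-5, -2e-4, 4e-4], [0.0], [[0.1, 0], [0, 0.1]])
        sel = apply_selection(params, ORDINAL_X, SIMPLE_Z)
        assert {"f[2]", "f[3]", "f[4]"} <= sel.excluded_location
        assert len(sel.fused_groups_location["f"]) == 1  # one group with everything


class TestFitting:
    @pytest.fixture(scope="class")
    def unpen(self, small_standardized):
        return fit_unpenalized(small_standardized, ModelSpec("location_shift", 3),
                               control=FAST, compute_se=False)

    def test_zero_lambda_reproduces_unpenalized(self, small_standardized, unpen):
        config = adaptive_weights(unpen).with_lambdas(0.0, 0.0)
        pen = fit_penalized(small_standardized, ModelSpec("location_shift", 3), None, config,
                            init=unpen.params, control=FAST)
        np.testing.assert_allclose(pen.params.beta, unpen.params.beta, atol=1e-4)
        np.testing.assert_allclose(pen.params.alpha, unpen.params.alpha, atol=1e-4)

    def test_huge_lambda_shrinks_everything(self, small_standardized, unpen):
        config = penalty_structure(unpen.x_columns, unpen.z_columns).with_lambdas(
            np.exp(5.0), np.exp(5.0))
        pen = fit_penalized(small_standardized, ModelSpec("location_shift", 3), None, config,
                            init=unpen.params, control=FAST)
        assert np.abs(pen.params.beta).max() < config.zero_tolerance
        assert np.abs(pen.params.alpha).max() < config.zero_tolerance
        # thresholds and Sigma_b remain free
        assert np.abs(np.diff(pen.params.thresholds)) > 0.5
        assert pen.params.Sigma_b[0, 0] > 1e-4

    def test_penalized_loglik_bounded_by_unpenalized_maximum(self, small_standardized, unpen):
        config = adaptive_weights(unpen).with_lambdas(np.exp(-6), np.exp(-6))
        pen = fit_penalized(small_standardized, ModelSpec("location_shift", 3), None, config,
                            init=unpen.params, control=FAST)
        assert pen.loglik <= unpen.loglik + 1e-6

    def test_refit_from_own_solution_is_a_fixed_point(self, small_standardized, unpen):
        again = fit_unpenalized(small_standardized, ModelSpec("location_shift", 3),
                                init=unpen.params, control=FAST, compute_se=False)
        np.testing.assert_allclose(again.params.beta, unpen.params.beta, atol=2e-4)
        assert again.loglik == pytest.approx(unpen.loglik, abs=1e-6)

    def test_parameter_count_for_wide_dispersion_model(self):
        # k=5 with 13 location and 13 dispersion columns: 4+13+13+3 = 33 parameters
        rng = np.random.default_rng(0)
        n = 400
        tab = pd.DataFrame({f"c{i}": rng.normal(size=n) for i in range(6)})
        tab["bin"] = rng.integers(0, 2, n)
        tab["f"] = rng.integers(1, 8, n)
        tab["cluster"] = np.repeat(np.arange(20), 20)
        tab["y"] = rng.integers(1, 6, n)
        schemas = [CovariateSchema(f"c{i}", "continuous") for i in range(6)]
        schemas += [CovariateSchema("bin", "binary", (0, 1)),
                    CovariateSchema("f", "ordinal", tuple(range(1, 8)))]
        data = encode_covariates(tab, schemas, k=5)
        assert data.X.shape[1] == 13
        fit = fit_unpenalized(data, ModelSpec("location_scale", 5),
                              control=FitControl(maxiter=3, fd_scheme="forward"),
                              compute_se=False)
        assert fit.n_parameters == 33


class TestRefitSelected:
    @pytest.fixture(scope="class")
    def unpen(self, small_standardized):
        return fit_unpenalized(small_standardized, ModelSpec("location_shift", 3), control=FAST)

    def test_empty_selection_equals_unpenalized(self, small_standardized, unpen):
        sel = apply_selection(
            Parameters([-1, 1], [1, 2, 3, 4, 5], [5, 4, 3, 2, 1], [[0.1, 0], [0, 0.1]]),
            unpen.x_columns, unpen.z_columns)
        refit = refit_selected(small_standardized, ModelSpec("location_shift", 3), None, sel,
                               control=FAST, compute_se=False, init=unpen.params)
        np.testing.assert_allclose(refit.params.beta, unpen.params.beta, atol=2e-4)
        assert refit.n_parameters == unpen.n_parameters

    def test_fused_levels_share_one_coefficient(self, small_standardized, unpen):
        fused = Parameters([-1, 1], [0.3, -0.3, 0.2, 0.5, 0.5005], np.zeros(5),
                           [[0.1, 0], [0, 0.1]])
        sel = apply_selection(fused, unpen.x_columns, unpen.z_columns)
        refit = refit_selected(small_standardized, ModelSpec("location_shift", 3), None, sel,
                               control=FAST, compute_se=False)
        beta = refit.params.beta
        assert beta[3] == beta[4]  # x3 levels 3 and 4 share one free parameter
        # dispersion entirely excluded: 2 thresholds + 4 location + 0 dispersion + 3
        assert refit.n_parameters == 2 + 4 + 0 + 3
        np.testing.assert_array_equal(refit.params.alpha, 0.0)

    def test_confidence_limits_are_t_intervals(self, small_standardized, unpen):
        from scipy.stats import t as t_dist

        table = unpen.coefficient_table()
        row = table[table.term == "x1"].iloc[0]
        tq = t_dist.ppf(0.975, small_standardized.n_clusters - 1)
        assert row.ci_low == pytest.approx(row.estimate - tq * row.se, rel=1e-10)
        assert row.exp_ci_high == pytest.approx(np.exp(row.estimate + tq * row.se), rel=1e-10)


class TestSelectionDesignMap:
    def test_excluded_and_fused_structure(self):
        from ordisp.penalized import SelectionSets

        sel = SelectionSets(
            excluded_location=frozenset({"x1", "f[2]"}),
            excluded_dispersion=frozenset(),
            fused_groups_location={"f": (("<ref>", 2), (3, 4))},
            fused_groups_dispersion={},
        )
        A, names = selection_design_map(ORDINAL_X, sel.excluded_location,
                                        sel.fused_groups_location)
        assert A.shape == (4, 1)  # only the fused (3,4) group survives
        np.testing.assert_array_equal(A[:, 0], [0, 0, 1, 1])


class TestEmpiricalBayes:
    def test_modes_shared_with_likelihood_machinery(self, small_standardized, bench_params):
        spec = ModelSpec("location_shift", 3)
        fit = fit_unpenalized(small_standardized, spec, control=FAST, compute_se=False)
        eb = empirical_bayes_intercepts(fit, small_standardized)
        first = small_standardized.restrict_to_cluster(small_standardized.cluster_ids[0])
        res = cluster_log_marginal_likelihood(first, spec, fit.params)
        assert eb.b_loc.iloc[0] == pytest.approx(res.posterior_mode.b_loc, abs=1e-7)
        assert eb.b_disp.iloc[0] == pytest.approx(res.posterior_mode.b_disp, abs=1e-7)
        assert (eb.se_b_loc > 0).all()

    def test_prior_dominates_as_sigma_vanishes(self, small_standardized):
        spec = ModelSpec("location_shift", 3)
        fit = fit_unpenalized(small_standardized, spec, control=FAST, compute_se=False)
        tiny = Parameters(fit.params.thresholds, fit.params.beta, fit.params.alpha,
                          np.array([[1e-8, 0], [0, 1e-8]]))
        fit.params = tiny
        eb = empirical_bayes_intercepts(fit, small_standardized)
        assert np.abs(eb.b_loc).max() < 1e-3
        assert np.abs(eb.b_disp).max() < 1e-3

    def test_large_positive_intercept_recovered_in_sign(self, schemas3):
        # one cluster generated with a strongly positive location intercept
        from ordisp import setting_config, simulate_dataset
        from ordisp.simulate import true_parameters

        cfg = setting_config(1, n_clusters=8, cluster_size=25)
        hits = 0
        for seed in range(10):
            b = np.zeros((8, 2))
            b[0, 0] = 1.2
            data = simulate_dataset(cfg, seed, random_effects=b)
            spec = ModelSpec("location_shift", 3)

            class F:
                params = true_parameters(cfg)
                pass

            F.spec = spec
            eb = empirical_bayes_intercepts(F, data)
            hits += eb.b_loc.iloc[0] > 0
        assert hits >= 9


class TestParameterTransform:
    def test_round_trip(self):
        tr = ParameterTransform(k=4, p=2, q=2, dim=2)
        params = Parameters([-1.0, 0.3, 2.0], [0.5, -0.5], [0.1, 0.2],
                            [[0.2, 0.05], [0.05, 0.1]])
        theta = tr.pack(params)
        back = tr.to_params(theta)
        np.testing.assert_allclose(back.thresholds, params.thresholds, atol=1e-10)
        np.testing.assert_allclose(back.beta, params.beta)
        np.testing.assert_allclose(back.Sigma_b, params.Sigma_b, atol=1e-9)

    def test_any_free_vector_yields_valid_parameters(self):
        tr = ParameterTransform(k=5, p=1, q=1, dim=2)
        rng = np.random.default_rng(0)
        for _ in range(50):
            params = tr.to_params(rng.normal(scale=2.0, size=tr.n_free))
            assert np.all(np.diff(params.thresholds) > 0)
            assert np.linalg.eigvalsh(np.atleast_2d(params.Sigma_b)).min() >= -1e-12
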