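"""Tests of the generative model, perturbations and estimation success."""

import numpy as np
import pytest
from dataclasses import replace

from paircause.causality import stat_skew
from paircause.exceptions import DegenerateInputError, InputError
from paircause.simulation import (
    DataGeneratingModel,
    GaussianMixtureSpec,
    PerturbationCondition,
    ShiftedExponentialSpec,
    add_measurement_error,
    default_grid,
    discretize,
    draw_pair,
    estimation_success,
    fit_data_model,
    fit_gaussian_mixture,
    fit_shifted_exponential,
    perturb_confound,
    run_experiment_grid,
)
from paircause.synthetic import make_pair


# ---------------------------------------------------------------------------
# Distribution fitting
# ---------------------------------------------------------------------------

class TestShiftedExponentialFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        v = rng.exponential(scale=1.0, size=10_000) + 2.0
        fit = fit_shifted_exponential(v)
        assert fit.shift == pytest.approx(2.0, abs=0.02)
        assert fit.rate == pytest.approx(1.0, rel=0.05)

    def test_fitted_mean_equals_sample_mean(self, rng):
        v = rng.exponential(scale=2.5, size=500) - 1.0
        fit = fit_shifted_exponential(v)
        assert fit.mean == pytest.approx(v.mean(), abs=1e-12)

    def test_translation_equivariance(self, rng):
        v = rng.exponential(size=200)
        base = fit_shifted_exponential(v)
        moved = fit_shifted_exponential(v + 3.0)
        assert moved.shift == pytest.approx(base.shift + 3.0, abs=1e-10)
        assert moved.rate == pytest.approx(base.rate, rel=1e-10)

    def test_constant_input(self):
        with pytest.raises(DegenerateInputError):
            fit_shifted_exponential(np.full(50, 1.0))


class TestGaussianMixtureFit:
    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(-3, 0.5, 2500), rng.normal(3, 0.5, 2500)])
        fit = fit_gaussian_mixture(v, components=2, seed=0)
        assert np.asarray(fit.means) == pytest.approx([-3.0, 3.0], abs=0.1)
        assert np.asarray(fit.weights) == pytest.approx([0.5, 0.5], abs=0.05)
        assert np.asarray(fit.sds) == pytest.approx([0.5, 0.5], abs=0.1)

    def test_single_component_is_sample_mle(self, rng):
        v = rng.exponential(size=100)
        fit = fit_gaussian_mixture(v, components=1)
        assert fit.means[0] == v.mean()
        assert fit.sds[0] == v.std(ddof=0)

    def test_same_seed_same_fit(self, rng):
        v = rng.standard_normal(400)
        assert fit_gaussian_mixture(v, 3, seed=9) == \
            fit_gaussian_mixture(v, 3, seed=9)

    def test_sample_size_precondition(self, rng):
        with pytest.raises(InputError):
            fit_gaussian_mixture(rng.standard_normal(30), components=4)


class TestFitDataModel:
    def test_recovers_generating_slope(self, mbdi_profile, mbdi_model):
        sample, truth = make_pair(mbdi_profile, seed=0)
        fitted = fit_data_model(sample, seed=0)
        assert fitted.beta == pytest.approx(truth.beta, rel=0.05)

    def test_residual_mixture_is_zero_mean(self, causal_pair):
        fitted = fit_data_model(causal_pair, seed=1)
        assert abs(fitted.resid.mean) < 1e-10

    def test_simulated_marginals_match_input(self, causal_pair):
        fitted = fit_data_model(causal_pair, seed=2)
        x, _, y = draw_pair(replace(fitted, n=100_000), seed=3)
        assert x.std(ddof=1) == pytest.approx(causal_pair.x.std(ddof=1),
                                              rel=0.10)
        assert y.std(ddof=1) == pytest.approx(causal_pair.y.std(ddof=1),
                                              rel=0.10)


# ---------------------------------------------------------------------------
# Drawing and perturbing
# ---------------------------------------------------------------------------

def _toy_model(n=500):
    return DataGeneratingModel(
        beta=0.4,
        exo=ShiftedExponentialSpec(shift=1.0, rate=1.0),
        resid=GaussianMixtureSpec((0.6, 0.4), (-0.4, 0.6), (0.5, 0.8)),
        n=n,
    )


class TestDrawPair:
    def test_structural_identity_is_bitwise(self):
        # y is exactly the structural expression, with no hidden noise
        model = _toy_model()
        x, e, y = draw_pair(model, seed=0)
        np.testing.assert_array_equal(y, model.intercept + model.beta * x + e)

    def test_moments_match_analytic_values(self):
        model = _toy_model(n=100_000)
        x, e, y = draw_pair(model, seed=1)
        assert x.mean() == pytest.approx(model.exo.mean, rel=0.02)
        assert x.std(ddof=1) == pytest.approx(model.exo.sd, rel=0.02)
        assert e.std(ddof=1) == pytest.approx(model.resid.sd, rel=0.02)

    def test_same_seed_identical_triple(self):
        model = _toy_model()
        a = draw_pair(model, seed=5)
        b = draw_pair(model, seed=5)
        for u, v in zip(a, b):
            np.testing.assert_array_equal(u, v)


class TestDiscretize:
    def test_forced_arithmetic_example(self):
        out = discretize([0.0, 0.4, 0.9, 1.0], k=2)
        np.testing.assert_allclose(out, [0.0, 0.0, 0.5, 0.5])

    def test_lattice_properties(self, rng):
        v = rng.standard_normal(500)
        for k in (2, 5, 9):
            out = discretize(v, k)
            assert len(np.unique(out)) <= k
            order = np.argsort(v)
            assert np.all(np.diff(out[order]) >= 0)  # monotone map

    def test_fine_lattice_converges_to_continuous_statistic(self, mbdi_model):
        x, _, y = draw_pair(mbdi_model, seed=4)
        cont = stat_skew(x, y).value
        disc = stat_skew(discretize(x, 1000), discretize(y, 1000)).value
        assert disc == pytest.approx(cont, abs=1e-3)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            discretize(np.ones(10), 4)


class TestPerturbConfound:
    @pytest.mark.parametrize("mode", ["linear", "proportional"])
    def test_lambda_zero_reproduces_unconfounded_draw(self, mode):
        model = _toy_model()
        x, e, y = draw_pair(model, seed=8)
        xc, yc = perturb_confound(model, lam=0.0, mode=mode, seed=8)
        np.testing.assert_array_equal(xc, x)
        np.testing.assert_array_equal(yc, y)

    def test_full_confounding_breaks_direct_path(self):
        # at lambda=1 both variables are functions of z only: the partial
        # correlation of x_conf and y_conf given their shared part comes
        # from e and e_z alone, so repeated draws decorrelate from x
        model = _toy_model(n=20_000)
        x, e, y = draw_pair(model, seed=9)
        xc, yc = perturb_confound(model, lam=1.0, mode="linear", seed=9)
        # x_conf no longer contains x: correlation with the original x
        # stream collapses to sampling noise
        assert abs(np.corrcoef(xc, x)[0, 1]) < 0.03
        assert np.corrcoef(xc, yc)[0, 1] > 0.1  # but z still links the pair

    def test_success_decreases_with_confounding(self, mbdi_model):
        succ = []
        for lam in (0.0, 0.5, 1.0):
            cond = PerturbationCondition("linear_confound", lam=lam,
                                         setting="GM_residual")
            succ.append(estimation_success(mbdi_model, cond, "skew",
                                           reps=200, seed=21).success)
        assert succ[0] >= succ[1] >= succ[2]
        assert 0.35 <= succ[2] <= 0.65  # coin flip at full confounding

    def test_lambda_range_validated(self):
        with pytest.raises(InputError):
            perturb_confound(_toy_model(), lam=1.5, mode="linear")


class TestMeasurementError:
    def test_zero_sd_is_identity(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(add_measurement_error(x, 0.0), x)

    def test_variance_addition(self, rng):
        x = rng.exponential(size=100_000)
        noisy = add_measurement_error(x, 2.0, seed=1)
        assert np.var(noisy) == pytest.approx(np.var(x) + 4.0, rel=0.02)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(InputError):
            add_measurement_error(rng.standard_normal(50), -0.1)

    def test_tanh_success_nonincreasing_in_noise(self, mbdi_model):
        sd_x = mbdi_model.exo.sd
        succ = []
        for mult in (0.0, 1.0, 3.0):
            cond = PerturbationCondition("noise", noise_sd=mult * sd_x)
            succ.append(estimation_success(mbdi_model, cond, "tanh",
                                           reps=150, seed=33).success)
        tol = 3 * np.sqrt(0.25 / 150)  # binomial simulation error
        assert succ[0] >= succ[1] - tol
        assert succ[1] >= succ[2] - tol


# ---------------------------------------------------------------------------
# Estimation success and the experiment grid
# ---------------------------------------------------------------------------

class TestEstimationSuccess:
    def test_unperturbed_model_is_easy(self, mbdi_model):
        cond = PerturbationCondition("none")
        res = estimation_success(mbdi_model, cond, "skew", reps=200, seed=0)
        assert res.success >= 0.99

    def test_counts_are_consistent(self, mbdi_model):
        cond = PerturbationCondition("discretize", k=3)
        res = estimation_success(mbdi_model, cond, "skew", reps=50, seed=1)
        assert 0 <= res.n_correct <= res.reps
        assert res.success == res.n_correct / res.reps

    def test_deterministic_given_seed(self, mbdi_model):
        cond = PerturbationCondition("proportional_confound", lam=0.4,
                                     setting="Different_residuals")
        a = estimation_success(mbdi_model, cond, "tanh", reps=60, seed=5)
        b = estimation_success(mbdi_model, cond, "tanh", reps=60, seed=5)
        assert a == b

    def test_doubling_reps_is_binomially_consistent(self, mbdi_model):
        cond = PerturbationCondition("linear_confound", lam=0.6,
                                     setting="Exp_residual")
        a = estimation_success(mbdi_model, cond, "skew", reps=150, seed=2)
        b = estimation_success(mbdi_model, cond, "skew", reps=300, seed=3)
        se = np.sqrt(a.success * (1 - a.success) / 150 + 1e-4)
        assert abs(a.success - b.success) < 3 * se + 0.02

    def test_zero_reps_rejected(self, mbdi_model):
        with pytest.raises(InputError):
            estimation_success(mbdi_model, PerturbationCondition("none"),
                               "skew", reps=0)

    def test_discretization_success_nondecreasing_in_k(self, mbdi_model):
        succ = [estimation_success(mbdi_model,
                                   PerturbationCondition("discretize", k=k),
                                   "skew", reps=100, seed=13).success
                for k in (2, 4, 8, 15)]
        tol = 3 * np.sqrt(0.01 / 100)
        assert all(b >= a - tol for a, b in zip(succ, succ[1:]))


class TestExperimentGrid:
    def test_default_grid_has_expected_condition_count(self, mbdi_model):
        grid = default_grid(mbdi_model)
        # 14 discretization + 2 modes * 4 settings * 15 lambdas + 15 noise
        assert len(grid) == 14 + 2 * 4 * 15 + 15 == 149

    def test_grid_run_is_deterministic(self, mbdi_model):
        conditions = [PerturbationCondition("discretize", k=2),
                      PerturbationCondition("linear_confound", lam=0.5)]
        a = run_experiment_grid(mbdi_model, methods=("skew", "tanh"),
                                reps=20, seed=7, conditions=conditions)
        b = run_experiment_grid(mbdi_model, methods=("skew", "tanh"),
                                reps=20, seed=7, conditions=conditions)
        assert a.equals(b)

    def test_lambda_zero_matches_unperturbed_condition(self, mbdi_model):
        cond_none = PerturbationCondition("none")
        base = estimation_success(mbdi_model, cond_none, "skew",
                                  reps=100, seed=17).success
        grid = run_experiment_grid(
            mbdi_model, methods=("skew",), reps=100, seed=17,
            conditions=[PerturbationCondition("linear_confound", lam=0.0)])
        assert abs(grid.success.iloc[0] - base) <= 3 * np.sqrt(0.01 / 100) + 0.02


class TestSpecValidation:
    def test_model_invariants(self):
        with pytest.raises(InputError):
            DataGeneratingModel(0.3, ShiftedExponentialSpec(0, 1.0),
                                GaussianMixtureSpec((1.0,), (0.5,), (1.0,)),
                                n=100)  # nonzero-mean residual
        with pytest.raises(InputError):
            ShiftedExponentialSpec(0.0, -1.0)
        with pytest.raises(InputError):
            GaussianMixtureSpec((0.5, 0.4), (0.0, 1.0), (1.0, 1.0))

    def test_condition_invariants(self):
        with pytest.raises(InputError):
            PerturbationCondition("discretize", k=1)
        with pytest.raises(InputError):
            PerturbationCondition("linear_confound", lam=-0.1)
        with pytest.raises(InputError):
            PerturbationCondition("noise", noise_sd=-1.0)
        with pytest.raises(InputError):
            PerturbationCondition("confound", lam=0.5)
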