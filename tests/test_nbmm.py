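import math

import numpy as np
import pytest

from nbmmseq import FitOptions, SimulationDesign, fit_nbmm, negbin_logpmf
from nbmmseq.fanova import (
    additive_spec,
    constant_spec,
    evaluate_eta,
    full_spec,
)
from nbmmseq.nbmm import (
    estimate_nu,
    fit_inner,
    initial_nu,
    nu_objective,
    penalized_objective,
    select_hyperparameters,
    working_quantities,
    _prepare_design,
)
from nbmmseq.simulate import eta_mean, simulate_gene


class TestNegbinLogpmf:
    def test_zero_count_reduces_to_p_power_nu(self):
        # gamma terms cancel at y = 0: P = p^nu
        assert negbin_logpmf(0, 2.0, 0.5) == pytest.approx(math.log(0.25))

    def test_geometric_case_normalises(self):
        # nu = 1, p = 0.5: P(y) = 0.5^(y+1)
        y = np.arange(0, 60)
        total = np.exp(negbin_logpmf(y, 1.0, 0.5)).sum()
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_gamma_formula(self):
        y, nu, p = 3, 2.5, 0.3
        direct = (
            math.lgamma(nu + y) - math.lgamma(y + 1) - math.lgamma(nu)
            + nu * math.log(p) + y * math.log(1 - p)
        )
        assert negbin_logpmf(y, nu, p) == pytest.approx(direct, abs=1e-12)

    def test_invalid_probability_errors(self):
        with pytest.raises(ValueError):
            negbin_logpmf(1, 2.0, 1.0)


class TestWorkingQuantities:
    def test_stationary_point(self):
        wd = working_quantities(np.array([0.0]), np.array([1000.0]), 1000.0)
        assert wd.mu[0] == pytest.approx(0.0)
        assert wd.omega[0] == pytest.approx(500.0)
        assert wd.Ytilde[0] == pytest.approx(0.0)

    def test_mean_matched_response_reproduces_zeta(self):
        zeta = np.array([-1.2, 0.4, 2.0])
        nu = 50.0
        p = 1 / (1 + np.exp(-zeta))
        Y = nu * (1 - p) / p  # score is zero at the mean
        wd = working_quantities(zeta, Y, nu)
        np.testing.assert_allclose(wd.mu, 0.0, atol=1e-9)
        np.testing.assert_allclose(wd.Ytilde, zeta, atol=1e-9)

    def test_mu_is_gradient_of_loglik_term(self):
        # l(zeta) = (nu + Y) log(1 + e^zeta) - nu zeta; dl/dzeta = mu
        rng = np.random.default_rng(3)
        zeta = rng.normal(0, 1.5, 20)
        Y = rng.poisson(40, 20).astype(float)
        nu = 17.0
        h = 1e-6
        l = lambda z: (nu + Y) * np.logaddexp(0, z) - nu * z
        grad = (l(zeta + h) - l(zeta - h)) / (2 * h)
        wd = working_quantities(zeta, Y, nu)
        np.testing.assert_allclose(wd.mu, grad, atol=1e-6)


class TestPenalizedObjective:
    def test_closed_form_at_zero(self):
        Y = np.array([3.0, 7.0, 1.0])
        nu = 2.0
        val = penalized_objective(
            np.zeros(3), Y, nu, np.zeros(2), 1.0, np.zeros(0), np.zeros((0, 0)),
            3, 0.5,
        )
        assert val == pytest.approx(np.sum((nu + Y) * math.log(2.0)))

    def test_zero_penalty_is_henderson_likelihood(self):
        rng = np.random.default_rng(1)
        zeta = rng.normal(size=6)
        Y = rng.poisson(20, 6).astype(float)
        b = rng.normal(size=2)
        c = rng.normal(size=3)
        gram = np.eye(3)
        with_pen = penalized_objective(zeta, Y, 5.0, b, 2.0, c, gram, 6, 0.0)
        direct = float(
            np.sum((5.0 + Y) * np.logaddexp(0, zeta) - 5.0 * zeta) + (b ** 2).sum() / 2.0
        )
        assert with_pen == pytest.approx(direct)


class TestInnerLoop:
    def test_objective_trace_monotone(self, de_gene, fast_options):
        fit = fit_nbmm(de_gene, full_spec(2), fast_options)
        trace = np.asarray(fit.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * (1 + np.abs(trace[:-1])))

    def test_single_exon_gene_is_fittable(self):
        design = SimulationDesign(setting="linear", replicates=3, z=(0.25,))
        rng = np.random.default_rng(9)
        ds = simulate_gene(lambda t, g: eta_mean("linear", t, g), design, rng, "k1")
        fit = fit_nbmm(ds, full_spec(2), FitOptions(fix_nu=1000.0))
        # z b is confounded with the baseline; the ridge keeps it small
        assert abs(fit.b[0]) < 3.0
        assert fit.converged

    def test_constant_data_recovers_flat_surface(self):
        design = SimulationDesign(setting="linear", replicates=3, nu=1e6, sigma_b=0.0)
        rng = np.random.default_rng(2)
        ds = simulate_gene(lambda t, g: 1.0, design, rng, "flat")
        fit = fit_nbmm(ds, full_spec(2), FitOptions(fix_nu=1e6))
        from nbmmseq.fanova import decompose_eta

        comp = decompose_eta(fit.eta, np.linspace(0, 1, 33))
        assert np.max(np.abs(comp["eta1"])) < 1e-2
        assert np.max(np.abs(comp["eta2"])) < 1e-2
        assert np.max(np.abs(comp["eta12"])) < 1e-2


class TestNuEstimation:
    def test_minimizer_contract(self, de_gene, fast_options):
        fit = fit_nbmm(de_gene, full_spec(2), fast_options)
        Y = de_gene.counts.astype(float).ravel()
        nu_hat = estimate_nu(Y, fit.fitted_p)
        at = nu_objective(nu_hat, Y, fit.fitted_p)
        assert at <= nu_objective(0.5 * nu_hat, Y, fit.fitted_p) + 1e-10
        assert at <= nu_objective(2.0 * nu_hat, Y, fit.fitted_p) + 1e-10

    def test_single_zero_count_hits_boundary(self):
        # with y = 0 the gamma terms cancel and the objective is -nu log p,
        # which for p = 0.5 grows linearly in nu: the minimiser sits at the
        # lower boundary and a warning is raised
        with pytest.warns(RuntimeWarning, match="boundary"):
            nu = estimate_nu(np.array([0.0]), np.array([0.5]))
        assert nu < 0.02

    def test_recovery_with_true_probabilities(self):
        # pooled over 50 genes at nu = 1000, supplying the generative p
        from scipy.special import expit

        design = SimulationDesign(setting="linear", replicates=3)
        rng_root = np.random.SeedSequence(123)
        Ys, ps = [], []
        for i, ss in enumerate(rng_root.spawn(50)):
            rng = np.random.default_rng(ss)
            z = np.asarray(design.z)
            b = rng.normal(0, 1, z.size)
            times = np.tile(np.repeat(np.asarray(design.times), design.replicates), 2)
            conds = np.repeat([1, 2], 8 * design.replicates)
            eta = np.array([eta_mean("linear", t, g) for t, g in zip(times, conds)])
            zeta = eta[:, None] + (z * b)[None, :]
            p = expit(zeta)
            Ys.append(rng.negative_binomial(design.nu, p).ravel())
            ps.append(p.ravel())
        nu_hat = estimate_nu(np.concatenate(Ys), np.concatenate(ps))
        assert abs(nu_hat - 1000.0) / 1000.0 < 0.15


class TestHyperparameterSelection:
    def test_score_is_deterministic(self, de_gene):
        a = select_hyperparameters(de_gene, full_spec(2), nu=1000.0)
        b = select_hyperparameters(de_gene, full_spec(2), nu=1000.0)
        assert a[0] == b[0] and a[2] == b[2]
        assert a[3].gml == b[3].gml

    def test_noiseless_linear_trend_selects_heavy_smoothing(self):
        design = SimulationDesign(setting="linear", replicates=3, nu=1e6, sigma_b=0.0)
        rng = np.random.default_rng(8)
        ds = simulate_gene(lambda t, g: eta_mean("linear", t, g), design, rng, "lin")
        fit = fit_nbmm(ds, full_spec(2), FitOptions(fix_nu=1e6))
        t = np.asarray(design.times)
        for g in (1, 2):
            est = evaluate_eta(fit.eta, t, g, scaled=False)
            truth = eta_mean("linear", t, g)
            offset = np.mean(est - truth)  # baseline absorbs mean of z b
            assert np.max(np.abs(est - truth - offset)) < 1e-2

    def test_cyclic_truth_is_tracked(self, cyclic_sim):
        ds = cyclic_sim.datasets[0]
        fit = fit_nbmm(ds, full_spec(2))
        t = np.array(cyclic_sim.design.times)
        for g in (1, 2):
            est = evaluate_eta(fit.eta, t, g, scaled=False)
            truth = eta_mean("cyclic", t, g)
            offset = np.mean(est - truth)
            rmse = np.sqrt(np.mean((est - truth - offset) ** 2))
            assert rmse < 0.2


class TestFullFit:
    def test_crossing_design_sign_pattern(self, de_gene):
        # linear setting: eta rises with t in condition 1, falls in condition 2
        fit = fit_nbmm(de_gene, full_spec(2))
        t = np.sort(np.unique(de_gene.times))
        up = evaluate_eta(fit.eta, t, 1, scaled=False)
        down = evaluate_eta(fit.eta, t, 2, scaled=False)
        assert up[-1] - up[0] > 0.5
        assert down[-1] - down[0] < -0.5

    def test_refit_at_fixed_hyperparameters_is_a_fixed_point(self, de_gene):
        fit = fit_nbmm(de_gene, full_spec(2))
        opts = FitOptions(
            fix_nu=fit.nu, fix_hyper=(fit.lambda_, fit.thetas[1], fit.sigma2)
        )
        refit = fit_nbmm(de_gene, full_spec(2), opts)
        # the stored hyperparameters reproduce the same fitted surface; the
        # agreement scale is set by the inner loop's objective tolerance
        t = np.linspace(0, 1, 17)
        for g in (1, 2):
            np.testing.assert_allclose(
                evaluate_eta(refit.eta, t, g), evaluate_eta(fit.eta, t, g),
                atol=1e-4,
            )
        np.testing.assert_allclose(refit.b, fit.b, atol=1e-4)

    def test_nesting_of_objectives(self, de_gene):
        # at shared (nu, sigma2, lambda) the larger function space fits at
        # least as well
        opts = FitOptions(fix_nu=1000.0, fix_hyper=(1e-3, 1.0, 1.0))
        full = fit_nbmm(de_gene, full_spec(2), opts)
        reduced = fit_nbmm(de_gene, additive_spec(2), opts)
        assert full.objective <= reduced.objective + 1e-6

    def test_lambda_to_infinity_kills_curvature(self, de_gene):
        opts = FitOptions(fix_nu=1000.0, fix_hyper=(1e8, 1.0, 1.0))
        fit = fit_nbmm(de_gene, full_spec(2), opts)
        assert fit.penalty_J < 1e-6
        # fitted eta is linear in t within each condition
        t = np.linspace(0, 1, 21)
        for g in (1, 2):
            vals = evaluate_eta(fit.eta, t, g)
            resid = vals - np.polyval(np.polyfit(t, vals, 1), t)
            assert np.max(np.abs(resid)) < 1e-4

    def test_insufficient_time_points_error(self):
        design = SimulationDesign(setting="linear", replicates=3,
                                  times=(0.1, 0.2))
        rng = np.random.default_rng(1)
        ds = simulate_gene(lambda t, g: 1.0, design, rng, "short")
        with pytest.raises(ValueError, match="insufficient time points"):
            fit_nbmm(ds, full_spec(2))

    def test_nu_initialisation_is_clipped(self, de_gene):
        nu0 = initial_nu(de_gene)
        assert 1.0 <= nu0 <= 1e4

    def test_free_nu_recovers_dispersion_scale(self, linear_sim):
        # per-gene estimates vary, but the scale should be right
        nus = [fit_nbmm(ds, full_spec(2)).nu for ds in linear_sim.datasets[:6]]
        assert np.median(nus) > 300
        assert np.median(nus) < 5000
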