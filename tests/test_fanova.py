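import numpy as np
import pytest
from hypothesis import given, strategies as st

from nbmmseq import FitOptions, fit_nbmm
from nbmmseq.fanova import (
    FanovaSpec,
    assemble_model_matrices,
    constant_spec,
    cubic_time_kernel,
    decompose_eta,
    evaluate_eta,
    full_spec,
    interaction_kernel,
    map_times_to_unit,
    null_space_basis,
    treatment_kernel,
)

GAUSS_X, GAUSS_W = np.polynomial.legendre.leggauss(64)
GRID = 0.5 * (GAUSS_X + 1.0)  # 64-point Gauss-Legendre nodes on [0, 1]
W = 0.5 * GAUSS_W


def integrate01(values: np.ndarray) -> float:
    return float(np.sum(W * values))


class TestTimeMapping:
    def test_affine_map(self):
        t = np.arange(1, 9) / 10
        s, (lo, hi) = map_times_to_unit(t)
        np.testing.assert_allclose(s, np.arange(8) / 7)
        assert (lo, hi) == (0.1, 0.8)

    def test_constant_times_map_to_half(self):
        s, _ = map_times_to_unit(np.array([2.0, 2.0]))
        np.testing.assert_allclose(s, 0.5)

    def test_idempotent_on_unit_data(self):
        t = np.array([0.0, 0.3, 1.0])
        s, _ = map_times_to_unit(t)
        np.testing.assert_allclose(s, t)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            map_times_to_unit(np.array([]))


class TestKernels:
    def test_cubic_kernel_origin_value(self):
        # k2(0) = 1/12, k4(0) = -1/720  =>  R(0,0) = 1/144 + 1/720 = 1/120
        assert cubic_time_kernel(0.0, 0.0) == pytest.approx(1.0 / 120.0, abs=1e-15)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_cubic_kernel_symmetric(self, s, t):
        assert cubic_time_kernel(s, t) == pytest.approx(cubic_time_kernel(t, s))

    @pytest.mark.parametrize("t0", [0.0, 0.17, 0.5, 0.93])
    def test_cubic_kernel_integrates_to_zero(self, t0):
        # split the quadrature at s = t0, where |s - t| kinks
        total = 0.0
        for lo, hi in [(0.0, t0), (t0, 1.0)]:
            if hi > lo:
                nodes = lo + (hi - lo) * GRID
                total += (hi - lo) * np.sum(W * cubic_time_kernel(nodes, t0))
        assert abs(total) < 1e-10

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cubic_time_kernel(1.5, 0.2)

    @pytest.mark.parametrize(
        "g1,g2,G,expected", [(1, 1, 2, 0.5), (1, 2, 2, -0.5), (1, 1, 3, 2 / 3)]
    )
    def test_treatment_kernel_values(self, g1, g2, G, expected):
        assert treatment_kernel(g1, g2, G) == pytest.approx(expected)

    @pytest.mark.parametrize("G", [2, 3, 5])
    def test_treatment_kernel_rows_sum_to_zero(self, G):
        for g1 in range(1, G + 1):
            total = sum(treatment_kernel(g1, g2, G) for g2 in range(1, G + 1))
            assert total == pytest.approx(0.0, abs=1e-14)

    def test_treatment_kernel_invalid_label(self):
        with pytest.raises(ValueError):
            treatment_kernel(0, 1, 2)

    @given(st.floats(0, 1), st.floats(0, 1),
           st.integers(1, 3), st.integers(1, 3))
    def test_interaction_kernel_is_product(self, s, t, g1, g2):
        v = interaction_kernel(s, g1, t, g2, 3)
        assert v == pytest.approx(
            cubic_time_kernel(s, t) * treatment_kernel(g1, g2, 3)
        )

    def test_interaction_kernel_side_conditions(self):
        G = 2
        total = sum(interaction_kernel(0.3, 1, 0.7, g2, G) for g2 in (1, 2))
        assert total == pytest.approx(0.0, abs=1e-14)
        total = 0.0
        for lo, hi in [(0.0, 0.3), (0.3, 1.0)]:  # split at the |s-t| kink
            nodes = lo + (hi - lo) * GRID
            vals = interaction_kernel(np.full_like(nodes, 0.3), 1, nodes, 2, G)
            total += (hi - lo) * np.sum(W * vals)
        assert abs(total) < 1e-10

    @pytest.mark.parametrize("kernel", ["time", "interaction"])
    def test_kernels_psd_on_random_points(self, kernel):
        rng = np.random.default_rng(11)
        for _ in range(5):
            t = rng.uniform(0, 1, 12)
            g = rng.integers(1, 3, 12)
            if kernel == "time":
                K = cubic_time_kernel(t[:, None], t[None, :])
            else:
                K = cubic_time_kernel(t[:, None], t[None, :]) * treatment_kernel(
                    g[:, None], g[None, :], 2
                )
            ev = np.linalg.eigvalsh(K)
            assert ev.min() >= -1e-9 * max(ev.max(), 1e-30)


class TestAssembly:
    def _coords(self):
        t = np.tile(np.arange(8) / 7, 2)
        g = np.repeat([1, 2], 8)
        return t, g

    def test_constant_spec_is_intercept_only(self):
        t, g = self._coords()
        dm = assemble_model_matrices(t, g, np.array([0.1, 0.25]), constant_spec(2))
        assert dm.S.shape[1] == 1
        np.testing.assert_allclose(dm.S, 1.0)
        assert dm.n_anchor == 0

    def test_gram_psd_and_linear_in_theta(self):
        t, g = self._coords()
        dm = assemble_model_matrices(t, g, np.array([0.1]), full_spec(2))
        Q1 = dm.gram((1.0, 1.0))
        ev = np.linalg.eigvalsh(Q1)
        assert ev.min() >= -1e-10
        Q2 = dm.gram((2.0, 1.0))
        # doubling theta_1 doubles the time-kernel contribution exactly
        np.testing.assert_allclose(Q2 - Q1, dm.Rc_gram, atol=1e-14)

    def test_confounded_treatment_errors(self):
        t = np.arange(8) / 7
        g = np.ones(8, dtype=int)
        with pytest.raises(ValueError, match="G < 2|rank"):
            assemble_model_matrices(
                t, g, np.array([0.1]), FanovaSpec(True, True, False, G=1)
            )

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="interaction requires"):
            FanovaSpec(include_time=False, include_treatment=True,
                       include_interaction=True)


class TestEtaEvaluation:
    def _fit(self, de_gene, fast_options):
        return fit_nbmm(de_gene, full_spec(2), fast_options)

    def test_zero_coefficients_evaluate_to_zero(self, de_gene, fast_options):
        fit = self._fit(de_gene, fast_options)
        rep = fit.eta
        rep2 = type(rep)(
            d=np.zeros_like(rep.d), c=np.zeros_like(rep.c), labels=rep.labels,
            anchors_t=rep.anchors_t, anchors_g=rep.anchors_g, thetas=rep.thetas,
            spec=rep.spec, time_range=rep.time_range,
        )
        np.testing.assert_allclose(evaluate_eta(rep2, GRID[:8], 1), 0.0)

    def test_constant_only_representation(self, de_gene, fast_options):
        fit = fit_nbmm(de_gene, constant_spec(2), fast_options)
        rep = fit.eta
        rep_c = type(rep)(
            d=np.array([3.2]), c=rep.c, labels=["const"],
            anchors_t=rep.anchors_t, anchors_g=rep.anchors_g,
            thetas=rep.thetas, spec=rep.spec, time_range=rep.time_range,
        )
        np.testing.assert_allclose(evaluate_eta(rep_c, GRID[:5], 1), 3.2)

    def test_evaluation_matches_training_values(self, de_gene, fast_options):
        fit = self._fit(de_gene, fast_options)
        eta_at = evaluate_eta(fit.eta, de_gene.times, de_gene.conditions, scaled=False)
        # stored zeta = log(beta) + eta + z b; strip offset and random effect
        k = 0
        zeta_k = fit.fitted_zeta[k::de_gene.K]
        expect = (
            zeta_k - np.log(de_gene.lib_sizes)
            - de_gene.exon_lengths[k] * fit.b[k]
        )
        np.testing.assert_allclose(eta_at, expect, atol=1e-10)

    def test_decomposition_sums_to_evaluation(self, de_gene, fast_options):
        fit = self._fit(de_gene, fast_options)
        comp = decompose_eta(fit.eta, GRID)
        for gi, g in enumerate((1, 2)):
            total = comp["eta0"] + comp["eta1"] + comp["eta2"][gi] + comp["eta12"][:, gi]
            np.testing.assert_allclose(
                total, evaluate_eta(fit.eta, GRID, g), atol=1e-8
            )

    def test_no_interaction_spec_gives_zero_interaction(self, de_gene, fast_options):
        from nbmmseq.fanova import additive_spec

        fit = fit_nbmm(de_gene, additive_spec(2), fast_options)
        comp = decompose_eta(fit.eta, GRID)
        np.testing.assert_allclose(comp["eta12"], 0.0, atol=1e-12)

    def test_side_conditions_on_fitted_model(self, de_gene, fast_options):
        fit = self._fit(de_gene, fast_options)
        comp = decompose_eta(fit.eta, GRID)
        assert abs(integrate01(comp["eta1"])) < 1e-8
        assert abs(comp["eta2"].sum()) < 1e-8
        for gi in range(2):
            assert abs(integrate01(comp["eta12"][:, gi])) < 1e-8
        np.testing.assert_allclose(comp["eta12"].sum(axis=1), 0.0, atol=1e-8)

    def test_out_of_domain_evaluation_errors(self, de_gene, fast_options):
        fit = self._fit(de_gene, fast_options)
        with pytest.raises(ValueError):
            evaluate_eta(fit.eta, [1.4], 1)

    def test_pde_truth_gene_has_small_interaction(self, fast_options):
        # construct a parallel-DE gene: condition offset, no interaction
        from nbmmseq.simulate import SimulationDesign, simulate_gene

        design = SimulationDesign(setting="linear", replicates=3, nu=100000.0,
                                  sigma_b=0.2)
        rng = np.random.default_rng(4)
        fn = lambda t, g: 2.0 * t + (0.8 if g == 2 else 0.0)
        ds = simulate_gene(fn, design, rng, "pde")
        fit = fit_nbmm(ds, full_spec(2), FitOptions(fix_nu=100000.0))
        comp = decompose_eta(fit.eta, GRID)
        assert np.max(np.abs(comp["eta12"])) < 0.1
        assert np.max(np.abs(comp["eta2"])) > 0.2
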