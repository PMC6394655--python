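"""Classical known-ratio solvers: closed form, iteration, uncertainty budget."""

import numpy as np
import pytest

import biodose as bd
from biodose.errors import BelowBackgroundError, DomainError
from tests.conftest import random_feasible_case


class TestAnalytical:
    def test_silene_worked_example(self, silene_sample, silene_curve):
        res = bd.solve_analytical(silene_sample, 0.64, silene_curve)
        assert res.d_gamma == pytest.approx(3.670, abs=5e-4)
        assert res.d_n == pytest.approx(2.349, abs=5e-4)
        assert res.d_n / res.d_gamma == pytest.approx(0.64, rel=1e-9)

    def test_clor_worked_example(self, clor_sample, clor_curve):
        res = bd.solve_analytical(clor_sample, 0.087, clor_curve)
        assert res.d_gamma == pytest.approx(0.797, abs=2e-3)
        assert res.d_n == pytest.approx(0.069, abs=1e-3)

    def test_solution_satisfies_yield_equation(self, silene_sample, silene_curve):
        res = bd.solve_analytical(silene_sample, 0.64, silene_curve)
        yf = bd.yield_mixed(res.d_n, res.d_gamma, silene_curve)
        assert abs(yf - silene_sample.yf) < 1e-9

    def test_background_only_sample_gives_zero_doses(self):
        c = bd.CalibrationCurve(y0=0.002, alpha=0.3, beta=0.01, gamma_coef=0.05)
        s = bd.AberrationSample(u=2, w=1000)  # u/w == y0 exactly
        res = bd.solve_analytical(s, 1.3, c)
        assert res.d_gamma == 0.0 and res.d_n == 0.0

    def test_below_background_rejected(self):
        c = bd.CalibrationCurve(y0=0.01, alpha=0.3, beta=0.01, gamma_coef=0.05)
        with pytest.raises(BelowBackgroundError):
            bd.solve_analytical(bd.AberrationSample(u=1, w=1000), 0.5, c)

    def test_negative_rho_rejected(self, silene_sample, silene_curve):
        with pytest.raises(DomainError):
            bd.solve_analytical(silene_sample, -0.1, silene_curve)

    def test_ratio_limits(self, silene_sample, silene_curve):
        # rho -> 0 equals the pure-gamma quadratic solve
        res0 = bd.solve_analytical(silene_sample, 0.0, silene_curve)
        a, b, cc = silene_curve.gamma_coef, silene_curve.beta, -silene_sample.yf
        pure_gamma = (-b + np.sqrt(b * b - 4 * a * cc)) / (2 * a)
        assert res0.d_gamma == pytest.approx(pure_gamma, rel=1e-12)
        assert res0.d_n == 0.0
        # rho -> inf approaches the pure-neutron linear solve
        res_inf = bd.solve_analytical(silene_sample, 1e6, silene_curve)
        assert res_inf.d_n == pytest.approx(silene_sample.yf / silene_curve.alpha, rel=1e-3)


class TestIterative:
    @pytest.mark.parametrize(
        "u, w, rho, curve_name, dg, dn",
        [(85, 28, 0.64, "silene", 3.670, 2.349),
         (35, 500, 0.087, "clor_bm", 0.796, 0.069)],
    )
    def test_worked_examples_match_analytical(self, u, w, rho, curve_name, dg, dn):
        curve = bd.load_curve(curve_name)
        s = bd.AberrationSample(u=u, w=w)
        res = bd.solve_iterative(s, rho, curve)
        ana = bd.solve_analytical(s, rho, curve)
        assert res.d_gamma == pytest.approx(ana.d_gamma, rel=1e-5)
        assert res.d_gamma == pytest.approx(dg, rel=0.01)
        assert res.d_n == pytest.approx(dn, rel=0.01)
        assert res.diagnostics["converged"]

    def test_agrees_with_analytical_on_random_inputs(self, rng):
        tol = 1e-6
        n_done = 0
        while n_done < 300:
            case = random_feasible_case(rng)
            if case is None:
                continue
            sample, rho, _, curve = case
            ana = bd.solve_analytical(sample, rho, curve)
            ite = bd.solve_iterative(sample, rho, curve, tol=tol)
            assert abs(ite.d_gamma - ana.d_gamma) <= 10 * tol * max(ana.d_gamma, 1.0)
            n_done += 1

    def test_round_trip_recovers_true_dose(self, rng):
        # exact-count samples generated through the forward model
        for _ in range(50):
            case = random_feasible_case(rng, w=10**6)
            if case is None:
                continue
            sample, rho, d_true, curve = case
            res = bd.solve_iterative(sample, rho, curve, tol=1e-9)
            assert res.d_gamma == pytest.approx(d_true, rel=1e-4)

    def test_zero_ratio_routes_to_pure_gamma(self, clor_sample, clor_curve):
        res = bd.solve_iterative(clor_sample, 0.0, clor_curve)
        ana = bd.solve_analytical(clor_sample, 0.0, clor_curve)
        assert res.d_gamma == pytest.approx(ana.d_gamma, rel=1e-9)
        assert res.d_n == 0.0


class TestUncertainty:
    def test_poisson_only_when_no_sds(self):
        c = bd.CalibrationCurve(y0=0.0, alpha=0.3, beta=0.01, gamma_coef=0.05)
        s = bd.AberrationSample(u=400, w=1000)
        sd_g, sd_n, info = bd.propagate_uncertainty_classical(s, 0.5, c)
        assert info["label"] == "poisson_only"
        assert sd_g > 0

    def test_silene_budget_same_order_as_published(self, silene_sample, silene_curve):
        sd_g, sd_n, info = bd.propagate_uncertainty_classical(
            silene_sample, 0.64, silene_curve, sd_rho=0.25
        )
        assert info["label"] == "finite_increments"
        # order-of-magnitude agreement with the ~2 Gy published budget
        assert 0.2 < sd_g < 8.0
        assert 0.13 < sd_n < 6.0

    def test_doubling_sds_increases_propagated_uncertainty(self, silene_sample):
        base = bd.load_curve("silene")
        doubled = base.replace(sd_alpha=2 * base.sd_alpha, sd_beta=2 * base.sd_beta,
                               sd_gamma=2 * base.sd_gamma)
        sd1, _, _ = bd.propagate_uncertainty_classical(silene_sample, 0.64, base, sd_rho=0.25)
        sd2, _, _ = bd.propagate_uncertainty_classical(silene_sample, 0.64, doubled, sd_rho=0.5)
        assert sd2 > sd1
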