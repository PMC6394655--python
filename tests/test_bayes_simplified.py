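"""Simplified Bayesian posterior: marginalization over the ratio prior."""

import numpy as np
import pytest

import biodose as bd
from biodose.bayes import DosePosterior, cramer_rao_sd
from biodose.errors import UndefinedCurvatureError
from tests.conftest import random_feasible_case


@pytest.fixture(scope="module")
def clor_pair():
    sample = bd.AberrationSample(u=35, w=500)
    curve = bd.load_curve("clor_bm")
    prior = bd.GaussianPrior(0.92, 0.02)
    return bd.estimate_pair(sample, curve, prior)


class TestPosteriorShape:
    def test_normalized_on_grid(self, clor_pair):
        for post in clor_pair.posteriors.values():
            z = np.trapezoid(post.density, post.dose_grid)
            assert z == pytest.approx(1.0, abs=1e-6)

    def test_tails_decay_below_peak(self, clor_pair):
        for post in clor_pair.posteriors.values():
            assert post.density[-1] <= 1e-6 * post.density.max()

    def test_credible_interval_brackets_mode(self, clor_pair):
        for post in clor_pair.posteriors.values():
            lo, hi = post.credible_interval
            assert lo <= post.point_estimate_mode <= hi


class TestPointEstimates:
    def test_clor_gaussian_prior_doses(self, clor_pair):
        # reactor-field sample under the measured-fraction prior
        assert clor_pair.d_gamma == pytest.approx(0.798, rel=5e-3)
        assert clor_pair.d_n == pytest.approx(0.071, rel=0.02)

    def test_clor_scaled_gaussian_matches_gaussian(self, clor_pair):
        sample = bd.AberrationSample(u=35, w=500)
        curve = bd.load_curve("clor_bm")
        prior = bd.ScaledGaussianPrior(0.087, 0.02 / 0.92**2)
        res = bd.estimate_pair(sample, curve, prior)
        assert res.d_gamma == pytest.approx(clor_pair.d_gamma, rel=5e-3)
        assert res.d_n == pytest.approx(clor_pair.d_n, rel=0.02)

    def test_constant_prior_far_from_informed_estimate(self):
        # with no ratio information the gamma estimate collapses well below
        # the physically measured 0.782 Gy
        sample = bd.AberrationSample(u=35, w=500)
        curve = bd.load_curve("clor_bm")
        res = bd.estimate_pair(sample, curve, bd.ConstantPrior())
        assert abs(res.d_gamma - 0.782) / 0.782 > 0.5

    def test_zero_count_sharp_prior_gives_zero_doses(self):
        c = bd.CalibrationCurve(y0=0.0, alpha=0.3, beta=0.01, gamma_coef=0.05)
        s = bd.AberrationSample(u=0, w=100)
        res = bd.estimate_pair(s, c, bd.GaussianPrior(0.9, 0.01),
                               bd.GridSpec(n_points=200))
        assert res.d_gamma == 0.0
        assert res.d_n == 0.0


class TestDegeneratePriorLimit:
    def test_sharp_prior_recovers_classical_solution(self, rng):
        # a near-point prior on theta must reproduce the known-ratio solver
        n_done = 0
        while n_done < 12:
            case = random_feasible_case(rng)
            if case is None:
                continue
            sample, rho, _, curve = case
            rho = min(rho, 4.0)
            theta = bd.theta_from_rho(rho)
            if not 0.05 < theta < 0.98:
                continue
            ana = bd.solve_analytical(sample, rho, curve)
            if ana.d_gamma < 0.05:
                continue
            post = bd.posterior_dose(sample, curve, bd.GaussianPrior(theta, 1e-4),
                                     "gamma", bd.GridSpec(n_points=500))
            assert post.point_estimate_mode == pytest.approx(ana.d_gamma, rel=5e-3)
            n_done += 1


class TestConsistencyProperties:
    def test_doubling_counts_sharpens_but_keeps_mode(self):
        curve = bd.load_curve("clor_bm")
        prior = bd.GaussianPrior(0.92, 0.02)
        r1 = bd.estimate_pair(bd.AberrationSample(35, 500), curve, prior)
        r2 = bd.estimate_pair(bd.AberrationSample(70, 1000), curve, prior)
        assert r2.sd_gamma < r1.sd_gamma
        assert r2.sd_n < r1.sd_n
        assert r2.d_gamma == pytest.approx(r1.d_gamma, rel=0.01)

    def test_component_modes_consistent_with_prior_ratio(self, clor_pair):
        # sharp prior at theta=0.92: the mode ratio sits near 1/0.92 - 1
        ratio = clor_pair.d_n / clor_pair.d_gamma
        assert 0.06 < ratio < 0.12


class TestCramerRao:
    def test_exact_gaussian_density_recovers_its_sd(self):
        s = 0.7
        grid = np.linspace(0.0, 10.0, 2000)
        dens = np.exp(-((grid - 5.0) ** 2) / (2 * s * s))
        post = DosePosterior(dose_grid=grid, density=dens, component="gamma")
        assert cramer_rao_sd(post) == pytest.approx(s, rel=1e-3)

    def test_boundary_mode_raises(self):
        grid = np.linspace(0.0, 5.0, 400)
        dens = np.exp(-grid)  # exponential: mode on the boundary
        post = DosePosterior(dose_grid=grid, density=dens, component="gamma")
        with pytest.raises(UndefinedCurvatureError):
            cramer_rao_sd(post)

    def test_clor_bound_matches_posterior_width(self, clor_pair):
        # the Cramer-Rao bound should be close to (but is a lower bound on)
        # the spread implied by the central credible interval
        post = clor_pair.posteriors["gamma"]
        lo, hi = post.credible_interval
        half_width = (hi - lo) / 2 / 1.96
        assert post.sd_cramer_rao == pytest.approx(half_width, rel=0.35)
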