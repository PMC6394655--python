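"""Prior catalogue: shapes, normalization and Gamma moment matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import biodose as bd
from biodose.errors import ConfigurationError, DomainError


def _normalized_integral(prior):
    z, _ = integrate.quad(prior.pdf, 1e-9, 1 - 1e-9,
                          points=prior.breakpoints() or None, limit=200)
    return z


class TestFamilies:
    def test_constant_prior_is_flat_and_unit(self):
        p = bd.ConstantPrior()
        t = np.array([0.1, 0.5, 0.9])
        assert np.allclose(p.density(t), p.density(0.3))
        assert np.allclose(p.pdf(t), 1.0)

    def test_simplified_beta_closed_form(self):
        p = bd.SimplifiedBetaPrior()
        # kernel theta*(1-theta) integrates to 1/6; normalized peak 6*0.25 = 1.5
        assert p.normalization() == pytest.approx(1 / 6, rel=1e-9)
        assert p.pdf(0.5) == pytest.approx(1.5, rel=1e-9)
        grid = np.linspace(0.01, 0.99, 199)
        assert grid[np.argmax(p.pdf(grid))] == pytest.approx(0.5, abs=0.01)

    def test_gaussian_prior_peaks_at_theta_hat(self):
        p = bd.GaussianPrior(0.92, 0.02)
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        assert grid[np.argmax(p.pdf(grid))] == pytest.approx(0.92, abs=1e-3)
        assert p.normalization() == pytest.approx(0.99997, abs=1e-4)

    def test_scaled_gaussian_peak_near_converted_ratio(self):
        # density in theta of a Gaussian in rho: argmax shifted from
        # 1/(1+rho_hat) only by the theta^-2 scaling
        p = bd.ScaledGaussianPrior(rho_hat=0.087, sigma_rho=0.02)
        grid = np.linspace(0.5, 1 - 1e-6, 200001)
        peak = grid[np.argmax(p.pdf(grid))]
        assert 0.90 <= peak <= 0.94

    def test_sigmoidal_monotone_increasing_for_positive_k(self):
        p = bd.SigmoidalPrior.from_threshold(0.8)
        grid = np.linspace(0.01, 0.99, 500)
        d = p.pdf(grid)
        assert np.all(np.diff(d) >= 0)
        # half-maximum at the threshold
        assert p.pdf(0.8) == pytest.approx(0.5 * p.pdf(0.999), rel=0.05)

    def test_beta_mode_concentration_helper(self):
        p = bd.BetaPrior.from_mode_concentration(0.92, 50)
        assert (p.k - 1) / (p.k + p.l - 2) == pytest.approx(0.92, rel=1e-12)

    @pytest.mark.parametrize(
        "family, kwargs",
        [
            (bd.GaussianPrior, {"theta_hat": 0.92, "sigma_theta": 0.0}),
            (bd.ScaledGaussianPrior, {"rho_hat": -0.1, "sigma_rho": 0.1}),
            (bd.BetaPrior, {"k": 0.0, "l": 2.0}),
            (bd.SigmoidalPrior, {"k": 0.0, "l": 1.0}),
            (bd.ConstantPrior, {"const": -1.0}),
        ],
    )
    def test_invalid_hyperparameters_rejected(self, family, kwargs):
        with pytest.raises(ConfigurationError):
            family(**kwargs)

    def test_theta_outside_open_interval_rejected(self):
        p = bd.GaussianPrior(0.9, 0.05)
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                p.density(bad)


class TestNormalization:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        st.sampled_from(["gaussian", "scaled_gaussian", "beta", "sigmoidal"]),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.02, max_value=0.5),
    )
    def test_every_family_normalizes_to_one(self, family, loc, scale):
        if family == "gaussian":
            p = bd.GaussianPrior(loc, scale)
        elif family == "scaled_gaussian":
            p = bd.ScaledGaussianPrior(bd.rho_from_theta(loc), scale)
        elif family == "beta":
            p = bd.BetaPrior(k=1 + loc * 10, l=1 + scale * 10)
        else:
            p = bd.SigmoidalPrior.from_threshold(loc, steepness=10 + 100 * scale)
        assert _normalized_integral(p) == pytest.approx(1.0, abs=1e-6)

    def test_sharp_prior_does_not_underflow(self):
        p = bd.GaussianPrior(0.92, 1e-4)
        assert _normalized_integral(p) == pytest.approx(1.0, abs=1e-6)
        assert p.pdf(0.92) > 1e3


class TestGammaPrior:
    def test_exponential_special_case(self):
        assert bd.gamma_prior_density(0.0, k=1, z=1) == pytest.approx(1.0)

    def test_moments_recovered_numerically(self):
        k, z = 3.0, 7.0
        mean, _ = integrate.quad(lambda x: x * bd.gamma_prior_density(x, k, z), 0, 50)
        var, _ = integrate.quad(
            lambda x: (x - k / z) ** 2 * bd.gamma_prior_density(x, k, z), 0, 50
        )
        assert mean == pytest.approx(k / z, abs=1e-4)
        assert var == pytest.approx(k / z**2, abs=1e-4)

    def test_moment_matching_round_trip(self):
        k, z = bd.moment_match_gamma(mean=0.835, sd=0.098)
        assert k == pytest.approx((0.835 / 0.098) ** 2, rel=1e-12)
        assert z == pytest.approx(0.835 / 0.098**2, rel=1e-12)
        assert k / z == pytest.approx(0.835, rel=1e-12)
        assert np.sqrt(k) / z == pytest.approx(0.098, rel=1e-12)


class TestParsing:
    def test_compact_string(self):
        p = bd.parse_prior("gaussian:theta_hat=0.92,sigma_theta=0.02")
        assert isinstance(p, bd.GaussianPrior)
        assert p.theta_hat == 0.92

    def test_dict_and_unknown_keys(self):
        p = bd.parse_prior({"family": "scaled_gaussian", "rho_hat": 0.64, "sigma_rho": 0.25})
        assert isinstance(p, bd.ScaledGaussianPrior)
        with pytest.raises(ConfigurationError):
            bd.parse_prior({"family": "gaussian", "theta_hat": 0.9, "sigma_theta": 0.1,
                            "bogus": 1})

    def test_json_and_yaml_files(self, tmp_path):
        j = tmp_path / "p.json"
        j.write_text('{"family": "beta", "k": 3, "l": 2}')
        assert isinstance(bd.parse_prior(j), bd.BetaPrior)
        y = tmp_path / "p.yaml"
        y.write_text("family: sigmoidal\nthreshold: 0.8\n")
        assert isinstance(bd.parse_prior(y), bd.SigmoidalPrior)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError):
            bd.parse_prior("cauchy:loc=0.5")
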