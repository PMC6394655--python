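"""Dose-response models, ratio/fraction conversions and curve serialization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biodose as bd
from biodose.errors import DomainError


class TestRatioConversions:
    @pytest.mark.parametrize(
        "rho, theta",
        [(0.0, 1.0), (1.0, 0.5), (0.087, 1 / 1.087), (0.64, 1 / 1.64)],
    )
    def test_theta_from_rho_values(self, rho, theta):
        assert bd.theta_from_rho(rho) == pytest.approx(theta, rel=1e-12)

    def test_measured_kerma_fraction_gives_known_ratio(self):
        # gamma kerma fraction 0.92 corresponds to a 0.087 dose ratio
        assert bd.rho_from_theta(0.92) == pytest.approx(0.087, abs=5e-4)
        assert bd.theta_from_rho(0.087) == pytest.approx(0.92, abs=5e-4)

    @pytest.mark.parametrize("rho", [-0.1, float("nan"), float("inf")])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(DomainError):
            bd.theta_from_rho(rho)

    @pytest.mark.parametrize("theta", [0.0, -0.2, 1.0001])
    def test_invalid_theta_rejected(self, theta):
        with pytest.raises(DomainError):
            bd.rho_from_theta(theta)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1.0))
    def test_round_trip(self, theta):
        assert bd.theta_from_rho(bd.rho_from_theta(theta)) == pytest.approx(theta, rel=1e-12)

    def test_dose_ratio_constructors_agree(self):
        a = bd.DoseRatio.from_rho(0.64)
        b = bd.DoseRatio.from_theta(a.theta)
        assert b.rho == pytest.approx(0.64, rel=1e-12)


class TestYields:
    def test_gamma_yield_hand_values(self):
        c = bd.CalibrationCurve(y0=0.0010, beta=0.011, gamma_coef=0.056)
        assert bd.yield_gamma(0.0, c) == pytest.approx(0.0010)
        assert bd.yield_gamma(1.0, c) == pytest.approx(0.068, abs=1e-12)
        assert bd.yield_gamma(2.0, c) == pytest.approx(0.2470, abs=1e-12)

    def test_neutron_yield_hand_values(self):
        c = bd.CalibrationCurve(y0=0.0005, alpha=0.354)
        assert bd.yield_neutron(0.0, c) == pytest.approx(0.0005)
        assert bd.yield_neutron(1.0, c) == pytest.approx(0.3545)
        assert bd.yield_neutron(0.068, c) == pytest.approx(0.0005 + 0.354 * 0.068)

    def test_mixed_yield_reproduces_worked_examples(self, silene_curve, clor_curve):
        # SILENE at its solved doses gives back (nearly) the observed 85/28
        assert bd.yield_mixed(2.349, 3.670, silene_curve) == pytest.approx(85 / 28, rel=2e-4)
        # CLOR at its solved doses gives back (nearly) the observed 35/500
        assert bd.yield_mixed(0.069, 0.796, clor_curve) == pytest.approx(35 / 500, rel=6e-3)

    def test_mixed_is_sum_of_components_minus_shared_background(self):
        c = bd.CalibrationCurve(y0=0.002, alpha=0.4, beta=0.02, gamma_coef=0.06)
        got = bd.yield_mixed(1.3, 2.1, c)
        expect = bd.yield_gamma(2.1, c) + bd.yield_neutron(1.3, c) - c.y0
        assert got == pytest.approx(expect, rel=1e-12)
        assert bd.yield_mixed(0.0, 2.1, c) == pytest.approx(bd.yield_gamma(2.1, c))
        assert bd.yield_mixed(1.3, 0.0, c) == pytest.approx(bd.yield_neutron(1.3, c))

    def test_negative_dose_rejected(self, silene_curve):
        with pytest.raises(DomainError):
            bd.yield_mixed(-0.1, 1.0, silene_curve)
        with pytest.raises(DomainError):
            bd.yield_gamma(-1e-9, silene_curve)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=1.0),  # alpha
        st.floats(min_value=0.001, max_value=0.2),  # beta
        st.floats(min_value=0.0, max_value=0.2),  # gamma
        st.floats(min_value=0.0, max_value=5.0),  # rho
    )
    def test_mixed_yield_increasing_along_ratio_ray(self, alpha, beta, gamma, rho):
        c = bd.CalibrationCurve(y0=0.001, alpha=alpha, beta=beta, gamma_coef=gamma)
        d = np.linspace(0.0, 5.0, 50)
        y = bd.yield_mixed(rho * d, d, c)
        assert np.all(np.diff(y) > 0)


class TestCurveValidationAndIO:
    def test_negative_coefficient_rejected(self):
        with pytest.raises(DomainError):
            bd.CalibrationCurve(y0=-0.001)
        with pytest.raises(DomainError):
            bd.CalibrationCurve(beta=0.01, sd_beta=-0.1)

    def test_json_round_trip(self, tmp_path, silene_curve):
        path = tmp_path / "curve.json"
        silene_curve.to_json(path)
        back = bd.CalibrationCurve.from_json(path)
        assert back == silene_curve

    def test_csv_round_trip(self, tmp_path, clor_curve):
        path = tmp_path / "curve.csv"
        clor_curve.to_csv(path)
        back = bd.CalibrationCurve.from_csv(path)
        assert back.beta == clor_curve.beta
        assert back.sd_gamma == clor_curve.sd_gamma

    def test_unknown_key_rejected(self):
        with pytest.raises(DomainError):
            bd.CalibrationCurve.from_dict({"y0": 0, "alfa": 0.1})

    def test_packaged_fixtures_present(self):
        for name in ("silene", "clor_bm", "clor_mle"):
            assert bd.load_curve(name) is not None
        assert bd.load_curve("clor_mle").beta == pytest.approx(0.012)


class TestAberrationSample:
    def test_frequency_is_exact_ratio(self):
        s = bd.AberrationSample(u=35, w=500)
        assert s.yf == 35 / 500

    @pytest.mark.parametrize("u, w", [(-1, 10), (3, 0), (2.5, 10)])
    def test_invalid_counts_rejected(self, u, w):
        with pytest.raises(DomainError):
            bd.AberrationSample(u=u, w=w)
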