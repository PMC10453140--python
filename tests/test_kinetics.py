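"""Kinetics estimators: moisture bases, lag-model fit, Biot/μ₁/D/h_m chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfdry import kinetics as K
from rfdry.kinetics import DryingCurve
from rfdry.properties import air_properties

from conftest import slab_series_mr


class TestMoistureRatioAndBases:
    def test_moisture_ratio_endpoints_and_midpoint(self):
        assert K.moisture_ratio(3.9, 0.1, 3.9) == pytest.approx(1.0)
        assert K.moisture_ratio(0.1, 0.1, 3.9) == pytest.approx(0.0)
        assert K.moisture_ratio(2.0, 0.1, 3.9) == pytest.approx(0.5)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            K.moisture_ratio(1.0, 2.0, 2.0)

    def test_dry_and_wet_basis_worked_example(self):
        assert K.dry_basis(10.0, 2.0) == pytest.approx(400.0)
        assert K.wet_basis(10.0, 2.0) == pytest.approx(80.0)
        assert K.dry_basis(5.0, 5.0) == 0.0
        assert K.wet_basis(5.0, 5.0) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(Wd=st.floats(0.1, 50.0), extra=st.floats(0.0, 200.0))
    def test_wet_dry_basis_identity(self, Wd, extra):
        Wt = Wd + extra
        db = K.dry_basis(Wt, Wd)
        wb = K.wet_basis(Wt, Wd)
        assert wb == pytest.approx(db / (1.0 + db / 100.0), rel=1e-10)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            K.dry_basis(1.0, 0.0)
        with pytest.raises(ValueError):
            K.wet_basis(1.0, 2.0)


class TestDryingCurveValidation:
    def test_requires_increasing_times_from_zero(self):
        with pytest.raises(ValueError):
            DryingCurve([10.0, 20.0], [3.0, 2.0])
        with pytest.raises(ValueError):
            DryingCurve([0.0, 10.0, 10.0], [3.0, 2.0, 1.0])

    def test_defaults_m0_to_first_sample(self):
        c = DryingCurve([0.0, 10.0], [3.5, 3.0])
        assert c.M0_db == 3.5


class TestLagModelFit:
    def test_noiseless_exponential_recovered_to_machine_precision(self):
        t = np.linspace(0.0, 10000.0, 10)
        mr = 1.10 * np.exp(-2e-4 * t)
        c = DryingCurve(t, 0.05 + mr * (3.9 - 0.05), M0_db=3.9, Me_db=0.05)
        Lf, S, r2 = K.fit_lag_model(c)
        assert Lf == pytest.approx(1.10, rel=1e-12)
        assert S == pytest.approx(2e-4, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_curve_gives_unit_lag_zero_rate(self):
        t = np.linspace(0.0, 1000.0, 5)
        c = DryingCurve(t, np.full(5, 3.9), Me_db=0.05)
        Lf, S, _ = K.fit_lag_model(c)
        assert Lf == pytest.approx(1.0)
        assert S == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_mr_points_excluded_then_error_when_too_few(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        c = DryingCurve(t, np.array([3.9, 0.05, 0.05, 0.05]), Me_db=0.05)
        with pytest.raises(ValueError, match="at least 3"):
            K.fit_lag_model(c)

    def test_noisy_recovery_within_five_percent(self):
        t = np.linspace(0.0, 12000.0, 60)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            mr = 1.10 * np.exp(-2e-4 * t) + rng.normal(0.0, 0.01, t.size)
            M = np.clip(0.05 + mr * (3.9 - 0.05), 0.0, None)
            Lf, S, _ = K.fit_lag_model(DryingCurve(t, M, M0_db=3.9, Me_db=0.05))
            errs.append((abs(Lf - 1.10) / 1.10, abs(S - 2e-4) / 2e-4))
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] < 0.05 and med[1] < 0.05


class TestBiotChain:
    def test_biot_one_from_forward_lag(self):
        Lf = math.exp(0.2533 / 2.3)  # forward map at Bi = 1
        assert K.biot_from_lag(Lf) == pytest.approx(1.0, rel=1e-12)

    def test_lag_below_one_returns_boundary(self):
        assert K.biot_from_lag(0.98) == 0.0

    def test_lag_at_asymptote_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            K.biot_from_lag(math.exp(0.2533))

    @pytest.mark.parametrize("Bi", [0.1, 1.0, 10.0, 99.0])
    def test_forward_inverse_roundtrip(self, Bi):
        assert K.biot_from_lag(K.lag_from_biot(Bi)) == pytest.approx(Bi, abs=1e-10)

    def test_mu1_branches(self):
        assert K.mu1_from_biot(100.0) == pytest.approx(math.pi / 2.0)
        assert K.mu1_from_biot(1.0) == pytest.approx(math.atan(1.020840), rel=1e-6)
        # explicit approximation nearly continuous at the branch switch
        below = K.mu1_from_biot(99.999999)
        above = math.pi / 2.0
        assert abs(above - below) / above < 0.01

    def test_diffusivity_and_hm_worked_example(self):
        D = K.diffusivity_dincer(2e-4, 0.004, 0.79573)
        assert D == pytest.approx(2e-4 * 0.004**2 / 0.79573**2, rel=1e-12)
        assert D == pytest.approx(5.054e-9, rel=1e-3)
        assert K.mass_transfer_coeff(1.0, 5.054e-9, 0.004) == pytest.approx(
            1.2635e-6, rel=1e-3
        )
        assert K.mass_transfer_coeff(0.0, 5e-9, 0.004) == 0.0

    def test_diffusivity_quadratic_in_half_thickness(self):
        assert K.diffusivity_dincer(1e-4, 0.008, 1.0) == pytest.approx(
            4.0 * K.diffusivity_dincer(1e-4, 0.004, 1.0)
        )

    def test_mu1_pi_half_recovers_infinite_biot_rate(self):
        # S = π²·D/(4·L²) with μ1 = π/2 inverts to exactly D
        D_true, L = 3e-9, 0.004
        S = math.pi**2 * D_true / (4.0 * L**2)
        assert K.diffusivity_dincer(S, L, math.pi / 2.0) == pytest.approx(
            D_true, rel=1e-12
        )


class TestDincerPipeline:
    def _forward_curve(self, Bi, D, L, t):
        Lf = K.lag_from_biot(Bi)
        S = D * K.mu1_from_biot(Bi) ** 2 / L**2
        return Lf * np.exp(-S * t), Lf, S

    @pytest.mark.parametrize("Bi_true", [0.5, 2.0, 20.0])
    def test_noiseless_roundtrip_recovers_parameters(self, Bi_true):
        D_true, L = 6.25e-9, 0.004
        mr, Lf, S = self._forward_curve(Bi_true, D_true, L,
                                        np.linspace(0.0, 15000.0, 40))
        t = np.linspace(0.0, 15000.0, 40)
        c = DryingCurve(t, 0.05 + mr * (3.902 - 0.05), M0_db=3.902, Me_db=0.05)
        fit = K.fit_dincer(c, L)
        assert fit.Bi == pytest.approx(Bi_true, rel=1e-6)
        assert fit.D == pytest.approx(D_true, rel=1e-6)
        assert fit.hm == pytest.approx(Bi_true * D_true / L, rel=1e-6)


class TestSlopeMethod:
    def test_first_term_curve_recovered_exactly(self):
        D, L = 1e-9, 0.008
        t = np.linspace(0.0, 60000.0, 30)
        mr = 8.0 / math.pi**2 * np.exp(-math.pi**2 * D * t / (4.0 * L**2))
        c = DryingCurve(t, 0.05 + mr * (3.9 - 0.05), M0_db=3.9, Me_db=0.05)
        assert K.eff_diffusivity_slope(c, L) == pytest.approx(D, rel=1e-10)

    def test_multiterm_series_late_window_within_three_percent(self):
        # 20-term eigenseries truth; fit restricted to late times
        D, L = 1e-9, 0.008
        t = np.linspace(0.0, 80000.0, 81)
        mr = slab_series_mr(D * t / (4.0 * L**2))
        c = DryingCurve(t, 0.05 + mr * (3.9 - 0.05), M0_db=3.9, Me_db=0.05)
        est = K.eff_diffusivity_slope(c, L, fit_slice=slice(30, None))
        assert est == pytest.approx(D, rel=0.03)

    def test_noisy_median_bias_below_five_percent(self):
        D, L = 1e-9, 0.008
        t = np.linspace(0.0, 60000.0, 61)
        mr0 = 8.0 / math.pi**2 * np.exp(-math.pi**2 * D * t / (4.0 * L**2))
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            M = np.clip(0.05 + (mr0 + rng.normal(0, 0.01, t.size)) * 3.85, 0, None)
            c = DryingCurve(t, M, M0_db=3.9, Me_db=0.05)
            errs.append(abs(K.eff_diffusivity_slope(c, L) - D) / D)
        assert np.median(errs) < 0.05

    def test_rising_curve_rejected(self):
        t = np.linspace(0.0, 100.0, 5)
        c = DryingCurve(t, np.array([1.0, 1.1, 1.2, 1.3, 1.4]) , M0_db=1.0, Me_db=0.0)
        with pytest.raises(ValueError, match="not drying"):
            K.eff_diffusivity_slope(c, 0.008)


class TestHeatTransferCorrelation:
    def test_worked_chain_at_drying_conditions(self):
        air = air_properties(60.0)
        Re = air.rho_a * 2.5 * 0.03 / air.mu_a
        assert Re == pytest.approx(3975.0, rel=0.01)
        assert air.prandtl == pytest.approx(0.699, abs=0.005)
        hT = K.heat_transfer_coeff(2.5, 0.03, air)
        Nu = 0.664 * Re**0.5 * air.prandtl**0.33
        assert hT == pytest.approx(Nu * air.k_a / 0.03, rel=1e-12)
        assert hT == pytest.approx(35.7, rel=0.01)

    def test_zero_velocity_gives_zero(self):
        assert K.heat_transfer_coeff(0.0, 0.03, air_properties(60.0)) == 0.0

    def test_square_root_velocity_scaling(self):
        air = air_properties(60.0)
        h1 = K.heat_transfer_coeff(1.0, 0.03, air)
        h4 = K.heat_transfer_coeff(4.0, 0.03, air)
        assert h4 == pytest.approx(2.0 * h1, rel=1e-12)
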