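"""Diffusive and ebullition flux operations."""

import math
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pondghg as pg

T0 = datetime(2011, 7, 1, 12, 0)


class TestK600:
    def test_zero_wind_intercept(self):
        assert pg.k600_wind(0.0) == pytest.approx(2.07)

    def test_direct_evaluation_at_5ms(self):
        assert pg.k600_wind(5.0) == pytest.approx(2.07 + 0.215 * 5.0**1.7)

    def test_monotone_increasing(self):
        grid = np.linspace(0, 15, 200)
        k = [pg.k600_wind(u) for u in grid]
        assert all(a < b for a, b in zip(k, k[1:]))

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            pg.k600_wind(-0.1)


class TestWindWindowMean:
    def _series(self, values, step_min=20):
        return [
            pg.WindObservation(T0 - timedelta(minutes=step_min * i), v)
            for i, v in enumerate(values)
        ]

    def test_constant_series(self):
        wind = self._series([3.2] * 7)
        assert pg.wind_window_mean(wind, T0) == pytest.approx(3.2)

    def test_two_point_mean(self):
        wind = [
            pg.WindObservation(T0 - timedelta(minutes=90), 2.0),
            pg.WindObservation(T0 - timedelta(minutes=30), 4.0),
        ]
        assert pg.wind_window_mean(wind, T0) == pytest.approx(3.0)

    def test_matches_brute_force_on_irregular_series(self, rng):
        times = [T0 - timedelta(minutes=float(m)) for m in rng.uniform(0, 300, 50)]
        speeds = rng.uniform(0, 12, 50)
        wind = [pg.WindObservation(t, float(u)) for t, u in zip(times, speeds)]
        window = timedelta(hours=2)
        inside = [u for t, u in zip(times, speeds) if T0 - window <= t <= T0]
        assert pg.wind_window_mean(wind, T0) == pytest.approx(np.mean(inside))

    def test_empty_window_names_interval(self):
        wind = [pg.WindObservation(T0 - timedelta(hours=5), 2.0)]
        with pytest.raises(ValueError, match="window"):
            pg.wind_window_mean(wind, T0)


class TestTransferVelocity:
    def test_normalization_point_sc600(self):
        for u10 in (1.0, 5.0):
            assert pg.transfer_velocity(2.07, 600.0, u10) == pytest.approx(2.07 * 0.24)

    def test_arithmetic_sc1200_windy(self):
        expected = 2.07 * 2.0 ** (-0.5) * 0.24
        assert pg.transfer_velocity(2.07, 1200.0, 5.0) == pytest.approx(expected)

    def test_exponent_switch_boundary_uses_half(self):
        # at exactly 3 m/s the rippled-surface exponent (-1/2) applies
        k_at = pg.transfer_velocity(2.07, 1200.0, 3.0)
        assert k_at == pytest.approx(2.07 * 2.0 ** (-0.5) * 0.24)
        k_below = pg.transfer_velocity(2.07, 1200.0, 2.999)
        assert k_below == pytest.approx(2.07 * 2.0 ** (-2 / 3) * 0.24)

    def test_decreasing_in_schmidt(self):
        ks = [pg.transfer_velocity(5.0, sc, 5.0) for sc in np.linspace(300, 1800, 50)]
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_nonpositive_schmidt_rejected(self):
        with pytest.raises(ValueError):
            pg.transfer_velocity(2.07, 0.0, 5.0)


class TestEquilibriumConcentration:
    def test_colder_water_higher_ceq(self):
        assert pg.equilibrium_concentration(pg.CO2, 5.0) > pg.equilibrium_concentration(
            pg.CO2, 25.0
        )

    def test_hand_evaluation_co2_10c(self):
        kh10 = 3.4e-2 * math.exp(2400.0 * (1 / 283.15 - 1 / 298.15))
        assert pg.equilibrium_concentration(pg.CO2, 10.0) == pytest.approx(
            kh10 * 390e-6 * 1e6, rel=1e-12
        )


class TestDiffusiveFlux:
    def test_zero_at_saturation(self):
        res = pg.diffusive_flux(pg.CH4, 5.0, 5.0, k=0.3)
        assert res.flux == 0.0

    def test_undersaturated_co2_is_uptake(self):
        # polygonal-pond style: surface CO2 below atmospheric equilibrium
        res = pg.diffusive_flux(pg.CO2, 9.6, 20.0, k=0.3)
        assert res.flux < 0

    def test_worked_arithmetic(self):
        res = pg.diffusive_flux(pg.CH4, 4.1, 0.004, k=0.351, correction=0.2458)
        assert res.flux == pytest.approx(0.2458 * 0.351 * (4.1 - 0.004), rel=1e-12)

    @given(
        st.floats(min_value=0, max_value=500),
        st.floats(min_value=0, max_value=50),
        st.floats(min_value=0.01, max_value=2.0),
        st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(deadline=None)
    def test_sign_matches_gradient(self, c_sur, c_eq, k, corr):
        res = pg.diffusive_flux(pg.CO2, c_sur, c_eq, k=k, correction=corr)
        assert math.copysign(1, res.flux) == math.copysign(1, c_sur - c_eq) or res.flux == 0

    def test_nonpositive_k_or_correction_rejected(self):
        with pytest.raises(ValueError):
            pg.diffusive_flux(pg.CO2, 1.0, 0.5, k=0.0)
        with pytest.raises(ValueError):
            pg.diffusive_flux(pg.CO2, 1.0, 0.5, k=0.3, correction=0.0)


class TestEbullition:
    def test_zero_volume_zero_flux(self):
        coll = pg.FunnelCollection(0.0, 24.0, 1.0, 10.0)
        assert pg.ebullition_flux(coll) == 0.0

    def test_worked_ideal_gas_example(self):
        # 10 mL pure CH4 over 24 h through the 0.3526 m2 funnel at 10 degC
        coll = pg.FunnelCollection(10.0, 24.0, 1.0, 10.0)
        mv = 0.0820573 * 283.15  # L/mol, independent hand value
        expected = 0.010 / (0.3526 * mv) * 1000.0
        assert pg.ebullition_flux(coll) == pytest.approx(expected, rel=1e-9)
        assert pg.ebullition_flux(coll) == pytest.approx(1.22, abs=0.01)

    def test_linear_in_ch4_fraction(self):
        full = pg.ebullition_flux(pg.FunnelCollection(10.0, 24.0, 0.30, 10.0))
        half = pg.ebullition_flux(pg.FunnelCollection(10.0, 24.0, 0.15, 10.0))
        assert full == pytest.approx(2 * half)

    def test_invariant_to_splitting_collections(self, rng):
        vols = rng.uniform(1, 20, 4)
        total = pg.ebullition_flux(pg.FunnelCollection(vols.sum(), 48.0, 0.2, 8.0))
        parts = [
            pg.ebullition_flux(pg.FunnelCollection(v, 12.0, 0.2, 8.0)) for v in vols
        ]
        # time-weighted mean of sub-collection fluxes equals the pooled flux
        assert np.mean(parts) == pytest.approx(total)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            pg.FunnelCollection(10.0, 0.0, 1.0, 10.0)


class TestCorrectionFit:
    def test_exact_proportionality(self, rng):
        model = rng.uniform(1, 20, 10)
        fit = pg.fit_correction_factor(0.5 * model, model)
        assert fit.factor == pytest.approx(0.5)
        assert fit.r2 == pytest.approx(1.0)

    def test_identity(self, rng):
        model = rng.uniform(1, 20, 10)
        fit = pg.fit_correction_factor(model, model)
        assert fit.factor == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        model = rng.uniform(1, 20, 30)
        chamber = 0.3 * model + rng.normal(0, 0.5, 30)
        f1 = pg.fit_correction_factor(chamber, model).factor
        f2 = pg.fit_correction_factor(3.0 * chamber, model).factor
        assert f2 == pytest.approx(3.0 * f1)

    def test_intercept_mode_recovers_line(self, rng):
        model = rng.uniform(1, 20, 40)
        chamber = 0.25 * model + 1.5
        fit = pg.fit_correction_factor(chamber, model, intercept=True)
        assert fit.factor == pytest.approx(0.25, rel=1e-9)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            pg.fit_correction_factor([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            pg.fit_correction_factor([1.0, 2.0], [1.0, 2.0])


class TestDiurnalVariation:
    def test_constant_series_zero(self):
        assert pg.diurnal_variation([2.0] * 5) == 0.0

    def test_hand_calculation(self):
        # {1, 1, 4}: mean 2, sample sd sqrt(3)
        assert pg.diurnal_variation([1.0, 1.0, 4.0]) == pytest.approx(
            100 * math.sqrt(3) / 2
        )

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 5, 12)
        assert pg.diurnal_variation(x) == pytest.approx(pg.diurnal_variation(7.3 * x))

    def test_range_mode(self):
        assert pg.diurnal_variation([1.0, 1.0, 4.0], mode="range") == pytest.approx(150.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            pg.diurnal_variation([-1.0, -2.0, 0.0])
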