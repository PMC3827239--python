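"""Gas-physics primitives: Henry's law, headspace inversion, Schmidt numbers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pondghg as pg
from pondghg.constants import R_L_ATM, GasSpecies


def forward_equilibrate_bisection(species, c0_uM, v_w, v_h, temp_c, air_ppm, p=1.0):
    """Independent forward oracle: bisect on the equilibrium partial pressure.

    Finds p_eq where Henry partitioning conserves total moles, without using
    the package's closed-form partition.
    """
    kh = species.kh_ref * math.exp(
        species.vant_hoff * (1 / (temp_c + 273.15) - 1 / 298.15)
    )
    t_k = temp_c + 273.15
    n_total = c0_uM * 1e-6 * v_w + air_ppm * 1e-6 * p * v_h / (R_L_ATM * t_k)

    def residual(p_eq):
        return kh * p_eq * v_w + p_eq * v_h / (R_L_ATM * t_k) - n_total

    lo, hi = 0.0, n_total * R_L_ATM * t_k / v_h  # all gas in headspace
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) / p * 1e6  # ppm


class TestHenry:
    def test_reference_temperature_identity(self):
        assert pg.henry_constant(pg.CO2, 25.0) == pytest.approx(pg.CO2.kh_ref)

    def test_colder_water_more_soluble(self):
        assert pg.henry_constant(pg.CH4, 5.0) > pg.henry_constant(pg.CH4, 25.0)

    def test_vant_hoff_hand_evaluation(self):
        # independent single-line arithmetic with the configured constants
        expected = 3.4e-2 * math.exp(2400.0 * (1 / 283.15 - 1 / 298.15))
        assert pg.henry_constant(pg.CO2, 10.0) == pytest.approx(expected, rel=1e-12)

    def test_monotone_on_grid(self):
        kh = [pg.henry_constant(pg.CO2, t) for t in np.linspace(-1.5, 39.5, 80)]
        assert all(a > b for a, b in zip(kh, kh[1:]))

    @pytest.mark.parametrize("temp", [-2.0, -5.0, 40.0, 55.0])
    def test_out_of_range_temperature_rejected(self, temp):
        with pytest.raises(ValueError, match="temperature"):
            pg.henry_constant(pg.CO2, temp)


class TestDissolvedAtPartialPressure:
    def test_zero_pressure_zero_concentration(self):
        assert pg.dissolved_at_partial_pressure(pg.CH4, 12.0, 0.0) == 0.0

    def test_linearity(self):
        c1 = pg.dissolved_at_partial_pressure(pg.CO2, 15.0, 1e-4)
        c2 = pg.dissolved_at_partial_pressure(pg.CO2, 15.0, 2e-4)
        assert c2 == pytest.approx(2 * c1)

    def test_hand_evaluation_co2_390ppm(self):
        kh15 = 3.4e-2 * math.exp(2400.0 * (1 / 288.15 - 1 / 298.15))
        expected_uM = kh15 * 390e-6 * 1e6
        got = pg.dissolved_at_partial_pressure(pg.CO2, 15.0, 390e-6)
        assert got == pytest.approx(expected_uM, rel=1e-12)

    def test_negative_pressure_rejected(self):
        with pytest.raises(ValueError):
            pg.dissolved_at_partial_pressure(pg.CO2, 15.0, -1e-6)


class TestHeadspaceInversion:
    def _measurement(self, species, ppm_final, temp=10.0, v_w=2.0, v_h=0.02, air_ppm=None):
        return pg.HeadspaceMeasurement(
            species=species,
            water_volume=v_w,
            headspace_volume=v_h,
            temperature=temp,
            headspace_ppm_final=ppm_final,
            air_ppm_initial=species.atm_mixing_ratio if air_ppm is None else air_ppm,
        )

    def test_no_net_transfer_at_atmospheric_equilibrium(self):
        # p_eq == p_air: the water was already at atmospheric equilibrium
        m = self._measurement(pg.CO2, ppm_final=390.0)
        res = pg.headspace_to_dissolved(m)
        expected = pg.henry_constant(pg.CO2, 10.0) * 390e-6 * 1e6
        assert res.valid
        assert res.concentration_uM == pytest.approx(expected, rel=1e-12)

    def test_vanishing_headspace_limit(self):
        m = self._measurement(pg.CH4, ppm_final=500.0, v_h=1e-9)
        res = pg.headspace_to_dissolved(m)
        expected = pg.henry_constant(pg.CH4, 10.0) * 500e-6 * 1e6
        assert res.concentration_uM == pytest.approx(expected, rel=1e-6)

    def test_inconsistent_reading_flagged_not_clamped(self):
        # headspace far below ambient air with CH4 (low solubility) implies
        # negative dissolved gas: must be carried and flagged
        m = self._measurement(pg.CH4, ppm_final=0.0, air_ppm=1000.0)
        res = pg.headspace_to_dissolved(m)
        assert not res.valid
        assert res.concentration_uM < 0

    @pytest.mark.parametrize("species_name", ["CO2", "CH4"])
    def test_roundtrip_against_bisection_oracle(self, species_name, rng):
        species = pg.get_species(species_name)
        worst = 0.0
        for _ in range(1000):
            c0 = float(rng.uniform(0.05, 500.0))
            temp = float(rng.uniform(0.5, 30.0))
            v_w = float(rng.uniform(0.5, 4.0))
            v_h = float(rng.uniform(0.005, 0.25))
            ppm = forward_equilibrate_bisection(
                species, c0, v_w, v_h, temp, species.atm_mixing_ratio
            )
            m = self._measurement(species, ppm, temp=temp, v_w=v_w, v_h=v_h)
            res = pg.headspace_to_dissolved(m)
            worst = max(worst, abs(res.concentration_uM / c0 - 1.0))
        assert worst < 1e-9

    def test_forward_simulator_matches_oracle(self, rng):
        for _ in range(50):
            c0 = float(rng.uniform(0.1, 300.0))
            temp = float(rng.uniform(1.0, 29.0))
            ppm_pkg = pg.equilibrate_headspace(pg.CO2, c0, 2.0, 0.02, temp, 390.0)
            ppm_orc = forward_equilibrate_bisection(pg.CO2, c0, 2.0, 0.02, temp, 390.0)
            assert ppm_pkg == pytest.approx(ppm_orc, rel=1e-10)


class TestSchmidt:
    def test_co2_normalization_point(self):
        assert 599.0 <= pg.schmidt_number(pg.CO2, 20.0) <= 601.0

    def test_ch4_hand_evaluation(self):
        a0, a1, a2, a3 = 1897.8, -114.28, 3.2902, -0.039061
        t = 20.0
        expected = a0 + a1 * t + a2 * t**2 + a3 * t**3
        assert pg.schmidt_number(pg.CH4, 20.0) == pytest.approx(expected)

    @pytest.mark.parametrize("species_name", ["CO2", "CH4"])
    def test_positive_and_decreasing(self, species_name):
        sp = pg.get_species(species_name)
        grid = np.linspace(0.0, 30.0, 301)
        sc = [pg.schmidt_number(sp, t) for t in grid]
        assert min(sc) > 0
        assert all(a > b for a, b in zip(sc, sc[1:]))

    def test_out_of_fit_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 30\]"):
            pg.schmidt_number(pg.CO2, 31.0)


class TestMolarVolume:
    def test_stp_reference(self):
        assert pg.molar_volume(0.0, 1.0) == pytest.approx(22.414, abs=0.01)

    def test_ten_degrees(self):
        assert pg.molar_volume(10.0, 1.0) == pytest.approx(
            22.414 * 283.15 / 273.15, abs=0.01
        )

    @given(st.floats(min_value=-30, max_value=40), st.floats(min_value=-30, max_value=40))
    @settings(deadline=None)
    def test_monotone_in_temperature(self, t1, t2):
        if t2 - t1 > 1e-6:
            assert pg.molar_volume(t1) < pg.molar_volume(t2)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            pg.molar_volume(10.0, 0.0)


class TestSpeciesConfig:
    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            GasSpecies("X", kh_ref=-1.0, vant_hoff=2000.0,
                       schmidt_coeffs=(1.0, 0, 0, 0), atm_mixing_ratio=1.0)
        with pytest.raises(ValueError):
            GasSpecies("X", kh_ref=1.0, vant_hoff=2000.0,
                       schmidt_coeffs=(-5.0, 0, 0, 0), atm_mixing_ratio=1.0)

    def test_toml_override_roundtrip(self, tmp_path):
        cfg = tmp_path / "species.toml"
        cfg.write_text(
            "[CO2]\nkh_ref = 0.04\nvant_hoff = 2300.0\n"
            "schmidt_coeffs = [1911.1, -118.11, 3.4527, -0.04132]\n"
            "atm_mixing_ratio = 400.0\n"
        )
        species = pg.load_species_config(str(cfg))
        assert species["CO2"].kh_ref == 0.04
        assert species["CO2"].atm_mixing_ratio == 400.0
        assert species["CH4"] == pg.CH4  # untouched default

    def test_headspace_csv_requires_columns(self, tmp_path):
        bad = tmp_path / "hs.csv"
        bad.write_text("pond_id,species\nP1,CO2\n")
        from pondghg.core_gas import read_headspace_csv

        with pytest.raises(ValueError, match="missing columns"):
            read_headspace_csv(str(bad))
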