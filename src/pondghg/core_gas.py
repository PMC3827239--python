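"""Gas-physics primitives.

Henry's law with van 't Hoff temperature adjustment, the headspace
mass-balance inversion that turns a gas-chromatograph reading into the
original dissolved concentration, freshwater Schmidt numbers, and the
ideal-gas molar volume.

Dissolved concentrations are reported in uM (umol L^-1) throughout, the
conventional unit for surface-water CO2 and CH4.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import R_L_ATM, T0_KELVIN, T_REF_KELVIN, GasSpecies, get_species

import math

_TEMP_MIN_C = -2.0
_TEMP_MAX_C = 40.0


def _check_temperature(temperature: float) -> None:
    if not (_TEMP_MIN_C < temperature < _TEMP_MAX_C):
        raise ValueError(
            f"temperature {temperature} degC outside valid open interval "
            f"({_TEMP_MIN_C}, {_TEMP_MAX_C}) degC"
        )


@dataclass(frozen=True)
class HeadspaceMeasurement:
    """One headspace-equilibration experiment.

    A known water volume is shaken with a known volume of ambient air; the
    equilibrated headspace is analysed by GC. Defaults follow the common
    field protocol of 2 L water against a small air headspace.

    Parameters
    ----------
    species : GasSpecies
        Gas analysed.
    water_volume : float
        Water volume, L.
    headspace_volume : float
        Air headspace volume, L.
    temperature : float
        Equilibration temperature, degC.
    headspace_ppm_final : float
        GC mixing ratio of the headspace after equilibration, ppm.
    air_ppm_initial : float
        Mixing ratio of the ambient air used as headspace, ppm.
    pressure : float
        Total pressure, atm.
    """

    species: GasSpecies
    water_volume: float
    headspace_volume: float
    temperature: float
    headspace_ppm_final: float
    air_ppm_initial: float
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if self.water_volume <= 0:
            raise ValueError("water_volume must be > 0")
        if self.headspace_volume <= 0:
            raise ValueError("headspace_volume must be > 0")
        if not (0 < self.pressure <= 1.2):
            raise ValueError("pressure must be in (0, 1.2] atm")
        if self.headspace_ppm_final < 0:
            raise ValueError("headspace_ppm_final must be >= 0")
        _check_temperature(self.temperature)


@dataclass(frozen=True)
class DissolvedResult:
    """Inversion output: concentration plus a validity flag.

    A negative concentration means the GC readings are mutually inconsistent
    (final headspace below what pure stripping of gas-free water would give);
    the value is carried, flagged, never clamped, so QC reports can count it.
    """

    concentration_uM: float
    valid: bool


def henry_constant(species: GasSpecies, temperature: float) -> float:
    """Henry solubility K_H at ``temperature``, mol L^-1 atm^-1.

    van 't Hoff form: ``KH(T) = kh_ref * exp(vant_hoff * (1/T_K - 1/298.15))``.
    Strictly decreasing in temperature (dissolution is exothermic).
    """
    _check_temperature(temperature)
    t_k = temperature + T0_KELVIN
    return species.kh_ref * math.exp(species.vant_hoff * (1.0 / t_k - 1.0 / T_REF_KELVIN))


def dissolved_at_partial_pressure(
    species: GasSpecies, temperature: float, partial_pressure: float
) -> float:
    """Equilibrium dissolved concentration at a partial pressure, uM.

    Henry's law: ``C = KH(T) * p``, converted from mol L^-1 to uM.
    """
    if partial_pressure < 0:
        raise ValueError(f"partial_pressure must be >= 0, got {partial_pressure}")
    return henry_constant(species, temperature) * partial_pressure * 1e6


def headspace_to_dissolved(meas: HeadspaceMeasurement) -> DissolvedResult:
    """Invert a headspace equilibration to the original dissolved concentration.

    Closed-form mass balance over the water + headspace system::

        C0 = KH(T) * p_eq + (p_eq - p_air) * V_h / (V_w * R * T_K)

    with ``p_eq`` the equilibrated headspace partial pressure and ``p_air``
    the partial pressure in the ambient air used. The first term is the gas
    remaining dissolved, the second the net amount transferred to (or from)
    the headspace, returned to water-volume units. Result in uM.
    """
    kh = henry_constant(meas.species, meas.temperature)
    t_k = meas.temperature + T0_KELVIN
    p_eq = meas.headspace_ppm_final * 1e-6 * meas.pressure
    p_air = meas.air_ppm_initial * 1e-6 * meas.pressure
    c0_mol_l = kh * p_eq + (p_eq - p_air) * meas.headspace_volume / (
        meas.water_volume * R_L_ATM * t_k
    )
    c0 = c0_mol_l * 1e6
    return DissolvedResult(concentration_uM=c0, valid=c0 >= 0)


def headspace_simple(meas: HeadspaceMeasurement) -> float:
    """Dissolved concentration ignoring the headspace perturbation, uM.

    ``KH(T) * p_eq`` only — the approximation is good when the headspace is
    tiny relative to the water volume (e.g. 20 mL against 2 L). Exposed for
    sensitivity checks; the full mass balance is the default.
    """
    kh = henry_constant(meas.species, meas.temperature)
    p_eq = meas.headspace_ppm_final * 1e-6 * meas.pressure
    return kh * p_eq * 1e6


def equilibrate_headspace(
    species: GasSpecies,
    dissolved_uM: float,
    water_volume: float,
    headspace_volume: float,
    temperature: float,
    air_ppm: float,
    pressure: float = 1.0,
) -> float:
    """Forward-simulate a headspace equilibration; returns final headspace ppm.

    Conserves total moles between the water (initially at ``dissolved_uM``)
    and the headspace (initially ambient air at ``air_ppm``), partitioning at
    Henry equilibrium. This is the generative counterpart of
    :func:`headspace_to_dissolved`.
    """
    if dissolved_uM < 0:
        raise ValueError("dissolved_uM must be >= 0")
    kh = henry_constant(species, temperature)
    t_k = temperature + T0_KELVIN
    n_water0 = dissolved_uM * 1e-6 * water_volume
    n_head0 = air_ppm * 1e-6 * pressure * headspace_volume / (R_L_ATM * t_k)
    # at equilibrium: n_total = KH*p_eq*Vw + p_eq*Vh/(R*Tk)
    p_eq = (n_water0 + n_head0) / (
        kh * water_volume + headspace_volume / (R_L_ATM * t_k)
    )
    return p_eq / pressure * 1e6


def schmidt_number(species: GasSpecies, temperature: float) -> float:
    """Freshwater Schmidt number from the third-order polynomial in degC.

    Valid on [0, 30] degC, where the fit is strictly decreasing.
    """
    if not (0.0 <= temperature <= 30.0):
        raise ValueError(
            f"temperature {temperature} degC outside Schmidt fit range [0, 30] degC"
        )
    a0, a1, a2, a3 = species.schmidt_coeffs
    return a0 + a1 * temperature + a2 * temperature**2 + a3 * temperature**3


def molar_volume(temperature: float, pressure: float = 1.0) -> float:
    """Ideal-gas molar volume ``R*T_K/P``, L mol^-1."""
    if pressure <= 0:
        raise ValueError(f"pressure must be > 0, got {pressure}")
    return R_L_ATM * (temperature + T0_KELVIN) / pressure


_HEADSPACE_COLUMNS = [
    "pond_id",
    "species",
    "water_volume_L",
    "headspace_volume_mL",
    "temp_C",
    "ppm_final",
    "ppm_air",
]


def read_headspace_csv(path: str) -> pd.DataFrame:
    """Read a headspace GC table, validating the required columns.

    Required columns: pond_id, species, water_volume_L, headspace_volume_mL,
    temp_C, ppm_final, ppm_air. Extra columns (timestamps, pressure) pass
    through untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in _HEADSPACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"headspace table {path} missing columns: {missing}")
    return df


def invert_headspace_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the mass-balance inversion to every row of a headspace table.

    Adds ``conc_uM`` and ``valid`` columns; rows with inconsistent readings
    keep their (negative) value with ``valid == False``.
    """
    out = df.copy()
    concs: list[float] = []
    valids: list[bool] = []
    for row in df.itertuples(index=False):
        meas = HeadspaceMeasurement(
            species=get_species(row.species),
            water_volume=float(row.water_volume_L),
            headspace_volume=float(row.headspace_volume_mL) / 1000.0,
            temperature=float(row.temp_C),
            headspace_ppm_final=float(row.ppm_final),
            air_ppm_initial=float(row.ppm_air),
            pressure=float(getattr(row, "pressure_atm", 1.0)),
        )
        res = headspace_to_dissolved(meas)
        concs.append(res.concentration_uM)
        valids.append(res.valid)
    out["conc_uM"] = concs
    out["valid"] = valids
    return out
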