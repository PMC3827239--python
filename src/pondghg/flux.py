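"""Air-water gas fluxes.

Diffusive flux from a wind-based gas transfer velocity with a multiplicative
small-pond correction, ebullition flux from passive funnel collections, the
chamber-calibration regression that produces the correction factor, and the
diurnal-variation summary.

Unit conventions: k600 and k are handled in cm h^-1 until the final
conversion to m d^-1 (x 0.24); concentrations in uM; fluxes in
mmol m^-2 d^-1 (uM x m d^-1 gives mmol m^-2 d^-1 directly).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np

from .constants import GasSpecies
from .core_gas import henry_constant, molar_volume

#: cm h^-1 to m d^-1.
CM_PER_H_TO_M_PER_D = 0.24

#: Default funnel mouth area, m^2.
DEFAULT_FUNNEL_AREA_M2 = 0.3526

#: Default small-pond chamber correction applied to wind-model fluxes.
DEFAULT_CORRECTION = 0.2458

#: Wind speed (m s^-1) at which the Schmidt exponent switches from -2/3
#: (smooth surface) to -1/2 (rippled); the boundary itself uses -1/2.
SCHMIDT_EXPONENT_SWITCH_U10 = 3.0


@dataclass(frozen=True)
class WindObservation:
    """A wind-speed reading at 10 m above ground."""

    timestamp: datetime
    u10: float

    def __post_init__(self) -> None:
        if self.u10 < 0:
            raise ValueError("u10 must be >= 0")


@dataclass(frozen=True)
class DiffusiveFluxResult:
    """A diffusive flux estimate with its full provenance.

    flux in mmol m^-2 d^-1; k600 in cm h^-1; k in m d^-1; concentrations
    in uM; correction_applied is the multiplicative factor used.
    """

    species: str
    flux: float
    k600: float
    k: float
    schmidt: float
    c_surface: float
    c_equilibrium: float
    correction_applied: float


@dataclass(frozen=True)
class FunnelCollection:
    """Gas accumulated in a submerged funnel over a known interval."""

    volume_collected: float  # mL
    duration: float  # h
    ch4_fraction: float  # volume fraction of CH4 in the collected gas
    air_temperature: float  # degC
    funnel_area: float = DEFAULT_FUNNEL_AREA_M2  # m^2
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if self.volume_collected < 0:
            raise ValueError("volume_collected must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.funnel_area <= 0:
            raise ValueError("funnel_area must be > 0")
        if not (0 <= self.ch4_fraction <= 1):
            raise ValueError("ch4_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CorrectionFit:
    """Chamber-vs-wind-model calibration slope."""

    factor: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correction fit needs n >= 3")
        if not (0 <= self.r2 <= 1):
            raise ValueError("r2 must be in [0, 1]")


def k600_wind(u10: float) -> float:
    """Wind-based gas transfer velocity normalized to Sc = 600, cm h^-1.

    ``k600 = 2.07 + 0.215 * u10**1.7`` — the classic low-wind lake model.
    Strictly increasing in wind speed; 2.07 cm h^-1 at zero wind.
    """
    if u10 < 0:
        raise ValueError(f"u10 must be >= 0, got {u10}")
    return 2.07 + 0.215 * u10**1.7


def wind_window_mean(
    wind: Sequence[WindObservation],
    at: datetime,
    window: timedelta = timedelta(hours=2),
) -> float:
    """Mean u10 over the window preceding ``at`` (inclusive bounds).

    Raises a missing-data error naming the interval if no observation falls
    inside [at - window, at].
    """
    lo = at - window
    values = [w.u10 for w in wind if lo <= w.timestamp <= at]
    if not values:
        raise ValueError(f"no wind observations in window [{lo}, {at}]")
    return float(np.mean(values))


def transfer_velocity(k600: float, schmidt: float, u10: float) -> float:
    """Species-specific gas transfer velocity k, m d^-1.

    ``k = k600 * (Sc/600)**(-x)`` with x = 2/3 below the 3 m s^-1 wind
    threshold and 1/2 at or above it, then converted cm h^-1 -> m d^-1.
    """
    if schmidt <= 0:
        raise ValueError(f"schmidt must be > 0, got {schmidt}")
    exponent = 0.5 if u10 >= SCHMIDT_EXPONENT_SWITCH_U10 else 2.0 / 3.0
    k_cmh = k600 * (schmidt / 600.0) ** (-exponent)
    return k_cmh * CM_PER_H_TO_M_PER_D


def equilibrium_concentration(
    species: GasSpecies, temperature: float, pressure: float = 1.0
) -> float:
    """Dissolved concentration in equilibrium with the atmosphere, uM.

    ``KH(T) * x_atm * P`` with the species' configured atmospheric mixing
    ratio. Colder water holds more gas.
    """
    return (
        henry_constant(species, temperature)
        * species.atm_mixing_ratio
        * 1e-6
        * pressure
        * 1e6
    )


def diffusive_flux(
    species: GasSpecies | str,
    c_surface: float,
    c_equilibrium: float,
    k: float,
    correction: float = DEFAULT_CORRECTION,
    k600: float = float("nan"),
    schmidt: float = float("nan"),
) -> DiffusiveFluxResult:
    """Diffusive air-water flux, mmol m^-2 d^-1.

    ``F_d = correction * k * (C_sur - C_eq)``. Positive = emission to the
    atmosphere; undersaturated water (C_sur < C_eq) yields a negative flux,
    i.e. atmospheric uptake.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if correction <= 0:
        raise ValueError(f"correction must be > 0, got {correction}")
    name = species if isinstance(species, str) else species.name
    return DiffusiveFluxResult(
        species=name,
        flux=correction * k * (c_surface - c_equilibrium),
        k600=k600,
        k=k,
        schmidt=schmidt,
        c_surface=c_surface,
        c_equilibrium=c_equilibrium,
        correction_applied=correction,
    )


def ebullition_flux(coll: FunnelCollection) -> float:
    """CH4 ebullition flux from a funnel collection, mmol m^-2 d^-1.

    ``F_e = V_CH4 / (A * MV(T, P) * t)`` with the collected CH4 volume
    converted to moles by the ideal-gas molar volume at ambient air
    temperature, and the accumulation time in days.
    """
    mv = molar_volume(coll.air_temperature, coll.pressure)  # L mol^-1
    v_ch4_L = coll.volume_collected / 1000.0 * coll.ch4_fraction
    days = coll.duration / 24.0
    mol_m2_d = v_ch4_L / (coll.funnel_area * mv * days)
    return mol_m2_d * 1000.0


def fit_correction_factor(
    chamber_flux: Sequence[float],
    model_flux: Sequence[float],
    intercept: bool = False,
) -> CorrectionFit:
    """Calibrate the wind-model flux against direct chamber measurements.

    Default is a zero-intercept least-squares slope (the correction is a pure
    multiplicative factor); ``intercept=True`` fits an ordinary line instead
    and reports its slope, for sensitivity analysis. r^2 is the conventional
    centred coefficient of determination of the fitted line.
    """
    x = np.asarray(model_flux, dtype=float)
    y = np.asarray(chamber_flux, dtype=float)
    if x.shape != y.shape:
        raise ValueError("chamber and model series must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("correction fit needs n >= 3")
    if np.allclose(x, 0):
        raise ValueError("model flux is identically zero: singular fit")
    if intercept:
        if np.allclose(x, x[0]):
            raise ValueError("degenerate predictor: singular fit")
        slope, b = np.polyfit(x, y, 1)
        fitted = slope * x + b
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        fitted = slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CorrectionFit(factor=float(slope), r2=float(np.clip(r2, 0.0, 1.0)), n=n)


def diurnal_variation(series: Sequence[float], mode: str = "cv") -> float:
    """Within-day variability of a concentration or flux series, percent.

    ``mode="cv"`` (default): coefficient of variation, 100*sd/mean with the
    sample (n-1) standard deviation. ``mode="range"``: 100*(max-min)/mean.
    Requires a positive mean.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("diurnal variation needs >= 3 points")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("diurnal variation requires a positive mean")
    if mode == "cv":
        return 100.0 * float(x.std(ddof=1)) / mean
    if mode == "range":
        return 100.0 * float(x.max() - x.min()) / mean
    raise ValueError(f"unknown mode {mode!r}; use 'cv' or 'range'")
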