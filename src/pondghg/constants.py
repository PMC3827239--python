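"""Physical constants and per-gas parameter bundles.

Every empirical constant used by the gas-physics layer lives here (or in a
user-supplied TOML override), never inline in the operations: Henry solubility
at the 25 degC reference with its van 't Hoff temperature coefficient, the
freshwater Schmidt-number polynomial, and the atmospheric mixing ratio used
for air-water equilibrium.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

#: Ideal-gas constant in L atm mol^-1 K^-1.
R_L_ATM = 0.0820573

#: 0 degC in kelvin.
T0_KELVIN = 273.15

#: van 't Hoff reference temperature (25 degC) in kelvin.
T_REF_KELVIN = 298.15


@dataclass(frozen=True)
class GasSpecies:
    """Physical parameter bundle for one gas.

    Parameters
    ----------
    name : str
        Gas identifier, ``"CO2"`` or ``"CH4"``.
    kh_ref : float
        Henry solubility at 25 degC, mol L^-1 atm^-1.
    vant_hoff : float
        van 't Hoff temperature coefficient, K. Positive for exothermic
        dissolution (solubility increases as water cools).
    schmidt_coeffs : tuple of float
        Coefficients (a0, a1, a2, a3) of the freshwater Schmidt-number
        polynomial ``a0 + a1*T + a2*T^2 + a3*T^3`` with T in degC.
    atm_mixing_ratio : float
        Dry-air mole fraction, ppm.
    """

    name: str
    kh_ref: float
    vant_hoff: float
    schmidt_coeffs: tuple[float, float, float, float]
    atm_mixing_ratio: float

    def __post_init__(self) -> None:
        if self.kh_ref <= 0:
            raise ValueError(f"kh_ref must be > 0, got {self.kh_ref}")
        if self.vant_hoff <= 0:
            raise ValueError(f"vant_hoff must be > 0, got {self.vant_hoff}")
        if self.atm_mixing_ratio <= 0:
            raise ValueError(
                f"atm_mixing_ratio must be > 0, got {self.atm_mixing_ratio}"
            )
        if len(self.schmidt_coeffs) != 4:
            raise ValueError("schmidt_coeffs must have exactly 4 entries")
        a0, a1, a2, a3 = self.schmidt_coeffs
        for t in (0.0, 10.0, 20.0, 30.0):
            if a0 + a1 * t + a2 * t**2 + a3 * t**3 <= 0:
                raise ValueError(
                    f"Schmidt polynomial for {self.name} is non-positive at {t} degC"
                )


# Freshwater Schmidt polynomials (Wanninkhof-style third-order fits in degC)
# and van 't Hoff Henry parameters for the two gases of interest.
CO2 = GasSpecies(
    name="CO2",
    kh_ref=3.4e-2,
    vant_hoff=2400.0,
    schmidt_coeffs=(1911.1, -118.11, 3.4527, -0.04132),
    atm_mixing_ratio=390.0,
)

CH4 = GasSpecies(
    name="CH4",
    kh_ref=1.4e-3,
    vant_hoff=1700.0,
    schmidt_coeffs=(1897.8, -114.28, 3.2902, -0.039061),
    atm_mixing_ratio=1.8,
)

DEFAULT_SPECIES: dict[str, GasSpecies] = {"CO2": CO2, "CH4": CH4}


def get_species(name: str) -> GasSpecies:
    """Look up a default gas bundle by name (case-insensitive)."""
    key = name.upper().replace("-", "")
    try:
        return DEFAULT_SPECIES[key]
    except KeyError:
        raise KeyError(
            f"unknown gas {name!r}; known: {sorted(DEFAULT_SPECIES)}"
        ) from None


def load_species_config(path: str) -> dict[str, GasSpecies]:
    """Read per-species constants from a TOML file.

    The file holds one block per gas::

        [CO2]
        kh_ref = 3.4e-2
        vant_hoff = 2400.0
        schmidt_coeffs = [1911.1, -118.11, 3.4527, -0.04132]
        atm_mixing_ratio = 390.0

    Blocks present in the file replace the built-in defaults; gases not
    mentioned keep their defaults.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    species = dict(DEFAULT_SPECIES)
    for name, block in raw.items():
        species[name.upper()] = GasSpecies(
            name=name.upper(),
            kh_ref=float(block["kh_ref"]),
            vant_hoff=float(block["vant_hoff"]),
            schmidt_coeffs=tuple(float(c) for c in block["schmidt_coeffs"]),
            atm_mixing_ratio=float(block["atm_mixing_ratio"]),
        )
    return species
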