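"""Radiocarbon conversions and two-endmember carbon-age apportionment.

Delta14C (the geochemical, decay-corrected reporting convention) is converted
to fraction modern with the reporting decay constant lambda = 1/8267 yr^-1
referenced to 1950; conventional ages use the Libby mean life 8033 yr.
Samples are classed modern (post-bomb or within a recent window) or old, and
a sample's fraction modern is apportioned linearly between a contemporary
endmember and an old endmember (by default, carbon of basal-peat age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Reporting decay constant, yr^-1 (1/8267), used to decay-correct Delta14C
#: to the year of measurement.
LAMBDA_REPORTING = 1.0 / 8267.0

#: Libby mean life, yr, used for conventional radiocarbon ages.
LIBBY_MEAN_LIFE = 8033.0

#: Default year of measurement.
DEFAULT_YEAR = 2011

#: Default age (14C yr BP) of the old endmember: basal peat of the thick
#: regional peat deposit.
OLD_ENDMEMBER_AGE_BP = 3670.0


@dataclass(frozen=True)
class EndmemberPair:
    """Fraction-modern values of the mixing endmembers.

    modern_fm: contemporary, recently atmosphere-fixed carbon (post-bomb,
    slightly above 1). old_fm: aged carbon, e.g. basal peat.
    """

    modern_fm: float = 1.05
    old_fm: float = math.exp(-OLD_ENDMEMBER_AGE_BP / LIBBY_MEAN_LIFE)

    def __post_init__(self) -> None:
        if not (self.modern_fm > self.old_fm >= 0):
            raise ValueError("endmembers require modern_fm > old_fm >= 0")


@dataclass(frozen=True)
class RadiocarbonMeasurement:
    """A Delta14C measurement with its derived quantities."""

    delta14c: float  # permil
    year_measured: int
    species: str = "CH4"  # CO2 | CH4

    def __post_init__(self) -> None:
        if self.delta14c <= -1000:
            raise ValueError("delta14c must exceed -1000 permil")

    @property
    def fraction_modern(self) -> float:
        return delta14c_to_fm(self.delta14c, self.year_measured)

    @property
    def conventional_age(self) -> float | str:
        return conventional_age(self.fraction_modern)

    @property
    def age_class(self) -> str:
        return classify_age(self.delta14c, self.year_measured)


def delta14c_to_fm(delta14c: float, year_measured: int) -> float:
    """Fraction modern from Delta14C (permil) and the year of measurement.

    ``Fm = (Delta14C/1000 + 1) / exp(lambda * (1950 - year))`` — undoes the
    decay correction built into the Delta14C reporting convention. Strictly
    increasing in Delta14C.
    """
    if delta14c <= -1000:
        raise ValueError(f"delta14c must exceed -1000 permil, got {delta14c}")
    return (delta14c / 1000.0 + 1.0) / math.exp(
        LAMBDA_REPORTING * (1950.0 - year_measured)
    )


def fm_to_delta14c(fm: float, year_measured: int) -> float:
    """Inverse of :func:`delta14c_to_fm` (exact round trip)."""
    if fm <= 0:
        raise ValueError(f"fm must be > 0, got {fm}")
    return (fm * math.exp(LAMBDA_REPORTING * (1950.0 - year_measured)) - 1.0) * 1000.0


def conventional_age(fm: float) -> float | str:
    """Conventional radiocarbon age ``-8033 * ln(Fm)`` in 14C yr BP.

    Fraction modern of exactly 1 is age 0; above 1 the sample is post-bomb
    and has no finite conventional age, so the flag ``"modern (post-bomb)"``
    is returned instead.
    """
    if fm <= 0:
        raise ValueError(f"fm must be > 0, got {fm}")
    if fm > 1:
        return "modern (post-bomb)"
    return -LIBBY_MEAN_LIFE * math.log(fm)


def classify_age(
    delta14c: float, year_measured: int = DEFAULT_YEAR, modern_window_yr: float = 60.0
) -> str:
    """Class a sample ``"modern"`` (post-bomb or younger than the window) or ``"old"``."""
    fm = delta14c_to_fm(delta14c, year_measured)
    if fm >= 1:
        return "modern"
    age = -LIBBY_MEAN_LIFE * math.log(fm)
    return "modern" if age <= modern_window_yr else "old"


def old_carbon_fraction(
    fm_sample: float, endmembers: EndmemberPair = EndmemberPair()
) -> tuple[float, bool]:
    """Linear two-endmember apportionment in fraction-modern space.

    ``f_old = (modern_fm - fm_sample) / (modern_fm - old_fm)``. A sample
    outside the endmember interval is clamped to [0, 1] and flagged rather
    than rejected (measurement noise routinely pushes near-pure samples just
    past an endmember). Returns ``(f_old, clamped)``.
    """
    span = endmembers.modern_fm - endmembers.old_fm
    if span == 0:
        raise ValueError("degenerate endmembers: modern_fm == old_fm")
    f_old = (endmembers.modern_fm - fm_sample) / span
    clamped = not (0.0 <= f_old <= 1.0)
    if clamped:
        f_old = min(max(f_old, 0.0), 1.0)
    return f_old, clamped


def mix_fm(f_old: float, endmembers: EndmemberPair = EndmemberPair()) -> float:
    """Forward mixing model: fraction modern of a mixture with ``f_old`` old carbon."""
    if not (0.0 <= f_old <= 1.0):
        raise ValueError("f_old must be in [0, 1]")
    return endmembers.modern_fm - f_old * (endmembers.modern_fm - endmembers.old_fm)
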