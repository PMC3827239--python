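"""Stable-isotope source attribution of methane.

Two complementary classifiers identify the methanogenic pathway behind a CH4
sample:

* the carbon-deuterium (CD) diagram — rectangular regions in the
  (d13C-CH4, dD-CH4) plane separating acetoclastic from hydrogenotrophic
  methanogenesis;
* the apparent carbon fractionation factor
  ``alphaC = (d13C-CO2 + 1000) / (d13C-CH4 + 1000)``, whose magnitude also
  flags methanotrophic oxidation (oxidation enriches the residual CH4 in
  13C, pushing alphaC below the production window).

Region boundaries are configuration, not constants baked into the logic:
published CD diagrams draw them slightly differently, so every
classification records the boundary set it used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MethaneIsotopeSample:
    """Isotopic description of one CH4 (and optionally CO2) sample."""

    d13c_ch4: float  # permil vs VPDB
    dd_ch4: float | None = None  # permil vs VSMOW
    d13c_co2: float | None = None  # permil vs VPDB
    transport: str = "diffusion"  # diffusion | ebullition
    o2_surface: float | None = None  # mg L^-1

    def __post_init__(self) -> None:
        if not (-130 < self.d13c_ch4 < 20):
            raise ValueError("d13c_ch4 outside plausible (-130, 20) permil")
        if self.dd_ch4 is not None and not (-500 < self.dd_ch4 < 0):
            raise ValueError("dd_ch4 outside plausible (-500, 0) permil")
        if self.d13c_co2 is not None and not (-130 < self.d13c_co2 < 20):
            raise ValueError("d13c_co2 outside plausible (-130, 20) permil")


@dataclass(frozen=True)
class CDBoundaries:
    """Rectangular CD-diagram regions, (d13C lo, hi) x (dD lo, hi), permil.

    Defaults follow the conventional freshwater CD diagram: acetoclastic
    methane is relatively 13C-enriched and strongly D-depleted, while
    hydrogenotrophic methane is 13C-depleted and less D-depleted.
    """

    acetoclastic_d13c: tuple[float, float] = (-65.0, -50.0)
    acetoclastic_dd: tuple[float, float] = (-400.0, -250.0)
    hydrogenotrophic_d13c: tuple[float, float] = (-110.0, -60.0)
    hydrogenotrophic_dd: tuple[float, float] = (-250.0, -150.0)

    def id(self) -> str:
        return (
            f"AM[{self.acetoclastic_d13c},{self.acetoclastic_dd}]"
            f"|HM[{self.hydrogenotrophic_d13c},{self.hydrogenotrophic_dd}]"
        )


@dataclass(frozen=True)
class AlphaBoundaries:
    """alphaC windows for the production pathways and the oxidation flag."""

    acetoclastic: tuple[float, float] = (1.040, 1.055)
    hydrogenotrophic: tuple[float, float] = (1.055, 1.090)
    oxidation_below: float = 1.040


@dataclass(frozen=True)
class PathwayClassification:
    """A source call for one CH4 sample."""

    label: str  # acetoclastic|hydrogenotrophic|mixed|indeterminate|oxidation_affected
    basis: str  # cd_diagram | alpha_c | both
    alpha_c: float | None = None
    boundary_id: str = ""

    _LABELS = frozenset(
        {"acetoclastic", "hydrogenotrophic", "mixed", "indeterminate", "oxidation_affected"}
    )

    def __post_init__(self) -> None:
        if self.label not in self._LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.alpha_c is not None and self.alpha_c <= 0:
            raise ValueError("alpha_c must be > 0")


def apparent_fractionation(d13c_co2: float, d13c_ch4: float) -> float:
    """Apparent carbon fractionation factor alphaC between CO2 and CH4.

    ``alphaC = (d13C-CO2 + 1000) / (d13C-CH4 + 1000)``; larger when the CH4
    is more 13C-depleted relative to coexisting CO2.
    """
    if d13c_co2 <= -1000 or d13c_ch4 <= -1000:
        raise ValueError("delta values must exceed -1000 permil")
    return (d13c_co2 + 1000.0) / (d13c_ch4 + 1000.0)


def _in_box(x: float, lo_hi: tuple[float, float]) -> bool:
    return lo_hi[0] <= x <= lo_hi[1]


def classify_pathway_cd(
    d13c_ch4: float,
    dd_ch4: float | None,
    boundaries: CDBoundaries = CDBoundaries(),
) -> PathwayClassification:
    """Classify the methanogenic pathway from the CD diagram.

    Membership in both rectangles yields ``mixed``, in neither
    ``indeterminate``. The hydrogen isotope is required: without dD-CH4 a
    13C-depleted sample cannot distinguish hydrogenotrophic production from
    other sources, so classification is refused rather than guessed.
    """
    if dd_ch4 is None:
        raise ValueError(
            "dD-CH4 is required for the CD diagram: hydrogenotrophic "
            "production cannot be ruled in or out from d13C alone"
        )
    in_am = _in_box(d13c_ch4, boundaries.acetoclastic_d13c) and _in_box(
        dd_ch4, boundaries.acetoclastic_dd
    )
    in_hm = _in_box(d13c_ch4, boundaries.hydrogenotrophic_d13c) and _in_box(
        dd_ch4, boundaries.hydrogenotrophic_dd
    )
    if in_am and in_hm:
        label = "mixed"
    elif in_am:
        label = "acetoclastic"
    elif in_hm:
        label = "hydrogenotrophic"
    else:
        label = "indeterminate"
    return PathwayClassification(label=label, basis="cd_diagram", boundary_id=boundaries.id())


def classify_pathway_alpha(
    alpha_c: float, boundaries: AlphaBoundaries = AlphaBoundaries()
) -> PathwayClassification:
    """Classify the pathway (or flag oxidation) from alphaC alone.

    Acetoclastic within [1.040, 1.055]; hydrogenotrophic within
    (1.055, 1.090]; below 1.040 the residual-CH4 enrichment signs
    methanotrophic oxidation; above 1.090 indeterminate.
    """
    if alpha_c <= 0:
        raise ValueError("alpha_c must be > 0")
    am_lo, am_hi = boundaries.acetoclastic
    hm_lo, hm_hi = boundaries.hydrogenotrophic
    if alpha_c < boundaries.oxidation_below:
        label = "oxidation_affected"
    elif am_lo <= alpha_c <= am_hi:
        label = "acetoclastic"
    elif hm_lo < alpha_c <= hm_hi:
        label = "hydrogenotrophic"
    else:
        label = "indeterminate"
    return PathwayClassification(label=label, basis="alpha_c", alpha_c=alpha_c)


def oxidation_regression(
    o2_surface: Sequence[float], d13c_ch4: Sequence[float]
) -> tuple[float, float, float]:
    """OLS of d13C-CH4 on surface O2: returns (slope, r2, two-sided p).

    A positive slope (heavier CH4 at higher O2) is the fingerprint of
    methanotrophic oxidation in oxygenated surface waters.
    """
    x = np.asarray(o2_surface, dtype=float)
    y = np.asarray(d13c_ch4, dtype=float)
    if x.size != y.size:
        raise ValueError("o2 and d13c series must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate predictor: all O2 values equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)
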