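"""Campaign orchestration: group statistics, landscape upscaling, reports.

The two-sample (Welch) and paired t statistics are implemented from their
formulas so the analysis is self-contained and directly testable against
brute-force oracles; only the t distribution's tail probability is taken
from scipy. Two-sided p values throughout; no multiple-testing correction is
applied, but the report records how many tests were run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import get_species
from .core_gas import invert_headspace_table, schmidt_number
from .flux import (
    DEFAULT_CORRECTION,
    FunnelCollection,
    WindObservation,
    ebullition_flux,
    equilibrium_concentration,
    k600_wind,
    transfer_velocity,
    wind_window_mean,
)
from .isotopes import (
    apparent_fractionation,
    classify_pathway_alpha,
    classify_pathway_cd,
)
from .radiocarbon import (
    EndmemberPair,
    classify_age,
    conventional_age,
    delta14c_to_fm,
    old_carbon_fraction,
)

#: Open-water area fractions of the valley occupied by each pond type.
DEFAULT_AREA_FRACTIONS = {"runnel": 0.44, "polygonal": 0.27}


@dataclass(frozen=True)
class GroupComparison:
    """A two-group or paired t-test result."""

    statistic: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    paired: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must be in [0, 1]")
        if self.df <= 0:
            raise ValueError("df must be > 0")


@dataclass(frozen=True)
class LandscapeShare:
    """Per-type contribution to total landscape emission."""

    area_fractions: dict
    mean_fluxes: dict
    shares: dict

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("emission shares must sum to 1")


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> GroupComparison:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Statistic ``t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)`` with
    Welch-Satterthwaite degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        # identical constant groups: no evidence of a difference
        return GroupComparison(
            statistic=0.0, df=float(na + nb - 2), p=1.0,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            n_a=na, n_b=nb, degenerate=True,
        )
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupComparison(
        statistic=float(t), df=float(df), p=min(p, 1.0),
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=na, n_b=nb,
    )


def paired_t_test(differences: Sequence[float]) -> GroupComparison:
    """One-sample t-test on paired differences, two-sided, df = n - 1.

    A constant nonzero difference has zero spread; the t statistic diverges,
    so the result is returned with p = 0 and the ``degenerate`` flag set
    instead of a division error. All-zero differences give t = 0, p = 1.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired test needs n >= 2 pairs")
    sd = d.std(ddof=1)
    mean = float(d.mean())
    if sd == 0:
        if mean == 0:
            return GroupComparison(
                statistic=0.0, df=float(n - 1), p=1.0, mean_a=0.0, mean_b=0.0,
                n_a=n, n_b=n, paired=True, degenerate=True,
            )
        return GroupComparison(
            statistic=math.copysign(math.inf, mean), df=float(n - 1), p=0.0,
            mean_a=mean, mean_b=0.0, n_a=n, n_b=n, paired=True, degenerate=True,
        )
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return GroupComparison(
        statistic=float(t), df=float(n - 1), p=min(p, 1.0),
        mean_a=mean, mean_b=0.0, n_a=n, n_b=n, paired=True,
    )


def landscape_upscale(
    area_fractions: Mapping[str, float], mean_fluxes: Mapping[str, float]
) -> LandscapeShare:
    """Emission share of each pond type: ``area_i * flux_i / sum_j area_j * flux_j``.

    Types present in both mappings are included; shares sum to 1 and are
    invariant to rescaling all fluxes by a common positive constant.
    """
    types = sorted(set(area_fractions) & set(mean_fluxes))
    if not types:
        raise ValueError("no pond types common to areas and fluxes")
    products = {}
    for t in types:
        a, f = area_fractions[t], mean_fluxes[t]
        if a < 0 or f < 0:
            raise ValueError(f"negative area fraction or flux for type {t!r}")
        products[t] = a * f
    total = sum(products.values())
    if total == 0:
        raise ValueError("all area x flux products are zero: shares undefined")
    shares = {t: v / total for t, v in products.items()}
    return LandscapeShare(
        area_fractions=dict(area_fractions), mean_fluxes=dict(mean_fluxes), shares=shares
    )


# ---------------------------------------------------------------------------
# report stages
# ---------------------------------------------------------------------------


def _load_wind(wind: pd.DataFrame) -> list[WindObservation]:
    return [
        WindObservation(datetime.fromisoformat(t), float(u))
        for t, u in zip(wind["timestamp"], wind["u10_ms"])
    ]


def dissolved_stage(headspace: pd.DataFrame) -> pd.DataFrame:
    """Invert every headspace GC reading to a dissolved concentration."""
    return invert_headspace_table(headspace)


def diffusive_stage(
    dissolved: pd.DataFrame,
    wind: pd.DataFrame,
    correction: float = DEFAULT_CORRECTION,
    window_h: float = 2.0,
) -> pd.DataFrame:
    """Diffusive flux per dissolved-gas row, with full provenance columns."""
    wind_obs = _load_wind(wind)
    window = timedelta(hours=window_h)
    rows = []
    for row in dissolved.itertuples(index=False):
        sp = get_species(row.species)
        at = datetime.fromisoformat(row.timestamp)
        u10 = wind_window_mean(wind_obs, at, window)
        k600 = k600_wind(u10)
        sc = schmidt_number(sp, float(row.temp_C))
        k = transfer_velocity(k600, sc, u10)
        c_eq = equilibrium_concentration(sp, float(row.temp_C))
        rows.append(
            {
                "pond_id": row.pond_id,
                "species": row.species,
                "timestamp": row.timestamp,
                "c_surface_uM": row.conc_uM,
                "c_equilibrium_uM": c_eq,
                "u10_ms": u10,
                "k600_cmh": k600,
                "schmidt": sc,
                "k_md": k,
                "correction": correction,
                "flux_mmol_m2_d": correction * k * (row.conc_uM - c_eq),
            }
        )
    return pd.DataFrame(rows)


def ebullition_stage(funnels: pd.DataFrame) -> pd.DataFrame:
    """CH4 ebullition flux per funnel collection."""
    rows = []
    for row in funnels.itertuples(index=False):
        start = datetime.fromisoformat(row.start)
        end = datetime.fromisoformat(row.end)
        duration_h = (end - start).total_seconds() / 3600.0
        coll = FunnelCollection(
            volume_collected=float(row.volume_mL),
            duration=duration_h,
            ch4_fraction=float(row.ch4_frac),
            air_temperature=float(row.air_temp_C),
            funnel_area=float(getattr(row, "funnel_area_m2", 0.3526)),
        )
        rows.append(
            {
                "pond_id": row.pond_id,
                "start": row.start,
                "duration_h": duration_h,
                "flux_mmol_m2_d": ebullition_flux(coll),
            }
        )
    return pd.DataFrame(rows)


def isotope_stage(isotopes: pd.DataFrame) -> pd.DataFrame:
    """Classify the methanogenic pathway for every isotope sample."""
    rows = []
    for row in isotopes.itertuples(index=False):
        dd = None if pd.isna(row.dd_ch4) else float(row.dd_ch4)
        cd = classify_pathway_cd(float(row.d13c_ch4), dd) if dd is not None else None
        alpha = None
        alpha_label = ""
        if not pd.isna(row.d13c_co2):
            alpha = apparent_fractionation(float(row.d13c_co2), float(row.d13c_ch4))
            alpha_label = classify_pathway_alpha(alpha).label
        rows.append(
            {
                "pond_id": row.pond_id,
                "transport": row.transport,
                "label_cd": cd.label if cd else "",
                "label_alpha": alpha_label,
                "alpha_c": alpha if alpha is not None else np.nan,
                "boundary_id": cd.boundary_id if cd else "",
            }
        )
    return pd.DataFrame(rows)


def radiocarbon_stage(
    radiocarbon: pd.DataFrame, endmembers: EndmemberPair = EndmemberPair()
) -> pd.DataFrame:
    """Derive fraction modern, age class and old-carbon fraction per sample."""
    rows = []
    for row in radiocarbon.itertuples(index=False):
        fm = delta14c_to_fm(float(row.delta14c_permil), int(row.year))
        age = conventional_age(fm)
        f_old, clamped = old_carbon_fraction(fm, endmembers)
        rows.append(
            {
                "pond_id": row.pond_id,
                "species": row.species,
                "fm": fm,
                "age_bp_or_modern": age,
                "age_class": classify_age(float(row.delta14c_permil), int(row.year)),
                "f_old": f_old,
                "f_old_clamped": clamped,
            }
        )
    return pd.DataFrame(rows)


def comparison_stage(
    diffusive: pd.DataFrame, ponds: pd.DataFrame
) -> pd.DataFrame:
    """Welch tests of runnel vs polygonal concentrations and fluxes per gas."""
    merged = diffusive.merge(ponds[["pond_id", "pond_type"]], on="pond_id")
    rows = []
    for sp in sorted(merged["species"].unique()):
        sub = merged[merged["species"] == sp]
        run = sub[sub["pond_type"] == "runnel"]
        pol = sub[sub["pond_type"] == "polygonal"]
        if len(run) < 2 or len(pol) < 2:
            continue
        for quantity, col in (("concentration", "c_surface_uM"), ("flux", "flux_mmol_m2_d")):
            cmp_ = welch_t_test(run[col], pol[col])
            rows.append(
                {
                    "species": sp,
                    "quantity": quantity,
                    "t": cmp_.statistic,
                    "df": cmp_.df,
                    "p": cmp_.p,
                    "mean_runnel": cmp_.mean_a,
                    "mean_polygonal": cmp_.mean_b,
                    "ratio": cmp_.mean_a / cmp_.mean_b if cmp_.mean_b != 0 else np.nan,
                    "n_runnel": cmp_.n_a,
                    "n_polygonal": cmp_.n_b,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(rows)
    return out


def upscaling_stage(
    diffusive: pd.DataFrame,
    ponds: pd.DataFrame,
    area_fractions: Mapping[str, float] = None,
    species: str = "CH4",
) -> pd.DataFrame:
    """Landscape emission share per pond type from mean areal flux x area."""
    if area_fractions is None:
        area_fractions = DEFAULT_AREA_FRACTIONS
    merged = diffusive.merge(ponds[["pond_id", "pond_type"]], on="pond_id")
    sub = merged[merged["species"] == species]
    mean_fluxes = sub.groupby("pond_type")["flux_mmol_m2_d"].mean().to_dict()
    # uptake (negative flux) cannot carry an emission share
    mean_fluxes = {t: max(f, 0.0) for t, f in mean_fluxes.items()}
    share = landscape_upscale(area_fractions, mean_fluxes)
    return pd.DataFrame(
        [
            {
                "pond_type": t,
                "area_fraction": share.area_fractions[t],
                "mean_flux_mmol_m2_d": share.mean_fluxes[t],
                "emission_share": s,
            }
            for t, s in sorted(share.shares.items())
        ]
    )


_STAGE_INPUTS = {
    "dissolved": ["headspace"],
    "diffusive_flux": ["headspace", "wind"],
    "ebullition_flux": ["funnels"],
    "isotopes_classified": ["isotopes"],
    "radiocarbon_derived": ["radiocarbon"],
    "comparisons": ["headspace", "wind", "ponds"],
    "upscaling": ["headspace", "wind", "ponds"],
}


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the missing input.

    Outputs of the stages that did complete are kept on ``.report``.
    """

    def __init__(self, message: str, report: dict | None = None) -> None:
        super().__init__(message)
        self.report = report or {}


def run_report(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path | None = None,
    correction: float = DEFAULT_CORRECTION,
    area_fractions: Mapping[str, float] | None = None,
    endmembers: EndmemberPair = EndmemberPair(),
) -> dict[str, pd.DataFrame]:
    """Run the full analysis: dissolved -> fluxes -> isotopes -> 14C -> stats.

    ``tables`` maps table names (ponds, wind, headspace, funnels, isotopes,
    radiocarbon) to DataFrames; any table may be absent, in which case the
    stages that need it fail with a stage-named error *after* the earlier
    stages have completed (their outputs are kept, and written if ``out_dir``
    is given). The report is a pure function of its inputs: re-running on the
    same tables yields identical outputs.
    """
    report: dict[str, pd.DataFrame] = {}
    errors: list[str] = []

    def need(stage: str, *names: str) -> bool:
        missing = [n for n in names if n not in tables]
        if missing:
            errors.append(f"stage {stage!r}: missing input table(s) {missing}")
            return False
        return True

    if need("dissolved", "headspace"):
        report["dissolved"] = dissolved_stage(tables["headspace"])
    if "dissolved" in report and need("diffusive_flux", "wind"):
        report["diffusive_flux"] = diffusive_stage(
            report["dissolved"], tables["wind"], correction=correction
        )
    if need("ebullition_flux", "funnels"):
        report["ebullition_flux"] = ebullition_stage(tables["funnels"])
    if need("isotopes_classified", "isotopes"):
        report["isotopes_classified"] = isotope_stage(tables["isotopes"])
    if need("radiocarbon_derived", "radiocarbon"):
        report["radiocarbon_derived"] = radiocarbon_stage(
            tables["radiocarbon"], endmembers
        )
    if "diffusive_flux" in report and need("comparisons", "ponds"):
        report["comparisons"] = comparison_stage(report["diffusive_flux"], tables["ponds"])
        report["upscaling"] = upscaling_stage(
            report["diffusive_flux"], tables["ponds"], area_fractions
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "correction": correction,
            "stages": sorted(report),
            "errors": errors,
            "n_statistical_tests": int(
                report["comparisons"].attrs.get("n_tests", 0)
            )
            if "comparisons" in report
            else 0,
        }
        (out / "report_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    if errors:
        raise StageError("; ".join(errors), report=report)
    return report
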