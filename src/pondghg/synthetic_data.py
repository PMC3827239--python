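"""Seeded synthetic field-campaign generator.

Emulates a summer sampling campaign on ice-wedge tundra thaw ponds: two pond
types (polygonal and runnel) with lognormal dissolved CO2 and CH4
concentrations moment-matched to the observed group means and standard
deviations, a wind record with the observed coefficient of variation,
headspace gas-chromatograph readings forward-simulated from the true
concentrations, funnel ebullition collections, pathway-consistent stable
isotope samples with instrument noise, and radiocarbon samples drawn from
modern/old endmember mixtures.

Every observational table is paired with a ground-truth table so parameter
recovery by the analysis pipeline can be tested exactly. A fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import get_species
from .core_gas import equilibrate_headspace, molar_volume, schmidt_number
from .flux import (
    DEFAULT_CORRECTION,
    DEFAULT_FUNNEL_AREA_M2,
    WindObservation,
    equilibrium_concentration,
    k600_wind,
    transfer_velocity,
    wind_window_mean,
)
from .radiocarbon import DEFAULT_YEAR, EndmemberPair, fm_to_delta14c, mix_fm

CAMPAIGN_START = datetime(2011, 7, 1, 6, 0)


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a lognormal to an arithmetic mean and standard deviation.

    ``mu = ln(mean^2 / sqrt(mean^2 + sd^2))``, ``sigma^2 = ln(1 + sd^2/mean^2)``.
    ``sd = 0`` degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    var_ratio = 1.0 + (sd / mean) ** 2
    mu = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
    sigma = math.sqrt(math.log(var_ratio))
    return mu, sigma


@dataclass(frozen=True)
class GroupConcentration:
    """Lognormal mean/sd (uM) of a dissolved gas in one pond type."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd < 0:
            raise ValueError("concentration group needs mean > 0 and sd >= 0")


@dataclass(frozen=True)
class CampaignConfig:
    """All tunable parameters of the synthetic campaign.

    Defaults reproduce the observed campaign structure: the compiled
    dissolved-gas series (33 polygonal + 58 runnel pond visits), group
    concentration summaries of CO2 119 +/- 124 uM (runnel) vs 9.6 +/- 8.9 uM
    (polygonal) and CH4 4.1 +/- 4.7 vs 1.3 +/- 1.7 uM, a 45% wind-speed
    coefficient of variation, bubble CH4 content between 1.5 and 32% by
    volume, ebullition at or below the 2.13 mmol m^-2 d^-1 maximum, and a
    higher old-carbon fraction in runnel-pond gas.
    """

    n_polygonal: int = 33
    n_runnel: int = 58
    seed: int = 0

    # dissolved concentration groups, uM: {species: {pond_type: GroupConcentration}}
    co2_polygonal: GroupConcentration = GroupConcentration(9.6, 8.9)
    co2_runnel: GroupConcentration = GroupConcentration(119.0, 124.0)
    ch4_polygonal: GroupConcentration = GroupConcentration(1.3, 1.7)
    ch4_runnel: GroupConcentration = GroupConcentration(4.1, 4.7)

    # wind regime
    wind_mean: float = 4.0  # m s^-1
    wind_cv: float = 0.45
    wind_step_min: int = 10  # record spacing, minutes

    # water/air temperature during the ice-free window, degC (uniform bounds)
    water_temp_range: tuple[float, float] = (4.0, 18.0)
    air_temp_range: tuple[float, float] = (2.0, 21.4)

    # headspace equilibration protocol
    water_volume_L: float = 2.0
    headspace_volume_mL: float = 20.0
    gc_noise_cv: float = 0.02  # multiplicative GC reading noise

    # small-pond chamber correction applied by the flux model
    correction: float = DEFAULT_CORRECTION

    # ebullition
    n_funnel_ponds: int = 2  # polygonal ponds instrumented with funnels
    n_collections_per_pond: int = 4
    funnel_area_m2: float = DEFAULT_FUNNEL_AREA_M2
    funnel_duration_h: float = 24.0
    bubble_ch4_fraction_range: tuple[float, float] = (0.015, 0.32)
    ebullition_cap: float = 2.13  # mmol m^-2 d^-1
    ebullition_median: float = 0.5  # mmol m^-2 d^-1, lognormal location
    ebullition_sigma: float = 0.9  # lognormal shape

    # stable isotopes
    n_iso_diffusion_polygonal: int = 9
    n_iso_diffusion_runnel: int = 10
    n_iso_ebullition_polygonal: int = 2
    n_iso_ebullition_runnel: int = 2
    acetoclastic_fraction: float = 1.0  # summer pathway mixture
    d13c_noise: float = 0.2  # permil, instrument precision
    dd_noise: float = 3.0  # permil
    o2_range: tuple[float, float] = (5.0, 13.0)  # mg L^-1
    oxidation_slope: float = 0.0  # permil per mg L^-1 O2 added to diffusive d13C

    # radiocarbon
    n_c14_polygonal: int = 7
    n_c14_runnel: int = 3
    f_old_polygonal: tuple[float, float] = (0.0, 0.04)
    f_old_runnel: tuple[float, float] = (0.05, 0.105)
    delta14c_noise: float = 2.8  # permil, AMS day-to-day relative error
    year_measured: int = DEFAULT_YEAR
    endmembers: EndmemberPair = EndmemberPair()

    def __post_init__(self) -> None:
        if self.n_polygonal < 1 or self.n_runnel < 1:
            raise ValueError("pond counts must be >= 1")
        if self.wind_mean <= 0 or self.wind_cv < 0:
            raise ValueError("wind regime needs mean > 0 and cv >= 0")
        lo, hi = self.bubble_ch4_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("bubble CH4 fraction range must lie within [0, 1]")
        if not (0.0 <= self.acetoclastic_fraction <= 1.0):
            raise ValueError("acetoclastic_fraction must be in [0, 1]")
        for nm in ("gc_noise_cv", "d13c_noise", "dd_noise", "delta14c_noise"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")

    def zero_noise(self) -> "CampaignConfig":
        """Copy with all measurement noise switched off (truth-closure mode)."""
        return replace(
            self, gc_noise_cv=0.0, d13c_noise=0.0, dd_noise=0.0, delta14c_noise=0.0
        )

    def concentration_group(self, species: str, pond_type: str) -> GroupConcentration:
        return getattr(self, f"{species.lower()}_{pond_type}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticCampaign:
    """All observational tables of one synthetic campaign plus ground truth."""

    config: CampaignConfig
    ponds: pd.DataFrame
    wind: pd.DataFrame
    headspace: pd.DataFrame
    funnels: pd.DataFrame
    isotopes: pd.DataFrame
    radiocarbon: pd.DataFrame
    ground_truth: pd.DataFrame

    _TABLES = (
        "ponds",
        "wind",
        "headspace",
        "funnels",
        "isotopes",
        "radiocarbon",
        "ground_truth",
    )

    def write_dir(self, out_dir: str | Path) -> Path:
        """Write the six observation tables, ground truth, and a manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "tables": [f"{n}.csv" for n in self._TABLES],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        return out

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> dict[str, pd.DataFrame]:
        """Read campaign tables back from a directory (as plain DataFrames)."""
        in_dir = Path(in_dir)
        tables = {}
        for name in cls._TABLES:
            path = in_dir / f"{name}.csv"
            if path.exists():
                tables[name] = pd.read_csv(path)
        return tables


def simulate_chamber_calibration(
    rng: np.random.Generator,
    n: int = 57,
    true_factor: float = 0.2458,
    target_r2: float = 0.689,
    model_median: float = 10.0,
    model_sigma: float = 0.7,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate paired chamber and wind-model CO2 fluxes for calibration.

    Wind-model fluxes are lognormal; chamber fluxes are ``true_factor`` times
    the model plus Gaussian noise scaled so the expected coefficient of
    determination of the calibration matches ``target_r2``. Returns
    ``(chamber, model)`` arrays of length ``n``.
    """
    if not (0 < target_r2 < 1):
        raise ValueError("target_r2 must be in (0, 1)")
    model = rng.lognormal(math.log(model_median), model_sigma, n)
    signal = true_factor * model
    sigma = signal.std(ddof=1) * math.sqrt(1.0 / target_r2 - 1.0)
    chamber = signal + rng.normal(0.0, sigma, n)
    return chamber, model


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    mu, sigma = lognormal_from_mean_sd(mean, sd)
    if sigma == 0:
        return np.full(n, mean)
    return rng.lognormal(mu, sigma, size=n)


def _wind_series(rng: np.random.Generator, cfg: CampaignConfig, n_steps: int) -> pd.DataFrame:
    mu, sigma = lognormal_from_mean_sd(cfg.wind_mean, cfg.wind_cv * cfg.wind_mean)
    u10 = rng.lognormal(mu, sigma, size=n_steps) if sigma > 0 else np.full(n_steps, cfg.wind_mean)
    ts = [CAMPAIGN_START + timedelta(minutes=cfg.wind_step_min * i) for i in range(n_steps)]
    return pd.DataFrame({"timestamp": [t.isoformat() for t in ts], "u10_ms": u10})


def _pathway_truth_draw(
    rng: np.random.Generator, pathway: str
) -> tuple[float, float, float]:
    """True (d13c_ch4, dd_ch4, d13c_co2) from the interior of a pathway region."""
    if pathway == "acetoclastic":
        d13c = rng.uniform(-64.0, -51.0)
        dd = rng.uniform(-395.0, -255.0)
        alpha = rng.uniform(1.042, 1.053)
    else:  # hydrogenotrophic
        d13c = rng.uniform(-105.0, -61.0)
        dd = rng.uniform(-245.0, -155.0)
        alpha = rng.uniform(1.057, 1.088)
    d13c_co2 = alpha * (d13c + 1000.0) - 1000.0
    return d13c, dd, d13c_co2


def generate_campaign(config: CampaignConfig) -> SyntheticCampaign:
    """Generate one fully reproducible synthetic campaign.

    The ground-truth table records, in long format, every latent quantity the
    analysis pipeline is meant to recover: true dissolved concentrations and
    the diffusive fluxes they imply, true ebullition fluxes per collection,
    true pathway labels per isotope sample, and true old-carbon fractions per
    radiocarbon sample.
    """
    rng = np.random.default_rng(config.seed)
    species_names = ["CO2", "CH4"]

    # --- ponds ---------------------------------------------------------
    pond_rows = []
    for i in range(config.n_polygonal):
        pond_rows.append(
            {
                "pond_id": f"POL{i + 1:02d}",
                "pond_type": "polygonal",
                "area_m2": float(rng.uniform(20.0, 500.0)),
                "depth_m": float(rng.uniform(0.5, 1.5)),
            }
        )
    for i in range(config.n_runnel):
        pond_rows.append(
            {
                "pond_id": f"RUN{i + 1:02d}",
                "pond_type": "runnel",
                "area_m2": float(rng.uniform(5.0, 200.0)),
                "depth_m": float(rng.uniform(0.1, 0.5)),
            }
        )
    ponds = pd.DataFrame(pond_rows)
    n_ponds = len(ponds)

    # --- wind record covering every sampling time plus a 2 h lead ------
    sample_times = [
        CAMPAIGN_START + timedelta(hours=2, minutes=15 * i) for i in range(n_ponds)
    ]
    total_min = int((sample_times[-1] - CAMPAIGN_START).total_seconds() / 60) + 60
    wind = _wind_series(rng, config, total_min // config.wind_step_min + 1)
    wind_obs = [
        WindObservation(datetime.fromisoformat(t), u)
        for t, u in zip(wind["timestamp"], wind["u10_ms"])
    ]

    # --- dissolved concentrations, headspace readings, true fluxes -----
    truth_rows: list[dict] = []
    headspace_rows: list[dict] = []
    water_temps = rng.uniform(*config.water_temp_range, size=n_ponds)
    for (idx, pond), t_sample, temp in zip(ponds.iterrows(), sample_times, water_temps):
        u10 = wind_window_mean(wind_obs, t_sample)
        k600 = k600_wind(u10)
        for sp_name in species_names:
            sp = get_species(sp_name)
            grp = config.concentration_group(sp_name, pond["pond_type"])
            conc = float(_draw_lognormal(rng, grp.mean, grp.sd, 1)[0])
            sc = schmidt_number(sp, float(temp))
            k = transfer_velocity(k600, sc, u10)
            c_eq = equilibrium_concentration(sp, float(temp))
            true_flux = config.correction * k * (conc - c_eq)
            ppm_eq = equilibrate_headspace(
                sp,
                conc,
                config.water_volume_L,
                config.headspace_volume_mL / 1000.0,
                float(temp),
                air_ppm=sp.atm_mixing_ratio,
            )
            noise = (
                math.exp(rng.normal(0.0, config.gc_noise_cv))
                if config.gc_noise_cv > 0
                else 1.0
            )
            headspace_rows.append(
                {
                    "pond_id": pond["pond_id"],
                    "species": sp_name,
                    "timestamp": t_sample.isoformat(),
                    "water_volume_L": config.water_volume_L,
                    "headspace_volume_mL": config.headspace_volume_mL,
                    "temp_C": float(temp),
                    "ppm_final": ppm_eq * noise,
                    "ppm_air": sp.atm_mixing_ratio,
                }
            )
            truth_rows.append(
                {
                    "kind": "concentration",
                    "pond_id": pond["pond_id"],
                    "species": sp_name,
                    "sample_idx": 0,
                    "value": conc,
                    "label": "",
                }
            )
            truth_rows.append(
                {
                    "kind": "diffusive_flux",
                    "pond_id": pond["pond_id"],
                    "species": sp_name,
                    "sample_idx": 0,
                    "value": true_flux,
                    "label": "",
                }
            )
    headspace = pd.DataFrame(headspace_rows)

    # --- funnel ebullition collections (polygonal ponds only) ----------
    funnel_rows = []
    funnel_ponds = ponds[ponds["pond_type"] == "polygonal"]["pond_id"].iloc[
        : config.n_funnel_ponds
    ]
    mu_e = math.log(config.ebullition_median)
    for pond_id in funnel_ponds:
        for j in range(config.n_collections_per_pond):
            # truncated lognormal: redraw until under the configured cap
            true_flux = float(rng.lognormal(mu_e, config.ebullition_sigma))
            while true_flux > config.ebullition_cap:
                true_flux = float(rng.lognormal(mu_e, config.ebullition_sigma))
            ch4_frac = float(rng.uniform(*config.bubble_ch4_fraction_range))
            air_temp = float(rng.uniform(*config.air_temp_range))
            mv = molar_volume(air_temp)  # L mol^-1 at 1 atm
            days = config.funnel_duration_h / 24.0
            v_ch4_L = true_flux / 1000.0 * config.funnel_area_m2 * mv * days
            volume_mL = v_ch4_L / ch4_frac * 1000.0
            start = CAMPAIGN_START + timedelta(days=j)
            funnel_rows.append(
                {
                    "pond_id": pond_id,
                    "start": start.isoformat(),
                    "end": (start + timedelta(hours=config.funnel_duration_h)).isoformat(),
                    "volume_mL": volume_mL,
                    "ch4_frac": ch4_frac,
                    "air_temp_C": air_temp,
                    "funnel_area_m2": config.funnel_area_m2,
                }
            )
            truth_rows.append(
                {
                    "kind": "ebullition_flux",
                    "pond_id": pond_id,
                    "species": "CH4",
                    "sample_idx": j,
                    "value": true_flux,
                    "label": "",
                }
            )
    funnels = pd.DataFrame(funnel_rows)

    # --- stable isotope samples ----------------------------------------
    iso_rows = []
    iso_plan = [
        ("polygonal", "diffusion", config.n_iso_diffusion_polygonal),
        ("runnel", "diffusion", config.n_iso_diffusion_runnel),
        ("polygonal", "ebullition", config.n_iso_ebullition_polygonal),
        ("runnel", "ebullition", config.n_iso_ebullition_runnel),
    ]
    for pond_type, transport, n in iso_plan:
        type_ponds = ponds[ponds["pond_type"] == pond_type]["pond_id"].tolist()
        for j in range(n):
            pond_id = type_ponds[j % len(type_ponds)]
            pathway = (
                "acetoclastic"
                if rng.uniform() < config.acetoclastic_fraction
                else "hydrogenotrophic"
            )
            d13c, dd, d13c_co2 = _pathway_truth_draw(rng, pathway)
            o2 = float(rng.uniform(*config.o2_range))
            d13c_obs = d13c + config.oxidation_slope * (o2 - config.o2_range[0])
            if config.d13c_noise > 0:
                d13c_obs += rng.normal(0.0, config.d13c_noise)
                d13c_co2 = d13c_co2 + rng.normal(0.0, config.d13c_noise)
            if config.dd_noise > 0:
                dd += rng.normal(0.0, config.dd_noise)
            iso_rows.append(
                {
                    "pond_id": pond_id,
                    "transport": transport,
                    "d13c_ch4": d13c_obs,
                    "dd_ch4": dd,
                    "d13c_co2": d13c_co2,
                    "o2_mgL": o2,
                }
            )
            truth_rows.append(
                {
                    "kind": "pathway",
                    "pond_id": pond_id,
                    "species": transport,
                    "sample_idx": j,
                    "value": np.nan,
                    "label": pathway,
                }
            )
    isotopes = pd.DataFrame(iso_rows)

    # --- radiocarbon samples --------------------------------------------
    c14_rows = []
    c14_plan = [
        ("polygonal", config.n_c14_polygonal, config.f_old_polygonal),
        ("runnel", config.n_c14_runnel, config.f_old_runnel),
    ]
    for pond_type, n, f_range in c14_plan:
        type_ponds = ponds[ponds["pond_type"] == pond_type]["pond_id"].tolist()
        for j in range(n):
            pond_id = type_ponds[j % min(2, len(type_ponds))]
            f_old = float(rng.uniform(*f_range))
            fm = mix_fm(f_old, config.endmembers)
            d14c = fm_to_delta14c(fm, config.year_measured)
            if config.delta14c_noise > 0:
                d14c += rng.normal(0.0, config.delta14c_noise)
            sp_name = "CH4" if j % 2 == 0 else "CO2"
            c14_rows.append(
                {
                    "pond_id": pond_id,
                    "species": sp_name,
                    "transport": "ebullition",
                    "delta14c_permil": d14c,
                    "year": config.year_measured,
                }
            )
            truth_rows.append(
                {
                    "kind": "f_old",
                    "pond_id": pond_id,
                    "species": sp_name,
                    "sample_idx": j,
                    "value": f_old,
                    "label": pond_type,
                }
            )
    radiocarbon = pd.DataFrame(c14_rows)

    ground_truth = pd.DataFrame(truth_rows)
    return SyntheticCampaign(
        config=config,
        ponds=ponds,
        wind=wind,
        headspace=headspace,
        funnels=funnels,
        isotopes=isotopes,
        radiocarbon=radiocarbon,
        ground_truth=ground_truth,
    )
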