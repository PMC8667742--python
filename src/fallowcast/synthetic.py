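"""Synthetic study-shaped data with known generative structure.

Emulates the trial's setting — a monsoon site where roughly 60% of annual
precipitation falls in the July–September fallow window, interannual
variability alternates drought and normal recharge years, fallow tillage
(DP ≥ SS > NT) raises both soil-water storage and yield, and a slow
technology trend underlies yields — while recording every generative
coefficient so pipeline stages can be tested against ground truth.

The year-level water signal ``w`` (standardized fallow precipitation
anomaly) drives both storage and yield: per-stage storage loads on ``w``
with the target storage–yield correlations (sowing 0.78, jointing 0.95,
anthesis 0.92, maturity 0.75), and the weather-driven yield component
splits evenly between ``w`` and the jointing-storage anomaly — the
controllable route through which tillage reaches yield — so the target
correlations are realized by construction and each driver carries an
independently recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agronomy import SOIL_STAGES, TILLAGES
from .errors import ValidationError
from .weather import DEFAULT_CALENDAR, aggregate_stages
from . import datasets

SITE_MEAN_TEMP = 13.72      # degC, annual mean at the trial site
SITE_TEMP_AMPLITUDE = 13.0  # degC, continental seasonal swing
SITE_ANNUAL_SUNSHINE = 2461.0  # h
SITE_ANNUAL_PRECIP = 480.0  # mm, long-run mean

_STAGE_STORAGE_MEAN = {  # mm over 0-3 m, declining as the crop draws water
    "sowing": 560.0, "wintering": 530.0, "jointing": 480.0,
    "anthesis": 430.0, "maturity": 390.0,
}
_STAGE_STORAGE_SD = 55.0


@dataclass
class GeneratorConfig:
    years: int = 10
    plots_per_year: int = 69        # 3 tillages x 23 replicate rows
    start_year: int = 2009
    seed: int = 0
    fallow_share_target: float = 0.6
    drought_year_fraction: float = 0.5
    drought_fallow_factor: float = 0.5   # fallow rainfall down-scaling in drought years
    tillage_effects: dict = field(
        default_factory=lambda: {"DP": 650.0, "SS": 500.0, "NT": -350.0}
    )
    storage_tillage_effects: dict = field(
        default_factory=lambda: {"DP": 30.0, "SS": 25.0, "NT": 0.0}
    )
    storage_yield_corr_targets: dict = field(
        default_factory=lambda: {
            "sowing": 0.78, "wintering": 0.80, "jointing": 0.95,
            "anthesis": 0.92, "maturity": 0.75,
        }
    )
    base_yield: float = 4000.0      # kg/ha at the first test year
    trend_slope: float = 60.0       # kg/ha per year, technology trend
    meteo_yield_sd: float = 550.0   # kg/ha, year-level weather-driven swing
    noise_sd: float = 150.0         # kg/ha, plot-level residual (matches the
                                    # trial's reported validation RMSE scale)
    shock: float = 0.0              # kg/ha, added to yields from shock_start_year on
    shock_start_year: int | None = None

    def __post_init__(self):
        if self.years < 1 or self.plots_per_year < 1:
            raise ValidationError("years and plots_per_year must be >= 1")
        if not 0 < self.fallow_share_target < 1:
            raise ValidationError("fallow_share_target must be in (0, 1)")
        if not 0 <= self.drought_year_fraction < 1:
            raise ValidationError("drought_year_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Generative ground truth stored alongside every generated dataset."""

    drought_years: list[int]
    water_signal: dict               # test year -> standardized fallow anomaly w
    trend: dict                      # test year -> technology trend (kg/ha)
    tillage_effects: dict
    meteo_yield_sd: float
    storage_loadings: dict           # stage -> correlation loading on w
    yield_betas: dict = field(default_factory=dict)
    # kg/ha per unit of the two standardized drivers: the year water signal w
    # and the (year x tillage) jointing-storage anomaly z


def _years(config: GeneratorConfig) -> list[int]:
    return list(range(config.start_year, config.start_year + config.years))


def gen_weather(config: GeneratorConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Monthly weather covering every test year's fallow and growth windows.

    Temperature follows the site sinusoid around the 13.72 °C annual mean;
    monthly precipitation is gamma-distributed with July–September means
    scaled to the fallow-share target, and drought years (a fixed fraction,
    drawn by the seeded RNG) have their fallow rainfall down-scaled.
    """
    rng = np.random.default_rng(config.seed)
    harvest = _years(config)
    n_drought = int(round(config.drought_year_fraction * len(harvest)))
    drought_years = sorted(rng.choice(harvest, size=n_drought, replace=False).tolist())
    # the final growth window spills into the year after the last test year
    cal_years = range(config.start_year, config.start_year + config.years + 1)
    # boost the non-drought fallow mean so the *overall* mean fallow share
    # still hits the target despite drought-year down-scaling
    deficit = 1.0 - config.drought_year_fraction * (1.0 - config.drought_fallow_factor)
    mu_fallow = config.fallow_share_target * SITE_ANNUAL_PRECIP / 3.0 / deficit
    mu_other = (1 - config.fallow_share_target) * SITE_ANNUAL_PRECIP / 9.0
    # continuous interannual variability of the monsoon on top of the
    # drought down-scaling: right-skewed, mean 1
    monsoon_strength = {
        y: float(np.exp(rng.normal(-0.25**2 / 2, 0.25))) for y in cal_years
    }
    rows = []
    for year in cal_years:
        for month in range(1, 13):
            t_mean = (
                SITE_MEAN_TEMP
                - SITE_TEMP_AMPLITUDE * np.cos(2 * np.pi * (month - 1) / 12.0)
                + rng.normal(0.0, 0.8)
            )
            spread_hi = 6.0 + abs(rng.normal(0.0, 1.0))
            spread_lo = 6.0 + abs(rng.normal(0.0, 1.0))
            # fallow (monsoon) months: many storm events, hence tighter
            # relative spread (shape 12) than the sparse off-season (shape 4)
            if month in (7, 8, 9):
                mu, shape = mu_fallow * monsoon_strength[year], 12.0
                # the fallow window of test year Y is Jul-Sep of calendar year Y
                if year in drought_years:
                    mu *= config.drought_fallow_factor
            else:
                mu, shape = mu_other, 4.0
            precip = rng.gamma(shape=shape, scale=mu / shape)
            sunshine = max(
                0.0,
                SITE_ANNUAL_SUNSHINE / 12.0
                + 35.0 * np.cos(2 * np.pi * (month - 6.5) / 12.0)
                + rng.normal(0.0, 15.0),
            )
            rows.append(
                {
                    "year": year, "month": month, "precip": float(precip),
                    "t_mean": float(t_mean), "t_max": float(t_mean + spread_hi),
                    "t_min": float(t_mean - spread_lo), "sunshine": float(sunshine),
                }
            )
    weather = pd.DataFrame(rows)
    stages = aggregate_stages(weather, DEFAULT_CALENDAR, years=harvest)
    fallow = stages[stages["stage"] == "fallow"].set_index("year")["precip_sum"]
    w = (fallow - fallow.mean()) / fallow.std(ddof=1)
    # the weather-driven yield component splits evenly between the fallow
    # water signal and the jointing-storage anomaly (the controllable,
    # tillage-sensitive route), so each driver carries an independently
    # detectable signal; the normalizer keeps its variance at
    # meteo_yield_sd^2 given corr(w, z_jointing) = rho
    rho_j = float(config.storage_yield_corr_targets["jointing"])
    norm = float(np.sqrt(0.5**2 + 0.5**2 + 2 * 0.5 * 0.5 * rho_j))
    truth = SyntheticTruth(
        drought_years=drought_years,
        water_signal=w.to_dict(),
        trend={
            y: config.base_yield + config.trend_slope * (y - config.start_year)
            for y in harvest
        },
        tillage_effects=dict(config.tillage_effects),
        meteo_yield_sd=config.meteo_yield_sd,
        storage_loadings=dict(config.storage_yield_corr_targets),
        yield_betas={
            "water_signal": 0.5 * config.meteo_yield_sd / norm,
            "jointing_storage_z": 0.5 * config.meteo_yield_sd / norm,
        },
    )
    return weather, truth


def gen_soil_water(
    weather: pd.DataFrame, config: GeneratorConfig, truth: SyntheticTruth
) -> pd.DataFrame:
    """Per (year × stage × tillage) 0–3 m storage (mm).

    Each stage's storage loads on the year water signal with that stage's
    target correlation (noise fills the remaining variance), plus the tillage
    recharge offsets, so DP/SS storage exceeds NT in expectation.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for year, w in truth.water_signal.items():
        for stage in SOIL_STAGES:
            rho = float(truth.storage_loadings[stage])
            stage_noise = rng.normal(0.0, 1.0)
            for tillage in TILLAGES:
                z = rho * w + np.sqrt(max(0.0, 1 - rho**2)) * (
                    stage_noise + 0.3 * rng.normal(0.0, 1.0)
                ) / np.sqrt(1.09)
                storage = (
                    _STAGE_STORAGE_MEAN[stage]
                    + _STAGE_STORAGE_SD * z
                    + config.storage_tillage_effects[tillage]
                )
                rows.append(
                    {"year": year, "stage": stage, "tillage": tillage,
                     "storage_mm": float(storage)}
                )
    return pd.DataFrame(rows)


def gen_yields(
    weather: pd.DataFrame,
    storage: pd.DataFrame,
    config: GeneratorConfig,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Plot-level observations: yield plus spike number, grains/spike, TGW.

    y = trend(year) + β_w · w + β_z · z_jointing + tillage effect + plot noise
    (+ any configured late-era shock), where z_jointing is the standardized
    jointing-stage storage anomaly of the plot's (year × tillage) cell — the
    controllable route through which fallow tillage reaches yield.
    Components share the water signal with positive loadings plus
    *year-level* noise that does not average out across plots — strong
    coupling for spike number and grains per spike, weak for thousand-grain
    weight.
    """
    rng = np.random.default_rng(config.seed + 2)
    reps = max(1, config.plots_per_year // len(TILLAGES))
    joint = storage[storage["stage"] == "jointing"].set_index(["year", "tillage"])
    beta_w = truth.yield_betas.get("water_signal", truth.meteo_yield_sd)
    beta_z = truth.yield_betas.get("jointing_storage_z", 0.0)
    rows = []
    for year, w in truth.water_signal.items():
        shock = (
            config.shock
            if config.shock_start_year is not None and year >= config.shock_start_year
            else 0.0
        )
        # year-level component noise: weather the water signal does not carry
        yn_spikes = rng.normal(0.0, 9.0)
        yn_grains = rng.normal(0.0, 1.0)
        yn_tgw = rng.normal(0.0, 0.7)
        for tillage in TILLAGES:
            till_y = truth.tillage_effects[tillage]
            z_joint = (
                joint.loc[(year, tillage), "storage_mm"]
                - _STAGE_STORAGE_MEAN["jointing"]
                - config.storage_tillage_effects[tillage]
            ) / _STAGE_STORAGE_SD
            for rep in range(1, reps + 1):
                noise = rng.normal(0.0, config.noise_sd) if config.noise_sd else 0.0
                y = (
                    truth.trend[year]
                    + beta_w * w
                    + beta_z * z_joint
                    + till_y
                    + noise
                    + shock
                )
                spikes = 430.0 + 26.0 * w + till_y / 12.0 + yn_spikes + rng.normal(0.0, 12.0)
                grains = 28.0 + 2.3 * w + till_y / 450.0 + yn_grains + rng.normal(0.0, 1.1)
                tgw = 39.5 + 0.45 * w + yn_tgw + rng.normal(0.0, 0.9)
                rows.append(
                    {
                        "year": year, "tillage": tillage, "replicate": rep,
                        "yield": float(max(y, 100.0)), "spikes": float(max(spikes, 50.0)),
                        "grains_per_spike": float(max(grains, 5.0)),
                        "tgw": float(max(tgw, 20.0)),
                    }
                )
    return pd.DataFrame(rows)


def storage_anomaly(
    storage: pd.DataFrame, config: GeneratorConfig, stage: str = "jointing"
) -> pd.DataFrame:
    """Standardized storage anomaly z per (year × tillage) for one stage.

    Inverts the generator's affine construction (stage mean, tillage offset,
    stage spread), recovering the latent driver used for yields.
    """
    sub = storage[storage["stage"] == stage].copy()
    offsets = sub["tillage"].map(config.storage_tillage_effects)
    sub["z"] = (sub["storage_mm"] - _STAGE_STORAGE_MEAN[stage] - offsets) / _STAGE_STORAGE_SD
    return sub[["year", "tillage", "z"]]


def gen_dataset(config: GeneratorConfig):
    """Weather + storage + plot observations + truth, in one call."""
    weather, truth = gen_weather(config)
    storage = gen_soil_water(weather, config, truth)
    obs = gen_yields(weather, storage, config, truth)
    return weather, storage, obs, truth


def meteo_features(weather: pd.DataFrame, years=None) -> pd.DataFrame:
    """The 14 per-test-year meteorological indices used for factor analysis.

    Growth-period aggregates pool the three growth stages; daily max/min
    temperature are approximated by growth-period means of the monthly
    extremes (the record is monthly).
    """
    stages = aggregate_stages(weather, DEFAULT_CALENDAR, years=years)
    wide = stages.set_index(["year", "stage"])
    years = sorted(stages["year"].unique())
    lookup = weather.set_index(["year", "month"])
    rows = []
    for y in years:
        growth_months = [
            (y + off, m)
            for st in ("sowing_jointing", "jointing_anthesis", "anthesis_maturity")
            for off, m in DEFAULT_CALENDAR[st]
        ]
        sub = lookup.loc[growth_months]
        g = {st: wide.loc[(y, st)] for st in
             ("fallow", "sowing_jointing", "jointing_anthesis", "anthesis_maturity")}
        rows.append(
            {
                "year": y,
                "fallow_precip": g["fallow"]["precip_sum"],
                "stage1_precip": g["sowing_jointing"]["precip_sum"],
                "stage2_precip": g["jointing_anthesis"]["precip_sum"],
                "growth_accum_temp": sum(
                    g[st]["accum_temp"] for st in
                    ("sowing_jointing", "jointing_anthesis", "anthesis_maturity")
                ),
                "growth_mean_temp": float(sub["t_mean"].mean()),
                "daily_max_temp": float(sub["t_max"].mean()),
                "daily_min_temp": float(sub["t_min"].mean()),
                "stage1_mean_temp": g["sowing_jointing"]["t_mean_avg"],
                "stage2_mean_temp": g["jointing_anthesis"]["t_mean_avg"],
                "growth_sunshine": sum(
                    g[st]["sunshine_sum"] for st in
                    ("sowing_jointing", "jointing_anthesis", "anthesis_maturity")
                ),
                "stage1_sunshine": g["sowing_jointing"]["sunshine_sum"],
                "stage2_sunshine": g["jointing_anthesis"]["sunshine_sum"],
                "stage1_accum_temp": g["sowing_jointing"]["accum_temp"],
                "stage2_accum_temp": g["jointing_anthesis"]["accum_temp"],
            }
        )
    return pd.DataFrame(rows).set_index("year")


def modeling_frame(
    weather: pd.DataFrame,
    storage: pd.DataFrame,
    observations: pd.DataFrame,
    storage_stages=("sowing", "jointing", "anthesis"),
) -> pd.DataFrame:
    """Plot-level modelling table: weather predictors + storage + targets.

    Joins each plot observation with its harvest year's fallow/stage-1
    precipitation and the plot's tillage-specific storage at the selected
    stages (columns ``storage_<stage>``).
    """
    feats = meteo_features(weather, years=sorted(observations["year"].unique()))
    out = observations.merge(
        feats[["fallow_precip", "stage1_precip"]].reset_index(), on="year"
    )
    for stage in storage_stages:
        sub = storage[storage["stage"] == stage][["year", "tillage", "storage_mm"]]
        sub = sub.rename(columns={"storage_mm": f"storage_{stage}"})
        out = out.merge(sub, on=["year", "tillage"])
    return out


def gen_paperlike_fixture() -> dict:
    """The bundled printed reference tables (see :mod:`fallowcast.datasets`)."""
    return {
        "station_precipitation": datasets.load_station_precipitation(),
        "validation_yields": datasets.load_validation_yields(),
        "validation_means": datasets.load_validation_means(),
        "summary_yields": datasets.load_summary_yields(),
    }
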