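"""Published reference tables from the 10-year dryland winter-wheat tillage trial.

These small tables — stage precipitation at the Wenxi (Loess Plateau)
station for harvest years 2009–2018, and per-year true/predicted yields by
tillage and precipitation type from the trial's validation report — anchor
the desk-scale arithmetic checks: fallow-period precipitation share,
treatment means, and the per-year relative-error table.  They are verbatim
printed values, not outputs of this package's generator.
"""

from __future__ import annotations

import io

import pandas as pd

# Stage precipitation (mm) per harvest year; "fallow" is the pre-sowing
# July–September window, the growth stages cover October–June.  The final
# column of the source (1981–2017 climatology) is kept separately below.
_STATION_PRECIP = """\
stage,2009,2010,2011,2012,2013,2014,2015,2016,2017,2018
fallow,206.2,390.0,506.8,218.9,210.7,472.4,214.8,184.2,196.9,234.4
sowing_jointing,82.2,75.6,165.6,52.4,62.9,100.1,58.3,196.9,125.1,46.5
jointing_anthesis,28.5,24.3,15.5,25.1,104.7,38.4,40.9,26.0,84.7,36.7
anthesis_maturity,65.0,27.1,45.1,95.2,35.9,29.3,76.8,77.4,50.1,41.4
"""

CLIMATOLOGY_1981_2017 = {
    "fallow": 284.6,
    "sowing_jointing": 88.6,
    "jointing_anthesis": 37.6,
    "anthesis_maturity": 80.2,
}

# Per-year validation table: measured vs model-predicted yield (kg/ha) per
# tillage under each precipitation type, plus the printed per-year error (%).
_VALIDATION_YIELDS = """\
type,year,tillage,true,pred,printed_error_pct
normal,2009,DP,3923.57,4283.53,9.17
normal,2010,DP,4588.15,4676.75,1.93
normal,2011,DP,5412.04,5208.05,3.77
normal,2012,DP,3915.32,4263.74,8.90
normal,2014,DP,4806.55,4879.21,1.51
normal,2009,SS,3639.82,3835.16,5.37
normal,2010,SS,4794.56,4791.82,0.06
normal,2011,SS,5612.45,5241.97,6.60
normal,2012,SS,3140.25,3877.02,23.46
normal,2014,SS,4999.96,4845.06,3.10
normal,2009,NT,2714.96,3012.48,10.96
normal,2010,NT,3705.67,3761.26,1.50
normal,2011,NT,4155.60,4065.82,2.16
normal,2012,NT,2608.30,3051.83,17.00
normal,2014,NT,3956.22,3860.30,2.42
drought,2013,DP,4818.74,4850.41,0.66
drought,2015,DP,6009.75,5483.64,8.75
drought,2016,DP,5032.00,4925.96,2.11
drought,2017,DP,4657.53,4767.79,2.37
drought,2018,DP,5227.48,5093.71,2.56
drought,2013,SS,4575.40,4626.02,1.11
drought,2015,SS,5719.08,5175.11,9.51
drought,2016,SS,4892.00,4789.95,2.09
drought,2017,SS,4093.03,4398.23,7.46
drought,2018,SS,4775.68,4824.75,1.03
drought,2013,NT,3866.73,3919.66,1.37
drought,2015,NT,4812.00,4170.89,13.32
drought,2016,NT,4274.00,3958.87,7.37
drought,2017,NT,3689.52,3753.52,1.73
drought,2018,NT,3711.17,3974.16,7.09
"""

# Printed MEAN rows of the same report.  Note: the printed drought-DP mean
# prediction (4984.30) does not equal the mean of that column's five printed
# per-year predictions (5024.30); the package recomputes means from per-year
# values and keeps the printed row here for the error-formula check.
_VALIDATION_MEANS = """\
type,tillage,true,pred,printed_error_pct
normal,DP,4529.12,4662.27,2.94
normal,SS,4437.41,4518.21,1.82
normal,NT,3428.15,3550.34,3.56
drought,DP,5149.10,4984.30,3.20
drought,SS,4811.04,4762.81,1.00
drought,NT,4070.68,3955.42,2.83
"""

# Treatment-summary yield means (kg/ha) per (precipitation type x tillage)
# as printed in the trial's summary table.  Its SS cells disagree with the
# per-year validation table (apparent label swap in the source); per-year
# values are authoritative for recomputation.
_SUMMARY_YIELDS = """\
type,tillage,yield,spikes,grains_per_spike,tgw
normal,DP,4529.12,482.21,26.32,40.30
normal,SS,4385.94,464.02,25.55,40.07
normal,NT,3428.15,402.30,23.75,37.54
drought,DP,5149.10,478.22,32.44,40.75
drought,SS,4437.41,447.08,31.70,39.27
drought,NT,4070.68,397.33,30.05,38.45
"""


def load_station_precipitation() -> pd.DataFrame:
    """Stage precipitation matrix (long form: year, stage, precip_mm)."""
    wide = pd.read_csv(io.StringIO(_STATION_PRECIP))
    long = wide.melt(id_vars="stage", var_name="year", value_name="precip_mm")
    long["year"] = long["year"].astype(int)
    return long[["year", "stage", "precip_mm"]].sort_values(["year", "stage"]).reset_index(drop=True)


def load_validation_yields() -> pd.DataFrame:
    """Per-year true/predicted yields with the printed error column."""
    return pd.read_csv(io.StringIO(_VALIDATION_YIELDS))


def load_validation_means() -> pd.DataFrame:
    """Printed MEAN rows of the validation report (see module note)."""
    return pd.read_csv(io.StringIO(_VALIDATION_MEANS))


def load_summary_yields() -> pd.DataFrame:
    """Printed (type x tillage) means of yield and yield components."""
    return pd.read_csv(io.StringIO(_SUMMARY_YIELDS))


def fallow_precipitation_summary() -> dict[str, float]:
    """Mean fallow precipitation and its share of the harvest-year total.

    The share divides mean fallow precipitation by the mean July–June total
    (fallow + whole growth period) over the record's ten years.
    """
    long = load_station_precipitation()
    wide = long.pivot(index="year", columns="stage", values="precip_mm")
    fallow_mean = float(wide["fallow"].mean())
    annual_mean = float(wide.sum(axis=1).mean())
    return {
        "mean_fallow_precip_mm": fallow_mean,
        "mean_annual_precip_mm": annual_mean,
        "fallow_share_pct": fallow_mean / annual_mean * 100.0,
    }
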