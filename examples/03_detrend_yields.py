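"""Separate measured yields into technology trend and weather-driven parts.

The 3-year centered moving average of each tillage's annual mean yield is
the trend (technology) component; the remainder is the meteorological
yield, and its ratio to the trend the relative meteorological yield.
"""

from fallowcast.detrend import decompose_yields
from fallowcast.synthetic import GeneratorConfig, gen_dataset

_, _, obs, _ = gen_dataset(GeneratorConfig(seed=3))
decomposed, fits = decompose_yields(obs, window=3, degree=3)

annual = (
    decomposed[decomposed.tillage == "DP"]
    .groupby("year")[["yield", "y_t", "y_c", "y_w"]]
    .mean()
)
print("deep ploughing, annual means (kg/ha; y_w dimensionless):")
print(annual.to_string(float_format=lambda v: f"{v:9.1f}"))
print()
for fit in fits:
    print(f"{fit.tillage}: cubic trend fit R^2 = {fit.r_squared:.2f}")

# y_t + y_c reconstructs the measured yield exactly; y_c swings with the
# fallow rainfall of each year while y_t carries the slow gain from
# improving practice.  The cubic fits summarize the trend curves the way
# the per-tillage trend lines are usually reported.
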