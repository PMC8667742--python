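"""Classify cultivation years as drought or normal from fallow-period SPEI-3.

Generates ten years of site-like monthly weather, runs the chain
PET -> water balance -> 3-month aggregation -> log-logistic standardization,
and labels each test year from its September index value.
"""

from fallowcast.spei import classify_years, spei_series
from fallowcast.synthetic import GeneratorConfig, gen_weather

weather, truth = gen_weather(GeneratorConfig(seed=42))
spei = spei_series(weather, scale=3)
labels = classify_years(spei, month=9, threshold=-0.5)
labels = labels[labels["year"].isin(truth.water_signal)]

print(labels.to_string(index=False, float_format=lambda v: f"{v:7.3f}"))
print()
print(f"drought years (index <= -0.5): {sorted(labels[labels.label == 'drought'].year)}")
print(f"generator's low-rainfall years: {truth.drought_years}")

# The September SPEI-3 standardizes the July-September climatic water
# balance against its own interannual distribution: values near 0 are
# typical recharge years, values at or below -0.5 mark fallow droughts.
# Labels track the planted low-rainfall years up to boundary cases where
# temperature (through PET) moves a year across the threshold.
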