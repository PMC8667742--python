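"""Recompute the published desk-scale arithmetic from the bundled tables.

The package ships the trial's printed stage-precipitation record and its
true/predicted validation yields; this script rederives the headline
numbers from those raw values.
"""

from fallowcast import datasets
from fallowcast.evaluate import relative_error, relative_error_table

summary = datasets.fallow_precipitation_summary()
print(f"mean fallow precipitation 2009-2018: {summary['mean_fallow_precip_mm']:.2f} mm")
print(f"share of the July-June annual total: {summary['fallow_share_pct']:.2f}%")

table = datasets.load_validation_yields()
errors = relative_error_table(table, denominator="true")
per_year = errors[errors.year != "MEAN"].merge(
    table, on=["type", "tillage", "year"], suffixes=("", "_pub")
)
dev = (per_year["error_pct"] - per_year["printed_error_pct"]).abs().max()
print(f"\nper-year relative errors recomputed for {len(per_year)} rows; "
      f"max deviation from the published column: {dev:.3f} points")

cells = datasets.load_summary_yields().set_index(["type", "tillage"])
uplift = (cells.loc[("drought", "DP"), "yield"]
          / cells.loc[("drought", "SS"), "yield"] - 1) * 100
print(f"deep ploughing vs subsoiling in drought years: +{uplift:.1f}% yield")

means = datasets.load_validation_means().set_index(["type", "tillage"])
dd = means.loc[("drought", "DP")]
print(f"drought-DP MEAN row: true {dd['true']:.2f}, pred {dd['pred']:.2f} "
      f"-> error {relative_error(dd['true'], dd['pred']):.2f}%")

# All quantities follow from the printed raw values by plain arithmetic;
# the error column uses |pred - true| / true x 100, the convention that
# reproduces the published per-year figures.
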