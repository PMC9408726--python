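"""Flag heat-wave days on synthetic weather under several definitions.

Generates two regions of daily summer weather (a 120-year climatology plus
five study seasons), resolves each definition's threshold from the
climatology, and flags study days by strict exceedance and run length.
"""

from hwsense import hwd_engine as he
from hwsense.synthetic_data import generate_dataset

ds = generate_dataset(seed=1)
defs = he.standard_definitions()
thresholds = he.compute_thresholds(ds.climatology, defs)
flags, counts = he.flag_all(ds.study_weather, defs, thresholds)

show = ["HW_07", "HW_15", "HW_16", "HW_17", "HW_27"]
print(f"{'definition':<12}{'metric':<14}{'duration':<16}{'region':<10}{'thr C':>7}{'days':>6}")
for def_id in show:
    d = next(x for x in defs if x.id == def_id)
    for region in ds.config.regions:
        row = counts[(counts.region == region) & (counts.definition_id == def_id)].iloc[0]
        print(
            f"{def_id:<12}{d.metric:<14}{d.duration:<16}{region:<10}"
            f"{row.threshold_c:>7.2f}{row.hw_days:>6d}"
        )

n_days = len(ds.true_flags["Coastal"])
print()
print(f"Study window: {n_days} summer days per region.")
print("3+ day definitions (HW_16) flag a subset of the matching 2+ day ones (HW_15);")
print("moderate 90th-percentile definitions flag ~30% of study days, the regime")
print("in which definition sensitivity against illness counts is informative.")
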