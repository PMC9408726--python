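"""Derive relative humidity and the NWS heat index for a few hot days.

RH comes from the Magnus saturation-vapour-pressure ratio of dew point to
air temperature; the heat index is the Rothfusz regression with the
standard humidity adjustments.  The printed apparent temperature exceeds
the air temperature whenever conditions are hot and humid.
"""

from hwsense import weather_metrics as wm

days = [
    ("warm, dry", 32.0, 12.0),
    ("hot, humid", 35.0, 24.0),
    ("very hot, humid", 38.0, 26.0),
]

print(f"{'conditions':<16}{'tmax C':>8}{'dew C':>7}{'RH %':>7}{'heat index C':>14}")
for label, tmax, dew in days:
    rh = wm.dewpoint_to_rh(tmax, dew)
    hi = wm.heat_index(tmax, rh)
    print(f"{label:<16}{tmax:>8.1f}{dew:>7.1f}{rh:>7.1f}{hi:>14.1f}")

print()
print("A heat index above tmax means humidity is adding physiological load;")
print("NWS advisories trigger near a heat index of 100 F (37.8 C).")
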