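"""From dated seedling counts to a thermal-time emergence curve.

Simulates one site-year of weather and destructive weekly counts, builds
the cumulative curve, and prints its early-season (0-50%) portion.
"""

import poa_emergence as pe

config = pe.SimulationConfig(seed=7)
weather = pe.simulate_weather(config)["site01"]
records = pe.simulate_emergence(weather, config)
tts = pe.accumulate(weather, anchor_date=config.anchor_date)
curve = pe.build_curve(records, tts, config.season_year)

print(f"{curve.yearly_total} seedlings across {len(curve.data)} observation dates")
early = pe.early_season_subset(curve, ceiling=0.5)
print("\nearly-season points (cumulative fraction of the yearly total):")
print(early.to_string(index=False))

shares = pe.weekly_shares(curve)
top = shares.sort_values(ascending=False).head(3)
print("\nbusiest weeks of the year (share of yearly emergence):")
for week, share in top.items():
    print(f"  week {week}: {share:.1%}")
print(
    "\ncum_fraction rescales counts by the yearly total, so curves from"
    "\ndifferent sites and years are comparable on one 0-1 axis."
)
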