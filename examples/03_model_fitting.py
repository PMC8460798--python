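"""Fitting the two emergence models and reading their fit statistics.

The early-season curve (0-50% of yearly total) is fit with a Gompertz
function; the full-season curve with a saturating exponential. Both are
least-squares fits from a deterministic multi-start grid.
"""

import poa_emergence as pe

config = pe.SimulationConfig(seed=7)
weather = pe.simulate_weather(config)["site01"]
records = pe.simulate_emergence(weather, config)
tts = pe.accumulate(weather, anchor_date=config.anchor_date)
curve = pe.build_curve(records, tts, config.season_year)

early = pe.early_season_subset(curve)
gfit = pe.fit((early["cdd"].to_numpy(), early["cum_fraction"].to_numpy()), "gompertz")
sfit = pe.fit(curve.points(), "saturating_exp")

for label, f in [("early-season Gompertz", gfit), ("full-season saturating", sfit)]:
    print(
        f"{label}: a={f.a:.4f} b={f.b:.4f} c={f.c:.4f} | "
        f"R2={f.r2:.4f} MAE={f.mae:.4f} MSLE={f.msle:.2e}"
    )

x_inflect = pe.gompertz_inflection(gfit.b, gfit.c)
print(
    f"\nGompertz inflection at {x_inflect:.1f} degree-days: the thermal time"
    f"\nof fastest early-season emergence (curve value a/e = {gfit.a / 2.718281828:.3f})."
    "\nR2 near 1 and tiny MAE/MSLE mean the fitted curve tracks the"
    "\nobserved cumulative fractions almost exactly."
)
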