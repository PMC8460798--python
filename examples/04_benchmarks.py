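"""Inverting an emergence model for thermal-time benchmarks.

Uses the published yearly-cumulative parameters (saturating exponential)
and asks at how many cooling degree days 50% and 75% emergence are
predicted - the numbers a manager would pencil in for interventions.
"""

import poa_emergence as pe
from poa_emergence.models import ModelFit

yearly = ModelFit("saturating_exp", a=0.01275, b=0.9220, c=0.004)
print(f"asymptote (-a + b): {yearly.asymptote:.5f} of the yearly total")

for target in (0.25, 0.50, 0.75):
    cdd = pe.invert(yearly, target)
    print(f"{target:.0%} emergence predicted at {cdd:6.1f} cooling degree-days")

try:
    pe.invert(yearly, 0.95)
except ValueError as err:
    print(f"\n95% is not attainable: {err}")

print(
    "\nThe curve is strictly increasing, so each target has a unique root;"
    "\ntargets above the asymptote are rejected rather than extrapolated."
)
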