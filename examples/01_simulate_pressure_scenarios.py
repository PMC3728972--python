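"""Simulate harvested populations under the two signature pressure regimes.

Builds a medium life-history population (r_max = 0.2/yr, K = 1000) and
applies (a) constant proportional harvest (10%/yr) and (b) increasing fixed
harvest (25 individuals/yr, +5/yr), printing the yearly abundance around
the pressure onset.  The proportional regime settles toward the harvested
equilibrium K(1 - P/r) ~ 500; the increasing fixed regime collapses.
"""

import numpy as np

from declinewatch import LifeHistoryParams, PressureScenario, simulate_trajectory

medium = LifeHistoryParams.preset("medium")

for code, label in [("P1", "constant proportional (10%/yr)"),
                    ("F3", "increasing fixed (25/yr, +5/yr)")]:
    scen = PressureScenario(code, "low")
    traj = simulate_trajectory(medium, scen, seed=7)
    print(f"\n{code}: {label}")
    print(f"  onset after post-burn-in year {scen.onset_year}; "
          f"extinct year: {traj.extinct_year}")
    for year in (1, 20, 25, 30, 35, 40, 45, 50):
        if year <= len(traj.counts):
            print(f"  year {year:3d}: {traj.counts[year - 1]:8.1f}")

print("\nThe proportional run levels off near 500 individuals (harvested")
print("equilibrium); the increasing fixed run accelerates toward extinction.")
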