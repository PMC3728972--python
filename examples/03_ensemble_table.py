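"""Tabulate best-fit function and concavity frequencies over an ensemble.

Reproduces (at reduced replicate count) the undegraded rows of the
published frequency tables: constant proportional pressure is dominated by
exponential/quadratic concave declines, increasing fixed pressure by
quadratic convex declines, and unpressured null models split ~50/50 in
concavity with quadratic the modal function.
"""

from declinewatch import LifeHistoryParams, PressureScenario, run_ensemble

medium = LifeHistoryParams.preset("medium")

rows = [
    ("P1 low (proportional, constant)", PressureScenario("P1", "low")),
    ("F3 low (fixed, increasing)", PressureScenario("F3", "low")),
    ("null (no pressure)", None),
]
print(f"{'scenario':35s} {'lin':>6s} {'quad':>6s} {'exp':>6s} "
      f"{'concave':>8s} {'convex':>7s}")
for label, scen in rows:
    s = run_ensemble(medium, scen, None, n_reps=100, seed=3, n_boot=25)
    print(f"{label:35s} {s.pct_linear:6.1f} {s.pct_quadratic:6.1f} "
          f"{s.pct_exponential:6.1f} {s.pct_concave:8.1f} {s.pct_convex:7.1f}")
print()
print("Percentages are over each replicate's principal classified decline.")
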