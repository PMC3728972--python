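# declinewatch

Detect, segment and classify **decline-curve dynamics** in wildlife
population abundance time-series.

Conservation triage often has nothing to work with but a yearly count
series. The *shape* of a decline carries information the decline rate does
not: a population losing a fixed, growing number of individuals each year
(disease, escalating exploitation) falls along an **accelerating, convex**
curve, while one losing a proportion of its (shrinking) size each year
(proportional harvest, habitat degradation) falls along a **decelerating,
concave** curve. `declinewatch` implements a simulation-validated pipeline
that recovers this signature from noisy monitoring data:

1. **Simulate** density-dependent populations with environmental
   stochasticity under defined harvesting regimes — the discrete logistic
   model

   *N*<sub>*t*+1</sub> = *N*<sub>*t*</sub> + *r*<sub>max</sub> *N*<sub>*t*</sub> (1 − *N*<sub>*t*</sub>/*K*),

   with *r*<sub>max</sub> and *K* drawn yearly from zero-truncated normal
   random walks, and harvest removing either a fixed number *F*(*t*) or a
   proportion *P*(*t*) of the population after renewal.
2. **Smooth** the count series with a penalized cubic spline (a GAM-style
   trend) whose smoothness minimizes GCV with effective degrees of freedom
   inflated by γ = 1.4.
3. **Detect switch points (SPs)** — years where the sign of the trend's
   second difference flips — and confirm them against stochastic noise by a
   parametric bootstrap (or, for real data, by detection frequency across a
   sweep of smoothing levels).
4. **Classify** each SP-delimited section: concavity from second-difference
   signs, decline significance by linear regression (α = 0.05, humped
   sections judged by their declining piece), and the best-fit algebraic
   form — linear (*N* = *m*₁*T* + *c*), quadratic
   (*N* = *m*₂*T*² + *m*₁*T* + *c*) or asymptotic exponential
   (*N* = *Asym* + (*R*₀ − *Asym*) e^(−e^*lrc* *T*)) — by AICc with a
   ΔAICc > 4 parsimony rule.
5. **Degrade** series (shortening, monitoring gaps with linear
   interpolation, observation error) to measure how robust each pressure
   signature is to realistic data quality, against unpressured null models.

## Worked example

```python
from declinewatch import analyze_series, make_fixture

years, counts = make_fixture("exponential_decline", n=40)
res = analyze_series(counts, n_boot=50, seed=1)
print(res.status, res.best_model, res.concavity, res.sp_years)
```

prints

```
classified exponential concave [32]
```

— the pipeline confirmed one switch point (year 32), found the declining
sections concave with the asymptotic-exponential model the best fit: the
signature of constant *proportional* pressure. An accelerating collapse
would instead come back `quadratic convex`, the signature of *increasing*
pressure and the cue for urgent intervention.

The `examples/` directory holds one short script per capability
(simulation, single-series classification, ensemble tables, degradation
robustness, real-data mode); each prints its numbers with a line on what
they mean. A thin CLI mirrors the library:

```bash
declinewatch simulate --config scenario.yaml --out runs/
declinewatch classify --in counts.csv --boot 100 --seed 1
declinewatch table --which 6 --reps 200 --seed 1
declinewatch test-proportions --x1 99 --n1 159 --x2 45 --n2 159
```

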