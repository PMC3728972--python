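# Methods

This note documents the models, parameter choices and numerical decisions
behind `declinewatch`, in the order the pipeline runs them.

## Population model

Populations follow the discrete logistic map
`N[t+1] = N[t] + r*N[t]*(1 - N[t]/K)` — a deliberately minimal scalar model
chosen to mirror the kind of data basic monitoring schemes produce, with no
age/stage structure and no demographic stochasticity (small-population
noise would mask the external-pressure signal the method targets).
Environmental stochasticity enters through `r` (maximum intrinsic growth
rate) and `K` (carrying capacity), redrawn each year from normal
distributions truncated below at zero and above at fixed thresholds, with
each year's distribution centred on the previous year's *realized* draw — a
bounded random walk that imposes temporal autocorrelation.

Life-history presets (slow / medium / fast):

| speed  | r̄ (1/yr) | CV(r) | r upper | K̄  | CV(K) | N upper |
|--------|-----------|-------|---------|------|-------|---------|
| slow   | 0.1       | 0.15  | 0.15    | 1000 | 0.01  | 1300    |
| medium | 0.2       | 0.15  | 0.3     | 1000 | 0.01  | 1600    |
| fast   | 0.3       | 0.2   | 0.5     | 1000 | 0.01  | 1900    |

Upper thresholds sit three standard deviations above the means (stored as
the canonical rounded values). Populations start at `N1 = 1000` (at K) or
500 (far from K). Simulations run 150 years; the first 50 are discarded as
burn-in; abundance is a continuous scalar and extinction (absorbing) is
declared the first year it drops below one individual, with that sub-unity
count retained as the final observation.

Truncated-normal draws use rejection sampling (resampling until in-bounds —
clipping would put point mass on the bounds) with an inverse-CDF fallback
when acceptance is poor; vectorized resampling elsewhere uses the exact
truncated-normal quantile function, the same distribution.

## Pressure scenarios

Six scenario codes combine harvest type with temporal trend: proportional
(P1 constant, P2 decreasing, P3 increasing — removal of a fraction of the
population, a density-*dependent* threat proxy) and fixed (F1/F2/F3 — removal
of an absolute number, density-*independent*). Harvest applies *after*
renewal, from post-burn-in year 26 onward (year 25 is the last unpressured
count; removal schedules are indexed t = 0 at the first pressured year).

Intensity tiers: proportional 10 / 20 / 30 %/yr (the 30 % tier is the level
used to illustrate the simulations); fixed 25 / 50 / 75 individuals/yr.
Trends are linear ramps, clamped to [0, 1] (proportional) or ≥ 0 (fixed):
±0.01/yr for proportional, ±5 individuals/yr² for fixed. The fixed ramp
deserves a note: with logistic renewal, the renewal term *grows* toward
r·K/4 as abundance falls to K/2, so a slowly increasing removal produces a
*decelerating* opening phase — the opposite of the increasing-pressure
archetype (an accelerating, convex collapse). A deterministic sweep shows
5/yr² is the smallest grid rate at which removal growth outpaces renewal
compensation from the first pressured year; below it the archetype fails at
every starting tier. Both tier tables and ramps are plain module constants
and per-scenario overridable.

The frequency-table reproductions use the **low** tier for both signature
scenarios (P1 at 10 %/yr; F3 from 25/yr), the tier stated for the
proportional case and applied to the fixed case in parallel.

## Trend smoothing

The smoother is a penalized cubic B-spline regression (P-spline: uniform
knots extended past the data range, second-order difference penalty) — the
discrete analogue of a GAM smooth of count on year. The penalty's null
space is exactly the straight lines, so linear data are reproduced to
machine precision at any smoothness. The smoothing parameter minimizes

    GCV(λ) = n·RSS / (n − γ·edf)²,   γ = 1.4,

on a 101-point log-spaced λ grid, preferring the smoothest fit among
numerically tied optima. Basis dimension is capped at n − 1 in simulation
mode. Gaussian fits use a Demmler–Reinsch reparameterization cached per
(series length, basis dimension), which makes the λ search and the
bootstrap re-fits essentially free (~0.05 ms per smooth). The pointwise
95 % band is 1.96 × SE of the fitted mean from the influence matrix, with
σ² = RSS/(n − edf). Reported `edf` excludes the intercept (a constant fit
reports ≈ 1). One test cross-checks the fitted trend against an independent
reference GAM (R/mgcv, cubic regression spline, GCV, γ = 1.4) run via
Rscript.

Real-data mode smooths counts on the log link by penalized IRLS
(poisson, or quasipoisson when a poisson GLM of count on year shows
Pearson dispersion > 1.5 — the threshold is configurable), with a
Pearson-statistic GCV and confidence bands scaled by √dispersion for
quasipoisson. Fitted values are always reported on the response (count)
scale so second differences are count-based in every mode. Smoothness is
swept from basis dimension ceil(0.3·n) down to 3 by ones.

## Switch points

The trend's second derivative is approximated algebraically:
change(t) = v(t) − v(t−1), rate(t) = change(t) − change(t−1). A switch
point (SP) is a year where the rate's sign flips, in either direction —
the upward flip is required to detect the final upturn that decreasing
pressure produces. Zero rates inherit the previous sign, so flat stretches
yield no SP.

Confirmation against stochastic noise, simulation mode: 100 (desk scale:
25) parametric-bootstrap replicates redraw each year from a zero-truncated
normal with mean = fitted value and SD = the 95 % CI half-width, re-smooth
and re-detect; a year is confirmed when it is a local maximum of detection
frequency above max(0.2·n_boot, median + 1.96·SD) of per-year frequencies.
Real-data mode tallies detections across the smoothing-level sweep and
confirms years above the upper 99.99 % band around the median frequency
(normal approximation, z = 3.89), falling back to per-run peak-picking
(ties to the earliest year) when no year qualifies — a deterministic
replacement for the visual inspection a human analyst would apply.

If a confirmed SP falls exactly one year before extinction, the series is
analyzed only up to that year (the terminal collapse rounds into a
spurious curvature flip otherwise).

**Sectioning convention.** rate(t) is a backward difference over years
t−2..t, so a recorded SP lags the centred inflection by one year; sections
are therefore cut at SP − 1 (the cut year shared by both neighbours). This
keeps each curvature regime's steepest year inside its own section;
without it, decelerating (concave) sections systematically lose their
steepest year to the preceding section and gain a rising year from the
following one, biasing classification toward convex.

## Section classification

Concavity follows the second-derivative test, with the field's sign
convention: positive second differences → **concave** (decline
decelerating, exponential-like), negative → **convex** (accelerating,
quadratic-like). A section needs ≥ 90 % of one sign to take a pure label;
otherwise it is *mixed* and resolves by majority sign. Sections with an
interior maximum are *humped*; with an interior minimum, *valley* (a
decline with a final upturn — the decreasing-pressure shape).

Decline significance is an OLS regression of the section's **observed**
counts on year (α = 0.05) — the smoothed values carry almost no residual
noise, so regressing them would declare even flat drift significant. A
non-significant humped section is rescued by its declining tail (smoothed
argmax → end), a valley by its declining head (start → smoothed argmin);
a significant piece classifies the whole section as declining. Years known
to be interpolated rather than observed can be masked out of this
regression (NaN in the raw values).

Fittable (≥ 6-point) declining sections get least-squares fits of the
three decline models on the *smoothed* values (years re-indexed from 0);
the asymptotic exponential self-starts from Asym₀ = min(N), R₀ = N(0) and
a log-linear slope, refined by Levenberg–Marquardt, and is dropped (never
fatal) on non-convergence. Models are compared by Gaussian-likelihood AICc
(k = 3/4/4 counting the error variance; AICc = AIC + 2k(k+1)/(n−k−1),
absent when n−k−1 ≤ 0, in which case plain AIC is used and recorded): the
*simplest* model within 4 units of the optimum wins, with complexity
ordered linear < quadratic < exponential (quadratic is the simpler of the
two k = 4 models). RSS is floored at numerical-noise level so models
fitting exactly compare as equal and parsimony decides. Real-data mode
attaches jackknife support: the fraction of leave-one-out refits (original
year spacing preserved) selecting the same model.

## Ensembles and tables

An ensemble run simulates replicates (survival filter: ≥ 25 recorded
post-burn-in years for pressured scenarios — a 50-year filter would
selectively discard exactly the rapid collapses the increasing-pressure
scenario studies — and ≥ 50 for unpressured nulls), applies the analysis
window (25 years either side of onset; nulls use their first 50 years),
applies any degradation (fixed order: truncate → thin → observation
error), and runs the full pipeline per replicate. Each classified
replicate contributes **one** decline curve: its *principal* section, the
declining fittable section with the largest net drop in smoothed abundance
(ties to the earliest). Percentages are over classified replicates;
replicates with no classifiable decline are reported separately.

Degradations: truncation keeps the stated window around onset (the
before-only grid includes the 2-year row); thinning with gap g retains
every (g+1)-th year plus the final year and restores yearly spacing by
linear interpolation (so second differences stay valid); observation error
redraws each year from a zero-truncated normal whose SD is the across-
ensemble SD of counts for that year (extinct replicates contributing zero)
times the multiplier, computed once per scenario from the clean ensemble.

Two-sample class-frequency comparisons (e.g. against null models) use the
standard χ² test for equality of proportions with Yates continuity
correction (df = 1), via the scipy contingency-table routine.

## What the generator does and does not emulate

The synthetic ensembles carry environmental autocorrelation, harvesting
pressure, extinction, irregular monitoring (via thinning) and observation
error — the features the method's robustness claims are about. They do not
carry demographic stochasticity, density-dependence beyond the logistic,
observer bias trends, or multi-threat interactions; passing tests
demonstrate the pipeline recovers pressure signatures under the stated
model, not that real populations follow it.

## Problem sizes and known limitations

Desk-scale defaults: 200 replicates per ensemble with 25 bootstrap
resamples (the full-scale method uses 1000 and 100); the unpressured null
ensemble runs at 1000 replicates and the monitoring-gap run at 400 because
their concavity splits are the most delicate estimates. A full
seven-ensemble sweep takes well under two minutes on one CPU.

Known limitations, measured on these ensembles:

- Null-model concavity splits ~39/61 concave/convex rather than ~50/50:
  declining sections at the analysis-window end are caught in their steep
  accelerating (convex) phase, while window-start sections are caught
  decelerating with small net drops, so the largest-net-drop reduction
  leans convex on drifting, unpressured trends.
- Under 8-year monitoring gaps an increasing-fixed-pressure collapse
  becomes two or three interpolated chords; mixed sections spanning a
  chord kink resolve by sign counts that include spline ripple, leaving
  convexity near 82 % rather than essentially 100 %. Resolving mixed
  sections by net slope change or by the fitted quadratic's curvature
  fixes this but pushes the proportional-pressure gap-8 concavity split
  well away from its coin-flip behaviour; the majority rule is kept.
- Short pre-onset windows (2 years) classify more declines as exponential
  than quadratic relative to the full-information expectation; the
  quadratic share is ~60–66 %.
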