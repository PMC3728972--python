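"""Replicate ensembles and frequency tables of decline-curve classes.

``run_ensemble`` repeats simulate -> degrade -> smooth -> switch points ->
segment -> classify -> select over many replicate populations generated
under one pressure scenario, and tabulates the percentage of classified
declines falling to each best-fit function (linear / quadratic /
exponential) and each concavity side (concave / convex).  Two-sample
proportion tests (chi-squared with Yates continuity correction) compare
class frequencies between ensembles, e.g. against the unpressured null
ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.stats import chi2_contingency

from .degradation import (
    DegradationSpec,
    add_observation_error,
    ensemble_yearly_sd,
    thin_and_interpolate,
    truncate,
)
from .params import LifeHistoryParams, PressureScenario
from .pipeline import ReplicateResult, analyze_series
from .popsim import Trajectory, simulate_ensemble

__all__ = [
    "EnsembleSummary",
    "run_ensemble",
    "proportion_test",
    "compare_to_null",
]

ANALYSIS_WINDOW_YEARS = 25   # years kept either side of onset by default

MODEL_CLASSES = ("linear", "quadratic", "exponential")
CONCAVITY_CLASSES = ("concave", "convex")


@dataclass
class EnsembleSummary:
    """Class frequencies of one replicate ensemble."""

    scenario: str
    degradation: str
    n_reps: int
    n_classified: int
    n_unclassifiable: int
    counts: dict
    pct_linear: float
    pct_quadratic: float
    pct_exponential: float
    pct_concave: float
    pct_convex: float

    @classmethod
    def from_results(
        cls, scenario: str, degradation: str, results: List[ReplicateResult]
    ) -> "EnsembleSummary":
        """Tally each replicate's principal decline section.

        Every classified replicate contributes exactly one decline curve
        (its largest net decline); replicates with no classifiable decline
        are counted separately in ``n_unclassifiable``.
        """
        counts = {k: 0 for k in MODEL_CLASSES + CONCAVITY_CLASSES}
        n_class = 0
        for r in results:
            if r.classified:
                n_class += 1
                counts[r.best_model] += 1
                counts[r.concavity] += 1
        pct = lambda k: 100.0 * counts[k] / n_class if n_class else float("nan")
        return cls(
            scenario=scenario,
            degradation=degradation,
            n_reps=len(results),
            n_classified=n_class,
            n_unclassifiable=sum(1 for r in results if not r.classified),
            counts=counts,
            pct_linear=pct("linear"),
            pct_quadratic=pct("quadratic"),
            pct_exponential=pct("exponential"),
            pct_concave=pct("concave"),
            pct_convex=pct("convex"),
        )


def _degraded_window(
    traj: Trajectory,
    degradation: Optional[DegradationSpec],
    yearly_sd: Optional[np.ndarray],
    rng: np.random.Generator,
) -> Trajectory:
    """Apply the analysis window and any degradation (fixed order:
    truncate, thin, observation error)."""
    if traj.onset_year is None:
        end = min(len(traj.counts), 2 * ANALYSIS_WINDOW_YEARS)
        return traj.window(1, end)
    if degradation is not None and degradation.family.startswith("truncate_"):
        mode = degradation.family.removeprefix("truncate_")
        return truncate(traj, mode, int(degradation.amount))
    out = truncate(traj, "both", ANALYSIS_WINDOW_YEARS)
    if degradation is None:
        return out
    if degradation.family == "thin":
        return thin_and_interpolate(out, int(degradation.amount))
    if degradation.family == "obs_error":
        if yearly_sd is None:
            raise ValueError("observation error needs the ensemble yearly SD")
        return add_observation_error(out, yearly_sd, degradation.amount, rng=rng)
    raise ValueError(f"unknown degradation family {degradation.family!r}")


def run_ensemble(
    life_history: LifeHistoryParams,
    scenario: Optional[PressureScenario] = None,
    degradation: Optional[DegradationSpec] = None,
    n_reps: int = 1000,
    seed: int = 0,
    n_boot: int = 100,
) -> EnsembleSummary:
    """Simulate, degrade and classify ``n_reps`` replicate populations.

    Pressured ensembles keep trajectories surviving at least 25 post-burn-in
    years (past the onset); unpressured (null) ensembles require the full
    50-year analysis span.  Each replicate contributes its principal
    declining section's best-fit function and concavity; replicates with no
    classifiable decline are counted separately.  Deterministic per seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    min_survival = ANALYSIS_WINDOW_YEARS if scenario is not None else 2 * ANALYSIS_WINDOW_YEARS
    trajs = simulate_ensemble(life_history, scenario, n_reps, min_survival, seed)

    yearly_sd = None
    if degradation is not None and degradation.family == "obs_error":
        clean = [
            _degraded_window(tr, None, None, np.random.default_rng(0))
            for tr in trajs
        ]
        yearly_sd = ensemble_yearly_sd(clean, 2 * ANALYSIS_WINDOW_YEARS)

    results: List[ReplicateResult] = []
    for i, tr in enumerate(trajs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i, 1]))
        try:
            win = _degraded_window(tr, degradation, yearly_sd, rng)
            res = analyze_series(
                win.counts, extinct_year=win.extinct_year, n_boot=n_boot, rng=rng
            )
        except (ValueError, RuntimeError):
            res = ReplicateResult(status="error")
        results.append(res)

    scen_label = "null" if scenario is None else f"{scenario.code}-{scenario.intensity}"
    deg_label = (
        "none" if degradation is None else f"{degradation.family}:{degradation.amount:g}"
    )
    return EnsembleSummary.from_results(scen_label, deg_label, results)


def proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> Tuple[float, float]:
    """Two-sample test for equality of proportions (chi-squared, df = 1).

    Yates continuity correction applied by default, as in the standard
    two-sample prop test.  Returns (chi2, p).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # a margin is empty: no variation
        return 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)


def compare_to_null(
    summary: EnsembleSummary,
    null_summary: EnsembleSummary,
    klass: str,
    continuity: bool = True,
) -> Tuple[float, float]:
    """Proportion test of one class frequency against the null ensemble."""
    for s in (summary, null_summary):
        if klass not in s.counts:
            raise ValueError(f"class {klass!r} not tabulated in summary")
    return proportion_test(
        summary.counts[klass],
        summary.n_reps,
        null_summary.counts[klass],
        null_summary.n_reps,
        continuity=continuity,
    )
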