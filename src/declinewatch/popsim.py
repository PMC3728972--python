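"""Density-dependent population simulation with stochastic harvesting.

Populations follow the discrete logistic model

    N[t+1] = N[t] + r_max * N[t] * (1 - N[t] / K)

with environmental stochasticity entering through r_max and K, drawn each
year from normal distributions truncated below at 0 and above at fixed
thresholds.  Temporal autocorrelation is imposed by centring year t's
distributions on the values realized in year t-1 (a bounded random walk).
Harvest removes either a fixed number of individuals or a proportion of the
population each year, after renewal.  The first 50 years are discarded as
burn-in; extinction is declared the first year abundance drops below one
individual and is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import stats

from .params import LifeHistoryParams, PressureScenario

__all__ = [
    "Trajectory",
    "step_population",
    "sample_truncated_normal",
    "harvest",
    "simulate_trajectory",
    "simulate_ensemble",
    "EnsembleAttritionError",
]

BURNIN_YEARS = 50
TOTAL_YEARS = 150
EXTINCTION_THRESHOLD = 1.0


class EnsembleAttritionError(RuntimeError):
    """Raised when the survival filter cannot be satisfied."""

    def __init__(self, n_kept: int, n_attempted: int, min_survival_years: int):
        self.attrition_rate = 1.0 - n_kept / max(n_attempted, 1)
        super().__init__(
            f"only {n_kept} trajectories survived >= {min_survival_years} "
            f"post-burn-in years out of {n_attempted} attempts "
            f"(attrition {self.attrition_rate:.1%})"
        )


@dataclass
class Trajectory:
    """A post-burn-in yearly abundance series.

    ``counts[i]`` is the abundance in post-burn-in year ``i + 1``.  Counts
    stop at the extinction year (the first year below one individual, whose
    sub-unity value is retained as the final observation).
    """

    counts: np.ndarray
    burnin_years: int = BURNIN_YEARS
    onset_year: Optional[int] = None     # last unpressured post-burn-in year
    extinct_year: Optional[int] = None   # post-burn-in year index (1-based)
    seed: Optional[int] = None
    scenario_code: Optional[str] = None
    observed: Optional[np.ndarray] = None  # False where a count is interpolated

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if len(self.observed) != len(self.counts):
                raise ValueError("observed mask must align with counts")

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)

    @property
    def extinct(self) -> bool:
        return self.extinct_year is not None

    def window(self, start_year: int, end_year: int) -> "Trajectory":
        """Sub-series for post-burn-in years [start_year, end_year]."""
        if start_year < 1:
            raise ValueError("window start before first post-burn-in year")
        sub = self.counts[start_year - 1 : end_year]
        ext = None
        if self.extinct_year is not None and start_year <= self.extinct_year <= end_year:
            ext = self.extinct_year - start_year + 1
        onset = None
        if self.onset_year is not None and start_year <= self.onset_year <= end_year:
            onset = self.onset_year - start_year + 1
        return Trajectory(
            sub, self.burnin_years, onset, ext, self.seed, self.scenario_code,
            None if self.observed is None
            else self.observed[start_year - 1 : end_year],
        )

    @property
    def observed_counts(self) -> np.ndarray:
        """Counts with interpolated years masked to NaN."""
        if self.observed is None:
            return self.counts
        return np.where(self.observed, self.counts, np.nan)


def step_population(n_t: float, r: float, k: float) -> float:
    """One year of logistic renewal; never returns a negative abundance."""
    if k <= 0:
        raise ValueError("carrying capacity K must be > 0")
    if n_t < 0:
        raise ValueError("abundance must be >= 0")
    return max(n_t + r * n_t * (1.0 - n_t / k), 0.0)


def sample_truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float = 0.0,
    upper: float = np.inf,
) -> float:
    """One draw from a normal truncated to [lower, upper].

    Rejection sampling (resample until in bounds), falling back to the
    inverse-CDF when acceptance is poor; sd = 0 returns the mean exactly.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    if sd == 0:
        if not (lower <= mean <= upper):
            raise ValueError("degenerate draw (sd=0) with mean outside bounds")
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lower <= x <= upper:
            return x
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(stats.truncnorm.ppf(rng.uniform(), a, b, loc=mean, scale=sd))


def harvest(
    n_renewed: float, scenario: PressureScenario, t_since_onset: float
) -> float:
    """Remove individuals after renewal; result clamped at zero."""
    level = scenario.level_at(t_since_onset)
    if scenario.pressure_type == "fixed":
        return max(n_renewed - level, 0.0)
    return max(n_renewed * (1.0 - level), 0.0)


def simulate_trajectory(
    life_history: LifeHistoryParams,
    scenario: Optional[PressureScenario] = None,
    total_years: int = TOTAL_YEARS,
    burnin_years: int = BURNIN_YEARS,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate one population and return its post-burn-in series.

    Harvest acts from post-burn-in year ``scenario.onset_year + 1`` onward
    (the onset year itself is the last unpressured count).  ``scenario=None``
    gives an unpressured (null) trajectory.
    """
    if total_years < burnin_years + 2:
        raise ValueError("total_years must exceed burn-in by at least 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    lh = life_history
    if scenario is not None and not scenario.start_at_K:
        lh = lh.with_(N1=500.0)

    onset_abs = None
    if scenario is not None:
        onset_abs = burnin_years + scenario.onset_year  # last unpressured year

    r_prev, k_prev = lh.r_mean, lh.K_mean
    n = float(lh.N1)
    counts: List[float] = [n]
    extinct_abs: Optional[int] = None
    for year in range(2, total_years + 1):
        r = sample_truncated_normal(rng, r_prev, lh.r_sd, 0.0, lh.r_upper)
        k = sample_truncated_normal(rng, k_prev, lh.K_sd, 0.0, lh.N_upper)
        r_prev, k_prev = r, k
        n = step_population(n, r, k)
        if onset_abs is not None and year > onset_abs:
            n = harvest(n, scenario, year - onset_abs - 1)
        n = min(n, lh.N_upper)
        counts.append(n)
        if n < EXTINCTION_THRESHOLD:
            extinct_abs = year
            break

    post = np.asarray(counts[burnin_years:], dtype=float)
    extinct_year = None
    if extinct_abs is not None:
        if extinct_abs <= burnin_years:
            post = post[:0]
        else:
            extinct_year = extinct_abs - burnin_years
    return Trajectory(
        post,
        burnin_years=burnin_years,
        onset_year=None if scenario is None else scenario.onset_year,
        extinct_year=extinct_year,
        seed=seed,
        scenario_code=None if scenario is None else scenario.code,
    )


def simulate_ensemble(
    life_history: LifeHistoryParams,
    scenario: Optional[PressureScenario],
    n_keep: int,
    min_survival_years: int,
    seed: int,
    total_years: int = TOTAL_YEARS,
    attempt_cap_factor: int = 50,
) -> List[Trajectory]:
    """Simulate until ``n_keep`` trajectories survive the filter.

    A trajectory qualifies when it records at least ``min_survival_years``
    post-burn-in years.  Child seeds come from a counter under one master
    seed, so the ensemble is reproducible and each member re-runnable.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    kept: List[Trajectory] = []
    cap = attempt_cap_factor * n_keep
    attempts = 0
    while len(kept) < n_keep and attempts < cap:
        child = np.random.SeedSequence([seed, attempts])
        traj = simulate_trajectory(
            life_history,
            scenario,
            total_years=total_years,
            rng=np.random.default_rng(child),
        )
        traj.seed = attempts
        attempts += 1
        if len(traj.counts) >= min_survival_years:
            kept.append(traj)
    if len(kept) < n_keep:
        raise EnsembleAttritionError(len(kept), attempts, min_survival_years)
    return kept
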