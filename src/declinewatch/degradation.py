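"""Time-series quality degradation and null-model ensembles.

Perfect simulated series are degraded to emulate realistic monitoring:
shortening of the series around the pressure onset, sparser monitoring
(gaps between counts, linearly interpolated back to a yearly grid), and
added observation error (truncated-normal resampling of each count with an
SD taken from the across-ensemble spread for that year, scaled by a
multiplier).  Null-model ensembles — unpressured, undegraded populations —
estimate the method's false-positive behaviour.

When degradations are composed the order is fixed: truncate, then thin,
then observation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from .params import LifeHistoryParams
from .popsim import Trajectory, simulate_ensemble

__all__ = [
    "DegradationSpec",
    "truncate",
    "thin_and_interpolate",
    "add_observation_error",
    "ensemble_yearly_sd",
    "make_null_ensemble",
]

TRUNCATION_GRID = {
    "truncate_both": (25, 20, 15, 10, 5),
    "truncate_after": (25, 20, 15, 10, 5),
    "truncate_before": (25, 20, 15, 10, 5, 2),
}
GAP_GRID = (1, 2, 3, 5, 8)
MULTIPLIER_GRID = (1.0, 1.5, 2.0, 2.5)


@dataclass(frozen=True)
class DegradationSpec:
    """One degradation applied to an analyzed series.

    ``family`` is one of truncate_both / truncate_after / truncate_before
    (amount = years kept on the affected side(s) of the pressure onset),
    thin (amount = gap length in missing years between counts), or
    obs_error (amount = SD multiplier).
    """

    family: str
    amount: float

    def __post_init__(self) -> None:
        if self.family in TRUNCATION_GRID:
            if self.amount < 2:
                raise ValueError("truncation window must keep at least 2 years")
        elif self.family == "thin":
            if self.amount < 1:
                raise ValueError("gap length must be >= 1")
        elif self.family == "obs_error":
            if self.amount < 0:
                raise ValueError("SD multiplier must be >= 0")
        else:
            raise ValueError(f"unknown degradation family {self.family!r}")


def truncate(traj: Trajectory, mode: str, years: int) -> Trajectory:
    """Keep a window of the series around the pressure onset.

    ``both`` keeps ``years`` on each side of the onset; ``after`` keeps the
    full pre-onset span plus ``years`` after; ``before`` keeps ``years``
    before plus the full 25-year post-onset span.  The onset year itself
    counts as the last pre-onset year.
    """
    if traj.onset_year is None:
        raise ValueError("trajectory has no recorded pressure onset")
    onset = traj.onset_year
    if mode in ("both", "truncate_both"):
        start, end = onset - years + 1, onset + years
    elif mode in ("after", "truncate_after"):
        start, end = 1, onset + years
    elif mode in ("before", "truncate_before"):
        start, end = onset - years + 1, onset + 25
    else:
        raise ValueError(f"unknown truncation mode {mode!r}")
    if start < 1:
        raise ValueError("window exceeds the available pre-onset data")
    return traj.window(start, end)


def thin_and_interpolate(traj: Trajectory, gap: int) -> Trajectory:
    """Sparser monitoring: keep every (gap+1)-th count, interpolate back.

    A gap of g means g missing years between retained counts.  Removed
    years are filled by linear interpolation so the output stays yearly and
    equal-length.  The final year is always retained (a monitoring series
    ends on an observed count), so the interpolation spans the whole
    series.
    """
    if gap < 1:
        raise ValueError("gap must be >= 1")
    n = len(traj.counts)
    kept = np.unique(np.append(np.arange(0, n, gap + 1), n - 1))
    filled = np.interp(np.arange(n), kept, traj.counts[kept])
    observed = np.zeros(n, dtype=bool)
    observed[kept] = True
    if traj.observed is not None:
        observed &= traj.observed
    return Trajectory(
        filled, traj.burnin_years, traj.onset_year, traj.extinct_year,
        traj.seed, traj.scenario_code, observed,
    )


def ensemble_yearly_sd(ensemble: List[Trajectory], n_years: int) -> np.ndarray:
    """Per-year SD of counts across an ensemble.

    Extinct trajectories contribute zero abundance after their last
    recorded year, mirroring the population being gone.
    """
    mat = np.zeros((len(ensemble), n_years))
    for i, tr in enumerate(ensemble):
        m = min(len(tr.counts), n_years)
        mat[i, :m] = tr.counts[:m]
    return mat.std(axis=0)


def add_observation_error(
    traj: Trajectory,
    yearly_sd: np.ndarray,
    multiplier: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Resample each count from a truncated normal around itself.

    The SD for year t is ``multiplier`` times the across-ensemble SD of
    counts for that year; the normal is truncated below at zero.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    y = traj.counts
    n = len(y)
    sd = np.asarray(yearly_sd, dtype=float)[:n] * multiplier
    noisy = y.copy()
    pos = sd > 0
    if np.any(pos):
        a = (0.0 - y[pos]) / sd[pos]
        noisy[pos] = stats.truncnorm.ppf(
            rng.uniform(size=int(pos.sum())), a, np.inf, loc=y[pos], scale=sd[pos]
        )
    return Trajectory(
        noisy, traj.burnin_years, traj.onset_year, traj.extinct_year,
        traj.seed, traj.scenario_code, traj.observed,
    )


def make_null_ensemble(
    n: int,
    seed: int,
    life_history: Optional[LifeHistoryParams] = None,
    min_survival_years: int = 50,
) -> List[Trajectory]:
    """Unpressured, undegraded medium-life-history populations at K."""
    from .params import LifeHistoryParams as LHP

    lh = life_history if life_history is not None else LHP.preset("medium")
    return simulate_ensemble(lh, None, n, min_survival_years, seed)
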