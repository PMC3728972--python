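"""Second-derivative switch-point (SP) detection on smoothed trends.

The second derivative of the smoothed trend is approximated algebraically
by second differences of the yearly fitted values: change(t) = v(t) -
v(t-1), rate(t) = change(t) - change(t-1).  A switch point is a year where
the sign of the rate of change flips, marking a transition in decline
speed.  Candidate SPs are confirmed against stochastic noise either by a
parametric bootstrap around the smoothed fit (simulation mode) or by
tallying detections across a sweep of smoothing levels (real-data mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .smoothing import SmoothedTrend, smooth_series

__all__ = [
    "SwitchPointSet",
    "second_differences",
    "detect_switches",
    "truncate_pre_extinction",
    "confirm_sps_bootstrap",
    "confirm_sps_levels",
]

Z_9999 = 3.89   # normal quantile for the upper 99.99% band around the median


@dataclass
class SwitchPointSet:
    """Candidate and confirmed SP locations for one series.

    Years are 1-based indices into the analyzed series.  ``frequencies``
    maps each year to its detection count across bootstrap replicates or
    smoothing levels.
    """

    candidate_years: List[int]
    confirmed_years: List[int]
    frequencies: Optional[np.ndarray] = None
    method: str = "none"
    truncation_year: Optional[int] = None

    def __post_init__(self) -> None:
        self.candidate_years = sorted(int(y) for y in self.candidate_years)
        self.confirmed_years = sorted(int(y) for y in self.confirmed_years)


def second_differences(values) -> np.ndarray:
    """Rates of change (discrete second derivative) of a yearly series.

    Returns an array aligned with the input; the first two entries are NaN
    (undefined).  rate(t) = [v(t) - v(t-1)] - [v(t-1) - v(t-2)].
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points for second differences")
    out = np.full(len(v), np.nan)
    out[2:] = np.diff(v, n=2)
    return out


def _carried_signs(rates: np.ndarray) -> np.ndarray:
    """Signs of the rates with zeros inheriting the last nonzero sign."""
    s = np.sign(rates)
    s[np.isnan(rates)] = np.nan
    last = 0.0
    for i in range(len(s)):
        if np.isnan(s[i]):
            continue
        if s[i] == 0.0:
            s[i] = last
        else:
            last = s[i]
    return s


def detect_switches(rates) -> List[int]:
    """Years (1-based) where the rate of change switches sign.

    Both switch directions are flagged; zero rates carry the previous sign
    forward, so flat stretches produce no SP.
    """
    r = np.asarray(rates, dtype=float)
    s = _carried_signs(r)
    years: List[int] = []
    for t in range(1, len(s)):
        a, b = s[t - 1], s[t]
        if np.isnan(a) or np.isnan(b) or a == 0.0 or b == 0.0:
            continue
        if a != b:
            years.append(t + 1)  # 1-based year index
    return years


def detect_switches_from_values(values) -> List[int]:
    """Convenience: second differences then sign-switch detection."""
    return detect_switches(second_differences(values))


def truncate_pre_extinction(
    sps: SwitchPointSet, extinct_year: Optional[int]
) -> SwitchPointSet:
    """Apply the pre-extinction truncation rule.

    If a confirmed SP sits one year before extinction, the trend is only
    analyzed up to that year: the SP is dropped from sectioning and the
    truncation year recorded.
    """
    if extinct_year is None or (extinct_year - 1) not in sps.confirmed_years:
        return sps
    cut = extinct_year - 1
    return SwitchPointSet(
        candidate_years=sps.candidate_years,
        confirmed_years=[y for y in sps.confirmed_years if y != cut],
        frequencies=sps.frequencies,
        method=sps.method,
        truncation_year=cut,
    )


def _confirm_from_frequencies(
    freqs: np.ndarray,
    threshold: float,
    candidates: Sequence[int],
    method: str,
    fallback_peak_pick: bool,
) -> SwitchPointSet:
    """Confirmed years = local frequency maxima above the threshold."""
    confirmed: List[int] = []
    for t in range(2, len(freqs)):
        f = freqs[t]
        if f <= threshold or f == 0:
            continue
        left = freqs[t - 1] if t - 1 >= 2 else -np.inf
        right = freqs[t + 1] if t + 1 < len(freqs) else -np.inf
        if f >= left and f >= right:
            confirmed.append(t + 1)
    if not confirmed and fallback_peak_pick:
        confirmed = _peak_pick(freqs)
    return SwitchPointSet(
        candidate_years=list(candidates),
        confirmed_years=confirmed,
        frequencies=freqs,
        method=method,
    )


def _peak_pick(freqs: np.ndarray) -> List[int]:
    """Within each run of adjacent detected years keep the most frequent
    year; ties go to the earliest year."""
    picked: List[int] = []
    t = 2
    n = len(freqs)
    while t < n:
        if freqs[t] == 0:
            t += 1
            continue
        start = t
        while t < n and freqs[t] > 0:
            t += 1
        run = freqs[start:t]
        picked.append(start + int(np.argmax(run)) + 1)
    return picked


def confirm_sps_bootstrap(
    trend: SmoothedTrend,
    n_boot: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    min_frac: float = 0.2,
) -> SwitchPointSet:
    """Confirm SPs against stochastic noise by a parametric bootstrap.

    Each replicate redraws yearly counts from a normal truncated at zero
    with mean equal to the smoothed count and SD equal to the 95% CI
    half-width, re-smooths, and re-detects SPs.  A year is confirmed when
    it is a local maximum of the detection frequency exceeding
    max(min_frac * n_boot, median + 1.96 * SD) of the per-year frequencies.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    fitted = trend.fitted
    sd = trend.ci95_half_width
    n = len(fitted)
    candidates = detect_switches_from_values(fitted)

    freqs = np.zeros(n)
    if np.all(sd <= 0):
        for y in candidates:
            freqs[y - 1] = n_boot
    else:
        sd_pos = np.maximum(sd, 1e-12)
        a = (0.0 - fitted) / sd_pos
        for _ in range(n_boot):
            u = rng.uniform(size=n)
            y_star = stats.truncnorm.ppf(u, a, np.inf, loc=fitted, scale=sd_pos)
            t_star = smooth_series(
                y_star, max_basis_dim=trend.basis_dim_used, family="gaussian"
            )
            for y in detect_switches_from_values(t_star.fitted):
                freqs[y - 1] += 1

    eligible = freqs[2:]
    med = float(np.median(eligible))
    sd_f = float(np.std(eligible))
    threshold = max(min_frac * n_boot, med + 1.96 * sd_f)
    return _confirm_from_frequencies(
        freqs, threshold, candidates, "bootstrap", fallback_peak_pick=False
    )


def confirm_sps_levels(levels: Sequence[SmoothedTrend]) -> SwitchPointSet:
    """Confirm SPs across a sweep of smoothing levels (real-data mode).

    Detections are tallied per year over all levels; confirmed years exceed
    the upper 99.99% band around the median per-year frequency.  If no year
    qualifies, peak-picking keeps the most frequent year of each run of
    adjacent detections (ties to the earliest year).
    """
    if not levels:
        raise ValueError("need at least one smoothing level")
    n = len(levels[0].fitted)
    freqs = np.zeros(n)
    all_candidates: set = set()
    for tr in levels:
        cand = detect_switches_from_values(tr.fitted)
        all_candidates.update(cand)
        for y in cand:
            freqs[y - 1] += 1
    if len(levels) == 1:
        return SwitchPointSet(
            candidate_years=sorted(all_candidates),
            confirmed_years=sorted(all_candidates),
            frequencies=freqs,
            method="smoothing-levels",
        )
    eligible = freqs[2:]
    med = float(np.median(eligible))
    sd_f = float(np.std(eligible))
    threshold = med + Z_9999 * sd_f
    return _confirm_from_frequencies(
        freqs, threshold, sorted(all_candidates), "smoothing-levels",
        fallback_peak_pick=True,
    )
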