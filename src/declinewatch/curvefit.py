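"""Classification of SP-delimited trend sections.

Each section of the smoothed trend between confirmed switch points is
(1) classified by concavity from the signs of its second differences —
"concave" (positive second derivative, decline decelerating, the
exponential-decay shape) vs. "convex" (negative second derivative, decline
accelerating, the quadratic-fall shape), following the sign convention of
the second-derivative test as used in trend analysis; (2) tested for a
significant decline by linear regression (alpha = 0.05), with humped
sections judged by their declining tail; and (3) fitted with linear,
quadratic, and asymptotic-exponential decline models compared by
small-sample-corrected AIC, the simplest model within 4 AICc units of the
optimum being preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .smoothing import SmoothedTrend
from .switchpoints import SwitchPointSet, second_differences

__all__ = [
    "DeclineSection",
    "CurveModelFit",
    "CurveFitResult",
    "segment",
    "classify_concavity",
    "test_decline",
    "fit_models",
    "select_best",
    "jackknife_support",
    "analyze_section",
]

MIN_FITTABLE = 6          # sections "longer than five data points"
CONCAVITY_MAJORITY = 0.9  # fraction of second-difference signs to call a side
DELTA_PARSIMONY = 4.0     # AICc units a complex model must win by
MODEL_COMPLEXITY = {"linear": 0, "quadratic": 1, "exponential": 2}
MODEL_K = {"linear": 3, "quadratic": 4, "exponential": 4}
_LOG2PI1 = np.log(2.0 * np.pi) + 1.0


@dataclass
class DeclineSection:
    """One SP-delimited stretch of the smoothed trend."""

    start_year: int
    end_year: int
    values: np.ndarray                      # smoothed trend values
    raw_values: Optional[np.ndarray] = None  # observed counts, same span
    fittable: bool = True
    concavity: Optional[str] = None       # concave | convex | mixed
    shape: str = "plain"                  # plain | humped
    decline_p_value: Optional[float] = None
    is_declining: Optional[bool] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.raw_values is not None:
            self.raw_values = np.asarray(self.raw_values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def resolved_concavity(self) -> Optional[str]:
        """Concavity with 'mixed' resolved by the majority sign of the
        section's second differences (ties go to concave)."""
        if self.concavity in ("concave", "convex", None):
            return self.concavity
        rates = second_differences(self.values)[2:]
        return "concave" if np.sum(rates > 0) >= np.sum(rates < 0) else "convex"


@dataclass
class CurveModelFit:
    """Least-squares fit of one decline model to a section."""

    model: str
    params: dict
    rss: float
    n: int
    k: int
    aic: float
    aicc: Optional[float]


@dataclass
class CurveFitResult:
    """Per-section model comparison outcome."""

    section: DeclineSection
    fits: List[CurveModelFit]
    best_model: str
    selection_rule_used: str
    delta_to_runner_up: float
    jackknife_support: Optional[float] = None


def segment(
    trend: SmoothedTrend,
    sps: SwitchPointSet,
    raw_counts=None,
) -> List[DeclineSection]:
    """Split the smoothed trend at confirmed SP years.

    An SP year ends one section and starts the next (boundary years are
    shared).  Sections shorter than six points are kept but flagged
    unfittable.  A recorded truncation year cuts the series first.  When
    the observed counts are supplied they travel with each section so the
    decline-significance test can run on the data rather than the smooth.
    """
    fitted = trend.fitted
    n = len(fitted)
    raw = None if raw_counts is None else np.asarray(raw_counts, dtype=float)
    if sps.truncation_year is not None:
        n = min(n, sps.truncation_year)
        fitted = fitted[:n]
    cuts = [y for y in sps.confirmed_years if 1 < y < n]
    bounds = [1] + cuts + [n]
    sections = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        vals = fitted[a - 1 : b]
        sections.append(
            DeclineSection(
                a, b, vals,
                raw_values=None if raw is None else raw[a - 1 : b],
                fittable=len(vals) >= MIN_FITTABLE,
            )
        )
    return sections


def _sign_fractions(values: np.ndarray) -> Tuple[float, float]:
    rates = second_differences(values)[2:]
    scale = max(np.max(np.abs(values)), 1.0)
    tol = 1e-9 * scale
    m = len(rates)
    if m == 0:
        return 0.0, 0.0
    return float(np.sum(rates > tol)) / m, float(np.sum(rates < -tol)) / m


def _hump_shape(values: np.ndarray) -> str:
    """plain / humped (interior maximum) / valley (interior minimum)."""
    rng = np.ptp(values)
    if rng == 0:
        return "plain"
    imax = int(np.argmax(values))
    if imax not in (0, len(values) - 1):
        rise = values[imax] - values[0]
        fall = values[imax] - values[-1]
        if rise > 0.05 * rng and fall > 0.05 * rng:
            return "humped"
    imin = int(np.argmin(values))
    if imin not in (0, len(values) - 1):
        fall = values[0] - values[imin]
        rise = values[-1] - values[imin]
        if rise > 0.05 * rng and fall > 0.05 * rng:
            return "valley"
    return "plain"


def classify_concavity(
    section: DeclineSection, majority: float = CONCAVITY_MAJORITY
) -> str:
    """Concavity from second-difference signs; sets the section's fields.

    At least ``majority`` of the second differences must share a sign to
    call the section concave (positive) or convex (negative); anything else
    is mixed.  Humped shapes (interior maximum) are marked for the
    declining-tail significance rule.
    """
    if len(section) < 3:
        raise ValueError("need at least 3 points to classify concavity")
    pos, neg = _sign_fractions(section.values)
    if pos >= majority:
        label = "concave"
    elif neg >= majority:
        label = "convex"
    else:
        label = "mixed"
    section.concavity = label
    section.shape = _hump_shape(section.values)
    return label


def test_decline(
    section: DeclineSection, alpha: float = 0.05
) -> Tuple[bool, float]:
    """Linear-regression decline test; humped sections use their tail.

    A section is declining when the OLS slope of count on year is negative
    with p < alpha.  The regression runs on the section's observed counts
    when available (the smoothed values carry almost no residual noise, so
    regressing them would declare even a flat stretch significant); the
    smoothed values are the fallback.  A humped section failing the test is
    re-examined over its declining tail (from the section's smoothed
    maximum to the end); a significant tail classifies the whole section as
    declining.
    """
    v = section.raw_values if section.raw_values is not None else section.values
    years = np.arange(len(v), dtype=float)
    # interpolated filler years (NaN in the observed counts) carry no
    # evidence and are excluded from the regression
    ok = np.isfinite(v)

    def _regress(idx_from: int, idx_to: int):
        m = ok.copy()
        m[:idx_from] = False
        m[idx_to:] = False
        if m.sum() < 3 or np.ptp(v[m]) == 0.0:
            return None
        return stats.linregress(years[m], v[m])

    res = _regress(0, len(v))
    if res is None:
        section.is_declining, section.decline_p_value = False, 1.0
        return False, 1.0
    declining = bool(res.slope < 0 and res.pvalue < alpha)
    p = float(res.pvalue)
    if not declining and section.shape in ("humped", "valley"):
        # non-monotone sections are judged by their declining piece alone:
        # a hump's tail (from the smoothed maximum to the end) or a
        # valley's head (from the start to the smoothed minimum)
        if section.shape == "humped":
            tres = _regress(int(np.argmax(section.values)), len(v))
        else:
            tres = _regress(0, int(np.argmin(section.values)) + 1)
        if tres is not None and tres.slope < 0 and tres.pvalue < alpha:
            declining, p = True, float(tres.pvalue)
    section.is_declining, section.decline_p_value = declining, p
    return declining, p


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    return n * np.log(rss / n) + n * _LOG2PI1 + 2 * k


def _make_fit(
    model: str, params: dict, resid: np.ndarray, n: int, scale: float
) -> CurveModelFit:
    # floor the RSS at numerical-noise level so that models fitting the data
    # essentially exactly compare as equal (parsimony then decides)
    k = MODEL_K[model]
    rss = max(float(resid @ resid), n * (1e-7 * scale) ** 2)
    aic = _gaussian_aic(rss, n, k)
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else None
    return CurveModelFit(model, params, rss, n, k, aic, aicc)


def _exp_model(t: np.ndarray, asym: float, r0: float, lrc: float) -> np.ndarray:
    return asym + (r0 - asym) * np.exp(-np.exp(np.clip(lrc, -50, 50)) * t)


def _exp_selfstart(t: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Starting values mimicking the asymptotic-regression self-starter."""
    asym0 = float(np.min(y))
    r00 = float(y[0])
    shift = asym0 * 0.95 if asym0 > 0 else asym0 - 0.05 * max(np.ptp(y), 1.0)
    z = y - shift
    ok = z > 0
    if ok.sum() >= 3:
        slope = stats.linregress(t[ok], np.log(z[ok])).slope
        lrc0 = float(np.log(max(-slope, 1e-4)))
    else:
        lrc0 = float(np.log(1.0 / max(len(t), 2)))
    return asym0, r00, lrc0


def fit_models(section: DeclineSection) -> List[CurveModelFit]:
    """Least-squares fits of the three decline models to a section.

    Years are re-indexed to start at zero.  The exponential model
    N = Asym + (R0 - Asym) * exp(-exp(lrc) * T) is fitted by refined
    nonlinear least squares from asymptotic-regression starting values; if
    it fails to converge it is dropped (never fatal).
    """
    if not section.fittable:
        raise ValueError("section has fewer than six points")
    return _fit_models_xy(np.arange(len(section), dtype=float), section.values)


def _fit_models_xy(t: np.ndarray, y: np.ndarray) -> List[CurveModelFit]:
    n = len(y)
    scale = max(float(np.ptp(y)), 1.0)
    fits: List[CurveModelFit] = []

    m1, c = np.polyfit(t, y, 1)
    fits.append(
        _make_fit("linear", {"m1": m1, "c": c}, y - (m1 * t + c), n, scale)
    )

    m2, m1q, cq = np.polyfit(t, y, 2)
    fits.append(
        _make_fit(
            "quadratic",
            {"m1": m1q, "m2": m2, "c": cq},
            y - (m2 * t**2 + m1q * t + cq),
            n,
            scale,
        )
    )

    try:
        p0 = _exp_selfstart(t, y)
        with warnings.catch_warnings():
            # near-perfect fits make the covariance inestimable; only the
            # point estimate is used here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_exp_model, t, y, p0=p0, maxfev=2000)
        resid = y - _exp_model(t, *popt)
        if np.all(np.isfinite(resid)):
            fits.append(
                _make_fit(
                    "exponential",
                    {"Asym": popt[0], "R0": popt[1], "lrc": popt[2]},
                    resid,
                    n,
                    scale,
                )
            )
    except (RuntimeError, ValueError, optimize.OptimizeWarning):
        pass
    return fits


def select_best(
    fits: Sequence[CurveModelFit],
    section: Optional[DeclineSection] = None,
    delta: float = DELTA_PARSIMONY,
) -> CurveFitResult:
    """Pick the best decline model under the parsimony-relaxed AICc rule.

    Models are compared by AICc (by AIC when any fit lacks AICc); the
    simplest model within ``delta`` units of the optimum is chosen, so a
    more complex model wins only by beating every simpler one by more than
    ``delta``.  Complexity order: linear < quadratic < exponential (the two
    k=4 models tie-broken with quadratic as the simpler).
    """
    if not fits:
        raise ValueError("need at least one fit")
    rule = "aicc" if all(f.aicc is not None for f in fits) else "aic"
    score = {f.model: (f.aicc if rule == "aicc" else f.aic) for f in fits}
    ordered = sorted(fits, key=lambda f: MODEL_COMPLEXITY[f.model])
    best_val = min(score.values())
    chosen = next(f for f in ordered if score[f.model] <= best_val + delta)
    others = [score[f.model] for f in fits if f.model != chosen.model]
    delta_ru = min(others) - score[chosen.model] if others else np.nan
    return CurveFitResult(
        section=section
        if section is not None
        else DeclineSection(0, 0, np.zeros(0), fittable=False),
        fits=list(fits),
        best_model=chosen.model,
        selection_rule_used=rule,
        delta_to_runner_up=float(delta_ru),
    )


def jackknife_support(section: DeclineSection) -> float:
    """Fraction of leave-one-out refits agreeing with the full-data model."""
    full = select_best(fit_models(section), section).best_model
    n = len(section)
    t_all = np.arange(n, dtype=float)
    agree = 0
    total = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            fits = _fit_models_xy(t_all[keep], section.values[keep])
            if fits and select_best(fits).best_model == full:
                agree += 1
            total += 1
        except (ValueError, RuntimeError):
            continue
    return agree / total if total else 0.0


def analyze_section(section: DeclineSection, alpha: float = 0.05,
                    majority: float = CONCAVITY_MAJORITY,
                    with_jackknife: bool = False) -> Optional[CurveFitResult]:
    """Full per-section pipeline: concavity, decline test, fit, select.

    Returns None when the section is unfittable or not significantly
    declining.
    """
    if len(section) < 3:
        return None
    classify_concavity(section, majority)
    declining, _ = test_decline(section, alpha)
    if not declining or not section.fittable:
        return None
    fits = fit_models(section)
    if not fits:
        return None
    result = select_best(fits, section)
    if with_jackknife:
        result.jackknife_support = jackknife_support(section)
    return result
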