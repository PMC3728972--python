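"""Life-history parameter blocks and harvesting-pressure scenarios.

The simulator represents mammal populations of three life-history "speeds"
(slow, medium, fast), each defined by a maximum intrinsic growth rate r_max,
a carrying capacity K, and the spread (coefficient of variation) of the
environmental noise on both.  Pressure scenarios combine a harvest type
(fixed number of individuals per year vs. a proportion of the population)
with a temporal trend (constant, decreasing, increasing) and an intensity
tier (low, medium, high).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "LifeHistoryParams",
    "PressureScenario",
    "LIFE_HISTORIES",
    "PROPORTIONAL_INTENSITY",
    "FIXED_INTENSITY",
    "PROPORTIONAL_RAMP",
    "FIXED_RAMP",
    "SCENARIO_CODES",
]


@dataclass(frozen=True)
class LifeHistoryParams:
    """Demographic parameters of one life-history speed.

    ``r_sd = r_cv * r_mean`` and ``K_sd = K_cv * K_mean``; the upper
    truncation thresholds sit three standard deviations above the means
    (stored as the canonical rounded values).  ``N1`` is the abundance at
    the start of the simulation (before burn-in).
    """

    label: str
    r_mean: float           # 1/yr, maximum intrinsic growth rate
    r_cv: float
    r_upper: float          # 1/yr, upper truncation for r_max draws
    K_mean: float           # individuals, carrying capacity
    K_cv: float
    N1: float               # individuals, starting abundance
    N_upper: float          # individuals, upper truncation/cap on abundance

    @property
    def r_sd(self) -> float:
        return self.r_cv * self.r_mean

    @property
    def K_sd(self) -> float:
        return self.K_cv * self.K_mean

    def __post_init__(self) -> None:
        for name in ("r_mean", "r_upper", "K_mean", "N1", "N_upper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.r_cv < 0 or self.K_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")

    def with_(self, **kwargs) -> "LifeHistoryParams":
        """Return a copy with fields replaced (e.g. zero-noise overrides)."""
        return replace(self, **kwargs)

    @classmethod
    def preset(cls, label: str, start_at_K: bool = True) -> "LifeHistoryParams":
        """One of the three canonical life-history speeds.

        ``start_at_K`` chooses N1 = K (1000) vs. far from K (500).
        """
        try:
            lh = LIFE_HISTORIES[label]
        except KeyError:
            raise ValueError(f"unknown life-history label {label!r}") from None
        return lh if start_at_K else lh.with_(N1=500.0)


LIFE_HISTORIES = {
    "slow": LifeHistoryParams("slow", 0.1, 0.15, 0.15, 1000.0, 0.01, 1000.0, 1300.0),
    "medium": LifeHistoryParams("medium", 0.2, 0.15, 0.3, 1000.0, 0.01, 1000.0, 1600.0),
    "fast": LifeHistoryParams("fast", 0.3, 0.2, 0.5, 1000.0, 0.01, 1000.0, 1900.0),
}

# Intensity tiers.  Proportional: fraction of the population removed per year
# (the high tier, 30 %, is the level illustrated in the simulation figures).
# Fixed: individuals removed per year.
PROPORTIONAL_INTENSITY = {"low": 0.10, "medium": 0.20, "high": 0.30}
FIXED_INTENSITY = {"low": 25.0, "medium": 50.0, "high": 75.0}

# Linear ramp rates for the decreasing / increasing temporal trends.  The
# fixed-pressure ramp must outpace the logistic's renewal compensation
# (renewal grows toward r*K/4 as abundance falls to K/2, decelerating the
# early decline): below about 5 individuals/yr^2 an increasing fixed
# pressure starting at the low tier produces a decelerating opening phase
# instead of the archetypal accelerating (convex) collapse.
PROPORTIONAL_RAMP = 0.01   # fraction per year
FIXED_RAMP = 5.0           # individuals per year per year

SCENARIO_CODES = {
    "P1": ("proportional", "constant"),
    "P2": ("proportional", "decreasing"),
    "P3": ("proportional", "increasing"),
    "F1": ("fixed", "constant"),
    "F2": ("fixed", "decreasing"),
    "F3": ("fixed", "increasing"),
}


@dataclass(frozen=True)
class PressureScenario:
    """A harvesting-pressure regime: type x temporal trend x intensity."""

    code: str
    intensity: str = "low"
    onset_year: int = 25          # post-burn-in year after which harvest acts
    start_at_K: bool = True
    base_level: Optional[float] = None   # override the intensity table
    ramp: Optional[float] = None         # override the ramp rate

    def __post_init__(self) -> None:
        if self.code not in SCENARIO_CODES:
            raise ValueError(f"unknown scenario code {self.code!r}")
        if self.intensity not in PROPORTIONAL_INTENSITY:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if self.pressure_type == "proportional" and not 0 < self.level0 <= 1:
            raise ValueError("proportional removal fraction must be in (0, 1]")
        if self.level0 <= 0:
            raise ValueError("pressure intensity must be positive")

    @property
    def pressure_type(self) -> str:
        return SCENARIO_CODES[self.code][0]

    @property
    def trend(self) -> str:
        return SCENARIO_CODES[self.code][1]

    @property
    def level0(self) -> float:
        """Removal level in the first pressured year."""
        if self.base_level is not None:
            return self.base_level
        table = (
            PROPORTIONAL_INTENSITY
            if self.pressure_type == "proportional"
            else FIXED_INTENSITY
        )
        return table[self.intensity]

    @property
    def ramp_rate(self) -> float:
        if self.ramp is not None:
            return self.ramp
        return PROPORTIONAL_RAMP if self.pressure_type == "proportional" else FIXED_RAMP

    def level_at(self, t_since_onset: float) -> float:
        """Removal schedule F(t) or P(t), t = 0 in the first pressured year.

        Decreasing/increasing trends are linear ramps, clamped to [0, 1] for
        proportional removal and to >= 0 for fixed removal.
        """
        if t_since_onset < 0:
            raise ValueError("t_since_onset must be >= 0")
        lvl = self.level0
        if self.trend == "increasing":
            lvl = lvl + self.ramp_rate * t_since_onset
        elif self.trend == "decreasing":
            lvl = lvl - self.ramp_rate * t_since_onset
        lvl = max(lvl, 0.0)
        if self.pressure_type == "proportional":
            lvl = min(lvl, 1.0)
        return lvl
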