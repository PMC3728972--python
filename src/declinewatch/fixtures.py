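"""Labelled synthetic series with known ground truth, for end-to-end tests.

The ``noisy_lpi_like`` kind emulates the monitoring-database style of
series the real-data mode must accept: a few to many yearly counts,
Poisson-like observation noise, and occasional gaps shorter than eight
years.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "exponential_decline",
    "quadratic_decline",
    "linear_decline",
    "humped",
    "stable",
    "noisy_lpi_like",
)


def make_fixture(
    kind: str,
    seed: Optional[int] = None,
    n: int = 40,
    noise_sd: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Generate one (years, counts) series of a known shape.

    ``noise_sd`` adds Gaussian noise (as a fraction of the series range) to
    the deterministic kinds; ``noisy_lpi_like`` ignores it and uses Poisson
    observation noise with random sub-8-year gaps instead.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)

    if kind == "exponential_decline":
        y = 200.0 + 800.0 * np.exp(-np.exp(-1.6) * t)
    elif kind == "quadratic_decline":
        y = 1000.0 - 2.0 * t - 0.45 * t**2
        y = np.maximum(y, 1.0)
    elif kind == "linear_decline":
        y = 1000.0 - 15.0 * t
        y = np.maximum(y, 1.0)
    elif kind == "humped":
        # logistic rise then collapse: mixed curvature with interior maximum
        rise = 400.0 + 500.0 / (1.0 + np.exp(-(t - n * 0.25) / 2.5))
        fall = 1.0 / (1.0 + np.exp((t - n * 0.55) / 3.0))
        y = 400.0 + (rise - 400.0) * fall
    elif kind == "stable":
        y = np.full(n, 800.0)
    else:  # noisy_lpi_like
        lam = 120.0 * np.exp(-0.02 * t)
        y = rng.poisson(lam).astype(float)
        years = np.arange(1970, 1970 + n)
        keep = np.ones(n, dtype=bool)
        i = 1
        while i < n - 1:
            if rng.uniform() < 0.15:
                gap = int(rng.integers(1, 7))  # < 8-year gaps
                keep[i : min(i + gap, n - 1)] = False
                i += gap + 1
            else:
                i += 1
        return years[keep], y[keep]

    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd * np.ptp(y), size=n)
        y = np.maximum(y, 0.0)
    years = np.arange(1, n + 1)
    return years, y
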