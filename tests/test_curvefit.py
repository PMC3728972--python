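"""Section classification, decline testing, model fitting and selection."""

import numpy as np
import pytest

from declinewatch.curvefit import (
    CurveModelFit,
    DeclineSection,
    analyze_section,
    classify_concavity,
    fit_models,
    jackknife_support,
    segment,
    select_best,
    _fit_models_xy,
)
from declinewatch.curvefit import test_decline as run_decline_test
from declinewatch.smoothing import SmoothedTrend
from declinewatch.switchpoints import SwitchPointSet


def _trend(values):
    v = np.asarray(values, dtype=float)
    return SmoothedTrend(np.arange(1, len(v) + 1), v, np.zeros(len(v)), 2.0,
                         len(v) - 1, "gaussian", 0.0)


def _section(values, **kw):
    v = np.asarray(values, dtype=float)
    return DeclineSection(1, len(v), v, fittable=len(v) >= 6, **kw)


def _exp(t, asym, r0, lrc):
    return asym + (r0 - asym) * np.exp(-np.exp(lrc) * t)


class TestSegment:
    def test_no_sps_single_section(self):
        secs = segment(_trend(np.arange(30.0)), SwitchPointSet([], []))
        assert len(secs) == 1
        assert (secs[0].start_year, secs[0].end_year) == (1, 30)

    def test_boundary_years_shared(self):
        secs = segment(_trend(np.arange(30.0)), SwitchPointSet([], [10, 20]))
        assert [(s.start_year, s.end_year) for s in secs] == [(1, 10), (10, 20), (20, 30)]

    def test_short_section_flagged_unfittable(self):
        secs = segment(_trend(np.arange(30.0)), SwitchPointSet([], [3]))
        assert not secs[0].fittable and len(secs[0]) == 3
        assert secs[1].fittable

    def test_truncation_year_respected(self):
        sps = SwitchPointSet([], [10], truncation_year=20)
        secs = segment(_trend(np.arange(30.0)), sps)
        assert secs[-1].end_year == 20


class TestClassifyConcavity:
    def test_exponential_decay_is_concave(self):
        t = np.arange(20.0)
        assert classify_concavity(_section(1000 * np.exp(-0.1 * t))) == "concave"

    def test_quadratic_fall_is_convex(self):
        t = np.arange(20.0)
        assert classify_concavity(_section(1000 - 2 * t**2)) == "convex"

    def test_s_shaped_hump_is_mixed_humped(self):
        t = np.arange(30.0)
        rise = 1 / (1 + np.exp(-(t - 8) / 2.0))
        fall = 1 / (1 + np.exp((t - 20) / 2.0))
        sec = _section(400 + 600 * rise * fall)
        assert classify_concavity(sec) == "mixed"
        assert sec.shape == "humped"

    def test_negation_swaps_labels(self):
        t = np.arange(20.0)
        y = 1000 * np.exp(-0.1 * t)
        assert classify_concavity(_section(y)) == "concave"
        assert classify_concavity(_section(2000 - y)) == "convex"


class TestDeclineTest:
    def test_noiseless_decreasing_line(self):
        sec = _section(np.linspace(1000, 400, 20))
        declining, p = run_decline_test(sec)
        assert declining and p < 1e-6

    def test_constant_not_declining(self):
        declining, p = run_decline_test(_section(np.full(15, 500.0)))
        assert not declining and p == 1.0

    def test_humped_section_rescued_by_declining_tail(self):
        y = np.concatenate([np.linspace(500, 600, 8), np.linspace(590, 300, 12)])
        sec = _section(y)
        classify_concavity(sec)
        assert sec.shape == "humped"
        declining, _ = run_decline_test(sec)
        assert declining

    def test_valley_section_rescued_by_declining_head(self):
        y = np.concatenate([np.linspace(600, 300, 12), np.linspace(310, 380, 8)])
        sec = _section(y)
        classify_concavity(sec)
        assert sec.shape == "valley"
        declining, _ = run_decline_test(sec)
        assert declining

    def test_raw_counts_preferred_over_smooth(self, rng):
        smooth = np.linspace(1000, 995, 20)     # trivially "significant" line
        raw = 1000 + rng.normal(0, 30, 20)      # flat noise: no real decline
        sec = DeclineSection(1, 20, smooth, raw_values=raw)
        declining, _ = run_decline_test(sec)
        assert not declining

    def test_interpolated_years_excluded(self):
        raw = np.full(20, np.nan)
        raw[[0, 9, 19]] = [1000, 701, 398]
        sec = DeclineSection(1, 20, np.linspace(1000, 400, 20), raw_values=raw)
        declining, p = run_decline_test(sec)
        assert declining


class TestFitModels:
    def test_exponential_self_consistency(self):
        t = np.arange(25.0)
        sec = _section(_exp(t, 200.0, 1000.0, -1.6))
        fits = {f.model: f for f in fit_models(sec)}
        e = fits["exponential"]
        assert e.params["Asym"] == pytest.approx(200.0, rel=0.01)
        assert e.params["R0"] == pytest.approx(1000.0, rel=0.01)
        assert e.params["lrc"] == pytest.approx(-1.6, abs=0.02)
        assert e.rss < fits["linear"].rss and e.rss < fits["quadratic"].rss

    def test_exact_line_linear_rss_negligible(self):
        sec = _section(np.linspace(900, 300, 15))
        fits = {f.model: f for f in fit_models(sec)}
        assert fits["linear"].rss < 1e-6
        assert select_best(fits.values(), sec).best_model == "linear"

    def test_aicc_absent_when_undefined(self):
        # n = 5 with the k = 4 models: n - k - 1 = 0, AICc undefined
        fits = {f.model: f for f in _fit_models_xy(np.arange(5.0),
                                                   np.array([9, 7, 6, 4, 3.0]))}
        assert fits["quadratic"].aicc is None
        assert fits["linear"].aicc is not None

    def test_parameter_counts(self):
        sec = _section(np.linspace(900, 300, 15))
        ks = {f.model: f.k for f in fit_models(sec)}
        assert ks["linear"] == 3 and ks["quadratic"] == 4
        assert ks.get("exponential", 4) == 4

    def test_aicc_at_least_aic(self):
        sec = _section(np.linspace(900, 300, 15) + np.sin(np.arange(15)))
        for f in fit_models(sec):
            if f.aicc is not None:
                assert f.aicc >= f.aic

    def test_unfittable_section_rejected(self):
        with pytest.raises(ValueError):
            fit_models(_section([5, 4, 3.0]))


def _fit(model, aicc):
    k = {"linear": 3, "quadratic": 4, "exponential": 4}[model]
    return CurveModelFit(model, {}, 1.0, 30, k, aicc - 1.0, aicc)


class TestSelectBest:
    def test_complex_model_needs_clear_margin(self):
        res = select_best([_fit("linear", 100), _fit("quadratic", 90),
                           _fit("exponential", 97)])
        assert res.best_model == "quadratic"

    def test_simplest_within_four_of_minimum_wins(self):
        res = select_best([_fit("linear", 100), _fit("quadratic", 97),
                           _fit("exponential", 99)])
        assert res.best_model == "linear"

    def test_exponential_must_beat_quadratic(self):
        # equal k: quadratic is the simpler tie-break
        res = select_best([_fit("linear", 120), _fit("quadratic", 101),
                           _fit("exponential", 100)])
        assert res.best_model == "quadratic"
        res = select_best([_fit("linear", 120), _fit("quadratic", 105),
                           _fit("exponential", 100)])
        assert res.best_model == "exponential"

    def test_single_fit_selected(self):
        res = select_best([_fit("quadratic", 50)])
        assert res.best_model == "quadratic"

    def test_aic_fallback_recorded(self):
        f1 = CurveModelFit("linear", {}, 1.0, 5, 3, 10.0, 30.0)
        f2 = CurveModelFit("quadratic", {}, 1.0, 5, 4, 9.0, None)
        res = select_best([f1, f2])
        assert res.selection_rule_used == "aic"

    def test_selection_invariant_to_constant_offset(self):
        t = np.arange(20.0)
        y = _exp(t, 300.0, 900.0, -1.2) + np.sin(t) * 3
        a = select_best(fit_models(_section(y))).best_model
        b = select_best(fit_models(_section(y + 500.0))).best_model
        assert a == b

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


class TestJackknife:
    def test_noiseless_line_full_support(self):
        assert jackknife_support(_section(np.linspace(800, 200, 12))) == 1.0

    def test_support_bounded(self, rng):
        y = np.linspace(800, 200, 15) + rng.normal(0, 30, 15)
        s = jackknife_support(_section(y))
        assert 0.0 <= s <= 1.0

    def test_clean_exponential_high_support(self):
        t = np.arange(30.0)
        r = np.random.default_rng(1)
        y = _exp(t, 200.0, 1000.0, -1.6)
        y = y + r.normal(0, 0.05 * np.ptp(y), 30)
        assert jackknife_support(_section(y)) >= 0.7


class TestAnalyzeSection:
    def test_rising_section_not_classified(self):
        assert analyze_section(_section(np.linspace(200, 900, 15))) is None

    def test_declining_exponential_classified(self):
        t = np.arange(25.0)
        res = analyze_section(_section(_exp(t, 200.0, 1000.0, -1.6)))
        assert res is not None
        assert res.best_model == "exponential"
        assert res.section.resolved_concavity == "concave"
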