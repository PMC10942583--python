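"""AUC computation, circular-shuffle classification, PETHs, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socialphys import (AnalysisParams, SessionTimeline, circular_shift,
                        classify_modulation, compute_auc, compute_peth,
                        movement_confound_check, population_summary)
from socialphys.modulation import ModulationResult


def brute_force_auc(activity, indicator):
    """P(act_in > act_out) + 0.5 P(equal) by exhaustive pair enumeration."""
    pos = activity[indicator]
    neg = activity[~indicator]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize("activity,indicator,expected", [
        ([0.1, 0.2, 0.9, 1.0], [0, 0, 1, 1], 1.0),   # perfect separation
        ([1, 3, 2, 4], [0, 1, 1, 0], 0.5),            # 2 of 4 pairs won
        ([1, 1, 2], [0, 1, 1], 0.75),                 # tie contributes 1/2
    ])
    def test_worked_examples(self, activity, indicator, expected):
        auc = compute_auc(np.array(activity, float), np.array(indicator, bool))
        assert auc == pytest.approx(expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        # integer-valued activity to force ties
        activity = rng.integers(0, 6, n).astype(float)
        indicator = rng.random(n) < 0.4
        if indicator.all() or not indicator.any():
            indicator[0] = True
            indicator[-1] = False
        assert compute_auc(activity, indicator) == pytest.approx(
            brute_force_auc(activity, indicator), abs=1e-12)

    def test_negation_complements(self, rng):
        x = rng.random(150)
        ind = rng.random(150) < 0.3
        ind[0], ind[-1] = True, False
        assert compute_auc(x, ind) + compute_auc(-x, ind) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_auc(np.ones(5), np.ones(5, bool))


class TestCircularShift:
    def test_zero_shift_identity(self, rng):
        x = rng.random(20)
        assert np.array_equal(circular_shift(x, 0), x)

    def test_double_half_shift_identity(self, rng):
        x = rng.random(30)
        assert np.array_equal(circular_shift(circular_shift(x, 15), 15), x)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        x = rng.random(n)
        s = int(rng.integers(0, n))
        assert np.array_equal(np.sort(circular_shift(x, s)), np.sort(x))

    def test_out_of_range_shift_rejected(self):
        with pytest.raises(ValueError):
            circular_shift(np.arange(5), 5)


class TestClassify:
    def test_indicator_as_activity_is_maximally_positive(self, rng):
        ind = np.zeros(3000, bool)
        ind[500:800] = True
        ind[1500:1900] = True
        params = AnalysisParams(n_shuffles=100, min_shift=2.0)
        m = classify_modulation(ind.astype(float), ind, params, rng, 30.0)
        assert m.auc == 1.0 and m.label == "positive"

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(3000)
        ind = np.zeros(3000, bool)
        ind[400:900] = True
        params = AnalysisParams(n_shuffles=200, min_shift=2.0)
        m1 = classify_modulation(x, ind, params, np.random.default_rng(5), 30.0)
        m2 = classify_modulation(np.exp(3 * x) + 1, ind, params,
                                 np.random.default_rng(5), 30.0)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-12)
        assert m1.label == m2.label and m1.p_high == m2.p_high

    def test_low_coverage_flagged_ns(self, rng):
        ind = np.zeros(3000, bool)
        ind[0] = True
        m = classify_modulation(rng.random(3000), ind, AnalysisParams(), rng,
                                30.0)
        assert m.label == "ns" and m.low_coverage

    def test_label_invariants(self):
        with pytest.raises(ValueError):
            ModulationResult("u", "social", 1.2, np.array([]), 0.5, 0.5, "ns")


class TestPeth:
    def test_constant_zscored_input_gives_zero_mean(self, timeline):
        peth = compute_peth(np.zeros(timeline.n_frames), timeline,
                            np.array([10.0, 20.0, 30.0]), (2.0, 4.0))
        assert np.allclose(peth.mean, 0.0)
        assert peth.n_events == 3

    def test_single_event_sem_flagged(self, timeline, rng):
        v = rng.random(timeline.n_frames)
        peth = compute_peth(v, timeline, np.array([30.0]), (1.0, 1.0))
        assert peth.single_event and not peth.sem.any()
        assert np.array_equal(peth.mean, peth.matrix[0])

    def test_window_exiting_session_excluded_and_counted(self, timeline, rng):
        v = rng.random(timeline.n_frames)
        peth = compute_peth(v, timeline, np.array([0.5, 30.0, 59.9]),
                            (2.0, 4.0))
        assert peth.n_events == 1 and peth.n_excluded == 2

    def test_zero_usable_events_raises(self, timeline):
        with pytest.raises(ValueError, match="no events"):
            compute_peth(np.zeros(timeline.n_frames), timeline,
                         np.array([0.1]), (2.0, 4.0))

    def test_step_suppression_recovered_within_smoothing_blur(self):
        """A planted 50% step suppression appears in the PETH with the depth
        and timing of the analytic Gaussian-convolved step."""
        from scipy.ndimage import correlate1d
        from socialphys.preprocess import gaussian_kernel
        tl = SessionTimeline.regular(200.0, 30.0)
        events = np.arange(10.0, 190.0, 10.0)
        rate = np.full(tl.n_frames, 60.0)
        dur_f = int(2.0 * 30)
        for e in events:
            k = int(e * 30)
            rate[k:k + dur_f] *= 0.5
        smoothed = correlate1d(rate, gaussian_kernel(0.1, 1 / 30),
                               mode="reflect")
        peth = compute_peth(smoothed, tl, events, (2.0, 4.0))
        trough = peth.mean.min()
        assert trough == pytest.approx(30.0, rel=0.02)
        in_window = (peth.lags > 0.3) & (peth.lags < 1.7)
        assert np.allclose(peth.mean[in_window], 30.0, rtol=0.02)


class TestPopulationSummary:
    def _results(self, labels, context="social"):
        return [ModulationResult(f"u{i}", context, 0.5, np.array([]), 0.5,
                                 0.5, lab) for i, lab in enumerate(labels)]

    def test_proportions_20_of_99(self):
        labels = ["positive"] * 20 + ["negative"] * 12 + ["ns"] * 67
        out = population_summary(self._results(labels))
        props = out["contexts"]["social"]["proportions"]
        assert props["positive"] == pytest.approx(20 / 99)
        assert round(100 * props["positive"], 1) == 20.2

    def test_disjoint_significant_sets_zero_overlap(self):
        soc = self._results(["positive", "ns", "ns"], "social")
        obj = self._results(["ns", "positive", "ns"], "object")
        out = population_summary(soc + obj)
        assert out["overlap"]["fraction_of_all_units"]["positive"] == 0.0

    def test_counting_matches_bruteforce(self, rng):
        labels = rng.choice(["positive", "negative", "ns"], size=50).tolist()
        out = population_summary(self._results(labels))
        counts = out["contexts"]["social"]["counts"]
        for lab in ("positive", "negative", "ns"):
            assert counts[lab] == sum(1 for x in labels if x == lab)

    def test_mismatched_unit_sets_raise(self):
        soc = self._results(["ns", "ns"], "social")
        obj = self._results(["ns"], "object")
        with pytest.raises(ValueError, match="unit sets differ"):
            population_summary(soc + obj)


class TestMovementConfound:
    def test_independent_events_not_significant(self, rng):
        """A bout-driven unit tested against unrelated movement events should
        be flagged at roughly the nominal rate, not systematically."""
        tl = SessionTimeline.regular(300.0, 30.0)
        v = rng.standard_normal(tl.n_frames)
        n_sig = 0
        for i in range(20):
            ev = rng.integers(100, tl.n_frames - 150, size=15)
            res = movement_confound_check(v, tl, ev, rng, n_shuffles=200)
            n_sig += res.p_value < 0.05
        assert n_sig <= 4  # ~0.05 * 20 plus slack

    def test_speed_driven_unit_detected(self, rng):
        tl = SessionTimeline.regular(300.0, 30.0)
        ev = np.arange(300, tl.n_frames - 300, 450)
        v = np.zeros(tl.n_frames)
        for e in ev:  # strong activity step after each event
            v[e:e + 60] = 3.0
        v += 0.1 * rng.standard_normal(tl.n_frames)
        res = movement_confound_check(v, tl, ev, rng, n_shuffles=500)
        assert res.p_value < 0.01

    def test_too_few_events_skipped(self, timeline, rng):
        res = movement_confound_check(np.zeros(timeline.n_frames), timeline,
                                      np.array([100]), rng)
        assert res.skipped and np.isnan(res.p_value)
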