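import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroassay.calcium import (FluorescenceTrace, PeakCall, active_cell_filter,
                                background_subtract, call_relevant_peaks,
                                event_frequency, find_candidate_peaks,
                                peak_relevance_area, under_curve_area)
from neuroassay.synth import SynthParams, simulate_calcium_cell
from oracles import match_events, naive_candidate_peaks


def _trace(vals, dt=1.0):
    return FluorescenceTrace(np.asarray(vals, float), dt=dt,
                             background_subtracted=True)


class TestBackgroundSubtract:
    def test_zero_background_sets_flag(self):
        tr = FluorescenceTrace(np.array([1.0, 2.0, 3.0]))
        out = background_subtract(tr, 0.0)
        np.testing.assert_array_equal(out.values, tr.values)
        assert out.background_subtracted and not tr.background_subtracted

    def test_scalar(self):
        out = background_subtract(FluorescenceTrace(np.array([5.0, 6.0, 5.0])), 5.0)
        np.testing.assert_array_equal(out.values, [0.0, 1.0, 0.0])

    def test_sequence_equal_to_trace_zeroes(self):
        vals = np.array([2.0, 4.0, 8.0])
        out = background_subtract(FluorescenceTrace(vals), vals)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            background_subtract(FluorescenceTrace(np.zeros(5)), np.zeros(4))


class TestCandidatePeaks:
    def test_worked_example(self, worked_trace):
        assert find_candidate_peaks(worked_trace) == [(1, 3, 5)]

    def test_monotone_increasing_empty(self):
        assert find_candidate_peaks(_trace(np.arange(10))) == []

    def test_two_separated_pulses(self):
        tr = _trace([0, 1, 2, 1, 0, 0, 0, 1, 3, 1, 0])
        triples = find_candidate_peaks(tr)
        assert len(triples) == 2
        assert triples == naive_candidate_peaks(tr.values)

    def test_plateau_collapses_to_midpoint(self):
        tr = _trace([0, 1, 2, 2, 2, 1, 0])
        assert find_candidate_peaks(tr) == [(0, 3, 6)]
        tr = _trace([0, 1, 2, 2, 1, 0])  # even plateau: left of center
        assert find_candidate_peaks(tr) == [(0, 2, 5)]

    def test_equal_step_terminates_flank(self):
        # strict descent: the 1,1 step stops the left flank at index 2
        tr = _trace([0, 1, 1, 3, 0])
        assert find_candidate_peaks(tr) == [(2, 3, 4)]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            find_candidate_peaks(_trace([0, 1]))

    def test_warns_without_background_flag(self):
        tr = FluorescenceTrace(np.array([0.0, 1.0, 0.0]))
        with pytest.warns(UserWarning, match="background"):
            find_candidate_peaks(tr)

    @settings(max_examples=150, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=3, max_size=40))
    def test_matches_naive_on_integer_traces(self, vals):
        # integer plateaus exercise the plateau-collapse rule heavily
        assert find_candidate_peaks(_trace(vals)) == naive_candidate_peaks(vals)

    def test_matches_naive_on_random_floats(self, rng):
        for _ in range(200):
            vals = rng.normal(size=rng.integers(3, 80))
            assert find_candidate_peaks(_trace(vals)) == naive_candidate_peaks(vals)


class TestRelevanceArea:
    def test_worked_example(self, worked_trace):
        assert peak_relevance_area(worked_trace, (1, 3, 5)) == pytest.approx(6.0)

    def test_collinear_zero(self):
        tr = _trace([1.0, 1.0, 1.0, 1.0])
        assert peak_relevance_area(tr, (0, 1, 3)) == pytest.approx(0.0)

    def test_dt_scaling(self, worked_trace):
        doubled = _trace(worked_trace.values, dt=2.0)
        assert peak_relevance_area(doubled, (1, 3, 5)) == pytest.approx(12.0)

    def test_offset_and_shift_invariance(self, rng):
        vals = np.array([0.0, 0.2, 2.5, 0.7, 0.1])
        a = peak_relevance_area(_trace(vals), (0, 2, 4))
        b = peak_relevance_area(_trace(vals + 100.0), (0, 2, 4))
        assert a == pytest.approx(b)
        padded = np.concatenate([np.full(5, 50.0), vals + 100.0])
        c = peak_relevance_area(_trace(padded), (5, 7, 9))
        assert a == pytest.approx(c)

    def test_non_negative_random(self, rng):
        for _ in range(100):
            vals = rng.normal(size=30)
            tr = _trace(vals)
            for triple in find_candidate_peaks(tr):
                assert peak_relevance_area(tr, triple) >= 0.0

    def test_invalid_triple_rejected(self, worked_trace):
        with pytest.raises(ValueError):
            peak_relevance_area(worked_trace, (3, 3, 5))

    def test_under_curve_alternative(self):
        tr = _trace([0, 3, 0])
        assert under_curve_area(tr, (0, 1, 2)) == pytest.approx(3.0)


class TestRelevanceRules:
    def test_literal_rule_worked_example(self, worked_trace):
        calls = call_relevant_peaks(worked_trace, rule="literal")
        assert len(calls) == 1
        c = calls[0]
        mean, sd = np.mean(worked_trace.values), np.std(worked_trace.values)
        assert mean + sd == pytest.approx(1.7437, abs=1e-3)
        assert c.relevance_area == pytest.approx(6.0)
        assert c.is_relevant

    def test_constant_trace_no_calls(self):
        assert call_relevant_peaks(_trace(np.ones(10))) == []

    def test_peak_population_rule_single_peak_never_relevant(self, worked_trace):
        calls = call_relevant_peaks(worked_trace, rule="peak_population")
        assert len(calls) == 1 and not calls[0].is_relevant

    def test_sd_multiplier_monotonicity(self, rng):
        p = SynthParams(seed=21, ca_event_rate_control=3.0, ca_noise_sd=0.4,
                        ca_baseline=0.0)
        tr, _ = simulate_calcium_cell(p, "control")
        tr.background_subtracted = True
        counts = [sum(c.is_relevant for c in
                      call_relevant_peaks(tr, sd_multiplier=m))
                  for m in (0.25, 0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_unknown_rule_rejected(self, worked_trace):
        with pytest.raises(ValueError):
            call_relevant_peaks(worked_trace, rule="nope")

    def test_warns_for_nonunit_dt_under_literal_rule(self):
        tr = _trace([0, 0, 1, 3, 1, 0, 0], dt=0.5)
        with pytest.warns(UserWarning, match="dt"):
            call_relevant_peaks(tr, rule="literal")


class TestEventFrequency:
    def _call(self, relevant):
        return PeakCall(peak_index=2, left_min_index=1, right_min_index=3,
                        amplitude=1.0, relevance_area=1.0, is_relevant=relevant)

    def test_zero_events(self):
        r = event_frequency([], 600.0)
        assert r.frequency_per_min == 0.0 and not r.active

    def test_twelve_events_in_ten_minutes(self):
        calls = [self._call(True)] * 12 + [self._call(False)] * 3
        r = event_frequency(calls, 600.0)
        assert r.frequency_per_min == pytest.approx(1.2)
        assert r.n_relevant_events == 12 and r.active

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            event_frequency([], 0.0)

    def test_rate_recovery_on_synthetic(self):
        # amplitude/noise = 10, rate 2/min: called rate within 10% on average
        freqs = []
        for seed in range(40):
            p = SynthParams(seed=seed, ca_event_rate_control=2.0,
                            ca_amplitude=5.0, ca_noise_sd=0.5)
            tr, gt = simulate_calcium_cell(p, "control")
            tr.background_subtracted = True
            calls = call_relevant_peaks(tr)
            freqs.append(event_frequency(calls, tr.duration_s).frequency_per_min)
        assert np.mean(freqs) == pytest.approx(2.0, rel=0.10)

    def test_event_times_recovered(self):
        p = SynthParams(seed=4, ca_event_rate_control=1.5, ca_amplitude=6.0,
                        ca_noise_sd=0.3)
        tr, gt = simulate_calcium_cell(p, "control")
        tr.background_subtracted = True
        calls = [c for c in call_relevant_peaks(tr) if c.is_relevant]
        det = np.array([c.peak_index * tr.dt for c in calls])
        tp, fp, fn = match_events(gt.ca_event_times["roi_0"], det, tol_s=2.0)
        truth_n = gt.ca_event_times["roi_0"].size
        assert tp >= 0.8 * truth_n


class TestActiveCellFilter:
    def _res(self, n):
        return event_frequency([PeakCall(2, 1, 3, 1.0, 1.0, True)] * n, 600.0)

    def test_all_inactive_empty(self):
        assert active_cell_filter([self._res(0), self._res(0)]) == []

    def test_mixed(self):
        results = [self._res(0), self._res(2), self._res(1)]
        kept = active_cell_filter(results)
        assert [r.n_relevant_events for r in kept] == [2, 1]

    def test_idempotent(self):
        results = [self._res(0), self._res(3)]
        once = active_cell_filter(results)
        assert active_cell_filter(once) == once
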