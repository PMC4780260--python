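"""Responder rule, multiunit thresholding, oximetry QC."""

import numpy as np
import pytest

from mazephys.evoked import (
    PhysioTrace,
    Sweep,
    detect_evoked_response,
    detect_multiunit_events,
    qc_physiology,
)
from mazephys.simulate import simulate_oximetry, simulate_sweeps


class TestEvokedResponse:
    def test_pure_noise_not_a_responder(self):
        sweeps = simulate_sweeps(10, 0.0, noise_sd=2.0, rng=0)
        assert not detect_evoked_response(sweeps).is_responder

    def test_injected_peak_detected_with_latency(self):
        sweeps = simulate_sweeps(
            10, 20.0, peak_latency=0.020, noise_sd=2.0, rng=1
        )
        res = detect_evoked_response(sweeps)
        assert res.is_responder
        assert res.peak_latency_ms == pytest.approx(20.0, abs=2.0)

    def test_late_peak_outside_window_rejected(self):
        sweeps = simulate_sweeps(
            10, 20.0, peak_latency=0.060, noise_sd=2.0, rng=2
        )
        assert not detect_evoked_response(sweeps).is_responder

    def test_negative_going_current_detected(self):
        sweeps = simulate_sweeps(
            10, -20.0, peak_latency=0.020, noise_sd=2.0, rng=3
        )
        res = detect_evoked_response(sweeps)
        assert res.is_responder
        assert res.peak_amplitude < 0

    def test_constant_offset_invariance(self):
        sweeps = simulate_sweeps(8, 15.0, noise_sd=2.0, rng=4)
        shifted = [
            Sweep(
                s.samples + 123.4,
                s.sampling_rate,
                s.pulse_onset,
                s.baseline_window,
            )
            for s in sweeps
        ]
        a = detect_evoked_response(sweeps)
        b = detect_evoked_response(shifted)
        assert a.peak_amplitude == pytest.approx(b.peak_amplitude)
        assert a.is_responder == b.is_responder

    def test_mismatched_sweep_lengths_rejected(self):
        good = simulate_sweeps(3, 0.0, rng=5)
        bad = Sweep(
            good[0].samples[:-10],
            good[0].sampling_rate,
            good[0].pulse_onset,
            good[0].baseline_window,
        )
        with pytest.raises(ValueError):
            detect_evoked_response(good + [bad])

    def test_sweep_count_outside_intended_range_warns(self):
        sweeps = simulate_sweeps(3, 0.0, rng=6)
        with pytest.warns(UserWarning):
            detect_evoked_response(sweeps)


def _baseline_trace(rng, n=10_000):
    # bounded noise: s.d. ~0.577, so the trace itself never crosses 3 s.d.
    return rng.uniform(-1.0, 1.0, n)


class TestMultiunit:
    FS = 30_000.0

    def test_no_events_on_spikeless_trace(self):
        rng = np.random.default_rng(0)
        trace = _baseline_trace(rng)
        events = detect_multiunit_events(trace, self.FS, (0.0, 0.1))
        assert events.size == 0

    def test_zero_variance_baseline_rejected(self):
        with pytest.raises(ValueError):
            detect_multiunit_events(np.zeros(1000), self.FS, (0.0, 0.01))

    def test_single_injected_spikelet_one_event(self):
        rng = np.random.default_rng(1)
        trace = _baseline_trace(rng)
        k = 6000
        trace[k : k + 6] += 6.0  # spikelet well above 3 s.d., 0.2 ms wide
        events = detect_multiunit_events(trace, self.FS, (0.0, 0.1))
        assert events.size == 1
        assert events[0] == pytest.approx(k / self.FS, abs=2e-4)

    def test_dead_time_merges_close_spikelets(self):
        rng = np.random.default_rng(2)
        trace = _baseline_trace(rng)
        k = 6000
        gap = int(0.0005 * self.FS)  # 0.5 ms apart
        trace[k : k + 3] += 6.0
        trace[k + gap : k + gap + 3] += 6.0
        events = detect_multiunit_events(trace, self.FS, (0.0, 0.1))
        assert events.size == 1

    def test_separated_spikelets_two_events(self):
        rng = np.random.default_rng(3)
        trace = _baseline_trace(rng)
        k = 6000
        gap = int(0.002 * self.FS)  # 2 ms apart
        trace[k : k + 3] += 6.0
        trace[k + gap : k + gap + 3] += 6.0
        events = detect_multiunit_events(trace, self.FS, (0.0, 0.1))
        assert events.size == 2

    def test_negative_polarity(self):
        rng = np.random.default_rng(4)
        trace = _baseline_trace(rng)
        trace[7000:7003] -= 6.0
        down = detect_multiunit_events(
            trace, self.FS, (0.0, 0.1), polarity="negative"
        )
        up = detect_multiunit_events(
            trace, self.FS, (0.0, 0.1), polarity="positive"
        )
        assert down.size == 1
        assert up.size == 0


class TestPhysioQC:
    def test_constant_error_free_included_and_unchanged(self):
        trace = PhysioTrace(
            np.full(60, 200.0), np.zeros(60, dtype=bool), "respiratory"
        )
        qc = qc_physiology(trace)
        assert qc.included
        assert qc.smoothed == pytest.approx(200.0)
        assert qc.full_window[9:].all() and not qc.full_window[:9].any()

    def test_session_below_thirty_percent_excluded(self):
        flags = np.ones(100, dtype=bool)
        flags[:25] = False  # 25% error-free
        qc = qc_physiology(PhysioTrace(np.full(100, 200.0), flags, "heart"))
        assert not qc.included
        assert qc.error_free_fraction == pytest.approx(0.25)

    def test_session_at_thirty_percent_included(self):
        flags = np.ones(100, dtype=bool)
        flags[:30] = False
        qc = qc_physiology(PhysioTrace(np.full(100, 200.0), flags, "heart"))
        assert qc.included

    def test_alternating_values_average_to_midpoint(self):
        vals = np.tile([180.0, 220.0], 10)
        qc = qc_physiology(
            PhysioTrace(vals, np.zeros(20, dtype=bool), "respiratory")
        )
        assert qc.smoothed[qc.full_window] == pytest.approx(200.0)

    def test_hand_computed_heart_window(self):
        vals = np.array([100.0, 110.0, 120.0, 130.0, 140.0, 150.0])
        qc = qc_physiology(PhysioTrace(vals, np.zeros(6, bool), "heart"))
        assert qc.smoothed[4] == pytest.approx(120.0)  # mean of first five
        assert qc.smoothed[5] == pytest.approx(130.0)
        assert list(qc.smoothed[:4]) == list(vals[:4])  # passthrough, flagged
        assert not qc.full_window[:4].any()

    def test_errors_removed_before_smoothing(self):
        vals = np.array([200.0, 999.0, 200.0, 200.0, 200.0, 200.0])
        flags = np.array([False, True, False, False, False, False])
        qc = qc_physiology(PhysioTrace(vals, flags, "heart"))
        assert qc.clean_values.size == 5
        assert qc.smoothed[-1] == pytest.approx(200.0)

    def test_simulated_clean_stream_passes(self):
        trace = simulate_oximetry(300.0, error_fraction=0.05, rng=1)
        qc = qc_physiology(trace)
        assert qc.included
        # trailing average preserves the mean of the error-free samples
        assert qc.smoothed[qc.full_window].mean() == pytest.approx(
            qc.clean_values.mean(), rel=0.05
        )
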