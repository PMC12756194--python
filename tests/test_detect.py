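"""Spike thresholding, telegraph segmentation and class merging."""

import numpy as np
import pytest

from biovolt import (
    FAST_SPIKE,
    RTS_STEP,
    DetectionConfig,
    EventRecord,
    RtsParams,
    default_schedule,
    detect_spikes,
    merge_and_classify,
    generate_rts,
    segment_rts,
    synthesize_schedule,
)
from biovolt.errors import ParameterError
from biovolt.pipeline import analyze_trace
from oracles import brute_force_spike_scan, dwell_spans, match_events


class TestDetectSpikes:
    def test_noise_free_recovery(self, pulse):
        """Seven rendered 20 µV pulses on a silent trace: all recovered."""
        fs = 2000.0
        n = int(10 * fs)
        x = np.zeros(n)
        for k in range(7):
            x += pulse(n, fs, 1.0 + k, 20.0, 5.0)
        events = detect_spikes(x, fs, sigma=1.0)
        assert len(events) == 7
        for e in events:
            assert e.peak_amp_uv == pytest.approx(20.0, abs=0.5)
            assert e.event_class == FAST_SPIKE

    def test_empty_trace(self):
        assert detect_spikes(np.zeros(0), 1000.0, 1.0) == []

    def test_non_finite_rejected(self):
        x = np.zeros(100)
        x[10] = np.nan
        with pytest.raises(ParameterError, match="finite"):
            detect_spikes(x, 1000.0, 1.0)

    def test_matches_brute_force_scan(self, rng):
        """Exact agreement with a sample-by-sample loop on random traces."""
        cfg = DetectionConfig()
        for _ in range(20):
            fs = float(rng.choice([500.0, 1000.0, 2000.0]))
            n = int(rng.integers(2000, 10_000))
            x = rng.normal(0, 1.0, n)
            for _ in range(int(rng.integers(0, 6))):
                c = int(rng.integers(50, n - 50))
                x[c - 10:c + 10] += rng.uniform(8, 30)
            ours = detect_spikes(x, fs, 1.0, cfg)
            ref = brute_force_spike_scan(x, fs, 1.0, cfg.k_sigma, cfg.refractory_ms)
            assert [(e.onset_s, e.peak_amp_uv, e.duration_s) for e in ours] == [
                pytest.approx(r) for r in ref]

    def test_threshold_monotonicity(self, rng):
        """Raising k_sigma never increases the number of detections."""
        x = rng.normal(0, 1.0, 20_000)
        x[5000:5010] += 12.0
        counts = [len(detect_spikes(x, 1000.0, 1.0, DetectionConfig(k_sigma=k)))
                  for k in (3.0, 4.0, 5.0, 6.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_refractory_merges_split_excursion(self):
        fs = 1000.0
        x = np.zeros(5000)
        x[1000:1005] = 10.0
        x[1010:1015] = 8.0  # 5 ms gap < 20 ms refractory
        events = detect_spikes(x, fs, 1.0)
        assert len(events) == 1
        assert events[0].peak_amp_uv == 10.0


class TestSegmentRts:
    def test_noise_free_telegraph_exact(self):
        """12 deterministic dwells recovered with sample-exact transitions."""
        fs = 100.0
        period = int(4 * fs)
        n = 12 * period
        state_true = ((np.arange(n) % period) >= period // 2).astype(float)
        seg = segment_rts(6.0 * state_true, fs)
        assert not seg.no_rts
        assert len(seg.events) == 12
        assert seg.separation_uv == pytest.approx(6.0, abs=1e-6)
        for k, e in enumerate(seg.events):
            assert e.onset_s == pytest.approx((k * 4) + 2.0, abs=1 / fs)
            assert e.duration_s == pytest.approx(2.0, abs=2 / fs)

    def test_noisy_telegraph_recovery(self):
        """Exponential dwells, step/noise = 6: representable dwells recovered."""
        fs = 500.0
        recovered = total = 0
        for seed in range(5):
            sig, state = generate_rts(300.0, fs, RtsParams(0.5, 0.5, 6.0), seed)
            noisy = sig + np.random.default_rng(1000 + seed).normal(0, 1.0, sig.size)
            seg = segment_rts(noisy, fs)
            det = [(e.onset_s, e.duration_s) for e in seg.events]
            highs = dwell_spans(state, fs, 1)
            lows = dwell_spans(state, fs, 0)
            low_end = {round((o + d) * fs): d for o, d in lows}
            low_start = {round(o * fs): d for o, d in lows}
            t_end = state.size / fs
            for onset, dur in highs:
                if onset == 0 or onset + dur >= t_end - 1 / fs:
                    continue  # censored at a trace boundary
                left = low_end.get(round(onset * fs), 0.0)
                right = low_start.get(round((onset + dur) * fs), 0.0)
                # representable: own dwell and both flanking gaps >= min dwell
                if dur < 0.5 or left < 0.5 or right < 0.5:
                    continue
                total += 1
                ok = any(abs(o - onset) < 0.25 and abs(d - dur) < 0.10 * dur
                         for o, d in det)
                recovered += ok
            assert seg.separation_uv == pytest.approx(6.0, rel=0.15)
        assert total > 50
        assert recovered / total >= 0.95

    def test_flat_noise_only_flagged(self, rng):
        x = rng.normal(0, 1.0, 20_000)
        seg = segment_rts(x, 1000.0)
        assert seg.no_rts and seg.events == []
        assert np.all(seg.state == 0)

    def test_too_short_rejected(self):
        with pytest.raises(ParameterError, match="shorter"):
            segment_rts(np.zeros(100), 1000.0)


class TestMergeAndClassify:
    def test_disjoint_concatenation_sorted(self):
        spikes = [EventRecord(1.0, 10.0, 0.005, FAST_SPIKE),
                  EventRecord(9.0, 12.0, 0.005, FAST_SPIKE)]
        rts = [EventRecord(4.0, 6.0, 2.0, RTS_STEP)]
        out = merge_and_classify(spikes, rts)
        assert [e.onset_s for e in out] == [1.0, 4.0, 9.0]

    def test_spike_inside_dwell_stays_fast(self):
        spikes = [EventRecord(5.0, 10.0, 0.005, FAST_SPIKE)]
        rts = [EventRecord(4.0, 6.0, 2.0, RTS_STEP)]
        out = merge_and_classify(spikes, rts)
        assert sum(e.event_class == FAST_SPIKE for e in out) == 1

    def test_step_edge_transient_removed(self):
        # a detection centred on a dwell edge is the step's own transient
        spikes = [EventRecord(3.98, 5.0, 0.05, FAST_SPIKE)]
        rts = [EventRecord(4.0, 6.0, 2.0, RTS_STEP)]
        out = merge_and_classify(spikes, rts)
        assert [e.event_class for e in out] == [RTS_STEP]

    def test_long_detection_inside_dwell_reclassified(self):
        spikes = [EventRecord(4.9, 6.0, 0.2, FAST_SPIKE)]
        rts = [EventRecord(4.0, 6.0, 2.0, RTS_STEP)]
        out = merge_and_classify(spikes, rts)
        assert all(e.event_class == RTS_STEP for e in out)

    def test_unsorted_inputs_rejected(self):
        from biovolt.errors import UnsortedEventsError
        bad = [EventRecord(2.0, 5.0, 0.005, FAST_SPIKE),
               EventRecord(1.0, 5.0, 0.005, FAST_SPIKE)]
        with pytest.raises(UnsortedEventsError):
            merge_and_classify(bad, [])


class TestEndToEndFidelity:
    def test_fast_spike_f1_on_peak_day(self):
        """Detection vs ground truth on the busiest starvation day: F1 >= 0.9."""
        sched = default_schedule(600.0)
        day4 = [c for c in sched if c.label == "-Nd4"]
        from biovolt import ConditionSchedule
        f1s = []
        for seed in range(8):
            (trace, truth), = synthesize_schedule(
                ConditionSchedule(tuple(day4)), 2000.0, seed)
            analysis = analyze_trace(trace)
            true_onsets = [e.onset_s for e in truth.events
                           if e.event_class == FAST_SPIKE]
            det_onsets = [e.onset_s for e in analysis.spike_events]
            m = match_events(true_onsets, det_onsets, tol_s=0.025)
            prec = m / max(len(det_onsets), 1)
            rec = m / max(len(true_onsets), 1)
            f1s.append(2 * prec * rec / max(prec + rec, 1e-12))
        assert np.mean(f1s) >= 0.9

    def test_noise_free_amplitude_fidelity(self):
        """Rendered events on a noise-free trace: < 3% amplitude error."""
        from biovolt import Condition, NoiseParams, SpikeParams, TraceMeta, VoltageTrace
        from biovolt.simulate import generate_spikes

        fs = 2000.0
        sig, truth = generate_spikes(120.0, fs, SpikeParams(20.0, 10.0, 0.3), seed=3)
        events = detect_spikes(sig + 0.0, fs, sigma=0.1)
        # compare per-event amplitudes for isolated events
        det = sorted(events, key=lambda e: e.onset_s)
        matched = 0
        for te in truth:
            cands = [d for d in det if abs(d.onset_s - te.onset_s) < 0.01]
            if len(cands) == 1:
                assert cands[0].peak_amp_uv == pytest.approx(te.peak_amp_uv, rel=0.03)
                matched += 1
        assert matched >= 0.8 * len(truth)
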