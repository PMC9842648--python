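"""Lead-seizure rule, analysis windows, filters, artifact detection,
segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from preictal_scout.preprocess import (BadSegmentParams, EEGRecord,
                                       SeizureEvent, SeizureRoster,
                                       build_analysis_window,
                                       detect_bad_segments, filter_signal,
                                       segment_and_rereference,
                                       select_lead_seizures)

H = 3600.0


def roster_from_gaps(gaps_h, dur_s=120.0):
    events, t = [], 0.0
    for i, g in enumerate([0.0] + list(gaps_h)):
        t += g * H
        events.append(SeizureEvent(i + 1, t, t + dur_s))
        t += dur_s
    return SeizureRoster(events)


class TestLeadSeizures:
    def test_hand_applied_gap_rule(self):
        roster = roster_from_gaps([5.0, 3.0, 6.0])
        kept = select_lead_seizures(roster)
        assert [e.seizure_id for e in kept] == [1, 2, 4]

    def test_empty_roster(self):
        assert len(select_lead_seizures(SeizureRoster([]))) == 0

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.1, 20.0), min_size=0, max_size=8))
    def test_idempotent(self, gaps):
        roster = roster_from_gaps(gaps)
        once = select_lead_seizures(roster)
        twice = select_lead_seizures(once)
        assert [e.seizure_id for e in once] == [e.seizure_id for e in twice]


class TestAnalysisWindow:
    def test_isolated_seizure_effective_duration(self):
        roster = roster_from_gaps([20.0])
        w = build_analysis_window(roster[1], roster)
        assert w.excluded_intervals == []
        assert w.effective_duration_hours == pytest.approx(4.3333, abs=1e-3)
        assert f"{w.effective_duration_hours:.2f}" == "4.33"

    def test_previous_offset_exactly_at_window_edge(self):
        # previous offset exactly 4.5 h before onset: postictal overlap
        # [-4.5 h, -4.0 h] plus the SPH leave 3.8333 h
        prev = SeizureEvent(1, 0.0, 100.0)
        cur = SeizureEvent(2, 100.0 + 4.5 * H, 100.0 + 4.5 * H + 60)
        roster = SeizureRoster([prev, cur])
        w = build_analysis_window(cur, roster)
        assert len(w.excluded_intervals) == 1
        a, b = w.excluded_intervals[0]
        assert (b - a) == pytest.approx(1800.0)
        assert w.effective_duration_hours == pytest.approx(3.8333, abs=1e-3)

    def test_previous_onset_inside_window_rejected(self):
        prev = SeizureEvent(1, 0.0, 100.0)
        cur = SeizureEvent(2, 4.2 * H, 4.2 * H + 60)
        roster = SeizureRoster([prev, cur])
        with pytest.raises(ValueError):
            build_analysis_window(cur, roster)


def sine_record(freq, fs=256.0, dur=120.0, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return EEGRecord(x, fs, [f"C{i}" for i in range(n_ch)])


def _steady_rms(x, fs):
    # drop 10 s on both ends to avoid filter edge transients
    pad = int(10 * fs)
    return np.sqrt(np.mean(x[:, pad:-pad] ** 2))


class TestFiltering:
    def test_passband_10hz_unity(self):
        rec = sine_record(10.0)
        out = filter_signal(rec)
        ratio = _steady_rms(out.signal, rec.fs) / _steady_rms(rec.signal, rec.fs)
        assert abs(20 * np.log10(ratio)) < 1.0  # within +/- 1 dB

    def test_notch_attenuates_50hz(self):
        rec = sine_record(50.0)
        out = filter_signal(rec)
        ratio = _steady_rms(out.signal, rec.fs) / _steady_rms(rec.signal, rec.fs)
        assert 20 * np.log10(ratio) < -20.0

    def test_highpass_attenuates_slow_drift(self):
        rec = sine_record(0.05, dur=240.0)
        out = filter_signal(rec)
        ratio = _steady_rms(out.signal, rec.fs) / _steady_rms(rec.signal, rec.fs)
        assert 20 * np.log10(ratio) < -20.0

    def test_linearity(self, rng):
        x = rng.normal(size=(3, 2560))
        rec = EEGRecord(x, 256.0, ["a", "b", "c"])
        rec5 = EEGRecord(5.0 * x, 256.0, ["a", "b", "c"])
        np.testing.assert_allclose(filter_signal(rec5).signal,
                                   5.0 * filter_signal(rec).signal,
                                   rtol=1e-9, atol=1e-9)

    def test_low_fs_rejected(self):
        rec = EEGRecord(np.zeros((1, 100)), 128.0, ["a"])
        with pytest.raises(ValueError):
            filter_signal(rec)


class TestBadSegments:
    def test_flatline_flagged(self, rng):
        x = rng.normal(scale=20, size=(2, 256 * 60))
        x[:, 256 * 20:256 * 25] = 3.14  # 5 s constant
        rec = EEGRecord(x, 256.0, ["a", "b"])
        mask = detect_bad_segments(rec)
        assert mask[256 * 21:256 * 24].all()

    def test_saturation_flagged(self, rng):
        x = rng.normal(scale=20, size=(2, 256 * 60))
        x[0, 256 * 30:256 * 32] = 500.0  # 2 s at the rail
        # add drift so the clipped stretch is not also a flatline-only call
        rec = EEGRecord(x, 256.0, ["a", "b"])
        mask = detect_bad_segments(rec, BadSegmentParams(flat_eps=0.0))
        assert mask[int(256 * 30.5):int(256 * 31.5)].all()

    def test_clean_noise_low_false_positive(self):
        fracs = []
        for seed in range(10):
            x = np.random.default_rng(seed).normal(scale=20,
                                                   size=(4, 256 * 120))
            mask = detect_bad_segments(EEGRecord(x, 256.0, list("abcd")))
            fracs.append(mask.mean())
        assert np.mean(fracs) < 0.01


class TestSegmentation:
    def test_27_segments_for_4p5_hours(self):
        fs = 4.0  # light-weight stand-in rate; segmentation is rate-agnostic
        rec = EEGRecord(np.zeros((2, int(4.5 * H * fs))), fs, ["a", "b"])
        segs = segment_and_rereference(rec)
        assert len(segs) == 27
        assert not any(s.partial for s in segs)

    def test_average_reference_zero_mean(self, rng):
        rec = EEGRecord(rng.normal(size=(5, 256 * 60)), 256.0, list("abcde"))
        segs = segment_and_rereference(rec)
        for s in segs:
            assert np.abs(s.signal.mean(axis=0)).max() < 1e-10

    def test_partial_trailing_segment_flagged(self):
        fs = 4.0
        rec = EEGRecord(np.zeros((1, int(25 * 60 * fs))), fs, ["a"])
        segs = segment_and_rereference(rec)
        assert [s.signal.shape[1] / fs / 60 for s in segs] == [10, 10, 5]
        assert [s.partial for s in segs] == [False, False, True]
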