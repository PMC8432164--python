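import math

import numpy as np
import pytest

from gabawindow.sniffer import (ChannelEvent, ChannelEventList, HillCalibration,
                                SingleChannelTrace, detect_openings,
                                estimate_gaba, fit_hill, lowpass_filter,
                                open_fraction_timecourse, open_time_fraction,
                                read_trace)
from gabawindow.synthetic_data import (ChannelGenParams, gen_channel_trace,
                                       true_open_fraction)

RATE = 10_000.0


def _trace(current, **kw):
    kw.setdefault("baseline", 0.0)
    return SingleChannelTrace(np.asarray(current, dtype=float), rate=RATE, **kw)


class TestLowpass:
    def test_dc_trace_unchanged(self):
        t = _trace(np.full(4000, 1.7))
        f = lowpass_filter(t, 1000.0)
        assert np.allclose(f.current, 1.7, atol=1e-9)
        assert len(f.current) == 4000

    def test_3khz_tone_attenuated_over_20db(self):
        tt = np.arange(20000) / RATE
        tone = np.sin(2 * np.pi * 3000 * tt)
        out = lowpass_filter(_trace(tone), 1000.0).current
        # compare RMS in the settled interior
        ratio = np.std(out[2000:-2000]) / np.std(tone[2000:-2000])
        assert ratio < 0.1  # >20 dB

    def test_idempotent_for_low_frequencies(self):
        tt = np.arange(20000) / RATE
        slow = np.sin(2 * np.pi * 100 * tt)
        once = lowpass_filter(_trace(slow), 1000.0).current
        twice = lowpass_filter(lowpass_filter(_trace(slow), 1000.0), 1000.0).current
        assert np.max(np.abs(once - twice)[2000:-2000]) < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(_trace(np.zeros(100)), 6000.0)


class TestDetectOpenings:
    def test_constructed_opening_detected_with_exact_duration(self):
        x = np.zeros(10000)
        x[5000:5010] = 2.0          # 1.0 ms at 2 pA
        ev = detect_openings(_trace(x), threshold=1.5, min_duration=0.2,
                             unitary_amp=2.0)
        assert len(ev) == 1
        assert ev.events[0].duration == pytest.approx(1.0)
        assert ev.events[0].level == 1

    def test_brief_opening_below_min_duration_discarded(self):
        x = np.zeros(10000)
        x[5000] = 2.0               # 0.1 ms
        ev = detect_openings(_trace(x), min_duration=0.2, unitary_amp=2.0)
        assert len(ev) == 0

    def test_double_amplitude_counts_two_channels(self):
        x = np.zeros(10000)
        x[100:110] = 4.0
        ev = detect_openings(_trace(x), unitary_amp=2.0)
        assert ev.events[0].level == 2

    def test_bad_unitary_amplitude_rejected(self):
        with pytest.raises(ValueError):
            detect_openings(_trace(np.zeros(100)), unitary_amp=0.0)

    def test_recall_and_duration_on_generated_trace(self):
        """Every isolated >=1 ms true opening is recovered, with sub-sample
        median duration error at the half-amplitude threshold."""
        p = ChannelGenParams(alpha=2.0, beta=100.0, duration=30.0, seed=77)
        trace, truth = gen_channel_trace(p)
        filt = lowpass_filter(trace, 1000.0)
        ev = detect_openings(filt, threshold=1.0, min_duration=0.2,
                             unitary_amp=2.0)
        starts = np.array([e.start for e in ev.events])
        tr = sorted(truth.events, key=lambda e: e.start)
        errs = []
        for i, te in enumerate(tr):
            if te.duration < 1.0:
                continue
            prev_end = tr[i - 1].start + tr[i - 1].duration if i else -1e9
            nxt = tr[i + 1].start if i + 1 < len(tr) else 1e18
            if te.start - prev_end < 2.0 or nxt - (te.start + te.duration) < 2.0:
                continue  # only isolated events have well-defined durations
            k = int(np.argmin(np.abs(starts - te.start)))
            assert abs(starts[k] - te.start) < 0.5   # recall
            errs.append(abs(ev.events[k].duration - te.duration))
        assert len(errs) > 30
        assert np.median(errs) <= 0.1   # one sample at 10 kHz
        assert max(errs) < 0.35         # rasterization quantization bound


class TestOpenTimeFraction:
    def test_no_events_zero(self):
        assert open_time_fraction(ChannelEventList([], t_f=1.0)) == 0.0

    def test_single_event_fraction(self):
        ev = ChannelEventList([ChannelEvent(0.0, 100.0, 1)], t_f=1.0)
        assert open_time_fraction(ev) == pytest.approx(0.1)

    def test_two_channels_open_throughout_exceeds_one(self):
        ev = ChannelEventList([ChannelEvent(0.0, 1000.0, 1),
                               ChannelEvent(0.0, 1000.0, 1)], t_f=1.0)
        assert open_time_fraction(ev) == pytest.approx(2.0)

    def test_level_weighting(self):
        ev = ChannelEventList([ChannelEvent(0.0, 100.0, 3)], t_f=1.0)
        assert open_time_fraction(ev) == pytest.approx(0.3)


class TestTimecourse:
    def test_stationary_channel_flat_series(self):
        p = ChannelGenParams(alpha=25.0, beta=100.0, duration=30.0, seed=5)
        trace, truth = gen_channel_trace(p)
        series = open_fraction_timecourse(trace, window=5.0, unitary_amp=2.0)
        fr = np.array([f for _, f in series])
        assert len(fr) == 6
        assert np.all(np.abs(fr - p.p_open) < 0.08)

    def test_empty_trace_all_zero(self):
        series = open_fraction_timecourse(_trace(np.zeros(30000)), window=1.0,
                                          unitary_amp=2.0)
        assert all(f == 0.0 for _, f in series)

    def test_tiled_windows_average_to_whole_trace_fraction(self):
        p = ChannelGenParams(alpha=10.0, beta=60.0, duration=12.0, seed=11)
        trace, _ = gen_channel_trace(p)
        whole = open_time_fraction(detect_openings(trace, unitary_amp=2.0))
        tiles = open_fraction_timecourse(trace, window=3.0, unitary_amp=2.0)
        assert abs(np.mean([f for _, f in tiles]) - whole) < 0.01

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            open_fraction_timecourse(_trace(np.zeros(100)), window=5.0)


class TestHill:
    CAL = HillCalibration(f_max=1.0, ec50=1000.0, n=1.5)

    def test_exact_parameter_recovery(self):
        c = np.array([50, 150, 400, 1000, 2500, 6000, 15000], dtype=float)
        cal = fit_hill(c, self.CAL(c))
        assert abs(cal.f_max - 1.0) < 1e-6
        assert abs(cal.ec50 - 1000.0) < 1e-3
        assert abs(cal.n - 1.5) < 1e-6

    def test_all_zero_fractions_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|zero"):
            fit_hill([100.0, 300.0, 900.0], [0.0, 0.0, 0.0])

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([100.0, 100.0, 300.0][:2], [0.1, 0.2])

    def test_noisy_ec50_recovery_within_10pct(self, rng):
        c = np.array([100, 250, 500, 1000, 2000, 4000, 8000], dtype=float)
        f = self.CAL(c) + rng.normal(0, 0.01, size=len(c))
        cal = fit_hill(c, np.clip(f, 1e-4, None))
        assert abs(cal.ec50 - 1000.0) / 1000.0 < 0.10

    def test_midpoint_and_inverse_roundtrip(self):
        assert estimate_gaba(0.5, self.CAL) == pytest.approx(1000.0)
        for c in (200.0, 700.0, 3000.0):
            assert estimate_gaba(self.CAL(c), self.CAL) == pytest.approx(c, rel=1e-9)

    def test_inverse_monotone_and_range_checked(self):
        fs = np.linspace(0.05, 0.9, 10)
        cs = [estimate_gaba(f, self.CAL) for f in fs]
        assert np.all(np.diff(cs) > 0)
        with pytest.raises(ValueError, match="range"):
            estimate_gaba(1.2, self.CAL)


def test_read_trace_two_column_csv(tmp_path):
    t = np.arange(1000) / RATE
    x = np.zeros(1000)
    x[200:400] = 2.0
    path = tmp_path / "trace.csv"
    np.savetxt(path, np.column_stack([t, x]), delimiter=",")
    tr = read_trace(path)
    assert tr.rate == pytest.approx(RATE)
    assert np.allclose(tr.current, x)
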