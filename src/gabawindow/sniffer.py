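"""Sniffer-patch analysis: from raw single-channel current to [GABA].

An outside-out patch held in the tissue reports ambient GABA through the
openings of its GABA_A channels.  The analysis chain is:

1. zero-phase low-pass filtering of the 10 kHz record (>1 kHz noise removed);
2. threshold idealization (1.5 pA, minimum event duration 0.2 ms) into an
   event list, with simultaneous multi-channel openings handled by rounding
   the event amplitude to multiples of the unitary current;
3. the open-time fraction t_o/t_f — summed (level-weighted) open durations
   over recording time, which may exceed 1 in multi-channel patches;
4. a Hill calibration f(C) = f_max·Cⁿ/(EC50ⁿ + Cⁿ) mapping fraction to
   concentration, invertible analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal


@dataclass
class SingleChannelTrace:
    current: np.ndarray          # pA
    rate: float = 10_000.0       # Hz
    baseline: float | None = None  # pA; None -> estimated from histogram mode
    polarity: int = 1            # sign of openings relative to baseline

    def __post_init__(self):
        self.current = np.asarray(self.current, dtype=float)
        if not np.all(np.isfinite(self.current)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.current) / self.rate

    def times_s(self) -> np.ndarray:
        return np.arange(len(self.current)) / self.rate


@dataclass(frozen=True)
class ChannelEvent:
    start: float     # ms
    duration: float  # ms
    level: int       # simultaneously open channels


@dataclass
class ChannelEventList:
    events: list
    t_f: float       # recording time, s
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.events)


def read_trace(path, rate: float | None = None) -> SingleChannelTrace:
    """Read a two-column (time_s, current_pA) CSV/TSV trace."""
    data = np.loadtxt(path, delimiter=None if str(path).endswith(".tsv") else ",")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, current_pA)")
    t, i = data[:, 0], data[:, 1]
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t)))
    return SingleChannelTrace(i, rate=rate)


def lowpass_filter(trace: SingleChannelTrace, cutoff: float = 1000.0,
                   order: int = 4) -> SingleChannelTrace:
    """Zero-phase Butterworth low-pass (forward-backward, length preserved)."""
    nyq = trace.rate / 2
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.current)
    return SingleChannelTrace(filtered, rate=trace.rate,
                              baseline=trace.baseline, polarity=trace.polarity)


def estimate_baseline(trace: SingleChannelTrace, bins: int = 200) -> float:
    """Histogram-mode baseline; robust even at high open probability."""
    hist, edges = np.histogram(trace.current, bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def detect_openings(trace: SingleChannelTrace, threshold: float = 1.5,
                    min_duration: float = 0.2, unitary_amp: float = 2.0) -> ChannelEventList:
    """Idealize the trace into channel-opening events.

    Contiguous stretches of baseline-subtracted current beyond ``threshold``
    (in the opening polarity) become events.  The minimum-duration rule is
    applied symmetrically, as in standard idealization practice: closures
    shorter than ``min_duration`` ms are treated as continuations (so noise
    dips do not fragment an opening), then openings shorter than
    ``min_duration`` are discarded.  The open-channel count of each event is
    its mean amplitude divided by ``unitary_amp``, rounded and clipped to >= 1.
    """
    if unitary_amp <= 0:
        raise ValueError("unitary_amp must be > 0")
    base = trace.baseline if trace.baseline is not None else estimate_baseline(trace)
    x = trace.polarity * (trace.current - base)
    above = x > threshold
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)          # exclusive
    dt_ms = 1000.0 / trace.rate
    min_samples = int(round(min_duration / dt_ms))

    # Bridge sub-minimum closures.
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_samples:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    events = []
    for s, e in merged:
        dur = (e - s) * dt_ms
        if dur + 1e-9 < min_duration:
            continue
        amp = float(np.mean(x[s:e]))
        level = max(1, int(round(amp / unitary_amp)))
        events.append(ChannelEvent(start=s * dt_ms, duration=dur, level=level))
    return ChannelEventList(events, t_f=trace.duration_s,
                            meta={"threshold": threshold, "min_duration": min_duration,
                                  "unitary_amp": unitary_amp, "baseline": base})


def open_time_fraction(events: ChannelEventList) -> float:
    """t_o/t_f: level-weighted summed open time over recording time.

    Dimensionless (equivalently ms of open time per ms of record); exceeds 1
    when several channels are open for most of the record.
    """
    if events.t_f <= 0:
        raise ValueError("t_f must be > 0")
    t_o_ms = sum(e.duration * e.level for e in events.events)
    return t_o_ms / (events.t_f * 1000.0)


def open_fraction_timecourse(trace: SingleChannelTrace, window: float = 5.0,
                             step: float | None = None, **detect_kw):
    """Sliding/tiled open-time fraction: list of (window-start s, fraction).

    ``window`` and ``step`` in seconds; ``step=None`` tiles (step = window).
    """
    if window > trace.duration_s:
        raise ValueError("window longer than trace")
    step = window if step is None else step
    n_win = int(window * trace.rate)
    n_step = max(1, int(step * trace.rate))
    out = []
    base = trace.baseline if trace.baseline is not None else estimate_baseline(trace)
    for s0 in range(0, len(trace.current) - n_win + 1, n_step):
        seg = SingleChannelTrace(trace.current[s0:s0 + n_win], rate=trace.rate,
                                 baseline=base, polarity=trace.polarity)
        out.append((s0 / trace.rate, open_time_fraction(detect_openings(seg, **detect_kw))))
    return out


@dataclass(frozen=True)
class HillCalibration:
    """Open-time fraction vs [GABA]: f(C) = f_max·Cⁿ/(EC50ⁿ + Cⁿ)."""
    f_max: float
    ec50: float      # nM
    n: float

    def __post_init__(self):
        if min(self.f_max, self.ec50, self.n) <= 0:
            raise ValueError("Hill parameters must be positive")

    def __call__(self, concentration_nM):
        c = np.asarray(concentration_nM, dtype=float)
        f = self.f_max * c**self.n / (self.ec50**self.n + c**self.n)
        return float(f) if f.ndim == 0 else f


#: Synthetic stand-in calibration: the published sniffer-patch dose-response
#: fit parameters are not available, so this curve is parameterized to pass
#: through the reported operating points (~0.12 at ~300 nM, ~0.39 at ~900 nM).
#: It is NOT a measured calibration.
SYNTHETIC_CALIBRATION = HillCalibration(f_max=1.0, ec50=1200.0, n=1.5)


def fit_hill(concentrations_nM, fractions) -> HillCalibration:
    """Least-squares Hill fit; needs >= 3 distinct concentrations."""
    c = np.asarray(concentrations_nM, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct concentrations")
    if not np.any(f > 0):
        raise ValueError("all-zero fractions: degenerate Hill fit")

    def model(c, fmax, ec50, n):
        return fmax * c**n / (ec50**n + c**n)

    p0 = (max(f.max(), 1e-3) * 1.2, float(np.median(c)), 1.0)
    popt, _ = optimize.curve_fit(model, c, f, p0=p0, maxfev=20000,
                                 bounds=([1e-9, 1e-9, 0.1], [np.inf, np.inf, 10.0]))
    return HillCalibration(*map(float, popt))


def estimate_gaba(fraction: float, cal: HillCalibration) -> float:
    """Invert the Hill calibration: C = EC50·(f/(f_max−f))^(1/n), in nM."""
    if not 0 < fraction < cal.f_max:
        raise ValueError(
            f"fraction {fraction} outside calibrated range (0, {cal.f_max})"
        )
    return float(cal.ec50 * (fraction / (cal.f_max - fraction)) ** (1.0 / cal.n))
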