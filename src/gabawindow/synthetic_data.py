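"""Generators for every synthetic input the pipeline consumes.

Each generator is seeded, bit-reproducible, and returns its ground truth
alongside the data so detection/estimation stages can be scored against it:

- two-state (closed/open) Markov GABA_A channel traces with Gaussian recording
  noise and optional multiple channels per patch;
- spike-probability-vs-offset profiles with binomial sampling noise;
- synthetic morphologies live in :func:`gabawindow.morphology.make_synthetic_ca1`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sniffer import ChannelEvent, ChannelEventList, HillCalibration, SingleChannelTrace
from .protocol import SpikeProbProfile


@dataclass(frozen=True)
class ChannelGenParams:
    """Two-state Markov channel: closed -> open at rate alpha, back at beta (1/s).

    Stationary open probability alpha/(alpha+beta).  Dwell times are drawn in
    continuous time and rasterized to the sampling grid; sub-sample openings
    are kept in the ground truth (so min-duration filtering is testable).
    """
    alpha: float = 11.1
    beta: float = 100.0
    unitary_amp: float = 2.0     # pA
    noise_sd: float = 0.35       # pA before low-pass filtering: a low-noise patch
    n_channels: int = 1
    rate: float = 10_000.0       # Hz
    duration: float = 60.0       # s
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("rates must be positive")

    @property
    def p_open(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def gen_channel_trace(p: ChannelGenParams) -> tuple[SingleChannelTrace, ChannelEventList]:
    """Simulate a patch of ``n_channels`` independent two-state channels.

    Returns the noisy summed-current trace and the exact per-channel opening
    table (level 1 per event; simultaneous openings overlap across events).
    """
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.rate))
    open_count = np.zeros(n, dtype=np.int32)
    truth = []
    for _ch in range(p.n_channels):
        t = 0.0
        is_open = rng.random() < p.p_open  # start from stationary distribution
        if is_open:
            start = 0.0
        while t < p.duration:
            dwell = rng.exponential(1.0 / (p.beta if is_open else p.alpha))
            t_next = t + dwell
            if is_open:
                end = min(t_next, p.duration)
                truth.append(ChannelEvent(start=t * 1000.0,
                                          duration=(end - t) * 1000.0, level=1))
                i0, i1 = int(round(t * p.rate)), int(round(end * p.rate))
                open_count[i0:min(i1, n)] += 1
            else:
                start = t_next
            is_open = not is_open
            t = t_next
    current = open_count * p.unitary_amp + rng.normal(0.0, p.noise_sd, size=n)
    trace = SingleChannelTrace(current, rate=p.rate, baseline=0.0, polarity=1)
    truth.sort(key=lambda e: e.start)
    return trace, ChannelEventList(truth, t_f=p.duration, meta={"params": p})


def true_open_fraction(truth: ChannelEventList) -> float:
    """Ground-truth t_o/t_f of a generated event table."""
    return sum(e.duration * e.level for e in truth.events) / (truth.t_f * 1000.0)


@dataclass(frozen=True)
class ProfileGenParams:
    """Binomial spike-probability profile around a Gaussian ground truth."""
    amplitude: float = 0.95
    sigma: float = 6.0           # ms
    offsets: tuple = tuple(float(o) for o in range(-30, 31, 5))
    trials: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.amplitude <= 1:
            raise ValueError("amplitude must be in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def gen_spike_profile(p: ProfileGenParams) -> SpikeProbProfile:
    """Draw Binomial(trials, A·exp(−Δt²/2σ²)) successes at each offset."""
    rng = np.random.default_rng(p.seed)
    off = np.asarray(p.offsets, dtype=float)
    prob = p.amplitude * np.exp(-(off**2) / (2 * p.sigma**2))
    ind = (rng.random((len(off), p.trials)) < prob[:, None]).astype(np.int8)
    return SpikeProbProfile(offsets=off, spike_probability=ind.mean(axis=1),
                            trials=p.trials, indicators=ind,
                            meta={"truth_sigma": p.sigma, "truth_amplitude": p.amplitude})


def gaba_to_open_fraction(concentration_nM: float, cal: HillCalibration,
                          n_channels: int = 1) -> float:
    """Forward Hill read-out: per-channel stationary open probability.

    The calibration maps [GABA] to a whole-patch open-time fraction; dividing
    by the channel count gives the per-channel open probability used by
    :func:`gen_channel_trace`.
    """
    if concentration_nM < 0:
        raise ValueError("concentration must be >= 0")
    return cal(concentration_nM) / n_channels


def channel_params_for_gaba(concentration_nM: float, cal: HillCalibration,
                            mean_open_ms: float = 10.0, **kw) -> ChannelGenParams:
    """Channel generator parameterized to emulate a given ambient [GABA].

    The mean open time sets beta; alpha follows from the stationary open
    probability implied by the calibration.
    """
    p_open = gaba_to_open_fraction(concentration_nM, cal, kw.get("n_channels", 1))
    if not 0 < p_open < 1:
        raise ValueError(f"open probability {p_open} outside (0, 1)")
    beta = 1000.0 / mean_open_ms
    alpha = beta * p_open / (1 - p_open)
    return ChannelGenParams(alpha=alpha, beta=beta, **kw)
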