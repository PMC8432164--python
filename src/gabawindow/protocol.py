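"""The coincidence-detection experiment run in silico.

Two groups of 20 excitatory synapses are scattered over the apical dendrites.
On every trial each synapse activates independently with probability
P_r = 0.35 (so ~7 synapses fire per group).  The first group fires at 50 ms;
the second at a programmable offset within ±30 ms.  The per-synapse peak
conductance G_s is first calibrated so that exactly coincident activation
fires a somatic spike on 95-99 of 100 trials, then the spike probability is
measured at each offset (10 trials each).  A Gaussian fit to the resulting
profile gives the coincidence window (2σ, see window_stats).

Randomness is organised as one substream per (offset, trial) derived from the
master seed, so different pharmacological conditions see identical synaptic
activation patterns — the in-silico analogue of a paired experimental design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cable_solver import SimulationConfig, SynapticEvent, detect_spikes, simulate
from .morphology import CompartmentalModel

DEFAULT_OFFSETS = tuple(float(o) for o in range(-30, 31, 5))


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class InputGroup:
    """One afferent input: synapse indices into model.synapses plus P_r."""
    synapses: tuple
    p_release: float = 0.35

    def __post_init__(self):
        if not 0 <= self.p_release <= 1:
            raise ValueError("p_release must be in [0, 1]")


@dataclass(frozen=True)
class ProtocolConfig:
    first_onset: float = 50.0
    offsets: tuple = DEFAULT_OFFSETS
    trials_per_offset: int = 10
    calibration_trials: int = 100
    spike_target: float = 0.9
    success_band: tuple = (0.95, 0.99)
    duration: float = 150.0
    dt: float = 0.025
    seed: int = 0

    def __post_init__(self):
        if self.trials_per_offset < 1:
            raise ValueError("trials_per_offset must be >= 1")
        offs = np.asarray(self.offsets)
        if not np.allclose(np.sort(offs), np.sort(-offs)):
            raise ValueError("offsets must be symmetric about 0")


@dataclass
class SpikeProbProfile:
    """Spike probability versus inter-input offset."""
    offsets: np.ndarray            # ms
    spike_probability: np.ndarray  # fraction in [0, 1] per offset
    trials: int
    indicators: np.ndarray | None = None   # (n_offsets, n_trials) 0/1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.spike_probability = np.asarray(self.spike_probability, dtype=float)
        if self.indicators is not None:
            assert np.allclose(self.spike_probability, self.indicators.mean(axis=1))


def place_synapses(model: CompartmentalModel, n_total: int = 40, seed: int = 0,
                   g_max: float = 1.0) -> tuple[InputGroup, InputGroup]:
    """Scatter n_total synapses over apical compartments, area-weighted,
    without replacement, and assign them alternately to groups A and B.

    Appends (compartment, g_max_nS) entries to ``model.synapses`` and returns
    the two groups.  Deterministic for a fixed seed.
    """
    apical = np.flatnonzero(model.region_mask("apical"))
    if len(apical) < n_total:
        raise ValueError(
            f"only {len(apical)} apical compartments for {n_total} synapses"
        )
    rng = np.random.default_rng(seed)
    w = model.area_cm2()[apical]
    comps = rng.choice(apical, size=n_total, replace=False, p=w / w.sum())
    base = len(model.synapses)
    for c in comps:
        model.synapses.append((int(c), g_max))
    idx = np.arange(base, base + n_total)
    return InputGroup(tuple(idx[0::2])), InputGroup(tuple(idx[1::2]))


def draw_activation(group: InputGroup, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(P_r) activation; returns activated synapse ids."""
    mask = rng.random(len(group.synapses)) < group.p_release
    return np.asarray(group.synapses)[mask]


def set_gs(model: CompartmentalModel, g_max: float) -> None:
    """Set the shared per-synapse peak conductance (nS)."""
    model.synapses = [(c, g_max) for c, _ in model.synapses]


def trial_rng(master_seed: int, offset_index: int, trial: int) -> np.random.Generator:
    """Substream for one (offset, trial); identical across conditions."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(offset_index), int(trial)])
    )


def run_trial(model, groups, cfg: ProtocolConfig, offset: float,
              rng: np.random.Generator, g_max: float | None = None) -> bool:
    """One stochastic trial; True if the soma fires >= 1 spike in the sweep."""
    if g_max is not None:
        set_gs(model, g_max)
    a, b = groups
    t_a = cfg.first_onset
    t_b = cfg.first_onset + offset
    events = [SynapticEvent(int(s), t_a) for s in draw_activation(a, rng)]
    events += [SynapticEvent(int(s), t_b) for s in draw_activation(b, rng)]
    sim = SimulationConfig(dt=cfg.dt, duration=cfg.duration, record_sites=(0,))
    trace = simulate(model, events, sim)
    return len(detect_spikes(trace)) > 0


def _success_count(model, groups, cfg: ProtocolConfig, g_max: float) -> int:
    """Spikes out of calibration_trials coincident trials, common random numbers."""
    count = 0
    for k in range(cfg.calibration_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), 1_000_003, int(k)])
        )
        if run_trial(model, groups, cfg, 0.0, rng, g_max=g_max):
            count += 1
    return count


def bisect_on_success(success_fn, lo: float, hi: float, band: tuple,
                      n_trials: int, tol: float = 0.02, max_iter: int = 30):
    """Bisection on a monotone success-count function of a scalar parameter.

    Returns the smallest tested value whose success fraction lies in ``band``;
    if the discrete trial granularity makes the band unreachable, returns the
    nearest value from above (with a warning).  ``success_fn`` must use common
    random numbers so that counts are monotone in the parameter.
    """
    lo_band = int(np.ceil(band[0] * n_trials))
    hi_band = int(np.floor(band[1] * n_trials))
    c_lo, c_hi = success_fn(lo), success_fn(hi)
    if c_hi < lo_band:
        raise CalibrationError(
            f"success {c_hi}/{n_trials} at upper bracket {hi}; target band "
            f"[{lo_band}, {hi_band}] unreachable in [{lo}, {hi}]"
        )
    if lo_band <= c_lo <= hi_band:
        return lo, c_lo
    if c_lo > hi_band:
        raise CalibrationError(
            f"success {c_lo}/{n_trials} already above band at lower bracket {lo}"
        )
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        c = success_fn(mid)
        if c < lo_band:
            lo = mid
        elif c > hi_band:
            hi, c_hi = mid, c
        else:
            return mid, c
    warnings.warn(
        f"calibration band [{lo_band}, {hi_band}]/{n_trials} straddled by trial "
        f"granularity; returning nearest value above ({hi}, {c_hi}/{n_trials})"
    )
    return hi, c_hi


def calibrate_gs(model, groups, cfg: ProtocolConfig,
                 g_lo: float = 0.1, g_hi: float = 12.0) -> float:
    """Calibrate the shared per-synapse peak conductance G_s (nS).

    Bisects G_s until coincident (offset 0) stochastic activation of both
    groups spikes the soma on 95-99 of the calibration trials, i.e. safely
    above the 0.9 spike-probability criterion.  Identical trial randomness is
    reused for every candidate G_s, so the success count is monotone in G_s
    and the procedure is reproducible.
    """
    g, _count = bisect_on_success(
        lambda g: _success_count(model, groups, cfg, g),
        g_lo, g_hi, cfg.success_band, cfg.calibration_trials,
    )
    set_gs(model, g)
    return g


def run_coincidence_sweep(model, groups, cfg: ProtocolConfig,
                          g_max: float | None = None) -> SpikeProbProfile:
    """Measure spike probability at every offset (trials_per_offset each).

    ``model`` must carry calibrated synapses (or pass ``g_max``).  Trial
    substreams depend only on (seed, offset index, trial), not on the
    condition baked into the model's mechanisms, giving a paired design.
    """
    if g_max is not None:
        set_gs(model, g_max)
    offsets = np.asarray(cfg.offsets, dtype=float)
    ind = np.zeros((len(offsets), cfg.trials_per_offset), dtype=np.int8)
    for oi, off in enumerate(offsets):
        for k in range(cfg.trials_per_offset):
            rng = trial_rng(cfg.seed, oi, k)
            ind[oi, k] = run_trial(model, groups, cfg, float(off), rng)
    return SpikeProbProfile(
        offsets=offsets,
        spike_probability=ind.mean(axis=1),
        trials=cfg.trials_per_offset,
        indicators=ind,
        meta={"seed": cfg.seed, "g_max": model.synapses[0][1] if model.synapses else None},
    )
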