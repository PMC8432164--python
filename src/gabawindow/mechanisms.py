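"""Membrane mechanisms: leak, dual-exponential synapse, tonic GABA_A, I_h, Na/K.

Scalar evaluation functions here are the reference definitions (and the ones
the tests exercise); the time-stepping loop in :mod:`gabawindow.cable_solver`
re-implements the same expressions in compiled form.

Unit conventions: voltages mV, time ms, conductance densities mS/cm²,
current densities returned in mA/cm² (1 mS/cm² · 1 mV = 1e-3 mA/cm²),
synaptic conductances nS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .morphology import CompartmentalModel


@dataclass(frozen=True)
class PassiveParams:
    """Leak conductance density (mS/cm²) and reversal (mV).

    The leak is not constrained by published CA1 measurements used here; the
    defaults put the passive resting potential at -70 mV with an input
    resistance in the CA1 range, and an effective membrane time constant of a
    few ms once the tonic GABA and I_h shunts are added — fast enough that the
    coincidence bump stays inside the ±30 ms offset grid.
    """
    g_leak: float = 0.05
    e_leak: float = -70.0

    def __post_init__(self):
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")


@dataclass(frozen=True)
class Exp2SynParams:
    """Dual-exponential synaptic conductance, peak-normalized to g_max.

    g(t) = g_max * (exp(-t/tau_decay) - exp(-t/tau_rise)) / N with N chosen so
    the peak equals g_max (the Exp2Syn convention).  Defaults: rise 2.5 ms,
    decay 10 ms, excitatory reversal 0 mV.
    """
    tau_rise: float = 2.5
    tau_decay: float = 10.0
    e_rev: float = 0.0

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay (equal taus are degenerate)")

    @property
    def t_peak(self) -> float:
        """Time to peak (ms): tau1*tau2/(tau2-tau1) * ln(tau2/tau1)."""
        t1, t2 = self.tau_rise, self.tau_decay
        return t1 * t2 / (t2 - t1) * math.log(t2 / t1)

    @property
    def norm(self) -> float:
        """Peak value of the un-normalized difference of exponentials."""
        tp = self.t_peak
        return math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)


def syn_conductance(t, g_max: float, p: Exp2SynParams = Exp2SynParams()):
    """Synaptic conductance (nS) at time t (ms) since activation.

    Peak-normalized: max over t equals ``g_max``; g(0) = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    g = g_max * (np.exp(-t / p.tau_decay) - np.exp(-t / p.tau_rise)) / p.norm
    return float(g) if g.ndim == 0 else g


@dataclass(frozen=True)
class TonicGABAParams:
    """Tonic GABA_A shunt: I = g_GABA * O * (V - E_GABA).

    ``g_gaba`` is the full-open conductance density (3 mS/cm²); ``o`` is the
    fraction of channels open, set by ambient GABA.  E_GABA defaults to the
    midpoint of the physiological -75..-55 mV range.
    """
    g_gaba: float = 3.0
    o: float = 0.03
    e_gaba: float = -65.0

    def __post_init__(self):
        if not 0 <= self.o <= 1:
            raise ValueError("open fraction o must be in [0, 1]")


def tonic_gaba_current(v, p: TonicGABAParams) -> float:
    """Tonic GABA_A current density (mA/cm²) at membrane potential v (mV)."""
    # mS/cm² · mV = µA/cm²; scale to mA/cm²
    return p.g_gaba * p.o * (v - p.e_gaba) * 1e-3


@dataclass(frozen=True)
class IhParams:
    """Hyperpolarization-activated cation current (HCN), single Boltzmann gate.

    I = g_h * m * (V - E_h); m_inf(V) = 1/(1 + exp((V - v_half)/k)) is
    monotonically decreasing in V (deactivates with depolarization), with
    midpoint at the -81 mV deactivation potential.  tau_m(V) is bell-shaped,
    peaking at tens of ms near v_half.
    """
    g_h: float = 0.1
    v_half: float = -81.0
    k: float = 10.0
    e_h: float = -30.0
    tau_min: float = 10.0
    tau_amp: float = 50.0
    k_tau: float = 15.0
    dist_grad: float = 0.0  # per µm: optional distance-dependent dendritic density rise


def ih_gate_inf(v, p: IhParams = IhParams()):
    x = np.clip((np.asarray(v, dtype=float) - p.v_half) / p.k, -700, 700)
    return 1.0 / (1.0 + np.exp(x))


def ih_gate_tau(v, p: IhParams = IhParams()):
    x = (np.asarray(v, dtype=float) - p.v_half) / p.k_tau
    return p.tau_min + p.tau_amp / (np.exp(x) + np.exp(-x))


def ih_current(v, m, p: IhParams = IhParams()):
    """I_h current density (mA/cm²) for gate state m in [0, 1]."""
    m = np.asarray(m, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("gate m must be in [0, 1]")
    return p.g_h * 1e-3 * m * (v - p.e_h)


@dataclass(frozen=True)
class SpikeChannelParams:
    """HH-style Na and delayed-rectifier K channels for somatic spiking.

    Classic squid-axon rate functions shifted to a -65 mV frame, with a
    uniform rate multiplier ``phi`` to sharpen spikes at near-physiological
    temperature.  Activation curves are shifted depolarized (``na_vshift``,
    ``k_vshift``) so neither channel contributes a resting shunt or window
    current that would mask the tonic GABA conductance at the soma; the Na
    inactivation gate is shifted further (``h_extra_shift``) so subthreshold
    EPSPs do not inactivate Na and suppress a second input arriving a few
    milliseconds later (accommodation would otherwise mask temporal
    summation).  Densities apply at the soma and proximal apical trunk only.
    """
    g_na: float = 150.0
    g_k: float = 45.0
    e_na: float = 50.0
    e_k: float = -90.0
    phi: float = 3.0
    na_vshift: float = 15.0
    h_extra_shift: float = 20.0
    k_vshift: float = 20.0

    def __post_init__(self):
        if self.g_na < 0 or self.g_k < 0:
            raise ValueError("conductances must be >= 0")


def _vtrap(x, y):
    """x / (1 - exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    z = np.clip(x / y, -50, 50)
    small = np.abs(z) < 1e-6
    denom = 1.0 - np.exp(-np.where(small, 1.0, z))
    return np.where(small, y * (1 + z / 2), x / np.where(small, 1.0, denom))


def hh_rates(v, na_vshift: float = 15.0, h_extra_shift: float = 20.0,
             k_vshift: float = 20.0):
    """HH rate constants (1/ms) at voltage v (mV): (am, bm, ah, bh, an, bn)."""
    v = np.asarray(v, dtype=float)
    vn = v - na_vshift
    am = 0.1 * _vtrap(vn + 40.0, 10.0)
    bm = 4.0 * np.exp(-(vn + 65.0) / 18.0)
    vh = vn - h_extra_shift
    ah = 0.07 * np.exp(-(vh + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(vh + 35.0) / 10.0))
    vk = v - k_vshift
    an = 0.01 * _vtrap(vk + 55.0, 10.0)
    bn = 0.125 * np.exp(-(vk + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def spike_currents(v, m, h, n, p: SpikeChannelParams = SpikeChannelParams()):
    """Na + K current density (mA/cm²) for given gate states."""
    i_na = p.g_na * 1e-3 * np.asarray(m) ** 3 * np.asarray(h) * (v - p.e_na)
    i_k = p.g_k * 1e-3 * np.asarray(n) ** 4 * (v - p.e_k)
    return i_na + i_k


@dataclass(frozen=True)
class MechanismSet:
    """Complete mechanism parameterization of a model cell."""
    passive: PassiveParams = PassiveParams()
    syn: Exp2SynParams = Exp2SynParams()
    tonic: TonicGABAParams = TonicGABAParams()
    ih: IhParams = IhParams()
    spike: SpikeChannelParams = SpikeChannelParams()
    spike_extent_um: float = 40.0  # path distance over which Na/K are inserted


#: Pharmacological condition presets.  "ptx" blocks GABA_A receptors (O = 0);
#: "zd" blocks I_h (g_h = 0); "gat" doubles ambient GABA (uptake blockade).
CONDITIONS = ("control", "zd", "ptx", "zd+ptx", "gat")


def apply_condition(mech: MechanismSet, condition: str, gat_factor: float = 2.0) -> MechanismSet:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    out = mech
    if "zd" in condition:
        out = replace(out, ih=replace(out.ih, g_h=0.0))
    if "ptx" in condition:
        out = replace(out, tonic=replace(out.tonic, o=0.0))
    if condition == "gat":
        out = replace(out, tonic=replace(out.tonic, o=min(1.0, gat_factor * out.tonic.o)))
    return out


def attach_mechanisms(model: CompartmentalModel, mech: MechanismSet = MechanismSet()) -> CompartmentalModel:
    """Insert per-compartment conductance-density arrays into the model.

    Leak, tonic GABA and I_h are uniform over soma and dendrites; Na/K spike
    channels are restricted to the soma and the proximal apical trunk
    (within ``spike_extent_um`` path distance).
    """
    n = model.n
    dist = model.path_distance()
    proximal = (model.region_mask("soma")) | (
        model.region_mask("apical") & (dist <= mech.spike_extent_um)
    )
    model.mech = {
        "params": mech,
        "g_leak": np.full(n, mech.passive.g_leak),
        "e_leak": mech.passive.e_leak,
        "g_tonic": np.full(n, mech.tonic.g_gaba * mech.tonic.o),
        "e_gaba": mech.tonic.e_gaba,
        # HCN density climbs along the apical dendrite, as in reconstructed
        # CA1 models; the printed 0.1 mS/cm2 is the somatic/base density.
        "g_h": mech.ih.g_h * (1.0 + mech.ih.dist_grad * np.where(
            model.region_mask("soma"), 0.0, dist)),
        "g_na": np.where(proximal, mech.spike.g_na, 0.0),
        "g_k": np.where(proximal, mech.spike.g_k, 0.0),
    }
    return model
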