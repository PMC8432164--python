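"""Implicit integration of the branched cable equation.

The tree system is solved each step by Hines elimination (one sweep from the
leaves to the root, one back-substitution sweep down), which is exact and
linear-cost because compartments are stored parent-before-child.  Time
integration is the theta method: theta = 0.5 gives Crank-Nicolson (default),
theta = 1 backward Euler.  Gate variables are advanced by their exact
single-step exponential relaxation at the pre-step voltage; the steady-state
values and per-step decay factors are linearly interpolated from tables on a
0.05 mV voltage grid (built from the closed-form rate functions each run), so
the hot loop is free of transcendental calls and strictly IEEE-deterministic.
Synaptic dual-exponential conductances are advanced analytically.

Internal units: mV, ms, mS, µA, µF (so C/dt in µF/ms is commensurate with
conductances in mS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .mechanisms import MechanismSet
from .morphology import CompartmentalModel

_VGRID_LO, _VGRID_HI, _VGRID_STEP = -150.0, 80.0, 0.05


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SynapticEvent:
    """Activation of one synapse at a given time (ms) within the sweep."""
    synapse: int
    t: float


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.025
    duration: float = 150.0
    record_sites: tuple = (0,)
    v_init: float | None = None   # None -> relax to steady state first
    method: str = "cn"            # "cn" or "be"
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0 or self.duration < self.dt:
            raise ValueError("need dt > 0 and duration >= dt")
        if self.method not in ("cn", "be"):
            raise ValueError("method must be 'cn' or 'be'")


@dataclass
class VoltageTrace:
    times: np.ndarray            # ms, uniform grid
    values: np.ndarray           # (n_sites, n_times) mV
    sites: tuple = (0,)
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def site(self, compartment: int) -> np.ndarray:
        return self.values[self.sites.index(compartment)]


@njit(cache=False)
def _step_loop(v, cdt, parent, gax, area,
               g_leak, e_leak, g_tonic, e_gaba,
               g_h, ih_eh, g_na, g_k, e_na, e_k,
               tab_v0, tab_idv, ih_inf, ih_dec,
               m_inf, m_dec, h_inf, h_dec, n_inf, n_dec,
               m_ih, hm, hh, hn,
               syn_comp, syn_amp, fa, fb, e_rev, sa, sb,
               ev_step, ev_syn,
               i_amp, i_on, i_off,
               nsteps, dt, theta, rec_idx, vrec):
    n = v.shape[0]
    nsyn = syn_comp.shape[0]
    ntab = ih_inf.shape[0]
    gm = np.empty(n)
    b = np.empty(n)
    gd = np.empty(n)
    rhs = np.empty(n)
    a = np.empty(n)
    ev_ptr = 0
    for r in range(rec_idx.shape[0]):
        vrec[r, 0] = v[rec_idx[r]]

    for step in range(nsteps):
        # --- gate updates: exact exponential relaxation, table lookup ---
        for i in range(n):
            u = (v[i] - tab_v0) * tab_idv
            if u < 0.0:
                u = 0.0
            j = int(u)
            if j > ntab - 2:
                j = ntab - 2
            w = u - j
            if g_h[i] > 0.0:
                minf = ih_inf[j] + w * (ih_inf[j + 1] - ih_inf[j])
                dec = ih_dec[j] + w * (ih_dec[j + 1] - ih_dec[j])
                m_ih[i] = minf + (m_ih[i] - minf) * dec
            if g_na[i] > 0.0 or g_k[i] > 0.0:
                x = m_inf[j] + w * (m_inf[j + 1] - m_inf[j])
                d = m_dec[j] + w * (m_dec[j + 1] - m_dec[j])
                hm[i] = x + (hm[i] - x) * d
                x = h_inf[j] + w * (h_inf[j + 1] - h_inf[j])
                d = h_dec[j] + w * (h_dec[j + 1] - h_dec[j])
                hh[i] = x + (hh[i] - x) * d
                x = n_inf[j] + w * (n_inf[j + 1] - n_inf[j])
                d = n_dec[j] + w * (n_dec[j + 1] - n_dec[j])
                hn[i] = x + (hn[i] - x) * d

        # --- synaptic state advance + events snapped to this step ---
        for s_ in range(nsyn):
            sa[s_] *= fa
            sb[s_] *= fb
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == step:
            sa[ev_syn[ev_ptr]] += 1.0
            sb[ev_syn[ev_ptr]] += 1.0
            ev_ptr += 1

        # --- assemble membrane conductance (mS) and driving term (µA) ---
        for i in range(n):
            gl = g_leak[i] + g_tonic[i]
            bb = g_leak[i] * e_leak + g_tonic[i] * e_gaba
            if g_h[i] > 0.0:
                gh = g_h[i] * m_ih[i]
                gl += gh
                bb += gh * ih_eh
            if g_na[i] > 0.0 or g_k[i] > 0.0:
                gna = g_na[i] * hm[i] * hm[i] * hm[i] * hh[i]
                gk = g_k[i] * hn[i] * hn[i] * hn[i] * hn[i]
                gl += gna + gk
                bb += gna * e_na + gk * e_k
            gm[i] = gl * area[i]
            b[i] = bb * area[i]
        for s_ in range(nsyn):
            gs = syn_amp[s_] * (sb[s_] - sa[s_])
            if gs != 0.0:
                c = syn_comp[s_]
                gm[c] += gs
                b[c] += gs * e_rev
        if i_on <= step < i_off:
            for i in range(n):
                b[i] += i_amp[i]

        # --- theta-method linear system, Hines solve ---
        for i in range(n):
            gd[i] = gm[i]
        for i in range(1, n):
            gd[i] += gax[i]
            gd[parent[i]] += gax[i]
        # rhs = cdt*v - (1-theta)*(A_G v) + b
        om = 1.0 - theta
        for i in range(n):
            rhs[i] = cdt[i] * v[i] - om * gd[i] * v[i] + b[i]
        for i in range(1, n):
            rhs[i] += om * gax[i] * v[parent[i]]
            rhs[parent[i]] += om * gax[i] * v[i]
        for i in range(n):
            gd[i] = cdt[i] + theta * gd[i]
            a[i] = -theta * gax[i]
        for i in range(n - 1, 0, -1):
            f = a[i] / gd[i]
            gd[parent[i]] -= f * a[i]
            rhs[parent[i]] -= f * rhs[i]
        v[0] = rhs[0] / gd[0]
        for i in range(1, n):
            v[i] = (rhs[i] - a[i] * v[parent[i]]) / gd[i]

        for r in range(rec_idx.shape[0]):
            vrec[r, step + 1] = v[rec_idx[r]]
        if not math.isfinite(v[0]):
            return step + 1
    return -1


def _mech_arrays(model: CompartmentalModel):
    if not model.mech:
        raise SimulationError("model has no mechanisms attached (use attach_mechanisms)")
    return model.mech


def _gate_tables(mech: MechanismSet, dt: float):
    """Steady-state and per-step decay tables on the voltage grid."""
    from .mechanisms import hh_rates, ih_gate_inf, ih_gate_tau

    v = np.arange(_VGRID_LO, _VGRID_HI + _VGRID_STEP / 2, _VGRID_STEP)
    ih_inf = ih_gate_inf(v, mech.ih)
    ih_dec = np.exp(-dt / ih_gate_tau(v, mech.ih))
    am, bm, ah, bh, an, bn = hh_rates(v, mech.spike.na_vshift,
                                      mech.spike.h_extra_shift,
                                      mech.spike.k_vshift)
    phi = mech.spike.phi
    tabs = (ih_inf, ih_dec,
            am / (am + bm), np.exp(-dt * phi * (am + bm)),
            ah / (ah + bh), np.exp(-dt * phi * (ah + bh)),
            an / (an + bn), np.exp(-dt * phi * (an + bn)))
    return tuple(np.ascontiguousarray(t) for t in tabs)


def _gate_init(model, v):
    from .mechanisms import hh_rates, ih_gate_inf

    mech: MechanismSet = model.mech["params"]
    v = np.broadcast_to(np.asarray(v, dtype=float), (model.n,))
    m_ih = np.ascontiguousarray(ih_gate_inf(v, mech.ih), dtype=float)
    am, bm, ah, bh, an, bn = hh_rates(v, mech.spike.na_vshift,
                                      mech.spike.h_extra_shift,
                                      mech.spike.k_vshift)
    hm = np.ascontiguousarray(am / (am + bm))
    hh = np.ascontiguousarray(ah / (ah + bh))
    hn = np.ascontiguousarray(an / (an + bn))
    return m_ih, hm, hh, hn


def _run_kernel(model, v, dt, theta, nsteps, rec_idx, vrec,
                syn_comp=None, syn_amp=None, fa=1.0, fb=1.0, e_rev=0.0,
                ev_step=None, ev_syn=None, i_amp=None, i_on=0, i_off=-1):
    """Shared dispatch into the compiled stepping loop (mutates v, vrec)."""
    md = _mech_arrays(model)
    mech: MechanismSet = md["params"]
    area = model.area_cm2()
    tabs = _gate_tables(mech, dt)
    m_ih, hm, hh, hn = _gate_init(model, v)
    z = np.zeros(0)
    zi = np.zeros(0, dtype=np.int64)
    if syn_comp is None:
        syn_comp, syn_amp = zi, z
        sa = sb = z.copy()
    else:
        sa = np.zeros(len(syn_comp))
        sb = np.zeros(len(syn_comp))
    return _step_loop(
        v, model.specific_capacitance * area / dt, model.parent,
        model.axial_conductance_mS(), area,
        md["g_leak"], md["e_leak"], md["g_tonic"], md["e_gaba"],
        md["g_h"], mech.ih.e_h, md["g_na"], md["g_k"],
        mech.spike.e_na, mech.spike.e_k,
        _VGRID_LO, 1.0 / _VGRID_STEP, *tabs,
        m_ih, hm, hh, hn,
        syn_comp, syn_amp, fa, fb, e_rev, sa, sb,
        (ev_step if ev_step is not None else zi),
        (ev_syn if ev_syn is not None else zi),
        (i_amp if i_amp is not None else np.zeros(model.n)),
        i_on, i_off, nsteps, dt, theta, rec_idx, vrec)


def simulate(model: CompartmentalModel, events, cfg: SimulationConfig,
             i_clamp=None) -> VoltageTrace:
    """Integrate the model and return recorded voltages.

    ``events`` is an iterable of :class:`SynapticEvent` indexing into
    ``model.synapses`` (a list of ``(compartment, g_max_nS)`` pairs, with
    kinetics shared from the mechanism set).  ``i_clamp``, if given, is
    ``(compartment, amplitude_nA, t_on_ms, t_off_ms)``.

    Deterministic: identical models, events and config give bit-identical
    traces.
    """
    md = _mech_arrays(model)
    mech: MechanismSet = md["params"]
    dt, theta = cfg.dt, (0.5 if cfg.method == "cn" else 1.0)
    nsteps = int(round(cfg.duration / dt))

    if cfg.v_init is None:
        if "_v_rest" not in md:
            md["_v_rest"] = steady_state(model)
        v = md["_v_rest"].copy()
    else:
        v = np.full(model.n, float(cfg.v_init))

    syn_comp = np.array([s[0] for s in model.synapses], dtype=np.int64)
    syn_gmax = np.array([s[1] for s in model.synapses], dtype=float)
    p = mech.syn
    syn_amp = syn_gmax * 1e-6 / p.norm            # nS -> mS, peak-normalized
    fa = math.exp(-dt / p.tau_rise)
    fb = math.exp(-dt / p.tau_decay)

    evs = sorted(events, key=lambda e: e.t)
    for e in evs:
        if not 0 <= e.t <= cfg.duration:
            raise ValueError(f"event time {e.t} outside [0, {cfg.duration}]")
        if not 0 <= e.synapse < len(syn_comp):
            raise ValueError(f"event references unknown synapse {e.synapse}")
    ev_step = np.array([int(round(e.t / dt)) for e in evs], dtype=np.int64)
    ev_syn = np.array([e.synapse for e in evs], dtype=np.int64)

    i_amp = None
    i_on, i_off = 0, -1
    if i_clamp is not None:
        comp, amp_nA, t_on, t_off = i_clamp
        i_amp = np.zeros(model.n)
        i_amp[comp] = amp_nA * 1e-3               # nA -> µA
        i_on, i_off = int(round(t_on / dt)), int(round(t_off / dt))

    rec_idx = np.array(cfg.record_sites, dtype=np.int64)
    vrec = np.empty((len(rec_idx), nsteps + 1))

    bad = _run_kernel(model, v, dt, theta, nsteps, rec_idx, vrec,
                      syn_comp=syn_comp, syn_amp=syn_amp, fa=fa, fb=fb,
                      e_rev=p.e_rev, ev_step=ev_step, ev_syn=ev_syn,
                      i_amp=i_amp, i_on=i_on, i_off=i_off)
    if bad != -1:
        raise SimulationError(
            f"non-finite voltage at step {bad} (t = {bad * dt:.3f} ms, dt = {dt}); "
            "reduce dt or check compartment parameters"
        )
    times = np.arange(nsteps + 1) * dt
    return VoltageTrace(times, vrec, tuple(cfg.record_sites),
                        meta={"dt": dt, "method": cfg.method})


def steady_state(model: CompartmentalModel, i_amp_uA: np.ndarray | None = None,
                 tol: float = 1e-10, max_iter: int = 2000,
                 relax_ms: float = 2000.0) -> np.ndarray:
    """Resting membrane potential of every compartment.

    First relaxes the full dynamical system from E_leak (backward Euler, large
    steps) to land in the basin of the stable rest state, then polishes with a
    damped fixed-point iteration: gates at their steady-state values for the
    current voltage, linear conductance system solved exactly on the tree.
    Optionally a constant injected current per compartment (µA) is included.
    """
    from .mechanisms import hh_rates, ih_gate_inf

    md = _mech_arrays(model)
    mech: MechanismSet = md["params"]
    n = model.n
    area = model.area_cm2()
    gax = model.axial_conductance_mS()
    parent = model.parent

    v = np.full(n, md["e_leak"])
    if relax_ms > 0:
        dt = 0.5
        nsteps = int(relax_ms / dt)
        vrec = np.empty((1, nsteps + 1))
        _run_kernel(model, v, dt, 1.0, nsteps,
                    np.zeros(1, dtype=np.int64), vrec,
                    i_amp=i_amp_uA, i_on=0,
                    i_off=nsteps if i_amp_uA is not None else -1)

    lam = 0.3  # damping keeps the iteration on the stable root
    for _ in range(max_iter):
        m_ih = ih_gate_inf(v, mech.ih)
        am, bm, ah, bh, an, bn = hh_rates(v, mech.spike.na_vshift,
                                          mech.spike.h_extra_shift,
                                          mech.spike.k_vshift)
        m3h = (am / (am + bm)) ** 3 * (ah / (ah + bh))
        n4 = (an / (an + bn)) ** 4
        gm = (md["g_leak"] + md["g_tonic"] + md["g_h"] * m_ih
              + md["g_na"] * m3h + md["g_k"] * n4) * area
        b = (md["g_leak"] * md["e_leak"] + md["g_tonic"] * md["e_gaba"]
             + md["g_h"] * m_ih * mech.ih.e_h + md["g_na"] * m3h * mech.spike.e_na
             + md["g_k"] * n4 * mech.spike.e_k) * area
        if i_amp_uA is not None:
            b = b + i_amp_uA
        v_new = v + lam * (_tree_solve(parent, gax, gm, b) - v)
        if np.max(np.abs(v_new - v)) < tol:
            return v_new
        v = v_new
    return v


def _tree_solve(parent, gax, gdiag_extra, rhs_in):
    """Solve (A_G) v = b on the tree, A_G = axial Laplacian + diag(extra)."""
    n = len(gdiag_extra)
    d = gdiag_extra.astype(float).copy()
    rhs = rhs_in.astype(float).copy()
    a = -gax.astype(float)
    for i in range(1, n):
        d[i] += gax[i]
        d[parent[i]] += gax[i]
    for i in range(n - 1, 0, -1):
        f = a[i] / d[i]
        d[parent[i]] -= f * a[i]
        rhs[parent[i]] -= f * rhs[i]
    v = np.empty(n)
    v[0] = rhs[0] / d[0]
    for i in range(1, n):
        v[i] = (rhs[i] - a[i] * v[parent[i]]) / d[i]
    return v


def detect_spikes(trace: VoltageTrace, threshold: float = 0.0,
                  refractory: float = 2.0, site: int | None = None) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by >= refractory."""
    v = trace.values[0] if site is None else trace.site(site)
    t = trace.times
    up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
    spikes = []
    last = -np.inf
    for i in up:
        ti = t[i + 1]
        if ti - last >= refractory:
            spikes.append(ti)
            last = ti
    return np.asarray(spikes)
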