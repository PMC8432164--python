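# Methods

## The model cell

The simulated neuron is a compartmental cable model of a CA1 pyramidal cell.
A morphology (an SWC reconstruction, or the built-in synthetic cell: 20 µm
soma, 400 µm apical trunk tapering 4→1 µm, eight unbranched 150 µm obliques
of 1 µm diameter attached at seeded-random trunk positions) is split into
cylindrical compartments of at most 10 µm (`morphology.discretize`; halving
the compartment length changes total membrane area by <0.1% and passive input
resistance by <1%).  Axial resistivity is 90 Ω·cm and specific capacitance
1 µF/cm².

Membrane mechanisms, per compartment (densities in mS/cm², potentials in mV):

| mechanism | form | defaults | why |
|---|---|---|---|
| leak | g_L(V−E_L) | g_L = 0.05, E_L = −70 | resting V and input resistance in the CA1 range; unconstrained by data used here |
| tonic GABA_A | g_GABA·O·(V−E_GABA) | g_GABA = 3, O₀ = 0.025–0.03 (0.03 used), E_GABA = −65 | the ambient-GABA shunt; O is the fraction of channels open and the single dial all GABA manipulations act on |
| I_h (HCN) | g_h·m·(V−E_h); m_inf = 1/(1+e^{(V+81)/10}); τ_m bell-shaped, 10–60 ms | g_h = 0.1, E_h = −30 | deactivates with depolarization (midpoint −81); an optional distance-dependent density gradient (`dist_grad`) is off by default |
| Na, K (soma + proximal 40 µm of trunk) | HH-style m³h / n⁴ | g_Na = 150, g_K = 45, rates ×3 | all-or-none somatic spike generation |
| excitatory synapse | g_max·(e^{−t/τ₂}−e^{−t/τ₁})/N, peak-normalized | τ₁ = 2.5 ms, τ₂ = 10 ms, E_rev = 0 | the dual-exponential AMPA-like conductance |

The Na/K kinetics are classic squid-frame rate functions with three voltage
shifts chosen so the spike generator does not distort subthreshold
integration: activation curves sit 15 mV (Na) and 20 mV (K) depolarized,
removing resting window/shunt currents that would otherwise mask the tonic
GABA conductance at the soma, and the Na inactivation curve sits a further
20 mV out so that a subthreshold EPSP does not inactivate Na and suppress a
second input arriving milliseconds later.  Without the last shift the model
shows strong accommodation: the spike-probability profile develops a trough
at ±5 ms instead of a coincidence bump.

Pharmacological conditions are parameter presets: `ptx` sets O = 0 (GABA_A
blockade), `zd` sets g_h = 0 (I_h blockade), `zd+ptx` both, `gat` doubles O
(GABA-uptake blockade raises ambient GABA roughly two-fold).

## Numerics

The branched cable system is integrated implicitly (Crank–Nicolson by
default, backward Euler available) with Hines elimination on the
parent-ordered compartment tree — one elimination sweep to the root and one
back-substitution sweep, exact for the tree linear system (verified against a
dense solver to 1e−10).  Gates advance by their exact single-step exponential
relaxation at the pre-step voltage; their steady states and per-step decay
factors are linearly interpolated from tables on a 0.05 mV grid built from
the closed-form rate functions at run start.  The hot loop (compiled with
numba) therefore contains no transcendental calls and is strictly
IEEE-deterministic: identical inputs give bit-identical traces, across runs
and machines with the same libm.  dt defaults to 0.025 ms; halving it changes
somatic EPSP peaks by <0.5%.  Synaptic onsets snap to the nearest grid point
(sub-dt jitter is irrelevant at ±30 ms offsets).  Resting state is found by
relaxing the full system for 2 s (backward Euler, 0.5 ms steps) and polishing
with a damped gate-steady-state fixed point; the damping keeps the iteration
on the stable root, which plain fixed-point iteration misses when the
I_h/Na/K nonlinearities admit unstable branches.

## The coincidence-detection experiment

Forty synapses are scattered over the apical dendrites (area-weighted,
without replacement) and assigned alternately to two 20-synapse groups.  On
each trial every synapse of a group activates independently with
P_r = 0.35 (≈7 per group).  Group A fires at 50 ms; group B at offset
Δt ∈ {0, ±5, …, ±30} ms; a trial counts as a success if the soma crosses
0 mV at any point in the 150 ms sweep.  The shared per-synapse peak
conductance G_s is first calibrated by bisection — with common random numbers
across candidate values, so the success count is monotone — until exactly
coincident activation spikes the cell on 95–99 of 100 trials (nearest value
above the band if the 100-trial granularity straddles it).  Each seed plays
the role of one recorded cell: its own morphology randomness, synapse
placement and trial streams.  Trial substreams are derived from
(seed, offset index, trial) only, so different pharmacological conditions see
identical activation patterns — the in-silico analogue of the paired design,
and G_s calibrated in control is reused across that cell's conditions, as in
the experiments.

## Window estimation

The window is 2σ of a Gaussian fitted to spike probability versus offset.
The fit is P(Δt) = b + A·exp(−Δt²/2σ²) by unweighted least squares with the
centre fixed at 0 (a free-centre variant exists behind a flag).  The
non-negative floor b is needed on principle, not convenience: with
Bernoulli(0.35) activation of 20-synapse groups, calibrating coincident
success to 95–99/100 forces the effective spike threshold down to ≈9 active
synapses, and P(Binom(20, 0.35) ≥ 9) ≈ 0.24, so a single group alone spikes
the cell in roughly a quarter of trials.  That puts an offset-independent
pedestal of ≈0.4 (often more, once a condition raises excitability) under
every profile; a zero-baseline Gaussian cannot represent such data and its σ
diverges.  The window reported is the width of the coincidence bump above the
pedestal.  Fits whose σ exceeds five times the offset span, or whose bump
amplitude falls below 0.05, are flagged non-convergent — this is how
saturated profiles (background spiking at ceiling, window wider than the
sampled grid) are reported rather than silently averaged.  Per-cell σ values
are the statistical units for two-sided paired t tests between conditions.

## Sniffer-patch analysis

Single-channel records (10 kHz) are low-pass filtered at 1 kHz with a
4th-order zero-phase Butterworth, then idealized by threshold crossing
(default 1.5 pA, unitary current ≈2 pA).  The 0.2 ms minimum-duration rule is
applied symmetrically: closures shorter than 0.2 ms are bridged before
openings shorter than 0.2 ms are dropped, so noise dips do not fragment an
opening.  Simultaneous multi-channel openings are handled by rounding event
amplitude to multiples of the unitary current; the open-time fraction
t_o/t_f sums level-weighted open durations over the record and may exceed 1.
A Hill curve f(C) = f_max·Cⁿ/(EC50ⁿ + Cⁿ) maps fraction to concentration,
inverted analytically as C = EC50·(f/(f_max−f))^{1/n}.  The calibration
shipped (`SYNTHETIC_CALIBRATION`: f_max = 1, EC50 = 1200 nM, n = 1.5) is a
synthetic stand-in parameterized to pass through open-time fractions of
~0.12 at ~300 nM and ~0.39 at ~900 nM; it is not a measured curve, and any
real deployment must fit its own with `fit_hill`.

## Synthetic data

`gen_channel_trace` simulates each channel as a two-state Markov process
(continuous exponential dwell times, rasterized to the 10 kHz grid; mean open
time 10 ms by default, stationary open probability α/(α+β)), sums channels,
and adds Gaussian noise (0.35 pA before filtering — a low-noise patch,
SNR ≈ 15 after the 1 kHz filter).  Every generator returns its exact ground
truth beside the data.  What it does not emulate: subconductance states,
open-channel noise, slow baseline drift, stimulus artefacts, or bursting
(non-exponential closed-time structure).  Passing the idealization tests on
this generator therefore shows correctness of the detection logic, not
robustness to every pathology of real patch recordings; at signal-to-noise
near the detection threshold (~4), threshold idealization measurably
fragments openings and biases fractions upward of 10%, so real low-SNR
records need either heavier filtering or a model-based idealizer, which is
out of scope here.  `gen_spike_profile` draws binomial successes around a
Gaussian profile and is used to validate σ recovery (median within 10%,
bias <5% at 10 trials/offset).

## Problem sizes

The default study runs 5 cells × 4 conditions × 13 offsets × 10 trials plus
~800 calibration trials per cell, about 9,000 sweep simulations of a
~160-compartment cell for 150 ms at dt = 0.025 ms — minutes on one core.
Sniffer analyses use 60 s records (600,000 samples).

## Known limitations

- Dendrites are passive.  The experimental literature attributes the large
  coincidence-window effects of I_h and GABA_A blockade partly to active
  dendritic amplification of small kinetic changes; this model reproduces the
  directions and ordering of the effects but not their experimental
  magnitudes.  In particular the I_h (ZD) effect is small here — with uniform
  g_h = 0.1 mS/cm² the I_h shunt is ~10% of total membrane conductance — and
  under GABA_A blockade the window frequently exceeds the ±30 ms grid
  (reported as a saturated, non-convergent fit).
- Removing the shunt also raises EPSP amplitude in a passive cell, so
  blockade conditions raise background (single-group) spiking as well as
  widening the bump; both effects point the same way, but the pedestal limits
  how precisely very wide windows can be measured at 10 trials/offset.
- The tonic-GABA open fraction O is a configuration scalar, not a fitted
  kinetic state; chloride dynamics, GABA_B signalling and temperature
  corrections are not modelled.
- Quantitative window values from a full 3D-reconstructed CA1 cell require
  that morphology and its channel-kinetics fit; with an SWC file in hand,
  `morphology.source: swc` runs the identical protocol, but no quantitative
  match to any particular reconstructed cell is claimed for the synthetic
  morphology.
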