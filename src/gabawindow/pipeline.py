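"""End-to-end study drivers, configuration, and run manifests.

``run_study`` executes the whole in-silico experiment — build cell, place
synapses, calibrate G_s, sweep offsets under each pharmacological condition,
fit windows, compare to control — across several seeds ("cells").
``run_sniffer`` executes the single-channel chain on generated or loaded
traces.  Every run writes a JSON manifest of all resolved parameters before
computing, so no default is silent and deterministic stages re-run
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mechanisms import MechanismSet, apply_condition, attach_mechanisms
from .morphology import discretize, make_synthetic_ca1, read_swc
from .protocol import (ProtocolConfig, calibrate_gs, place_synapses,
                       run_coincidence_sweep, set_gs)
from .sniffer import (SYNTHETIC_CALIBRATION, detect_openings, estimate_gaba,
                      lowpass_filter, open_time_fraction, read_trace)
from .synthetic_data import ChannelGenParams, gen_channel_trace
from .window_stats import fit_gaussian, paired_window_test, summarize_windows

DEFAULT_STUDY = {
    "morphology": {"source": "synthetic", "trunk_length": 400.0, "n_obliques": 8,
                   "oblique_length": 150.0, "max_seg_length": 10.0, "swc_path": None},
    "protocol": {"n_synapses": 40, "p_release": 0.35, "first_onset": 50.0,
                 "offsets": [float(o) for o in range(-30, 31, 5)],
                 "trials_per_offset": 10, "calibration_trials": 100,
                 "spike_target": 0.9, "duration": 150.0},
    "solver": {"dt": 0.025, "method": "cn"},
    "conditions": ["control", "zd", "ptx", "zd+ptx"],
    "seeds": [1, 2, 3, 4, 5],
}


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(x).items()}
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def write_manifest(out_dir: Path, config: dict, stage: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": _jsonable(config),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def build_cell(config: dict, condition: str, seed: int,
               mech: MechanismSet = MechanismSet()):
    """Morphology -> compartments -> mechanisms -> synapses for one cell."""
    mcfg = config["morphology"]
    if mcfg["source"] == "swc":
        morph = read_swc(mcfg["swc_path"])
    else:
        morph = make_synthetic_ca1(mcfg["trunk_length"], mcfg["n_obliques"],
                                   mcfg["oblique_length"], seed=seed)
    model = discretize(morph, mcfg["max_seg_length"])
    attach_mechanisms(model, apply_condition(mech, condition))
    pcfg = config["protocol"]
    groups = place_synapses(model, pcfg["n_synapses"], seed=seed)
    return model, groups


def _protocol_config(config: dict, seed: int) -> ProtocolConfig:
    p, s = config["protocol"], config["solver"]
    return ProtocolConfig(
        first_onset=p["first_onset"], offsets=tuple(p["offsets"]),
        trials_per_offset=p["trials_per_offset"],
        calibration_trials=p["calibration_trials"],
        spike_target=p["spike_target"], duration=p["duration"],
        dt=s["dt"], seed=seed,
    )


def run_study(config: dict | None = None, out_dir=None,
              mech: MechanismSet = MechanismSet()) -> dict:
    """Run the full coincidence-window study.

    Each seed plays the role of one recorded cell: its own synapse placement
    and trial randomness, with G_s calibrated once under the control condition
    and reused (paired design) across conditions.  Returns a report dict:
    per-condition per-seed sigmas, mean 2σ ± SD, and paired t tests vs control.
    """
    config = _merge(DEFAULT_STUDY, config)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir:
        write_manifest(out_dir, config, "study")

    conditions = list(config["conditions"])
    report = {"config": _jsonable(config), "conditions": {}, "calibration": {}}
    sigmas: dict[str, list[float]] = {c: [] for c in conditions}
    estimates: dict[str, list] = {c: [] for c in conditions}
    profiles_rows = []

    for seed in config["seeds"]:
        pcfg = _protocol_config(config, seed)
        model, groups = build_cell(config, "control", seed, mech)
        g_s = calibrate_gs(model, groups, pcfg)
        report["calibration"][str(seed)] = {"g_s_nS": g_s}
        for cond in conditions:
            cmodel, cgroups = build_cell(config, cond, seed, mech)
            set_gs(cmodel, g_s)
            profile = run_coincidence_sweep(cmodel, cgroups, pcfg)
            est = fit_gaussian(profile)
            sigmas[cond].append(est.sigma)
            estimates[cond].append(est)
            for off, p in zip(profile.offsets, profile.spike_probability):
                profiles_rows.append({"seed": seed, "condition": cond,
                                      "offset_ms": off, "p_spike": p,
                                      "n_trials": profile.trials})

    for cond in conditions:
        conv = [e.converged for e in estimates[cond]]
        good = [e for e in estimates[cond] if e.converged]
        entry = {"per_seed_sigma": sigmas[cond], "converged": conv,
                 "n_converged": len(good)}
        if good:
            # Saturated profiles (window wider than the offset grid) do not
            # converge and are excluded from the summary, not averaged in.
            mean2s, sd2s = summarize_windows(good)
            entry["mean_2sigma"] = mean2s
            entry["sd_2sigma"] = sd2s
        else:
            entry["mean_2sigma"] = None
            entry["sd_2sigma"] = None
        if cond != "control" and "control" in sigmas:
            ctrl_conv = [e.converged for e in estimates["control"]]
            pairs = [(a, b) for a, b, ca, cb in zip(
                sigmas[cond], sigmas["control"], conv, ctrl_conv) if ca and cb]
            if len(pairs) >= 2:
                try:
                    cmp_ = paired_window_test([p[0] for p in pairs],
                                              [p[1] for p in pairs])
                    entry["t_vs_control"] = cmp_.t
                    entry["p_vs_control"] = cmp_.p
                    entry["n_pairs"] = cmp_.n_pairs
                except ValueError:
                    entry["t_vs_control"] = None
        report["conditions"][cond] = entry

    if out_dir:
        pd.DataFrame(profiles_rows).to_csv(out_dir / "profiles.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


DEFAULT_SNIFFER = {
    "traces": None,            # list of file paths, or None to generate
    "generator": {"alpha": 11.1, "beta": 100.0, "unitary_amp": 2.0,
                  "noise_sd": 0.35, "n_channels": 1, "rate": 10000.0,
                  "duration": 60.0, "seed": 1},
    "filter_cutoff": 1000.0,
    "threshold": 1.5,
    "min_duration": 0.2,
    "unitary_amp": 2.0,
    "calibration": None,       # {f_max, ec50, n} or None for the synthetic curve
}


def run_sniffer(config: dict | None = None, out_dir=None) -> dict:
    """Run the sniffer chain on each trace: filter, idealize, t_o/t_f, [GABA]."""
    config = _merge(DEFAULT_SNIFFER, config)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir:
        write_manifest(out_dir, config, "sniffer")

    if config["traces"]:
        traces = [(str(p), read_trace(p)) for p in config["traces"]]
        truths = [None] * len(traces)
    else:
        p = ChannelGenParams(**config["generator"])
        trace, truth = gen_channel_trace(p)
        traces = [("generated", trace)]
        truths = [truth]

    if config["calibration"]:
        from .sniffer import HillCalibration
        c = config["calibration"]
        cal = HillCalibration(c["f_max"], c["ec50"], c["n"])
    else:
        cal = SYNTHETIC_CALIBRATION

    results = []
    for (name, trace), truth in zip(traces, truths):
        filtered = lowpass_filter(trace, config["filter_cutoff"])
        events = detect_openings(filtered, threshold=config["threshold"],
                                 min_duration=config["min_duration"],
                                 unitary_amp=config["unitary_amp"])
        frac = open_time_fraction(events)
        entry = {"trace": name, "n_events": len(events), "open_time_fraction": frac}
        if 0 < frac < cal.f_max:
            entry["gaba_nM"] = estimate_gaba(frac, cal)
        if truth is not None:
            from .synthetic_data import true_open_fraction
            entry["true_open_fraction"] = true_open_fraction(truth)
        results.append(entry)
        if out_dir:
            pd.DataFrame([{"start_ms": e.start, "duration_ms": e.duration,
                           "level": e.level} for e in events.events]).to_csv(
                out_dir / f"events_{Path(name).stem}.csv", index=False)

    report = {"config": _jsonable(config),
              "calibration": _jsonable(cal), "results": results}
    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report
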