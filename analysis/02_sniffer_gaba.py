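#!/usr/bin/env python
"""Sniffer-patch read-out of an activity-driven rise in extracellular GABA.

Emulates the burst experiment: a patch reporting ambient [GABA] at a ~300 nM
baseline and during the ~900 nM elevation that follows a stimulus burst.
Each condition is a 60 s two-state Markov channel record (10 kHz, Gaussian
noise) generated at the open probability the Hill calibration assigns to that
concentration.  The records are low-pass filtered at 1 kHz, idealized
(1.5 pA-scale threshold, 0.2 ms minimum event duration), summarized as
open-time fractions t_o/t_f, and inverted back to [GABA].

The calibration curve here is a synthetic stand-in (the published fit
parameters are not available); it passes through open-time fractions of
~0.12 at 300 nM and ~0.39 at 900 nM.

Writes results/sniffer/{baseline,burst}/ event tables and a summary JSON.
"""

import json
from pathlib import Path

from gabawindow.pipeline import run_sniffer
from gabawindow.sniffer import SYNTHETIC_CALIBRATION
from gabawindow.synthetic_data import channel_params_for_gaba

OUT = Path(__file__).resolve().parent.parent / "results" / "sniffer"


def main():
    summary = {}
    for label, gaba_nM, seed in (("baseline", 300.0, 101), ("burst", 900.0, 102)):
        p = channel_params_for_gaba(gaba_nM, SYNTHETIC_CALIBRATION,
                                    duration=60.0, seed=seed)
        rep = run_sniffer({"generator": {
            "alpha": p.alpha, "beta": p.beta, "unitary_amp": p.unitary_amp,
            "noise_sd": p.noise_sd, "duration": p.duration, "seed": p.seed}},
            out_dir=OUT / label)
        r = rep["results"][0]
        summary[label] = {"true_gaba_nM": gaba_nM,
                          "open_time_fraction": r["open_time_fraction"],
                          "estimated_gaba_nM": r.get("gaba_nM"),
                          "n_events": r["n_events"]}
        print(f"{label:>9}: [GABA] = {gaba_nM:.0f} nM -> t_o/t_f = "
              f"{r['open_time_fraction']:.3f} ({r['n_events']} openings) -> "
              f"[GABA] estimate {r.get('gaba_nM', float('nan')):.0f} nM")
    ratio = summary["burst"]["open_time_fraction"] / \
        summary["baseline"]["open_time_fraction"]
    print(f"burst/baseline open-time fraction ratio: {ratio:.2f} "
          "(a ~3x rise for a 300->900 nM step)")
    summary["fraction_ratio"] = ratio
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
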