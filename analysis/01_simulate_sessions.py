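#!/usr/bin/env python
"""Simulate the two-group imaging sessions for both neuronal populations.

Generates raw fluorescence traces (and one small rendered movie for the
motion-correction benchmark) for the excitatory-like design (161 treated vs
145 control cells) and the PV-like design (15 vs 24), with the treated
group's event rate doubled (excitatory) or halved (PV) in the 11-15-min
window.  Full traces and the movie go to scratch/ (large, regenerable);
a small design summary goes to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from catrans import SessionSpec, simulate_movie, simulate_traces
from catrans.scenarios import EXCITATORY, PV

SEED = 20260922
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for scen in (EXCITATORY, PV):
        for gi, (label, rates, n) in enumerate([
                ("control", scen.control_rates, scen.n_control),
                ("treated", scen.treated_rates, scen.n_treated)]):
            spec = SessionSpec(n_cells=n, rate_per_window=rates, seed=SEED * 2 + gi)
            F, gt = simulate_traces(spec)
            np.savez_compressed(SCRATCH / f"{scen.name}_{label}.npz",
                                F=F, seed=spec.seed,
                                event_counts=gt.events_per_window(
                                    spec.frames_per_window, spec.n_windows))
            inj = gt.events_per_window(spec.frames_per_window, spec.n_windows)
            rows.append({"population": scen.name, "group": label, "n_cells": n,
                         **{f"rate_w{k+1}": r for k, r in enumerate(rates)},
                         "injected_events_per_cell": inj.sum() / n})
            print(f"{scen.name}/{label}: {n} cells, "
                  f"{inj.sum()} injected events ({inj.sum()/n:.1f}/cell)")

    # a short jittered movie for the registration benchmark
    mspec = SessionSpec(n_cells=4, rate_per_window=(20.0,), n_frames=80,
                        noise_sd=3.0, drift_amplitude=0.0, motion_sd_px=0.5,
                        seed=SEED)
    movie, gt = simulate_movie(mspec, height=96, width=96)
    movie.save(SCRATCH / "jittered_movie.tif")
    pd.DataFrame(gt.shifts, columns=["dx_px", "dy_px"]).to_csv(
        SCRATCH / "jittered_movie_true_shifts.csv", index_label="frame")
    print(f"movie: {movie.n_frames} frames, jitter SD {mspec.motion_sd_px} px")

    pd.DataFrame(rows).to_csv(RESULTS / "01_session_design.csv", index=False)
    (SCRATCH / "meta.json").write_text(json.dumps({"seed": SEED}))
    print(f"design summary -> {RESULTS / '01_session_design.csv'}")


if __name__ == "__main__":
    main()
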