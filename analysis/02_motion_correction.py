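#!/usr/bin/env python
"""Benchmark rigid motion correction on the simulated jittered movie.

Estimates per-frame shifts by phase cross-correlation, compares them to the
injected ground truth, and verifies that correction reduces the
frame-to-template error.  Writes a one-row summary to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from catrans import Movie, correct

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sessions"
RESULTS = ROOT / "results"


def main() -> None:
    movie_path = SCRATCH / "jittered_movie.tif"
    if not movie_path.exists():
        raise SystemExit("run analysis/01_simulate_sessions.py first")
    movie = Movie.load(movie_path)
    truth = pd.read_csv(SCRATCH / "jittered_movie_true_shifts.csv")[
        ["dx_px", "dy_px"]].to_numpy()
    corrected, est = correct(movie)
    rmse = float(np.sqrt(np.mean((est.shifts - truth) ** 2)))

    def template_mse(m):
        data = m.data.astype(float)
        return float(np.mean((data - data.mean(axis=0)) ** 2))

    before, after = template_mse(movie), template_mse(corrected)
    summary = pd.DataFrame([{
        "n_frames": movie.n_frames,
        "true_jitter_sd_px": truth.std(),
        "shift_rmse_px": rmse,
        "template_mse_before": before,
        "template_mse_after": after,
    }])
    summary.to_csv(RESULTS / "02_motion_correction.csv", index=False)
    print(f"shift RMSE {rmse:.3f} px; frame-to-template MSE {before:.1f} -> {after:.1f}")
    assert rmse < 0.25 and after < before


if __name__ == "__main__":
    main()
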