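#!/usr/bin/env python
"""Sliding-window mean-entropy profile of the synthetic trajectory.

Reads the trajectory written by 01_simulate_data.py (regenerating it if
absent), computes per-gene BUB entropy over windows of 50 cells stepping
by 10, and reports where the mean-entropy peak falls relative to the
planted variability bump.  Writes the per-window profile and a peak
summary under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from entrocell.entropy import CoefficientCache
from entrocell.io import write_table
from entrocell.simulate import SyntheticTrajectoryConfig, simulate_trajectory
from entrocell.trajectory import (
    PathwaySpec,
    WindowSpec,
    build_ordering,
    peak_summary,
    profile_table,
    window_profiles,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    cfg = SyntheticTrajectoryConfig(seed=1)
    matrix, ann, pt, truth = simulate_trajectory(cfg)
    pathway = PathwaySpec("trajectory", [f"stage{i+1}" for i in range(cfg.n_stages)])
    ordering = build_ordering(matrix, ann, pt, pathway)
    spec = WindowSpec()  # 50 cells, step 10
    series = window_profiles(ordering, matrix, spec, "bub", CoefficientCache())
    pk = peak_summary(series)

    idx_center = int(np.argmin(np.abs(truth.pseudotime - cfg.bump_center)))
    w_center = int(np.argmin(np.abs(series.window_starts + spec.window_size // 2 - idx_center)))

    write_table(profile_table(series), RESULTS / "trajectory_profile.tsv",
                {"estimator": "bub", "window_size": spec.window_size, "step": spec.step,
                 "seed": cfg.seed})
    summary = pd.DataFrame([{
        "n_windows": series.n_windows,
        "argmax_window": pk.argmax_window,
        "bump_center_window": w_center,
        "offset_windows": pk.argmax_window - w_center,
        "is_transient": pk.is_transient,
        "peak_mean_entropy": round(pk.peak_mean_entropy, 4),
        "first_window_mean_entropy": round(float(series.mean_entropy[0]), 4),
        "last_window_mean_entropy": round(float(series.mean_entropy[-1]), 4),
    }])
    write_table(summary, RESULTS / "trajectory_peak_summary.tsv", {"seed": cfg.seed})
    print(f"{series.n_windows} windows; mean-entropy argmax at window "
          f"{pk.argmax_window} (bump-centre window {w_center}, offset "
          f"{pk.argmax_window - w_center:+d}); transient={pk.is_transient}")
    print(f"profile -> {RESULTS / 'trajectory_profile.tsv'}")


if __name__ == "__main__":
    main()
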