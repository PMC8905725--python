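#!/usr/bin/env python
"""Generate the two synthetic study designs and persist them for reuse.

Writes the default single-pathway trajectory (2,000 cells x 2,000 genes,
transient dispersion bump at pseudotime 0.5) and the two-group HSC design
(control vs 1.5x dispersion-inflated) as Matrix Market triplets under
scratch/datasets/, plus a small manifest and ground-truth summary under
results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from entrocell.io import write_matrix_market_triplet, write_table
from entrocell.simulate import (
    SyntheticTrajectoryConfig,
    TwoGroupHSCConfig,
    simulate_trajectory,
    simulate_two_group_hsc,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "datasets"
RESULTS = ROOT / "results"

TRAJ_SEED = 1
TWO_GROUP_SEED = 42


def main() -> None:
    traj_cfg = SyntheticTrajectoryConfig(seed=TRAJ_SEED)
    matrix, ann, pt, truth = simulate_trajectory(traj_cfg)
    out = DATA / "trajectory"
    write_matrix_market_triplet(matrix, out / "matrix")
    write_table(ann, out / "annotation.tsv")
    write_table(pt, out / "pseudotime.tsv")
    write_table(truth.genes, out / "ground_truth.tsv")
    print(f"trajectory: {matrix.n_genes} genes x {matrix.n_cells} cells -> {out}")

    tg_cfg = TwoGroupHSCConfig(seed=TWO_GROUP_SEED)
    ctrl, case = simulate_two_group_hsc(tg_cfg)
    write_matrix_market_triplet(ctrl, DATA / "two_group" / "control")
    write_matrix_market_triplet(case, DATA / "two_group" / "case")
    print(f"two-group: control/case {ctrl.n_genes} x {ctrl.n_cells} -> {DATA / 'two_group'}")

    RESULTS.mkdir(exist_ok=True)
    manifest = {
        "trajectory": {"seed": TRAJ_SEED, "n_genes": matrix.n_genes,
                       "n_cells": matrix.n_cells,
                       "bump_center": traj_cfg.bump_center,
                       "bump_amplitude": traj_cfg.bump_amplitude},
        "two_group": {"seed": TWO_GROUP_SEED, "n_genes": ctrl.n_genes,
                      "n_cells_per_group": ctrl.n_cells,
                      "dispersion_ratio": tg_cfg.dispersion_ratio},
    }
    (RESULTS / "datasets_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"manifest -> {RESULTS / 'datasets_manifest.json'}")


if __name__ == "__main__":
    main()
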