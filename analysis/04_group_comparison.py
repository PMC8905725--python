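#!/usr/bin/env python
"""Subsampled entropy comparison of control vs dispersion-inflated HSCs.

Generates the two-group design (shared means, case NB dispersion ratio
1.5), runs 100 subsamplings of 700 cells with a two-sided Wilcoxon
rank-sum on per-gene BUB entropy, and tallies the significance tiers —
the synthetic counterpart of comparing a patient stem-cell compartment
with an age-matched control.  Outputs go under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from entrocell.compare import ComparisonConfig, hsc_entropy_comparison, tier_table
from entrocell.entropy import CoefficientCache
from entrocell.io import write_table
from entrocell.simulate import TwoGroupHSCConfig, simulate_two_group_hsc

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    gen_cfg = TwoGroupHSCConfig(seed=42)  # rho = 1.5
    ctrl, case = simulate_two_group_hsc(gen_cfg)
    comp = ComparisonConfig(n_subsamples=100, subsample_size=700, seed=1)
    result = hsc_entropy_comparison(case, ctrl, comp, CoefficientCache())

    d = result.table["mean_entropy_a"] - result.table["mean_entropy_b"]
    print(f"case - control mean entropy: {d.mean():+.4f} nats "
          f"(min {d.min():+.4f}, every subsample positive: {(d > 0).all()})")
    print("tier tallies:", result.tier_counts)

    meta = {"generator_seed": gen_cfg.seed, "comparison_seed": comp.seed,
            "test_variant": result.test_variant, "estimator": comp.estimator,
            "subsample_size": comp.subsample_size}
    write_table(result.table, RESULTS / "comparison_subsamples.tsv", meta)
    write_table(tier_table(result), RESULTS / "comparison_tier_tally.tsv", meta)
    print(f"tables -> {RESULTS}")


if __name__ == "__main__":
    main()
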