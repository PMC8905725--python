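# entrocell

Intercellular Shannon-entropy profiling of single-cell RNA-seq
differentiation trajectories.

## The problem

During differentiation, is cell-to-cell gene expression variability flat
(as an instructive, program-following model would predict) or does it
surge transiently where lineage decisions are made (as a stochastic model
predicts)? `entrocell` quantifies cell-to-cell variability as the
**intercellular entropy** of each gene: the Shannon entropy, in nats, of
the gene's raw-count distribution across the N cells of a pseudotime
window,

    H = - sum_k p(k) ln p(k),

estimated over a sliding window (default 50 cells, step 10) along a
supplied pseudotime ordering. The mean of this per-gene entropy over the
whole gene set gives a trajectory-level variability profile; a transient
peak of that profile marks a stage of elevated cellular indetermination.

With N = 50 cells and counts spanning up to m levels, N/m is small and the
naive (plugin) entropy estimator is badly biased. The package therefore
implements the family of *linear* estimators on the occupancy vector
h (h_j = number of expression levels held by exactly j cells):

* plugin (maximum likelihood), Miller–Madow, jackknife — as comparators;
* the **best upper bound (BUB)** estimator, whose weights a_j minimise a
  computable bound on worst-case RMS error,
  `sqrt((m·max|f−g|)² + N·max|Δa|²)`, where f is the estimator's Bernstein
  form and g(p) = −p ln p — the estimator of choice in the undersampled
  regime.

Downstream analyses: per-gene **delta-entropy** and **delta-expression**
(max − min over windows), top-k gene rankings and their cross-pathway
overlaps, the delta correlation, transcription-factor subsets, and a
repeated-subsampling Wilcoxon comparison of stem-cell compartments between
samples (e.g. patient vs control), with dissociation-gene exclusion and
per-cell-type equalizing subsampling.

A first-class synthetic-data module generates negative-binomial count
matrices with smooth mean trajectories, a programmable transient
dispersion bump, pathway-specific switch genes vs shared housekeeping
genes, and a two-group control-vs-inflated design — with ground-truth
oracles for end-to-end validation.

## Worked example

```python
from entrocell import (
    SyntheticTrajectoryConfig, simulate_trajectory, PathwaySpec, WindowSpec,
    build_ordering, window_profiles, peak_summary, CoefficientCache,
)

cfg = SyntheticTrajectoryConfig(seed=1)          # 2000 cells x 2000 genes,
matrix, ann, pt, truth = simulate_trajectory(cfg)  # dispersion bump at t=0.5
pathway = PathwaySpec("trajectory", [f"stage{i+1}" for i in range(cfg.n_stages)])
ordering = build_ordering(matrix, ann, pt, pathway)
series = window_profiles(ordering, matrix, WindowSpec(), "bub", CoefficientCache())
pk = peak_summary(series)
print(series.n_windows, pk.argmax_window, pk.is_transient)
```

prints `196 96 True`: 196 sliding windows (floor((2000−50)/10)+1), with the
mean-entropy maximum at window 96 — one window away from the window
containing the planted bump centre (pseudotime 0.5) — and the peak is
transient (it exceeds both ends of the profile). The same run via the
analysis drivers reports:

```
$ python analysis/02_entropy_profiles.py
196 windows; mean-entropy argmax at window 96 (bump-centre window 97, offset -1); transient=True

$ python analysis/04_group_comparison.py
case - control mean entropy: +0.0462 nats (min +0.0447, every subsample positive: True)
tier tallies: {0.05: 100, 0.01: 100, 0.001: 100, 0.0001: 100}
```

i.e. the dispersion-inflated ("MDS-like") group shows higher mean
intercellular entropy than its control in every one of 100 subsamples of
700 cells, and every rank-sum test lands below p = 0.0001.

The numbered scripts under `analysis/` run the full narrative (simulate →
profile → delta rankings → group comparison) and write their tables under
`results/`; `analysis/03_delta_rankings.py` shows the ranking dissociation:
the 20 highest delta-entropy genes are pathway-private switch genes (0
shared between pathways) while the 20 highest delta-expression genes are
housekeeping genes common to essentially all pathways (18/20 in all four).

## Command-line interface

A thin `entrocell` CLI wraps the same library calls for shell pipelines:

```
entrocell simulate        --config sim.yaml  --out data/
entrocell qc              --matrix data/matrix --out data/filtered
entrocell entropy-profile --config prof.yaml --out profiles/
entrocell delta           --config delta.yaml --out deltas/
entrocell compare         --config cmp.yaml  --out comparison/
```

All inputs are 10x-style Matrix Market triplets or dense (gzipped)
TSV/CSV; all outputs are TSV with a reproducibility header (package
version, config hash, seed, estimator).

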