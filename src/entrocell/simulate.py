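"""Synthetic scRNA-seq generators with ground truth.

Two designs mirror the statistical structure the entropy analysis assumes:

* :func:`simulate_trajectory` — a single differentiation pathway: cells on
  a uniform latent pseudotime grid, negative-binomial counts whose means
  vary smoothly with pseudotime, a programmable transient dispersion bump
  (elevated cell-to-cell variability around a chosen pseudotime), and
  three gene classes: pathway "switch" genes (sigmoid mean transitions at
  scattered switch times), "housekeeping" genes (large smooth mean ramps
  with low dispersion), and flat "noise" genes.  A family variant builds
  several pathways sharing housekeeping/noise genes while each pathway's
  switch genes are private to it.
* :func:`simulate_two_group_hsc` — a control vs dispersion-inflated
  ("MDS-like") stem-cell design: identical per-gene mean vectors, with the
  case group's negative-binomial size parameter divided by a dispersion
  ratio rho >= 1 (smaller size = more overdispersion = higher
  cell-to-cell entropy at fixed mean).

Counts are drawn as gamma-Poisson mixtures (the exact NB sampling scheme)
with a lognormal per-cell library-size multiplier.  Monte-Carlo oracles
for the true entropy of any gene/window mixture support estimator
validation end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CountMatrix

GENE_CLASSES = ("switch", "housekeeping", "noise")


@dataclass(frozen=True)
class SyntheticTrajectoryConfig:
    """One pathway's generative parameters.

    Means: switch genes follow mu_low + (mu_high - mu_low) * sigmoid of
    slope ``switch_slope`` centred at a per-gene switch time scattered
    uniformly in ``switch_band``; housekeeping genes ramp linearly from
    hk_mu_start to a per-gene endpoint around hk_mu_end (lognormal scatter
    hk_amp_sigma, shared across pathways in the family variant); noise
    genes are flat with per-gene lognormal means.

    Dispersion: every gene's NB size parameter is its class baseline
    divided by (1 + A * exp(-(t - c)^2 / (2 w^2))) — the transient
    variability bump of amplitude ``bump_amplitude`` at pseudotime
    ``bump_center``.

    Cells carry a lognormal library-size multiplier (sigma ``lib_sigma``,
    unit mean) and are labelled into ``n_stages`` contiguous pseudotime
    segments ("stage1"..) for window labelling.
    """

    n_cells: int = 2000
    n_switch_genes: int = 300
    n_housekeeping_genes: int = 200
    n_noise_genes: int = 1500
    mu_low: float = 0.5
    mu_high: float = 8.0
    switch_slope: float = 15.0
    switch_band: tuple[float, float] = (0.2, 0.8)
    hk_mu_start: float = 5.0
    hk_mu_end: float = 50.0
    hk_amp_sigma: float = 0.3
    hk_size: float = 50.0
    noise_mu_log_mean: float = 2.0
    noise_mu_log_sigma: float = 0.5
    base_size: float = 8.0
    bump_amplitude: float = 3.0
    bump_center: float = 0.5
    bump_width: float = 0.04
    lib_sigma: float = 0.05
    n_stages: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_stages) < 1 or self.n_cells < self.n_stages:
            raise ConfigError("need n_cells >= n_stages >= 1")
        if min(self.mu_low, self.mu_high, self.hk_mu_start, self.hk_mu_end) <= 0:
            raise ConfigError("all means must be positive")
        if min(self.base_size, self.hk_size) <= 0:
            raise ConfigError("NB size parameters must be positive")
        if self.bump_amplitude < 0:
            raise ConfigError("bump amplitude must be >= 0")
        if self.bump_width <= 0 or self.lib_sigma < 0:
            raise ConfigError("invalid bump_width or lib_sigma")
        lo, hi = self.switch_band
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("switch_band must be an ordered sub-interval of [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_switch_genes + self.n_housekeeping_genes + self.n_noise_genes


@dataclass(frozen=True)
class TrajectoryTruth:
    """Generator ground truth: per-gene class/parameters and the bump location."""

    config: SyntheticTrajectoryConfig
    genes: pd.DataFrame          # gene_id, gene_class, switch_time, flat params
    pseudotime: np.ndarray
    library_sizes: np.ndarray


def _bump_factor(t: np.ndarray, cfg: SyntheticTrajectoryConfig) -> np.ndarray:
    A, c, w = cfg.bump_amplitude, cfg.bump_center, cfg.bump_width
    return 1.0 + A * np.exp(-((t - c) ** 2) / (2.0 * w**2))


def _balanced_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    d = np.ones(n)
    d[: n // 2] = -1.0
    rng.shuffle(d)
    return d


def _gene_universe(cfg: SyntheticTrajectoryConfig, rng: np.random.Generator):
    """Per-gene class labels and gene-level parameters (shared across a family)."""
    ids, classes = [], []
    for i in range(cfg.n_switch_genes):
        ids.append(f"SW{i:04d}")
        classes.append("switch")
    for i in range(cfg.n_housekeeping_genes):
        ids.append(f"HK{i:04d}")
        classes.append("housekeeping")
    for i in range(cfg.n_noise_genes):
        ids.append(f"NS{i:04d}")
        classes.append("noise")
    hk_end = cfg.hk_mu_end * np.exp(
        rng.normal(0.0, cfg.hk_amp_sigma, cfg.n_housekeeping_genes)
    )
    # ramp direction: exactly half the housekeeping genes decline through
    # the trajectory, so the aggregate mean level stays roughly level
    hk_dir = _balanced_directions(cfg.n_housekeeping_genes, rng)
    noise_mu = np.exp(
        rng.normal(cfg.noise_mu_log_mean, cfg.noise_mu_log_sigma, cfg.n_noise_genes)
    )
    return ids, classes, hk_end, hk_dir, noise_mu


def trajectory_parameters(
    cfg: SyntheticTrajectoryConfig,
    switch_times: np.ndarray | None = None,
    switch_directions: np.ndarray | None = None,
    universe: tuple | None = None,
    rng: np.random.Generator | None = None,
):
    """Deterministic NB parameter fields: mean and size matrices (genes x cells).

    Used both by the generator and by the Monte-Carlo entropy oracle, so
    oracle and data share exactly the same parameters.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    t = np.linspace(0.0, 1.0, cfg.n_cells)
    ids, classes, hk_end, hk_dir, noise_mu = (
        universe if universe is not None else _gene_universe(cfg, rng)
    )
    if switch_times is None:
        lo, hi = cfg.switch_band
        switch_times = rng.uniform(lo, hi, cfg.n_switch_genes)
    if switch_directions is None:
        # Exactly half the pathway genes are induced, half repressed, so
        # the aggregate mean level is stable while transitions still
        # create a localized surge of cell-to-cell variability.
        switch_directions = _balanced_directions(cfg.n_switch_genes, rng)
    lib = np.exp(rng.normal(-cfg.lib_sigma**2 / 2.0, cfg.lib_sigma, cfg.n_cells))

    G = cfg.n_genes
    mean = np.empty((G, cfg.n_cells))
    size = np.empty((G, cfg.n_cells))
    bump = _bump_factor(t, cfg)
    sw = slice(0, cfg.n_switch_genes)
    hk = slice(cfg.n_switch_genes, cfg.n_switch_genes + cfg.n_housekeeping_genes)
    ns = slice(cfg.n_switch_genes + cfg.n_housekeeping_genes, G)
    # switch: sigmoid between mu_low and mu_high at per-gene switch times;
    # direction +1 = induced (low -> high), -1 = repressed (high -> low)
    z = (
        cfg.switch_slope
        * (t[None, :] - switch_times[:, None])
        * switch_directions[:, None]
    )
    mean[sw] = cfg.mu_low + (cfg.mu_high - cfg.mu_low) / (1.0 + np.exp(-z))
    size[sw] = cfg.base_size / bump[None, :]
    # housekeeping: linear ramp (rising or falling per gene), low dispersion
    frac = np.where(hk_dir[:, None] > 0, t[None, :], 1.0 - t[None, :])
    mean[hk] = cfg.hk_mu_start + (hk_end[:, None] - cfg.hk_mu_start) * frac
    size[hk] = cfg.hk_size / bump[None, :]
    # noise: flat per-gene means
    mean[ns] = np.repeat(noise_mu[:, None], cfg.n_cells, axis=1)
    size[ns] = cfg.base_size / bump[None, :]
    mean *= lib[None, :]

    genes = pd.DataFrame(
        {
            "gene_id": ids,
            "gene_class": classes,
            "switch_time": np.concatenate(
                [switch_times, np.full(G - cfg.n_switch_genes, np.nan)]
            ),
            "switch_direction": np.concatenate(
                [switch_directions, np.full(G - cfg.n_switch_genes, np.nan)]
            ),
        }
    )
    truth = TrajectoryTruth(config=cfg, genes=genes, pseudotime=t, library_sizes=lib)
    return mean, size, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Gamma-Poisson (exact negative binomial) sampling."""
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam).astype(np.int64)


def _stage_labels(n_cells: int, n_stages: int) -> list[str]:
    edges = np.linspace(0, n_cells, n_stages + 1).astype(int)
    labels = []
    for s in range(n_stages):
        labels.extend([f"stage{s + 1}"] * (edges[s + 1] - edges[s]))
    return labels


def simulate_trajectory(cfg: SyntheticTrajectoryConfig):
    """One pathway: (CountMatrix, annotation, pseudotime table, ground truth)."""
    rng = np.random.default_rng(cfg.seed)
    mean, size, truth = trajectory_parameters(cfg, rng=rng)
    counts = _nb_draw(rng, mean, size)
    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    matrix = CountMatrix(list(truth.genes["gene_id"]), cell_ids, counts)
    annotation = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "population_label": _stage_labels(cfg.n_cells, cfg.n_stages),
            "sample_id": "synthetic",
        }
    )
    pseudotime = pd.DataFrame({"cell_id": cell_ids, "pseudotime": truth.pseudotime})
    return matrix, annotation, pseudotime, truth


def simulate_pathway_family(cfg: SyntheticTrajectoryConfig, n_pathways: int = 4):
    """Several pathways over one gene universe.

    Housekeeping and noise genes (ids, means, ramps) are shared across
    pathways; each pathway receives its own private block of switch genes
    (named SW<p>_..), flat at mu_low everywhere except in its own pathway.
    Returns {pathway_name: (matrix, annotation, pseudotime, truth)}.
    """
    if n_pathways < 2:
        raise ConfigError("a pathway family needs at least 2 pathways")
    master = np.random.default_rng(cfg.seed)
    _, _, hk_end, hk_dir, noise_mu = _gene_universe(cfg, master)
    sw_ids = [
        f"SW{p + 1}_{i:04d}" for p in range(n_pathways) for i in range(cfg.n_switch_genes)
    ]
    out = {}
    for p in range(n_pathways):
        rng = np.random.default_rng(master.integers(2**31))
        lo, hi = cfg.switch_band
        own_t0 = rng.uniform(lo, hi, cfg.n_switch_genes)
        hk_ns_ids = [f"HK{i:04d}" for i in range(cfg.n_housekeeping_genes)] + [
            f"NS{i:04d}" for i in range(cfg.n_noise_genes)
        ]
        ids_own = [f"SW{p + 1}_{i:04d}" for i in range(cfg.n_switch_genes)] + hk_ns_ids
        classes_own = (
            ["switch"] * cfg.n_switch_genes
            + ["housekeeping"] * cfg.n_housekeeping_genes
            + ["noise"] * cfg.n_noise_genes
        )
        # Other pathways' switch genes are present but flat at mu_low with
        # the baseline dispersion (pathway-private signal).
        mean_own, size_own, truth = trajectory_parameters(
            cfg,
            switch_times=own_t0,
            universe=(ids_own, classes_own, hk_end, hk_dir, noise_mu),
            rng=rng,
        )
        n_sw, n_other = cfg.n_switch_genes, (n_pathways - 1) * cfg.n_switch_genes
        t = truth.pseudotime
        bump = _bump_factor(t, cfg)
        mean_other = np.full((n_other, cfg.n_cells), cfg.mu_low) * truth.library_sizes[None, :]
        size_other = np.repeat((cfg.base_size / bump)[None, :], n_other, axis=0)
        # gene order: own switch genes, other pathways' switch genes, hk, noise
        mean = np.vstack([mean_own[:n_sw], mean_other, mean_own[n_sw:]])
        size = np.vstack([size_own[:n_sw], size_other, size_own[n_sw:]])
        gene_ids = (
            [f"SW{p + 1}_{i:04d}" for i in range(n_sw)]
            + [s for s in sw_ids if not s.startswith(f"SW{p + 1}_")]
            + [f"HK{i:04d}" for i in range(cfg.n_housekeeping_genes)]
            + [f"NS{i:04d}" for i in range(cfg.n_noise_genes)]
        )
        counts = _nb_draw(rng, mean, size)
        cell_ids = [f"p{p + 1}_cell{i:05d}" for i in range(cfg.n_cells)]
        matrix = CountMatrix(gene_ids, cell_ids, counts)
        annotation = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "population_label": _stage_labels(cfg.n_cells, cfg.n_stages),
                "sample_id": f"pathway{p + 1}",
            }
        )
        pseudotime = pd.DataFrame({"cell_id": cell_ids, "pseudotime": t})
        genes = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "gene_class": ["switch"] * n_sw
                + ["switch_other"] * n_other
                + ["housekeeping"] * cfg.n_housekeeping_genes
                + ["noise"] * cfg.n_noise_genes,
            }
        )
        truth = TrajectoryTruth(
            config=cfg, genes=genes, pseudotime=t, library_sizes=truth.library_sizes
        )
        out[f"pathway{p + 1}"] = (matrix, annotation, pseudotime, truth)
    return out


# ---------------------------------------------------------------------------
# Two-group HSC design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGroupHSCConfig:
    """Control vs dispersion-inflated stem-cell design.

    Both groups share one lognormal per-gene mean vector; the case group's
    NB size parameter is control_size / dispersion_ratio.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    mean_log_mean: float = 1.0
    mean_log_sigma: float = 0.3
    control_size: float = 4.0
    dispersion_ratio: float = 1.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ConfigError("need n_cells >= 2 and n_genes >= 1")
        if self.control_size <= 0:
            raise ConfigError("control_size must be positive")
        if self.dispersion_ratio < 1:
            raise ConfigError("dispersion_ratio must be >= 1")


def simulate_two_group_hsc(cfg: TwoGroupHSCConfig):
    """(control CountMatrix, case CountMatrix), deterministic given the seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_mean, rng_ctrl, rng_case = (np.random.default_rng(s) for s in ss.spawn(3))
    mu = np.exp(rng_mean.normal(cfg.mean_log_mean, cfg.mean_log_sigma, cfg.n_genes))
    mean = np.repeat(mu[:, None], cfg.n_cells, axis=1)
    size_ctrl = np.full_like(mean, cfg.control_size)
    size_case = size_ctrl / cfg.dispersion_ratio
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    ctrl = CountMatrix(
        gene_ids,
        [f"ctrl{i:05d}" for i in range(cfg.n_cells)],
        _nb_draw(rng_ctrl, mean, size_ctrl),
    )
    case = CountMatrix(
        gene_ids,
        [f"case{i:05d}" for i in range(cfg.n_cells)],
        _nb_draw(rng_case, mean, size_case),
    )
    return ctrl, case


# ---------------------------------------------------------------------------
# Monte-Carlo entropy oracles
# ---------------------------------------------------------------------------

def nb_mixture_entropy(
    means, sizes, n_draws: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo entropy (nats) of a uniform mixture of NB distributions.

    Draws counts from the mixture, estimates entropy with the
    Miller-Madow-corrected plugin on the empirical distribution (bias is
    O(m / n_draws)), and returns (entropy, standard error), the latter
    from the delta-method variance of -ln p_hat(X).
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if means.shape != sizes.shape or means.ndim != 1 or means.size == 0:
        raise ConfigError("means and sizes must be matching 1-D arrays")
    rng = np.random.default_rng(seed)
    which = rng.integers(0, means.size, n_draws)
    lam = rng.gamma(shape=sizes[which], scale=means[which] / sizes[which])
    draws = rng.poisson(lam)
    counts = np.bincount(draws)
    occ = counts[counts > 0]
    p = occ / n_draws
    H = float(-np.sum(p * np.log(p))) + (len(occ) - 1) / (2 * n_draws)
    var = float(np.sum(p * np.log(p) ** 2) - np.sum(p * np.log(p)) ** 2)
    return H, float(np.sqrt(max(var, 0.0) / n_draws))


def true_window_entropy(
    cfg: SyntheticTrajectoryConfig,
    gene: int,
    window_cells,
    n_draws: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Ground-truth entropy of one gene over a window of cell indices.

    The oracle mixes the exact NB parameter fields the generator used
    (including library-size multipliers), so it is directly comparable to
    window estimates on data simulated from the same config.
    """
    mean, size, _ = trajectory_parameters(cfg)
    cells = np.asarray(window_cells, dtype=int)
    return nb_mixture_entropy(mean[gene, cells], size[gene, cells], n_draws, seed)
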