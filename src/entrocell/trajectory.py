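"""Sliding-window intercellular entropy profiles along a pseudotime ordering.

Cells belonging to a differentiation pathway are selected by population
label and sorted by a supplied pseudotime; per-gene entropy and per-gene
mean raw expression are then computed on a window of fixed size (default
50 cells) sliding with a fixed step (default 10 cells).  The window mean
entropy — averaged over the full, fixed gene set so profiles are
comparable across windows — is the trajectory-level readout: a transient
surge in cell-to-cell variability appears as a peak of this profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import CoefficientCache, ESTIMATORS, matrix_entropies
from .errors import ConfigError, DataError
from .io import CountMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwaySpec:
    """A named differentiation pathway given by its member population labels."""

    name: str
    ordered_labels: tuple[str, ...]

    def __init__(self, name: str, ordered_labels) -> None:
        labels = tuple(ordered_labels)
        if not labels:
            raise ConfigError(f"pathway {name!r} has no labels")
        if len(set(labels)) != len(labels):
            raise ConfigError(f"pathway {name!r} has duplicate labels")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "ordered_labels", labels)


@dataclass(frozen=True)
class WindowSpec:
    window_size: int = 50
    step: int = 10

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ConfigError("window_size must be >= 2")
        if not (1 <= self.step <= self.window_size):
            raise ConfigError("step must lie in [1, window_size]")


@dataclass(frozen=True)
class TrajectoryOrdering:
    """Pathway cells sorted by non-decreasing pseudotime (ties by cell id)."""

    pathway: PathwaySpec
    cell_ids: tuple[str, ...]
    pseudotimes: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        pt = np.asarray(self.pseudotimes, dtype=float)
        object.__setattr__(self, "pseudotimes", pt)
        if not (len(self.cell_ids) == len(pt) == len(self.labels)):
            raise DataError("ordering fields must have equal length")
        if np.any(np.diff(pt) < 0):
            raise DataError("pseudotimes must be non-decreasing")

    def __len__(self) -> int:
        return len(self.cell_ids)


def build_ordering(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    pseudotime: pd.DataFrame,
    pathway: PathwaySpec,
) -> TrajectoryOrdering:
    """Select and order the pathway's cells.

    Retains exactly the matrix cells whose label belongs to the pathway,
    sorted by pseudotime ascending with ties broken lexicographically by
    cell id (so the ordering is stable across runs).
    """
    labels = dict(zip(annotation["cell_id"].astype(str), annotation["population_label"]))
    pt = dict(zip(pseudotime["cell_id"].astype(str), pseudotime["pseudotime"].astype(float)))
    member = set(pathway.ordered_labels)
    picked = [c for c in matrix.cell_ids if labels.get(c) in member]
    if not picked:
        raise DataError(f"no cells match pathway {pathway.name!r}")
    missing = [c for c in picked if c not in pt]
    if missing:
        raise DataError(
            f"pathway {pathway.name!r}: {len(missing)} matched cells lack a "
            f"pseudotime (first: {missing[0]!r})"
        )
    order = sorted(picked, key=lambda c: (pt[c], c))
    log.info("pathway %s: %d cells ordered", pathway.name, len(order))
    return TrajectoryOrdering(
        pathway=pathway,
        cell_ids=tuple(order),
        pseudotimes=np.array([pt[c] for c in order]),
        labels=tuple(labels[c] for c in order),
    )


def sliding_windows(n_cells: int, spec: WindowSpec, context: str = "") -> np.ndarray:
    """Start offsets of all full windows: 0, step, ..., floor((n-w)/s)*s."""
    if n_cells < spec.window_size:
        where = f" in {context}" if context else ""
        raise DataError(
            f"{n_cells} cells{where} is fewer than the window size {spec.window_size}"
        )
    n_windows = (n_cells - spec.window_size) // spec.step + 1
    return np.arange(n_windows) * spec.step


@dataclass(frozen=True)
class WindowProfileSeries:
    """Per-window profile of a pathway.

    entropy and mean_expression are genes x windows; mean_entropy[w] is the
    average of entropy[:, w] over the full gene set.  first_cell_labels
    carry the annotation of each window's first (most immature) cell, as
    used to colour trajectory profiles.
    """

    pathway_name: str
    gene_ids: tuple[str, ...]
    window_starts: np.ndarray
    first_cell_labels: tuple[str, ...]
    first_cell_pseudotimes: np.ndarray
    entropy: np.ndarray
    mean_expression: np.ndarray
    mean_entropy: np.ndarray
    estimator: str

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)


def window_profiles(
    ordering: TrajectoryOrdering,
    matrix: CountMatrix,
    spec: WindowSpec = WindowSpec(),
    estimator: str = "bub",
    cache: CoefficientCache | None = None,
) -> WindowProfileSeries:
    """Per-gene entropy and mean raw expression over all sliding windows.

    Entropy is computed on raw counts (no depth normalisation), with
    m = (largest count in the window) + 1 per gene.
    """
    if estimator not in ESTIMATORS:
        raise ConfigError(f"unknown estimator: {estimator!r}")
    if estimator == "bub" and cache is None:
        cache = CoefficientCache()
    sub = matrix.subset_cells(list(ordering.cell_ids))
    X = sub.dense()
    starts = sliding_windows(len(ordering), spec, context=f"pathway {ordering.pathway.name!r}")
    G, W = X.shape[0], len(starts)
    ent = np.empty((G, W))
    mean = np.empty((G, W))
    for wi, s in enumerate(starts):
        block = X[:, s : s + spec.window_size]
        ent[:, wi] = matrix_entropies(block, estimator=estimator, cache=cache)
        mean[:, wi] = block.mean(axis=1)
    return WindowProfileSeries(
        pathway_name=ordering.pathway.name,
        gene_ids=tuple(sub.gene_ids),
        window_starts=starts,
        first_cell_labels=tuple(ordering.labels[s] for s in starts),
        first_cell_pseudotimes=np.array([ordering.pseudotimes[s] for s in starts]),
        entropy=ent,
        mean_expression=mean,
        mean_entropy=ent.mean(axis=0),
        estimator=estimator,
    )


@dataclass(frozen=True)
class PeakSummary:
    argmax_window: int
    first_cell_label: str
    is_transient: bool
    peak_mean_entropy: float


def peak_summary(series: WindowProfileSeries) -> PeakSummary:
    """Locate the mean-entropy peak; ties resolve to the earliest window.

    The peak is transient when it exceeds both the first and the last
    window's mean entropy (strictly).
    """
    me = series.mean_entropy
    if len(me) < 3:
        raise DataError("peak summary requires at least 3 windows")
    w = int(np.argmax(me))  # argmax takes the first maximum
    return PeakSummary(
        argmax_window=w,
        first_cell_label=series.first_cell_labels[w],
        is_transient=bool(me[w] > me[0] and me[w] > me[-1]),
        peak_mean_entropy=float(me[w]),
    )


def profile_table(series: WindowProfileSeries) -> pd.DataFrame:
    """One row per window: start, first-cell pseudotime/label, mean entropy."""
    return pd.DataFrame(
        {
            "window": np.arange(series.n_windows),
            "start": series.window_starts,
            "first_cell_pseudotime": series.first_cell_pseudotimes,
            "first_cell_label": list(series.first_cell_labels),
            "mean_entropy": series.mean_entropy,
        }
    )
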