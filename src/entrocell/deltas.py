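"""Delta-entropy / delta-expression gene rankings and cross-pathway overlaps.

For each gene along one pathway, delta-entropy is the max - min of its
window entropy and delta-expression the max - min of its window mean raw
expression.  The top-k lists (default k = 20) by each key, their overlaps
across pathways, the correlation between the two deltas, and the
transcription-factor subset of the top delta-entropic genes reproduce the
ranking analyses of the trajectory study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .trajectory import WindowProfileSeries

log = logging.getLogger(__name__)

DELTA_KEYS = ("delta_entropy", "delta_expression")


def compute_deltas(series: WindowProfileSeries) -> pd.DataFrame:
    """Per-gene max - min over windows, for entropy and mean expression.

    Returns a DataFrame with columns gene_id, delta_entropy,
    delta_expression, pathway.
    """
    if series.n_windows < 2:
        raise DataError("delta computation requires at least 2 windows")
    return pd.DataFrame(
        {
            "gene_id": list(series.gene_ids),
            "delta_entropy": series.entropy.max(axis=1) - series.entropy.min(axis=1),
            "delta_expression": series.mean_expression.max(axis=1)
            - series.mean_expression.min(axis=1),
            "pathway": series.pathway_name,
        }
    )


@dataclass(frozen=True)
class TopKList:
    pathway: str
    key: str
    k: int
    genes: tuple[str, ...]


def top_k(table: pd.DataFrame, key: str, k: int = 20) -> TopKList:
    """Top-k genes by the given delta, descending; ties break by gene id."""
    if key not in DELTA_KEYS:
        raise ConfigError(f"unknown ranking key: {key!r}")
    if table.empty:
        raise DataError("empty delta table")
    ranked = table.sort_values(
        [key, "gene_id"], ascending=[False, True], kind="mergesort"
    )
    pathways = table["pathway"].unique()
    pathway = pathways[0] if len(pathways) == 1 else "combined"
    genes = tuple(ranked["gene_id"].head(k))
    return TopKList(pathway=str(pathway), key=key, k=k, genes=genes)


@dataclass(frozen=True)
class OverlapSummary:
    """Cross-pathway membership of top-k lists.

    membership: gene -> number of pathway lists containing it;
    n_exactly_one / n_in_multiple / n_in_all partition-or-count the union;
    per_pathway: pathway -> (#genes shared with >= 1 other list,
    #genes shared with >= 2 other lists).
    """

    membership: dict[str, int]
    n_exactly_one: int
    n_in_multiple: int
    n_in_all: int
    per_pathway: dict[str, tuple[int, int]]


def overlap_lists(lists: list[TopKList]) -> OverlapSummary:
    if len(lists) < 2:
        raise DataError("overlap requires at least 2 lists")
    names = [l.pathway for l in lists]
    if len(set(names)) != len(names):
        raise DataError("duplicate pathway names in overlap")
    sets = {l.pathway: set(l.genes) for l in lists}
    union = sorted(set().union(*sets.values()))
    membership = {g: sum(g in s for s in sets.values()) for g in union}
    counts = np.array(list(membership.values()))
    per_pathway = {}
    for l in lists:
        others = [s for p, s in sets.items() if p != l.pathway]
        in_other = [sum(g in s for s in others) for g in l.genes]
        per_pathway[l.pathway] = (
            sum(n >= 1 for n in in_other),
            sum(n >= 2 for n in in_other),
        )
    return OverlapSummary(
        membership=membership,
        n_exactly_one=int((counts == 1).sum()),
        n_in_multiple=int((counts >= 2).sum()),
        n_in_all=int((counts == len(lists)).sum()),
        per_pathway=per_pathway,
    )


def membership_table(summary: OverlapSummary) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(summary.membership.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "n_pathways"],
    )


def delta_correlation(
    table: pd.DataFrame, method: str = "pearson", log_transform: bool = True
) -> dict:
    """Correlation of delta-expression vs delta-entropy across genes.

    By default Pearson on log(1 + x)-transformed deltas (the two deltas
    span orders of magnitude and are conventionally displayed on log
    scales).  Returns {"r", "p", "n", "method", "log_transform"}.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigError(f"unknown correlation method: {method!r}")
    x = table["delta_entropy"].to_numpy(dtype=float)
    y = table["delta_expression"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise DataError("correlation requires at least 3 genes with finite deltas")
    if log_transform:
        x, y = np.log1p(x), np.log1p(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("zero variance on one axis; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)
    return {"r": float(r), "p": float(p), "n": int(len(x)),
            "method": method, "log_transform": log_transform}


def tf_subset(table: pd.DataFrame, tf_list, top_n: int = 1000) -> list[str]:
    """Transcription factors among the top_n delta-entropic genes, in delta order."""
    tfs = set(tf_list)
    if not tfs:
        raise DataError("empty transcription-factor list")
    head = top_k(table, "delta_entropy", k=top_n).genes
    result = [g for g in head if g in tfs]
    if not result:
        log.warning("no transcription factors found in the top %d delta-entropic genes", top_n)
    return result
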