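"""Ordering, window arithmetic and sliding-window profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from entrocell.entropy import matrix_entropies, summarize_histogram, plugin_entropy
from entrocell.errors import ConfigError, DataError
from entrocell.io import CountMatrix
from entrocell.trajectory import (
    PathwaySpec,
    WindowProfileSeries,
    WindowSpec,
    build_ordering,
    peak_summary,
    sliding_windows,
    window_profiles,
)


def make_inputs(labels, pseudotimes, n_genes=3, seed=0):
    n = len(labels)
    rng = np.random.default_rng(seed)
    matrix = CountMatrix(
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n)],
        rng.integers(0, 5, size=(n_genes, n)),
    )
    ann = pd.DataFrame(
        {"cell_id": matrix.cell_ids, "population_label": labels, "sample_id": "s"}
    )
    pt = pd.DataFrame({"cell_id": matrix.cell_ids, "pseudotime": pseudotimes})
    return matrix, ann, pt


class TestBuildOrdering:
    def test_filters_and_sorts(self):
        matrix, ann, pt = make_inputs(
            ["A", "B", "A", "B", "A", "B"], [5.0, 0.1, 3.0, 0.2, 1.0, 0.3]
        )
        ordering = build_ordering(matrix, ann, pt, PathwaySpec("p", ["A"]))
        assert list(ordering.cell_ids) == ["c4", "c2", "c0"]
        assert list(ordering.labels) == ["A", "A", "A"]

    def test_tie_break_is_lexicographic(self):
        matrix, ann, pt = make_inputs(["A", "A", "A"], [1.0, 1.0, 0.5])
        ordering = build_ordering(matrix, ann, pt, PathwaySpec("p", ["A"]))
        assert list(ordering.cell_ids) == ["c2", "c0", "c1"]

    def test_missing_pseudotime_raises(self):
        matrix, ann, pt = make_inputs(["A", "A"], [1.0, 2.0])
        pt = pt.iloc[:1]
        with pytest.raises(DataError, match="pseudotime"):
            build_ordering(matrix, ann, pt, PathwaySpec("p", ["A"]))

    def test_no_match_raises(self):
        matrix, ann, pt = make_inputs(["A"], [1.0])
        with pytest.raises(DataError, match="no cells"):
            build_ordering(matrix, ann, pt, PathwaySpec("p", ["Z"]))

    def test_recovers_latent_order(self, small_trajectory, small_trajectory_config):
        """Pseudotime = latent time: output rank correlates perfectly."""
        matrix, ann, pt, truth = small_trajectory
        labels = [f"stage{i+1}" for i in range(small_trajectory_config.n_stages)]
        ordering = build_ordering(matrix, ann, pt, PathwaySpec("traj", labels))
        latent_rank = {c: i for i, c in enumerate(matrix.cell_ids)}
        rho = spearmanr(
            np.arange(len(ordering)), [latent_rank[c] for c in ordering.cell_ids]
        ).statistic
        assert rho == pytest.approx(1.0)


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n,expected", [(50, 1), (444, 40), (59, 1), (60, 2), (2000, 196)]
    )
    def test_window_counts(self, n, expected):
        assert len(sliding_windows(n, WindowSpec(50, 10))) == expected

    def test_too_few_cells_names_context(self):
        with pytest.raises(DataError, match="erythroid"):
            sliding_windows(49, WindowSpec(50, 10), context="erythroid")

    @given(
        n=st.integers(2, 3000),
        w=st.integers(2, 100),
        s=st.integers(1, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_count_formula(self, n, w, s):
        s = min(s, w)
        if n < w:
            with pytest.raises(DataError):
                sliding_windows(n, WindowSpec(w, s))
        else:
            starts = sliding_windows(n, WindowSpec(w, s))
            assert len(starts) == (n - w) // s + 1
            assert starts[-1] + w <= n  # no partial windows
            assert np.all(np.diff(starts) == s)

    def test_invalid_spec(self):
        with pytest.raises(ConfigError):
            WindowSpec(1, 1)
        with pytest.raises(ConfigError):
            WindowSpec(50, 60)


class TestWindowProfiles:
    def profiles_fixture(self, n=60, n_genes=3, seed=9):
        matrix, ann, pt = make_inputs(
            ["A"] * n, np.linspace(0, 1, n), n_genes=n_genes, seed=seed
        )
        ordering = build_ordering(matrix, ann, pt, PathwaySpec("p", ["A"]))
        return matrix, ordering

    def test_matches_per_window_recomputation(self, cache):
        matrix, ordering = self.profiles_fixture()
        spec = WindowSpec(50, 10)
        series = window_profiles(ordering, matrix, spec, "bub", cache)
        assert series.n_windows == 2
        X = matrix.subset_cells(list(ordering.cell_ids)).dense()
        for wi, s in enumerate([0, 10]):
            block = X[:, s : s + 50]
            expected = matrix_entropies(block, "bub", cache)
            assert np.allclose(series.entropy[:, wi], expected)
            assert np.allclose(series.mean_expression[:, wi], block.mean(axis=1))
        assert np.allclose(series.mean_entropy, series.entropy.mean(axis=0))

    def test_all_zero_genes_give_zero(self, cache):
        matrix, ann, pt = make_inputs(["A"] * 55, np.arange(55.0))
        zero = CountMatrix(matrix.gene_ids, matrix.cell_ids, np.zeros((3, 55), dtype=int))
        ordering = build_ordering(zero, ann, pt, PathwaySpec("p", ["A"]))
        series = window_profiles(ordering, zero, WindowSpec(50, 10), "bub", cache)
        assert np.all(series.entropy == 0) and np.all(series.mean_expression == 0)

    def test_invariant_to_shuffle_within_window(self, cache):
        """Entropy and means only depend on the multiset of cells per window."""
        matrix, ordering = self.profiles_fixture(n=50)
        spec = WindowSpec(50, 10)
        base = window_profiles(ordering, matrix, spec, "bub", cache)
        rng = np.random.default_rng(1)
        perm = rng.permutation(50)
        shuffled = type(ordering)(
            pathway=ordering.pathway,
            cell_ids=tuple(ordering.cell_ids[i] for i in perm),
            pseudotimes=np.sort(ordering.pseudotimes),  # keep the invariant
            labels=tuple(ordering.labels[i] for i in perm),
        )
        out = window_profiles(shuffled, matrix, spec, "bub", cache)
        assert np.allclose(out.entropy, base.entropy)
        assert np.allclose(out.mean_expression, base.mean_expression)

    def test_constant_gene_zero_delta_under_plugin(self):
        matrix, ann, pt = make_inputs(["A"] * 70, np.arange(70.0), n_genes=1)
        const = CountMatrix(["g0"], matrix.cell_ids, np.full((1, 70), 3, dtype=int))
        ordering = build_ordering(const, ann, pt, PathwaySpec("p", ["A"]))
        series = window_profiles(ordering, const, WindowSpec(50, 10), "plugin")
        assert np.ptp(series.entropy[0]) == 0.0

    def test_first_cell_labels(self, cache):
        labels = ["A"] * 30 + ["B"] * 40
        matrix, ann, pt = make_inputs(labels, np.arange(70.0))
        ordering = build_ordering(matrix, ann, pt, PathwaySpec("p", ["A", "B"]))
        series = window_profiles(ordering, matrix, WindowSpec(50, 10), "plugin")
        assert list(series.first_cell_labels) == ["A", "A", "A"]


class TestPeakSummary:
    def series_with(self, mean_entropy):
        w = len(mean_entropy)
        return WindowProfileSeries(
            pathway_name="p",
            gene_ids=("g",),
            window_starts=np.arange(w),
            first_cell_labels=tuple("L" for _ in range(w)),
            first_cell_pseudotimes=np.arange(w, dtype=float),
            entropy=np.asarray(mean_entropy)[None, :],
            mean_expression=np.zeros((1, w)),
            mean_entropy=np.asarray(mean_entropy, dtype=float),
            estimator="plugin",
        )

    def test_monotone_decreasing_not_transient(self):
        pk = peak_summary(self.series_with([3.0, 2.0, 1.0]))
        assert pk.argmax_window == 0 and not pk.is_transient

    def test_unimodal_is_transient(self):
        pk = peak_summary(self.series_with([1.0, 3.0, 1.5]))
        assert pk.argmax_window == 1 and pk.is_transient

    def test_flat_ties_to_first_window(self):
        pk = peak_summary(self.series_with([2.0, 2.0, 2.0]))
        assert pk.argmax_window == 0 and not pk.is_transient

    def test_requires_three_windows(self):
        with pytest.raises(DataError):
            peak_summary(self.series_with([1.0, 2.0]))
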