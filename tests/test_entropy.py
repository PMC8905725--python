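"""Unit and property tests for the linear entropy estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entrocell.entropy import (
    BUBCoefficients,
    CoefficientCache,
    HistogramSummary,
    _solve_candidates,
    bub_coefficients,
    bub_entropy,
    estimate_entropy,
    jackknife_entropy,
    matrix_entropies,
    miller_madow_entropy,
    plugin_entropy,
    summarize_histogram,
)
from entrocell.errors import ConfigError, DataError

from conftest import brute_force_plugin


# ---------------------------------------------------------------------------
# Histogram summaries
# ---------------------------------------------------------------------------

class TestSummarizeHistogram:
    def test_degenerate_all_zero(self):
        h = summarize_histogram([0, 0, 0, 0])
        assert (h.N, h.m) == (4, 1)
        assert h.h[4] == 1 and h.h[:4].sum() == 0

    def test_zero_level_is_always_a_bin(self):
        h = summarize_histogram([2, 2])
        assert (h.N, h.m) == (2, 3)  # levels 0, 1, 2
        assert h.h[0] == 2 and h.h[2] == 1

    def test_observed_support_policy(self):
        h = summarize_histogram([2, 2], m_policy="observed_support")
        assert h.m == 1

    def test_matches_independent_double_tally(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 10, 50)
        h = summarize_histogram(counts)
        # brute force: cells per level, then levels per occupancy
        expected = np.zeros(51, dtype=int)
        for level in range(int(counts.max()) + 1):
            expected[np.sum(counts == level)] += 1
        assert np.array_equal(h.h, expected)

    def test_empty_vector_rejected(self):
        with pytest.raises(DataError):
            summarize_histogram([])

    def test_invariants_enforced(self):
        with pytest.raises(DataError):
            HistogramSummary(N=2, m=3, h=np.array([1, 0, 1]), observed_bins=1)


# ---------------------------------------------------------------------------
# Plugin / Miller-Madow / jackknife against literal oracles
# ---------------------------------------------------------------------------

class TestSimpleEstimators:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5], 0.0),
            ([0, 1], np.log(2)),
            ([0, 1, 1, 2], -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))),
        ],
    )
    def test_plugin_hand_values(self, counts, expected):
        assert plugin_entropy(summarize_histogram(counts)).value == pytest.approx(expected)

    def test_miller_madow_hand_values(self):
        assert miller_madow_entropy(summarize_histogram([7, 7])).value == 0.0
        assert miller_madow_entropy(summarize_histogram([0, 1])).value == pytest.approx(
            np.log(2) + 0.25
        )

    def test_jackknife_hand_value(self):
        # both leave-one-out entropies are 0, so N*H - (N-1)/N * 0 = 2 ln 2
        assert jackknife_entropy([0, 1]).value == pytest.approx(2 * np.log(2))

    def test_jackknife_requires_two_cells(self):
        with pytest.raises(DataError):
            jackknife_entropy([3])

    def test_thousand_random_histograms_match_brute_force(self):
        """plugin/MM/jackknife equal their literal formulas to 1e-12 relative."""
        rng = np.random.default_rng(202)
        for _ in range(1000):
            N = int(rng.integers(2, 30))
            counts = rng.integers(0, rng.integers(2, 12), N)
            hist = summarize_histogram(counts)
            plug = brute_force_plugin(counts)
            mm = plug + (len(np.unique(counts)) - 1) / (2 * N)
            loo = [
                brute_force_plugin(np.delete(counts, i)) for i in range(N)
            ]
            jack = N * plug - (N - 1) / N * sum(loo)
            assert plugin_entropy(hist).value == pytest.approx(plug, rel=1e-12, abs=1e-12)
            assert miller_madow_entropy(hist).value == pytest.approx(mm, rel=1e-12, abs=1e-12)
            assert jackknife_entropy(counts).value == pytest.approx(jack, rel=1e-12, abs=1e-12)

    @given(st.lists(st.integers(0, 8), min_size=2, max_size=40), st.randoms())
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance(self, counts, rnd):
        shuffled = list(counts)
        rnd.shuffle(shuffled)
        for est in ("plugin", "miller_madow", "jackknife"):
            a = estimate_entropy(counts, est).value
            b = estimate_entropy(shuffled, est).value
            assert a == pytest.approx(b, abs=1e-12)

    @given(st.lists(st.integers(0, 10), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_plugin_bounds_and_mm_dominance(self, counts):
        hist = summarize_histogram(counts)
        p = plugin_entropy(hist).value
        assert 0.0 <= p <= np.log(min(hist.N, hist.m)) + 1e-12
        assert miller_madow_entropy(hist).value >= p


# ---------------------------------------------------------------------------
# BUB estimator
# ---------------------------------------------------------------------------

class TestBUB:
    def test_degenerate_histogram_is_linear_form(self, cache):
        """All cells in one bin: estimate is exactly a_N + (m-1) a_0."""
        N, m = 20, 7
        c = cache.get_or_solve(N, m)
        hist = HistogramSummary.from_bin_counts([N], m)
        assert bub_entropy(hist, c).value == pytest.approx(
            c.a[N] + (m - 1) * c.a[0], rel=1e-12
        )

    def test_free_block_matches_independent_normal_equations(self):
        """The penalised fit solves the same quadratic an explicit normal-
        equation construction solves (independent oracle for the solver)."""
        N, k, lam, mesh = 12, 6, 1e-3, 400
        cand = [c for c in _solve_candidates(N, [k], [lam], mesh)][0]
        # independent construction
        from scipy.special import gammaln, xlogy

        p = np.linspace(0, 1, mesh)
        j = np.arange(N + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            B = np.exp(
                gammaln(N + 1) - gammaln(j + 1) - gammaln(N - j + 1)
                + xlogy(j[None, :], p[:, None])
                + xlogy((N - j)[None, :], (1 - p)[:, None])
            )
        g = np.asarray(-xlogy(p, p))
        aP = -xlogy(j / N, j / N) + 1 / (2 * N)
        y = g - B[:, k + 1:] @ aP[k + 1:]
        D = np.zeros((k + 1, k + 1))
        d = np.zeros(k + 1)
        for r in range(k):
            D[r, r], D[r, r + 1] = -1, 1
        D[k, k] = -1
        d[k] = -aP[k + 1]
        Bk = B[:, : k + 1]
        lhs = Bk.T @ Bk + lam * D.T @ D
        rhs = Bk.T @ y + lam * D.T @ d
        x = np.linalg.solve(lhs, rhs)
        assert np.allclose(cand.a[: k + 1], x, atol=1e-8)

    def test_lambda_limit_smooths_coefficients(self):
        """Increasing lambda monotonically shrinks the largest coefficient step."""
        deltas = [
            c.max_delta
            for lam in (1e-4, 1e-2, 1.0, 100.0)
            for c in _solve_candidates(30, [30], [lam], 500)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(deltas, deltas[1:]))

    def test_linearity_in_occupancy(self, cache):
        """Estimate decomposes as coefficient arithmetic over h."""
        N, m = 10, 6
        c = cache.get_or_solve(N, m)
        counts = np.array([0, 0, 1, 1, 1, 2, 3, 3, 5, 5])
        hist = summarize_histogram(counts)
        manual = float(np.dot(c.a, hist.h))
        assert bub_entropy(hist, c).value == pytest.approx(manual, rel=1e-14)

    def test_consistency_uniform_large_n(self, cache):
        """N = 10^4 >> m = 8: all four estimators near ln 8 (within 0.02 nats)."""
        rng = np.random.default_rng(99)
        counts_per_bin = np.bincount(rng.integers(0, 8, 10_000), minlength=8)
        hist = HistogramSummary.from_bin_counts(counts_per_bin, 8)
        target = np.log(8)
        assert plugin_entropy(hist).value == pytest.approx(target, abs=0.02)
        assert miller_madow_entropy(hist).value == pytest.approx(target, abs=0.02)
        c = cache.get_or_solve(10_000, 8)
        assert bub_entropy(hist, c).value == pytest.approx(target, abs=0.02)

    def test_undersampled_mean_closer_than_plugin(self, cache):
        """N=50 draws from uniform over m=100: mean BUB estimate is closer to
        ln(100) than the mean plugin estimate (the undersampled regime)."""
        rng = np.random.default_rng(42)
        c = cache.get_or_solve(50, 100)
        bub_vals, plug_vals = [], []
        for _ in range(300):
            bc = np.bincount(rng.integers(0, 100, 50), minlength=100)
            hist = HistogramSummary.from_bin_counts(bc, 100)
            bub_vals.append(bub_entropy(hist, c).value)
            plug_vals.append(plugin_entropy(hist).value)
        target = np.log(100)
        assert abs(np.mean(bub_vals) - target) < abs(np.mean(plug_vals) - target)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ConfigError):
            bub_coefficients(10, 5, k_max_grid=[], lambda_grid=[0.0])
        with pytest.raises(ConfigError):
            bub_coefficients(10, 5, mesh_size=1)

    def test_nm_mismatch_rejected(self, cache):
        c = cache.get_or_solve(10, 5)
        hist = summarize_histogram([0, 1, 2, 0, 1, 2, 0, 1, 2, 0])
        with pytest.raises(DataError):
            bub_entropy(hist, c)  # hist has m=3, coeffs m=5


class TestCoefficientCache:
    def test_repeat_queries_identical(self):
        cache = CoefficientCache()
        a1 = cache.get_or_solve(50, 17).a
        a2 = cache.get_or_solve(50, 17).a
        assert np.array_equal(a1, a2)

    def test_keyed_by_m(self):
        cache = CoefficientCache()
        c17 = cache.get_or_solve(50, 17)
        c18 = cache.get_or_solve(50, 18)
        assert (c17.m, c18.m) == (17, 18)

    def test_solve_counter_counts_distinct_keys(self):
        cache = CoefficientCache()
        rng = np.random.default_rng(0)
        ms = rng.integers(2, 32, 1000)
        for m in ms:
            cache.get_or_solve(40, int(m))
        assert cache.solve_count == len(set(ms.tolist()))

    def test_roundtrip_persistence(self, tmp_path):
        cache = CoefficientCache()
        c = cache.get_or_solve(12, 5)
        cache.save(tmp_path / "coeffs.tsv")
        fresh = CoefficientCache()
        fresh.load(tmp_path / "coeffs.tsv")
        c2 = fresh.get_or_solve(12, 5)
        assert np.array_equal(c.a, c2.a) and c2.error_bound == c.error_bound
        assert fresh.solve_count == 0  # served from disk


class TestMatrixEntropies:
    def test_matches_scalar_path(self, cache):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 6, size=(20, 30))
        vec = matrix_entropies(X, "bub", cache)
        for gi in range(20):
            assert vec[gi] == pytest.approx(
                estimate_entropy(X[gi], "bub", cache).value, rel=1e-12
            )

    def test_all_zero_rows_are_zero(self, cache):
        X = np.zeros((4, 25), dtype=int)
        assert np.all(matrix_entropies(X, "bub", cache) == 0.0)
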