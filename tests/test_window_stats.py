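"""Wilcoxon rank-sum correctness and the window p-value family."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats

from splicemaps.motifs import WindowCountMatrix
from splicemaps.window_stats import (
    MapConfig,
    WindowPValueSeries,
    enrichment_pvalues,
    rank_sum_pvalues_matrix,
    summarize_min_p,
    wilcoxon_rank_sum,
)


def enumeration_oracle(x, y, alternative="greater"):
    """Exact p by explicit enumeration of all rank assignments (tie-free)."""
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n, n1 = len(pooled), len(x)
    sums = [sum(combo) for combo in itertools.combinations(range(1, n + 1), n1)]
    p_greater = sum(s >= w_obs for s in sums) / len(sums)
    p_less = sum(s <= w_obs for s in sums) / len(sums)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


class TestWilcoxonRankSum:
    def test_small_one_sided_case_is_exactly_one_tenth(self):
        statistic, p = wilcoxon_rank_sum([3, 4, 5], [1, 2], "greater")
        assert statistic == 12.0
        assert p == 0.1

    def test_fully_tied_samples_sit_at_null_mean(self):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2], "greater")
        assert p == 0.5

    def test_identical_samples_two_sided_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided")
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_exact_path_matches_enumeration_oracle_all_small_partitions(self, alternative):
        rng = np.random.default_rng(0)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                if n1 + n2 > 10:
                    continue
                values = rng.permutation(np.arange(1, n1 + n2 + 1, dtype=float) * 1.37)
                x, y = list(values[:n1]), list(values[n1:])
                _, p = wilcoxon_rank_sum(x, y, alternative)
                assert p == pytest.approx(enumeration_oracle(x, y, alternative), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n20(self):
        # independent oracle: scipy's exact Mann-Whitney distribution
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(30):
            x = rng.normal(0.3, 1.0, 20)
            y = rng.normal(0.0, 1.0, 20)
            _, p_approx = wilcoxon_rank_sum(x, y, "greater", exact_max_n=10)
            p_exact = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            worst = max(worst, abs(p_approx - p_exact))
        assert worst <= 0.02

    def test_ties_fall_back_to_corrected_normal_approximation(self):
        x, y = [0, 0, 1, 1], [0, 0, 0, 1]
        _, p = wilcoxon_rank_sum(x, y, "greater", exact_max_n=10)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=1e-12)


class TestMatrixPath:
    def test_matches_scipy_asymptotic_per_column(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(0.3, size=(40, 25))
        y = rng.poisson(0.2, size=(60, 25))
        ours = rank_sum_pvalues_matrix(x, y, "greater")
        ref = stats.mannwhitneyu(x, y, alternative="greater",
                                 method="asymptotic", axis=0).pvalue
        assert np.allclose(ours, ref, atol=1e-12)

    def test_two_sided_matches_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(0.5, size=(30, 10))
        y = rng.poisson(0.5, size=(30, 10))
        ours = rank_sum_pvalues_matrix(x, y, "two_sided")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", axis=0).pvalue
        assert np.allclose(ours, ref, atol=1e-12)

    def test_degenerate_all_tied_column(self):
        x = np.zeros((10, 2), dtype=int)
        y = np.zeros((12, 2), dtype=int)
        assert (rank_sum_pvalues_matrix(x, y, "greater") == 0.5).all()

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(1.0, size=(25, 8))
        y = rng.poisson(1.0, size=(35, 8))
        base = rank_sum_pvalues_matrix(x, y, "greater")
        transformed = rank_sum_pvalues_matrix(3 * x + 1, 3 * y + 1, "greater")
        assert np.array_equal(base, transformed)

    def test_super_uniform_under_label_permutation_null(self):
        """Shuffling regulated/background labels must give (super-)uniform
        window p-values: empirical P(p <= t) <= t + 3*SE."""
        rng = np.random.default_rng(5)
        pooled = rng.poisson(0.4, size=(60, 1))
        n_perm = 1000
        pvals = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(60)
            pvals[i] = rank_sum_pvalues_matrix(
                pooled[perm[:20]], pooled[perm[20:]], "greater"
            )[0]
        for t in (0.01, 0.05, 0.1, 0.25, 0.5):
            se = np.sqrt(t * (1 - t) / n_perm)
            assert (pvals <= t).mean() <= t + 3 * se


def _matrix(motif, label, counts):
    counts = np.asarray(counts)
    return WindowCountMatrix(
        motif_name=motif,
        region_label=label,
        window_width=50,
        step=1,
        counts=counts,
        window_offsets=np.arange(counts.shape[1]),
    )


class TestEnrichmentPValues:
    def test_family_size_is_250_for_default_geometry(self):
        assert MapConfig().n_windows == 250
        rng = np.random.default_rng(6)
        reg = _matrix("m", "R2", rng.poisson(0.3, size=(20, 250)))
        bg = _matrix("m", "R2", rng.poisson(0.3, size=(40, 250)))
        series = enrichment_pvalues(reg, bg)
        assert len(series.pvalues) == 250
        assert series.min_p == series.pvalues.min()
        assert series.min_p_window == int(np.argmin(series.pvalues))

    def test_identical_row_sets_give_no_enrichment(self):
        rng = np.random.default_rng(7)
        rows = rng.poisson(0.5, size=(30, 40))
        reg = _matrix("m", "R1", rows)
        bg = _matrix("m", "R1", rows[rng.permutation(30)])
        series = enrichment_pvalues(reg, bg)
        assert (series.pvalues >= 0.5).all()

    def test_planted_signal_min_p_lands_in_signal_block(self):
        rng = np.random.default_rng(8)
        n_reg, n_bg, w = 50, 150, 250
        reg = rng.poisson(0.05, size=(n_reg, w))
        bg = rng.poisson(0.05, size=(n_bg, w))
        # motif at offset 100 in 80% of regulated, 5% of background events:
        # exactly windows 51..100 contain it
        reg[rng.random(n_reg) < 0.8, 51:101] += 1
        bg[rng.random(n_bg) < 0.05, 51:101] += 1
        series = enrichment_pvalues(_matrix("m", "R2", reg), _matrix("m", "R2", bg))
        assert 51 <= series.min_p_window <= 100

    def test_mismatched_families_rejected(self):
        reg = _matrix("m", "R1", np.zeros((3, 10), dtype=int))
        bg = _matrix("m", "R2", np.zeros((3, 10), dtype=int))
        with pytest.raises(ValueError, match="different region labels"):
            enrichment_pvalues(reg, bg)


class TestSummarizeMinP:
    def test_sorted_ascending_with_name_tiebreak(self):
        s1 = WindowPValueSeries("b", "R1", "c", np.array([0.3, 0.4]), np.arange(2))
        s2 = WindowPValueSeries("a", "R1", "c", np.array([1e-6, 0.9]), np.arange(2))
        s3 = WindowPValueSeries("c", "R1", "c", np.array([0.3, 0.5]), np.arange(2))
        table = summarize_min_p([s1, s2, s3])
        assert list(table["motif"]) == ["a", "b", "c"]

    def test_empty_collection_gives_empty_table(self):
        assert len(summarize_min_p([])) == 0

    def test_null_min_p_is_small_despite_no_signal(self):
        """The min of 250 dependent null p-values is typically far below
        0.05 — the multiplicity artifact the post-hoc bounds exist for."""
        rng = np.random.default_rng(9)
        minima = []
        for _ in range(20):
            reg = _matrix("m", "R1", rng.poisson(0.3, size=(40, 250)))
            bg = _matrix("m", "R1", rng.poisson(0.3, size=(120, 250)))
            minima.append(enrichment_pvalues(reg, bg).min_p)
        assert np.median(minima) < 0.05
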