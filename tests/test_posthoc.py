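"""Simes post-hoc FDP bounds, interval tables and the screening logic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from splicemaps.posthoc import (
    PosthocConfig,
    interval_bounds,
    posthoc_screen,
    select_intervals,
    simes_posthoc_bound,
    simes_rejects,
)
from splicemaps.window_stats import WindowPValueSeries


def naive_interval_bounds(pvalues, config):
    """Independent oracle: evaluate the Simes bound interval by interval."""
    m = len(pvalues)
    rows = []
    for i in range(m):
        for j in range(i, m):
            v = simes_posthoc_bound(pvalues[i : j + 1], m, config.alpha)
            rows.append((i, j, j - i + 1, v, v / (j - i + 1)))
    return pd.DataFrame(rows, columns=["start", "end", "size", "fp_bound", "fdp_bound"])


def _series(pvalues, motif="m", region="R2"):
    pvalues = np.asarray(pvalues, dtype=float)
    return WindowPValueSeries(motif, region, "test", pvalues, np.arange(len(pvalues)))


class TestSimesBound:
    def test_worked_example(self):
        # k = 1..4 give 2, 3, 3, 4 -> bound 2 (FDP bound 0.5)
        assert simes_posthoc_bound([0.001, 0.008, 0.03, 0.2], m=5, alpha=0.05) == 2

    def test_all_zero_pvalues_bound_zero(self):
        assert simes_posthoc_bound([0.0, 0.0, 0.0], m=10, alpha=0.05) == 0

    def test_single_pvalue_of_one_bound_one(self):
        assert simes_posthoc_bound([1.0], m=10, alpha=0.05) == 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simes_posthoc_bound([0.5], m=0, alpha=0.05)
        with pytest.raises(ValueError):
            simes_posthoc_bound([0.5], m=10, alpha=1.5)
        with pytest.raises(ValueError):
            simes_posthoc_bound([0.1, 0.2], m=1, alpha=0.05)


class TestIntervalBounds:
    def test_matches_naive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        config = PosthocConfig()
        for _ in range(20):
            m = int(rng.integers(2, 40))
            p = rng.uniform(0, 1, m)
            p[rng.random(m) < 0.3] *= 1e-4  # sprinkle signal
            fast = interval_bounds(_series(p), config)
            naive = naive_interval_bounds(p, config)
            merged = fast.merge(naive, on=["start", "end"], suffixes=("", "_naive"))
            assert len(merged) == len(naive)
            assert (merged["fp_bound"] == merged["fp_bound_naive"]).all()

    def test_all_ones_every_interval_bound_is_one(self):
        table = interval_bounds(_series(np.ones(12)), PosthocConfig())
        assert (table["fdp_bound"] == 1.0).all()

    def test_strong_run_is_argmin_and_near_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 1.0, 100)
        p[40:70] = 1e-8
        table = interval_bounds(_series(p), PosthocConfig())
        best = table.loc[table["fdp_bound"].idxmin()]
        assert best["fdp_bound"] == 0.0
        assert 40 <= best["start"] and best["end"] <= 69

    def test_singletons_reproduce_scalar_bound(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 1, 30)
        config = PosthocConfig()
        table = interval_bounds(_series(p), config)
        singles = table[table["size"] == 1].sort_values("start")
        expected = [simes_posthoc_bound([v], 30, config.alpha) for v in p]
        assert list(singles["fp_bound"]) == expected

    def test_lowering_pvalues_never_raises_bounds(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 40)
        lowered = p.copy()
        lowered[rng.random(40) < 0.5] *= 0.1
        config = PosthocConfig()
        before = interval_bounds(_series(p), config)["fp_bound"].to_numpy()
        after = interval_bounds(_series(lowered), config)["fp_bound"].to_numpy()
        assert (after <= before).all()


class TestSelection:
    def test_single_qualifying_interval_selected(self):
        table = pd.DataFrame(
            {
                "motif": "m",
                "region": "R2",
                "start": [120, 10],
                "end": [160, 20],
                "size": [41, 11],
                "fp_bound": [4, 11],
                "fdp_bound": [0.1, 1.0],
            }
        )
        summary = select_intervals(table, PosthocConfig())
        assert summary.ph_fdp == 0.1
        assert [(iv.start, iv.end) for iv in summary.selected_intervals] == [(120, 160)]

    def test_nested_qualifying_intervals_reduced_to_maximal(self):
        table = pd.DataFrame(
            {
                "motif": "m",
                "region": "R2",
                "start": [100, 90],
                "end": [150, 160],
                "size": [51, 71],
                "fp_bound": [5, 7],
                "fdp_bound": [0.098, 0.0986],
            }
        )
        summary = select_intervals(table, PosthocConfig())
        assert [(iv.start, iv.end) for iv in summary.selected_intervals] == [(90, 160)]

    def test_threshold_is_strict(self):
        table = pd.DataFrame(
            {
                "motif": "m",
                "region": "R2",
                "start": [0],
                "end": [3],
                "size": [4],
                "fp_bound": [1],
                "fdp_bound": [0.25],
            }
        )
        summary = select_intervals(table, PosthocConfig(fdp_threshold=0.25))
        assert summary.selected_intervals == []
        assert summary.ph_fdp == 0.25


class TestScreen:
    def test_empty_input_gives_empty_ranking(self):
        assert posthoc_screen([]) == []

    def test_equal_ph_fdp_breaks_ties_alphabetically(self):
        p = np.ones(20)
        screen = posthoc_screen([_series(p, motif="zeta"), _series(p, motif="alpha")])
        assert [s.motif_name for s in screen] == ["alpha", "zeta"]

    def test_fast_path_equals_exhaustive_path(self):
        rng = np.random.default_rng(4)
        series = []
        for name in "abcdef":
            p = rng.uniform(0, 1, 60)
            if name in "ab":
                p[10:30] *= 1e-6
            series.append(_series(p, motif=name))
        config = PosthocConfig()
        fast = posthoc_screen(series, config, fast=True)
        slow = posthoc_screen(series, config, fast=False)
        assert [(s.motif_name, s.ph_fdp, s.best_interval_size) for s in fast] == [
            (s.motif_name, s.ph_fdp, s.best_interval_size) for s in slow
        ]
        assert [
            [(iv.region_label, iv.start, iv.end) for iv in s.selected_intervals]
            for s in fast
        ] == [
            [(iv.region_label, iv.start, iv.end) for iv in s.selected_intervals]
            for s in slow
        ]

    def test_alpha_split_across_families(self):
        """With split_alpha the same p-value family is judged at a stricter
        per-family level when more families enter the screen."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        p[5:15] = 2e-4  # rejectable at alpha=0.05, not at alpha=0.05/4
        lone = posthoc_screen([_series(p, motif="a")], PosthocConfig())
        crowd = posthoc_screen(
            [_series(p, motif="a")]
            + [_series(np.ones(50), motif=n) for n in "bcd"],
            PosthocConfig(),
        )
        lone_a = lone[0]
        crowd_a = next(s for s in crowd if s.motif_name == "a")
        assert lone_a.ph_fdp <= crowd_a.ph_fdp

    def test_null_coverage_of_simes_selection(self):
        """Under independent uniform p-values every selected window would be
        a false positive; the chance of any selection (equivalently a Simes
        family rejection) must stay within alpha + 3*SE."""
        rng = np.random.default_rng(6)
        n_reps, m, alpha = 400, 50, 0.05
        rejections = sum(
            simes_rejects(rng.uniform(0, 1, m), alpha=alpha) for _ in range(n_reps)
        )
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert rejections / n_reps <= alpha + 3 * se

    def test_simes_rejection_equivalence_with_interval_selection(self):
        """simes_rejects is exactly the condition for any interval to have a
        bound below 1 — the correctness contract of the screening fast path."""
        rng = np.random.default_rng(7)
        config = PosthocConfig()
        for _ in range(30):
            p = rng.uniform(0, 1, 25)
            if rng.random() < 0.5:
                p *= rng.uniform(0.001, 1.0)
            table = interval_bounds(_series(p), config)
            assert (table["fdp_bound"] < 1.0).any() == simes_rejects(p, config.alpha)
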