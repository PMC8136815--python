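"""Sliding-window Wilcoxon rank-sum comparison of motif counts.

For each window of the RNA map, per-event motif counts in the regulated exon
set are compared against the background exon set with the two-sample Wilcoxon
rank-sum (Mann-Whitney) test.  With the default 300-nt regions, 50-nt windows
and step 1 this yields a family of 250 highly correlated p-values per
(motif, region), summarized by the minimum raw p-value.  The minimum of many
dependent tests is a multiplicity artifact by itself, which is why interval
selection is delegated to the post-hoc FDP bounds in :mod:`splicemaps.posthoc`.

Test details
------------
* midranks for ties;
* exact p-value by enumeration of rank assignments when the pooled sample is
  small (``n <= exact_max_n``) and tie-free;
* otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction;
* a zero null variance (all observations tied) yields p = 0.5 one-sided /
  1.0 two-sided, the statistic sitting exactly at its null mean;
* the one-sided ``greater`` alternative (enrichment of the regulated set)
  is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import WindowCountMatrix

Alternative = str  # "greater", "less" or "two_sided"


@dataclass
class MapConfig:
    """Window-family geometry and test options for one RNA-map run."""

    window_width: int = 50
    step: int = 1
    region_length: int = 300
    alternative: Alternative = "greater"
    exact_max_n: int = 10

    def __post_init__(self) -> None:
        if self.region_length <= self.window_width:
            raise ValueError("region_length must exceed window_width")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.alternative not in ("greater", "less", "two_sided"):
            raise ValueError(f"bad alternative {self.alternative!r}")

    @property
    def n_windows(self) -> int:
        return len(range(0, self.region_length - self.window_width, self.step))


@dataclass
class WindowPValueSeries:
    """The per-window p-value family of one motif x region comparison."""

    motif_name: str
    region_label: str
    comparison: str
    pvalues: np.ndarray
    window_offsets: np.ndarray
    min_p: float = field(init=False)
    min_p_window: int = field(init=False)

    def __post_init__(self) -> None:
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        # argmin breaks ties at the smallest window index
        self.min_p_window = int(np.argmin(self.pvalues))
        self.min_p = float(self.pvalues[self.min_p_window])


@lru_cache(maxsize=64)
def _exact_ranksum_tail(n1: int, n2: int) -> np.ndarray:
    """P(W >= w) for the tie-free rank-sum W of a size-``n1`` sample drawn
    from ranks 1..n1+n2, for w = 0..max; computed by subset-sum counting."""
    n = n1 + n2
    max_w = n1 * (2 * n - n1 + 1) // 2
    # counts[k][s] = number of k-subsets of {1..n} with sum s
    counts = np.zeros((n1 + 1, max_w + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for value in range(1, n + 1):
        for k in range(min(n1, value), 0, -1):
            counts[k, value:] += counts[k - 1, : max_w + 1 - value]
    pmf = counts[n1]
    total = pmf.sum()
    sf = np.cumsum(pmf[::-1])[::-1] / total  # sf[w] = P(W >= w)
    return sf


def _ranks_and_ties(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = stats.rankdata(pooled, method="average")
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(np.float64) ** 3 - counts))
    return ranks, tie_term


def _normal_tail_p(
    w: float, n1: int, n2: int, tie_term: float, alternative: Alternative
) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0 if alternative == "two_sided" else 0.5
    sd = np.sqrt(var)
    p_greater = float(stats.norm.sf((w - mu - 0.5) / sd))
    p_less = float(stats.norm.cdf((w - mu + 0.5) / sd))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2.0 * min(p_greater, p_less))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative = "greater",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum test; returns (rank-sum of ``x``, p).

    ``greater`` tests enrichment of ``x`` over ``y``.  Exact enumeration is
    used for tie-free pooled samples of at most ``exact_max_n`` observations;
    ties force the tie-corrected normal approximation (with continuity
    correction) regardless of sample size.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"bad alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks, tie_term = _ranks_and_ties(pooled)
    w = float(ranks[: x.size].sum())
    n1, n2 = x.size, y.size
    if n1 + n2 <= exact_max_n and tie_term == 0:
        sf = _exact_ranksum_tail(n1, n2)
        w_int = int(round(w))
        max_w = len(sf) - 1
        p_greater = float(sf[w_int])
        p_less = float(1.0 - (sf[w_int + 1] if w_int < max_w else 0.0))
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return w, p
    return w, _normal_tail_p(w, n1, n2, tie_term, alternative)


def rank_sum_pvalues_matrix(
    x: np.ndarray, y: np.ndarray, alternative: Alternative = "greater"
) -> np.ndarray:
    """Column-wise tie-corrected normal-approximation rank-sum p-values.

    ``x`` (n1 x w) and ``y`` (n2 x w) are count matrices; each column is an
    independent window test of x-rows vs y-rows.  Small-integer count data
    take a histogram fast path (midranks and tie terms from per-value counts)
    that avoids per-column sorting.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 2 or y.ndim != 2 or x.shape[1] != y.shape[1]:
        raise ValueError("x and y must be 2-D with matching column counts")
    n1, n2 = x.shape[0], y.shape[0]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    width = x.shape[1]
    combined = np.vstack([x, y])

    integral = np.issubdtype(combined.dtype, np.integer)
    if integral and combined.min() >= 0 and combined.max() <= 256:
        values = np.unique(combined)
        less = np.zeros(width)
        w_stat = np.zeros(width)
        tie_term = np.zeros(width)
        for v in values:
            eq = combined == v
            c = eq.sum(axis=0).astype(np.float64)
            c1 = eq[:n1].sum(axis=0).astype(np.float64)
            midrank = less + (c + 1) / 2.0
            w_stat += c1 * midrank
            tie_term += c**3 - c
            less += c
    else:
        ranks = stats.rankdata(combined, method="average", axis=0)
        w_stat = ranks[:n1].sum(axis=0)
        srt = np.sort(combined, axis=0)
        tie_term = np.zeros(width)
        for col in range(width):
            _, counts = np.unique(srt[:, col], return_counts=True)
            tie_term[col] = np.sum(counts.astype(np.float64) ** 3 - counts)

    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(np.maximum(var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_greater = np.where(sd > 0, (w_stat - mu - 0.5) / sd, 0.0)
        z_less = np.where(sd > 0, (w_stat - mu + 0.5) / sd, 0.0)
    p_greater = stats.norm.sf(z_greater)
    p_less = stats.norm.cdf(z_less)
    degenerate = sd == 0
    if alternative == "greater":
        p = np.where(degenerate, 0.5, p_greater)
    elif alternative == "less":
        p = np.where(degenerate, 0.5, p_less)
    else:
        p = np.where(degenerate, 1.0, np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less)))
    return p


def enrichment_pvalues(
    counts_reg: WindowCountMatrix,
    counts_bg: WindowCountMatrix,
    config: MapConfig | None = None,
    comparison: str = "regulated_vs_background",
) -> WindowPValueSeries:
    """Per-window rank-sum p-values of regulated vs background counts for one
    motif x region; records the min-p summary (argmin ties -> smallest
    window index)."""
    config = config or MapConfig()
    if counts_reg.motif_name != counts_bg.motif_name:
        raise ValueError("count matrices come from different motifs")
    if counts_reg.region_label != counts_bg.region_label:
        raise ValueError("count matrices come from different region labels")
    if (
        counts_reg.n_windows != counts_bg.n_windows
        or counts_reg.window_width != counts_bg.window_width
        or counts_reg.step != counts_bg.step
    ):
        raise ValueError("window families do not match")
    n_total = counts_reg.counts.shape[0] + counts_bg.counts.shape[0]
    if n_total <= config.exact_max_n:
        pvalues = np.array(
            [
                wilcoxon_rank_sum(
                    counts_reg.counts[:, j],
                    counts_bg.counts[:, j],
                    alternative=config.alternative,
                    exact_max_n=config.exact_max_n,
                )[1]
                for j in range(counts_reg.n_windows)
            ]
        )
    else:
        pvalues = rank_sum_pvalues_matrix(
            counts_reg.counts, counts_bg.counts, alternative=config.alternative
        )
    return WindowPValueSeries(
        motif_name=counts_reg.motif_name,
        region_label=counts_reg.region_label,
        comparison=comparison,
        pvalues=pvalues,
        window_offsets=np.asarray(counts_reg.window_offsets),
    )


def summarize_min_p(series_collection: Iterable[WindowPValueSeries]) -> pd.DataFrame:
    """Rank motif x region p-value families by their minimum raw p-value
    (ascending; ties broken by motif name, then region label)."""
    rows = [
        {
            "motif": s.motif_name,
            "region": s.region_label,
            "comparison": s.comparison,
            "min_p": s.min_p,
            "min_p_window": s.min_p_window,
        }
        for s in series_collection
    ]
    table = pd.DataFrame(rows, columns=["motif", "region", "comparison", "min_p", "min_p_window"])
    if len(table):
        table = table.sort_values(
            ["min_p", "motif", "region"], kind="mergesort"
        ).reset_index(drop=True)
    return table
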