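"""Post-hoc false-discovery-proportion bounds over window intervals.

Post-hoc inference (Goeman-Solari closed testing; Blanchard-Neuvial-Roquain
reference families) provides, at confidence level 1 - alpha, a simultaneous
upper bound V(S) on the number of false positives inside *every* candidate
selection set S.  Because the bounds hold simultaneously, the FDP threshold
may be chosen after seeing the data without invalidating the guarantee.

We use the Simes (linear-template) bound over the m p-values of one motif x
region window family,

    V(S) = min_{k=1..|S|} [ #{p_i in S : p_i > alpha * k / m} + k - 1 ],

clipped to [0, |S|].  Its validity assumes the Simes inequality, which holds
under the positive dependence typical of overlapping-window statistics.  For
every contiguous window interval S = [i, j] the bound gives an FDP upper
bound V(S)/|S|; intervals with a bound strictly below the user's threshold
(25% by default) are called significantly enriched, reported as maximal
intervals, and each motif is ranked by its minimal interval bound (ph-FDP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .window_stats import WindowPValueSeries

INTERVAL_COLUMNS = ["motif", "region", "start", "end", "size", "fp_bound", "fdp_bound"]


@dataclass
class PosthocConfig:
    """Confidence level and selection threshold for the post-hoc bounds.

    ``alpha`` is the overall confidence level of the screen: when
    ``split_alpha`` is set (default), :func:`posthoc_screen` divides it
    equally across the motif x region families it scans, so that the FDP
    bounds hold simultaneously over every interval of every motif the user
    inspects — without the split, each family carries its own level-alpha
    guarantee and a multi-motif screen accumulates false selections.
    Functions operating on a single family (:func:`simes_posthoc_bound`,
    :func:`interval_bounds`) always use ``alpha`` directly.
    """

    alpha: float = 0.05
    fdp_threshold: float = 0.25
    split_alpha: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        if not (0.0 < self.fdp_threshold < 1.0):
            raise ValueError("fdp_threshold must lie in (0,1)")


@dataclass
class EnrichedInterval:
    """A contiguous window interval [start, end] (inclusive) with its
    false-positive upper bound."""

    motif_name: str
    region_label: str
    start: int
    end: int
    fp_upper_bound: int
    fdp_bound: float

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class MotifPosthocSummary:
    """Per-motif result: the minimal interval FDP bound (ph-FDP) and the
    maximal selected intervals per region.

    ``best_interval_size`` is the size of the largest interval attaining the
    ph-FDP value; it disambiguates ranks when several motifs share the same
    (often zero) bound — a bound covering more windows carries more evidence.
    """

    motif_name: str
    ph_fdp: float
    selected_intervals: list[EnrichedInterval] = field(default_factory=list)
    best_interval_size: int = 0


def simes_posthoc_bound(
    p_subset: Sequence[float], m: int, alpha: float = 0.05
) -> int:
    """Simes upper bound on the number of false positives in ``p_subset``,
    a subset of a family of ``m`` p-values."""
    p = np.asarray(p_subset, dtype=float)
    if p.size == 0:
        raise ValueError("p_subset must be non-empty")
    if m < p.size or m < 1:
        raise ValueError("family size m must be >= |p_subset|")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    k = np.arange(1, p.size + 1)
    thresholds = alpha * k / m
    exceed = (p[:, None] > thresholds[None, :]).sum(axis=0)
    bound = int(np.min(exceed + k - 1))
    return int(np.clip(bound, 0, p.size))


def simes_rejects(pvalues: Sequence[float], alpha: float = 0.05, m: int | None = None) -> bool:
    """Whether the Simes test rejects the family-wide intersection null,
    i.e. whether p_(k) <= alpha * k / m for some k.

    When it does not, every subset S of the family provably has
    V(S) = |S| (FDP bound 1), so no interval can be selected at any
    threshold below 1 — the screening fast path relies on this.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = m or p.size
    k = np.arange(1, p.size + 1)
    return bool(np.any(p <= alpha * k / m))


def interval_bounds(
    pvalues: WindowPValueSeries | Sequence[float],
    config: PosthocConfig | None = None,
) -> pd.DataFrame:
    """Simes FDP bounds for *all* contiguous window intervals of one family.

    Returns a DataFrame with columns motif, region, start, end (inclusive),
    size, fp_bound and fdp_bound.  For each interval the bound is evaluated
    against the full family size m = number of windows; per-k indicator
    prefix sums keep the full m = 250 table under a second.
    """
    config = config or PosthocConfig()
    if isinstance(pvalues, WindowPValueSeries):
        motif, region = pvalues.motif_name, pvalues.region_label
        p = np.asarray(pvalues.pvalues, dtype=float)
    else:
        motif, region = "", ""
        p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("empty p-value family")
    k = np.arange(1, m + 1)
    thresholds = config.alpha * k / m
    indicator = (p[None, :] > thresholds[:, None]).astype(np.int64)  # (k, window)
    prefix = np.concatenate(
        [np.zeros((m, 1), dtype=np.int64), np.cumsum(indicator, axis=1)], axis=1
    )
    starts_out = np.empty(m * (m + 1) // 2, dtype=np.int64)
    ends_out = np.empty_like(starts_out)
    fp_out = np.empty_like(starts_out)
    pos = 0
    diag = np.arange(m)
    for i in range(m):
        width = m - i
        # counts[k-1, c] = #{p in [i, i+c] : p > alpha*k/m}
        counts = prefix[:, i + 1 :] - prefix[:, i : i + 1]
        value = counts + (k - 1)[:, None]
        running_min = np.minimum.accumulate(value, axis=0)
        v = running_min[diag[:width], diag[:width]]  # k limited to interval size
        sizes = diag[:width] + 1
        v = np.clip(v, 0, sizes)
        starts_out[pos : pos + width] = i
        ends_out[pos : pos + width] = i + diag[:width]
        fp_out[pos : pos + width] = v
        pos += width
    sizes_all = ends_out - starts_out + 1
    table = pd.DataFrame(
        {
            "motif": motif,
            "region": region,
            "start": starts_out,
            "end": ends_out,
            "size": sizes_all,
            "fp_bound": fp_out,
            "fdp_bound": fp_out / sizes_all,
        },
        columns=INTERVAL_COLUMNS,
    )
    return table


def _maximal(intervals: list[EnrichedInterval]) -> list[EnrichedInterval]:
    """Drop intervals contained in another selected interval of the same
    region (keeps the outermost representation of each enriched locus)."""
    by_region: dict[str, list[EnrichedInterval]] = {}
    for iv in intervals:
        by_region.setdefault(iv.region_label, []).append(iv)
    kept: list[EnrichedInterval] = []
    for region in sorted(by_region):
        ordered = sorted(by_region[region], key=lambda iv: (iv.start, -iv.end))
        max_end = -1
        for iv in ordered:
            if iv.end > max_end:
                kept.append(iv)
                max_end = iv.end
    return kept


def select_intervals(
    interval_table: pd.DataFrame,
    config: PosthocConfig | None = None,
    motif_name: str | None = None,
) -> MotifPosthocSummary:
    """Select intervals with fdp_bound strictly below the threshold, reduce
    them to maximal intervals per region, and record the table-wide minimum
    bound as the motif's ph-FDP."""
    config = config or PosthocConfig()
    if motif_name is None:
        motifs = interval_table["motif"].unique()
        motif_name = str(motifs[0]) if len(motifs) else ""
    ph_fdp = float(interval_table["fdp_bound"].min()) if len(interval_table) else 1.0
    hits = interval_table[interval_table["fdp_bound"] < config.fdp_threshold]
    intervals = [
        EnrichedInterval(
            motif_name=motif_name,
            region_label=str(row.region),
            start=int(row.start),
            end=int(row.end),
            fp_upper_bound=int(row.fp_bound),
            fdp_bound=float(row.fdp_bound),
        )
        for row in hits.itertuples()
    ]
    return MotifPosthocSummary(
        motif_name=motif_name, ph_fdp=ph_fdp, selected_intervals=_maximal(intervals)
    )


def posthoc_screen(
    all_series: Iterable[WindowPValueSeries],
    config: PosthocConfig | None = None,
    fast: bool = True,
) -> list[MotifPosthocSummary]:
    """One post-hoc summary per motif over its region families, ranked
    ascending by ph-FDP (ties broken by motif name).

    With ``fast`` (default), families in which the Simes test does not reject
    the global null are skipped: every interval bound in such a family equals
    its size, so the family contributes ph-FDP 1 and no selection — identical
    to the exhaustive path.
    """
    config = config or PosthocConfig()
    by_motif: dict[str, list[WindowPValueSeries]] = {}
    n_families = 0
    for series in all_series:
        by_motif.setdefault(series.motif_name, []).append(series)
        n_families += 1
    family_alpha = config.alpha / n_families if (config.split_alpha and n_families) else config.alpha
    family_config = PosthocConfig(
        alpha=family_alpha, fdp_threshold=config.fdp_threshold, split_alpha=False
    )
    summaries: list[MotifPosthocSummary] = []
    for motif_name, series_list in by_motif.items():
        ph_fdp = 1.0
        best_size = 0
        intervals: list[EnrichedInterval] = []
        for series in series_list:
            if fast and not simes_rejects(series.pvalues, alpha=family_alpha):
                continue
            table = interval_bounds(series, family_config)
            series_min = float(table["fdp_bound"].min())
            series_best = int(table.loc[table["fdp_bound"] == series_min, "size"].max())
            if series_min < ph_fdp:
                ph_fdp, best_size = series_min, series_best
            elif series_min == ph_fdp:
                best_size = max(best_size, series_best)
            intervals.extend(
                select_intervals(table, family_config, motif_name).selected_intervals
            )
        if ph_fdp >= 1.0:
            best_size = 0  # a trivial bound covers no evidence
        summaries.append(
            MotifPosthocSummary(
                motif_name=motif_name,
                ph_fdp=ph_fdp,
                selected_intervals=_maximal(intervals),
                best_interval_size=best_size,
            )
        )
    # ties on the (frequently zero) bound are broken by how many windows the
    # bound covers, then by name for determinism
    summaries.sort(key=lambda s: (s.ph_fdp, -s.best_interval_size, s.motif_name))
    return summaries


def summaries_to_frame(summaries: Sequence[MotifPosthocSummary]) -> pd.DataFrame:
    """Flatten a screen into the per-motif ranking table."""
    return pd.DataFrame(
        {
            "motif": [s.motif_name for s in summaries],
            "ph_fdp": [s.ph_fdp for s in summaries],
            "best_interval_size": [s.best_interval_size for s in summaries],
            "n_selected_intervals": [len(s.selected_intervals) for s in summaries],
        },
        columns=["motif", "ph_fdp", "best_interval_size", "n_selected_intervals"],
    )


def intervals_to_frame(summaries: Sequence[MotifPosthocSummary]) -> pd.DataFrame:
    """Selected maximal intervals of a screen as one table."""
    rows = [
        {
            "motif": s.motif_name,
            "region": iv.region_label,
            "start": iv.start,
            "end": iv.end,
            "size": iv.size,
            "fp_bound": iv.fp_upper_bound,
            "fdp_bound": iv.fdp_bound,
        }
        for s in summaries
        for iv in s.selected_intervals
    ]
    return pd.DataFrame(
        rows, columns=["motif", "region", "start", "end", "size", "fp_bound", "fdp_bound"]
    )
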