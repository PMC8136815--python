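"""Cross-dataset event overlap and dPSI direction-concordance statistics.

Two knockdown experiments are compared by matching splicing events on exact
coordinates, testing whether the overlap of their regulated sets exceeds the
hypergeometric expectation nA*nB/N (the universe size N — e.g. all events
passing the read-support filter in both datasets — must be supplied, never
guessed), and classifying shared events as 'similar' or 'opposite' by the
sign of their dPSI values.  A plain 2x2 Pearson chi-square is provided for
two-proportion comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .events import SplicingEvent

logger = logging.getLogger(__name__)


class EventKey(NamedTuple):
    """Coordinate identity of a splicing event across datasets."""

    chrom: str
    strand: str
    event_type: str
    exon_start: int
    exon_end: int
    upstream_exon_end: int
    downstream_exon_start: int


def event_key(event: SplicingEvent) -> EventKey:
    return EventKey(
        chrom=event.chrom,
        strand=event.strand,
        event_type=event.event_type.value,
        exon_start=event.exon_start,
        exon_end=event.exon_end,
        upstream_exon_end=event.upstream_exon_end,
        downstream_exon_start=event.downstream_exon_start,
    )


@dataclass
class OverlapResult:
    """Observed vs expected overlap of two event sets from a universe of N."""

    n_a: int
    n_b: int
    universe: int
    k_observed: int
    expected: float
    p_value: float


@dataclass
class ConcordanceResult:
    """Direction agreement of dPSI across paired events; zero-dPSI pairs are
    excluded from both counts and reported separately."""

    n_common: int
    n_similar: int
    n_opposite: int
    n_zero: int
    proportion_similar: float


def _collapse(events: Iterable[SplicingEvent]) -> dict[EventKey, SplicingEvent]:
    unique: dict[EventKey, SplicingEvent] = {}
    duplicates = 0
    for ev in events:
        key = event_key(ev)
        if key in unique:
            duplicates += 1
            continue
        unique[key] = ev
    if duplicates:
        logger.warning("collapsed %d duplicate event keys", duplicates)
    return unique


def match_events(
    events_a: Sequence[SplicingEvent], events_b: Sequence[SplicingEvent]
) -> list[tuple[SplicingEvent, SplicingEvent]]:
    """Pair events sharing an identical coordinate key; duplicates within a
    list are collapsed (first occurrence wins) with a warning.  Order follows
    ``events_a``."""
    index_b = _collapse(events_b)
    pairs = []
    seen: set[EventKey] = set()
    for ev in events_a:
        key = event_key(ev)
        if key in seen:
            logger.warning("collapsed duplicate event key %s", (key,))
            continue
        seen.add(key)
        if key in index_b:
            pairs.append((ev, index_b[key]))
    return pairs


def overlap_test(n_a: int, n_b: int, universe: int, k_observed: int) -> OverlapResult:
    """Hypergeometric overlap test: expected overlap nA*nB/N and the
    upper-tail probability P(K >= k) of observing at least ``k_observed``
    shared events when both sets are drawn from a universe of size N."""
    if min(n_a, n_b, universe, k_observed) < 0:
        raise ValueError("set sizes must be non-negative")
    if n_a > universe or n_b > universe:
        raise ValueError("set sizes cannot exceed the universe size")
    if k_observed > min(n_a, n_b):
        raise ValueError("observed overlap cannot exceed the smaller set")
    expected = n_a * n_b / universe
    p_value = float(stats.hypergeom.sf(k_observed - 1, universe, n_a, n_b))
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        universe=universe,
        k_observed=k_observed,
        expected=expected,
        p_value=p_value,
    )


def direction_concordance(
    paired_events: Sequence[tuple[SplicingEvent, SplicingEvent]]
) -> ConcordanceResult:
    """Classify each pair as similar (same non-zero dPSI sign) or opposite
    (discordant non-zero signs); pairs with a zero dPSI on either side are
    excluded and counted separately."""
    similar = opposite = zero = 0
    for ev_a, ev_b in paired_events:
        sign_a = np.sign(ev_a.delta_psi)
        sign_b = np.sign(ev_b.delta_psi)
        if sign_a == 0 or sign_b == 0:
            zero += 1
        elif sign_a == sign_b:
            similar += 1
        else:
            opposite += 1
    n_common = similar + opposite
    proportion = similar / n_common if n_common else float("nan")
    return ConcordanceResult(
        n_common=n_common,
        n_similar=similar,
        n_opposite=opposite,
        n_zero=zero,
        proportion_similar=proportion,
    )


def two_proportion_chisq(
    counts: Sequence[Sequence[int]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table (no continuity correction by
    default); returns (statistic, p) against the 1-df distribution."""
    table = np.asarray(counts, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    if (table == table[0, 0]).all():
        # scipy handles homogeneous tables fine; keep explicit zero-statistic
        return 0.0, 1.0
    result = stats.chi2_contingency(table, correction=correction)
    return float(result.statistic), float(result.pvalue)
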