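"""Reading, writing and filtering of rMATS-style differential splicing tables.

An *event* is one alternative-splicing unit (a skipped exon, alternative
splice site, mutually exclusive exon pair or retained intron) quantified by
inclusion/skipping junction read counts and per-replicate PSI (percent
spliced-in) values in two conditions.  This module parses the rMATS TSV
dialects into :class:`SplicingEvent` records and applies the standard
selection rules used in RNA-map analyses:

* significance — read support, |dPSI| and FDR thresholds;
* background — unaffected exons (high FDR, PSI away from 0/1 extremes);
* direction — spliced-in vs spliced-out, with dPSI = mean PSI(control)
  - mean PSI(knockdown);
* validation candidates — events with deep read support in one condition.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

DELTA_PSI_TOLERANCE = 1e-6


class EventType(str, enum.Enum):
    """rMATS alternative-splicing event categories."""

    SE = "SE"
    A3SS = "A3SS"
    A5SS = "A5SS"
    MXE = "MXE"
    RI = "RI"


class Direction(str, enum.Enum):
    """Sign of dPSI = mean PSI(group1/control) - mean PSI(group2)."""

    SPLICED_IN = "spliced_in"
    SPLICED_OUT = "spliced_out"
    UNCHANGED = "unchanged"


@dataclass
class SplicingEvent:
    """One alternative-splicing event in 0-based half-open genomic coordinates.

    ``exon_start``/``exon_end`` bound the target (cassette) exon;
    ``upstream_exon_end``/``downstream_exon_start`` bound the flanking introns
    in genomic orientation (upstream = lower coordinate).  Count and PSI lists
    carry one entry per replicate; PSI lists may be ``None`` when the table
    had no usable values.
    """

    event_id: str
    gene_id: str
    event_type: EventType
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_exon_end: int
    downstream_exon_start: int
    inc_counts_g1: list[int]
    skip_counts_g1: list[int]
    inc_counts_g2: list[int]
    skip_counts_g2: list[int]
    psi_g1: list[float] | None
    psi_g2: list[float] | None
    pvalue: float
    fdr: float
    delta_psi: float

    def validate(self) -> None:
        """Check coordinate ordering, value ranges and dPSI consistency."""
        if self.strand not in ("+", "-"):
            raise ValueError(f"event {self.event_id}: bad strand {self.strand!r}")
        if not (
            self.upstream_exon_end
            <= self.exon_start
            < self.exon_end
            <= self.downstream_exon_start
        ):
            raise ValueError(
                f"event {self.event_id}: coordinates violate "
                "upstream_exon_end <= exon_start < exon_end <= downstream_exon_start"
            )
        if len(self.inc_counts_g1) != len(self.skip_counts_g1) or len(
            self.inc_counts_g2
        ) != len(self.skip_counts_g2):
            raise ValueError(f"event {self.event_id}: replicate count lists disagree")
        for counts in (
            self.inc_counts_g1,
            self.skip_counts_g1,
            self.inc_counts_g2,
            self.skip_counts_g2,
        ):
            if any(c < 0 for c in counts):
                raise ValueError(f"event {self.event_id}: negative read count")
        for frac, name in ((self.pvalue, "pvalue"), (self.fdr, "fdr")):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"event {self.event_id}: {name}={frac} outside [0,1]")
        if not (-1.0 <= self.delta_psi <= 1.0):
            raise ValueError(f"event {self.event_id}: delta_psi outside [-1,1]")
        if self.psi_g1 and self.psi_g2:
            observed = sum(self.psi_g1) / len(self.psi_g1) - sum(self.psi_g2) / len(
                self.psi_g2
            )
            if not math.isclose(
                observed, self.delta_psi, abs_tol=max(DELTA_PSI_TOLERANCE, 5e-4)
            ):
                # rMATS prints IncLevelDifference rounded to 3 decimals, so
                # allow that much; warn rather than fail on real tables.
                logger.warning(
                    "event %s: delta_psi %.6f inconsistent with mean PSI "
                    "difference %.6f",
                    self.event_id,
                    self.delta_psi,
                    observed,
                )


@dataclass
class FilterCriteria:
    """Thresholds defining a significantly regulated event.

    Defaults follow the standard rule set: at least 15 supporting reads,
    |dPSI| > 10% and FDR < 0.05, with >50 reads in one condition for
    RT-PCR validation candidates.  All inequalities are strict except the
    read-support floor.
    """

    min_unique_reads: int = 15
    min_abs_delta_psi: float = 0.10
    max_fdr: float = 0.05
    min_validation_reads: int = 50

    def __post_init__(self) -> None:
        if self.min_unique_reads < 0 or self.min_validation_reads < 0:
            raise ValueError("read thresholds must be non-negative")
        for frac in (self.min_abs_delta_psi, self.max_fdr):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fraction thresholds must lie in [0,1]")


@dataclass
class BackgroundCriteria:
    """Rule for unaffected (background) exons: FDR > 0.5, maxPSI > 0.15,
    minPSI < 0.85 over all replicate PSI values of both groups."""

    min_fdr: float = 0.5
    min_max_psi: float = 0.15
    max_min_psi: float = 0.85

    def __post_init__(self) -> None:
        for frac in (self.min_fdr, self.min_max_psi, self.max_min_psi):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("background thresholds must lie in [0,1]")


# Per-dialect coordinate columns mapped onto
# (exon_start, exon_end, upstream_exon_end, downstream_exon_start).
_COORD_COLUMNS: dict[EventType, tuple[str, str, str, str]] = {
    EventType.SE: ("exonStart_0base", "exonEnd", "upstreamEE", "downstreamES"),
    EventType.MXE: ("1stExonStart_0base", "1stExonEnd", "upstreamEE", "downstreamES"),
    EventType.RI: ("upstreamEE", "downstreamES", "upstreamEE", "downstreamES"),
}

_STAT_COLUMNS = [
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncLevel1",
    "IncLevel2",
    "PValue",
    "FDR",
    "IncLevelDifference",
]

SE_COLUMNS = [
    "ID",
    "GeneID",
    "chr",
    "strand",
    "exonStart_0base",
    "exonEnd",
    "upstreamEE",
    "downstreamES",
] + _STAT_COLUMNS


def _required_columns(event_type: EventType) -> list[str]:
    base = ["ID", "GeneID", "chr", "strand"]
    if event_type in _COORD_COLUMNS:
        coords = [c for c in _COORD_COLUMNS[event_type] if c not in base]
    else:  # A3SS / A5SS
        coords = ["longExonStart_0base", "longExonEnd", "flankingES", "flankingEE"]
    # preserve order, drop duplicates (RI reuses intron bounds)
    seen: list[str] = []
    for c in base + coords + _STAT_COLUMNS:
        if c not in seen:
            seen.append(c)
    return seen


def _parse_int_list(text: str, row: int, column: str) -> list[int]:
    try:
        return [int(tok) for tok in str(text).strip().split(",") if tok != ""]
    except ValueError as exc:
        raise ValueError(f"row {row}, column {column}: bad count list {text!r}") from exc


def _parse_psi_list(text: str) -> list[float] | None:
    values = [
        float(tok)
        for tok in str(text).strip().split(",")
        if tok not in ("", "NA", "nan")
    ]
    return values or None


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row}, column {column}: bad number {text!r}") from exc


def read_events(table_path: str | Path, event_type: EventType | str) -> list[SplicingEvent]:
    """Parse one rMATS-style TSV into :class:`SplicingEvent` records.

    rMATS prints 0-based starts and 1-based inclusive ends, numerically
    identical to 0-based half-open intervals, so coordinates are taken as-is.
    Replicate fields are comma-separated; ``NA`` PSI entries are dropped.
    Malformed rows raise ``ValueError`` naming the row and column.
    """
    try:
        event_type = EventType(event_type)
    except ValueError as exc:
        raise ValueError(f"unknown event type {event_type!r}") from exc
    table_path = Path(table_path)
    with open(table_path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        required = _required_columns(event_type)
        missing = [c for c in required if c not in header]
        if missing:
            raise ValueError(
                f"{table_path}: missing required columns for {event_type.value}: {missing}"
            )
        index = {name: i for i, name in enumerate(header)}
        events: list[SplicingEvent] = []
        for row_number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < len(header):
                raise ValueError(
                    f"row {row_number}, column {header[len(fields)]}: truncated row"
                )

            def get(col: str) -> str:
                return fields[index[col]]

            if event_type in _COORD_COLUMNS:
                cs, ce, uee, des = _COORD_COLUMNS[event_type]
                exon_start = int(get(cs))
                exon_end = int(get(ce))
                upstream_end = int(get(uee))
                downstream_start = int(get(des))
            else:
                # Alternative splice sites: the flanking exon sits on one side
                # only; the other bound degenerates to the target exon edge.
                exon_start = int(get("longExonStart_0base"))
                exon_end = int(get("longExonEnd"))
                flank_start = int(get("flankingES"))
                flank_end = int(get("flankingEE"))
                if flank_end <= exon_start:
                    upstream_end, downstream_start = flank_end, exon_end
                elif flank_start >= exon_end:
                    upstream_end, downstream_start = exon_start, flank_start
                else:
                    raise ValueError(
                        f"row {row_number}, column flankingES: flanking exon "
                        "overlaps target exon"
                    )

            event = SplicingEvent(
                event_id=get("ID"),
                gene_id=get("GeneID").strip('"'),
                event_type=event_type,
                chrom=get("chr"),
                strand=get("strand"),
                exon_start=exon_start,
                exon_end=exon_end,
                upstream_exon_end=upstream_end,
                downstream_exon_start=downstream_start,
                inc_counts_g1=_parse_int_list(get("IJC_SAMPLE_1"), row_number, "IJC_SAMPLE_1"),
                skip_counts_g1=_parse_int_list(get("SJC_SAMPLE_1"), row_number, "SJC_SAMPLE_1"),
                inc_counts_g2=_parse_int_list(get("IJC_SAMPLE_2"), row_number, "IJC_SAMPLE_2"),
                skip_counts_g2=_parse_int_list(get("SJC_SAMPLE_2"), row_number, "SJC_SAMPLE_2"),
                psi_g1=_parse_psi_list(get("IncLevel1")),
                psi_g2=_parse_psi_list(get("IncLevel2")),
                pvalue=_parse_float(get("PValue"), row_number, "PValue"),
                fdr=_parse_float(get("FDR"), row_number, "FDR"),
                delta_psi=_parse_float(
                    get("IncLevelDifference"), row_number, "IncLevelDifference"
                ),
            )
            try:
                event.validate()
            except ValueError as exc:
                raise ValueError(f"row {row_number}: {exc}") from exc
            events.append(event)
    return events


def _format_float(value: float) -> str:
    return f"{value:.6g}"


def _format_psi_list(values: list[float] | None) -> str:
    if not values:
        return "NA"
    return ",".join(_format_float(v) for v in values)


def write_events(
    events: Sequence[SplicingEvent],
    table_path: str | Path,
    event_type: EventType | str | None = None,
    directions: Sequence[Direction] | None = None,
) -> None:
    """Write events back to the canonical SE-style TSV dialect.

    Floats are printed with 6 significant digits, a formatting that is
    idempotent under a read/write round trip.  When ``directions`` is given,
    an extra ``Direction`` column is appended (used for filtered-event
    exports).
    """
    if event_type is None:
        if not events:
            raise ValueError("cannot infer event type from an empty list")
        event_type = events[0].event_type
    event_type = EventType(event_type)
    if any(ev.event_type != event_type for ev in events):
        raise ValueError("mixed event types in write_events")
    columns = list(SE_COLUMNS)
    if event_type is not EventType.SE:
        # non-SE dialects re-use the normalized coordinate columns
        columns = list(SE_COLUMNS)
    header = columns + (["Direction"] if directions is not None else [])
    lines = ["\t".join(header)]
    for i, ev in enumerate(events):
        row = [
            ev.event_id,
            ev.gene_id,
            ev.chrom,
            ev.strand,
            str(ev.exon_start),
            str(ev.exon_end),
            str(ev.upstream_exon_end),
            str(ev.downstream_exon_start),
            ",".join(str(c) for c in ev.inc_counts_g1),
            ",".join(str(c) for c in ev.skip_counts_g1),
            ",".join(str(c) for c in ev.inc_counts_g2),
            ",".join(str(c) for c in ev.skip_counts_g2),
            _format_psi_list(ev.psi_g1),
            _format_psi_list(ev.psi_g2),
            _format_float(ev.pvalue),
            _format_float(ev.fdr),
            _format_float(ev.delta_psi),
        ]
        if directions is not None:
            row.append(directions[i].value)
        lines.append("\t".join(row))
    Path(table_path).write_text("\n".join(lines) + "\n")


def total_unique_reads(event: SplicingEvent) -> int:
    """Total read support: sum of inclusion + skipping junction counts over
    all replicates of both groups (the simplest monotone support measure)."""
    return (
        sum(event.inc_counts_g1)
        + sum(event.skip_counts_g1)
        + sum(event.inc_counts_g2)
        + sum(event.skip_counts_g2)
    )


def filter_significant(
    events: Iterable[SplicingEvent], criteria: FilterCriteria | None = None
) -> list[SplicingEvent]:
    """Retain significantly regulated events.

    Rules (order preserved): total read support >= ``min_unique_reads``,
    |dPSI| strictly above ``min_abs_delta_psi`` and FDR strictly below
    ``max_fdr``.  Boundary values are excluded by the strict inequalities.
    """
    criteria = criteria or FilterCriteria()
    return [
        ev
        for ev in events
        if total_unique_reads(ev) >= criteria.min_unique_reads
        and abs(ev.delta_psi) > criteria.min_abs_delta_psi
        and ev.fdr < criteria.max_fdr
    ]


def select_background(
    events: Iterable[SplicingEvent], criteria: BackgroundCriteria | None = None
) -> list[SplicingEvent]:
    """Retain unaffected exons: FDR > ``min_fdr``, max replicate PSI >
    ``min_max_psi`` and min replicate PSI < ``max_min_psi`` (both groups
    pooled).  Events without PSI values are skipped with a warning."""
    criteria = criteria or BackgroundCriteria()
    selected = []
    for ev in events:
        psi = (ev.psi_g1 or []) + (ev.psi_g2 or [])
        if not psi:
            logger.warning("event %s: no PSI values; excluded from background", ev.event_id)
            continue
        if (
            ev.fdr > criteria.min_fdr
            and max(psi) > criteria.min_max_psi
            and min(psi) < criteria.max_min_psi
        ):
            selected.append(ev)
    return selected


def classify_direction(event: SplicingEvent) -> Direction:
    """spliced_in for dPSI > 0 (exon more included in control/group1),
    spliced_out for dPSI < 0, unchanged at exactly zero."""
    if event.delta_psi > 0:
        return Direction.SPLICED_IN
    if event.delta_psi < 0:
        return Direction.SPLICED_OUT
    return Direction.UNCHANGED


def select_validation_candidates(
    events: Iterable[SplicingEvent], criteria: FilterCriteria | None = None
) -> list[SplicingEvent]:
    """Events with strictly more than ``min_validation_reads`` supporting
    reads (inclusion + skipping) within at least one condition."""
    criteria = criteria or FilterCriteria()
    return [
        ev
        for ev in events
        if sum(ev.inc_counts_g1) + sum(ev.skip_counts_g1) > criteria.min_validation_reads
        or sum(ev.inc_counts_g2) + sum(ev.skip_counts_g2) > criteria.min_validation_reads
    ]
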