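"""End-to-end orchestration: filter events, build regions, scan motifs,
compute window p-value families and post-hoc FDP screens, with deterministic
TSV/JSON outputs.

:func:`analyze_rna_map` is the in-memory core (used directly by tests and
simulations); :func:`run_map` wraps it with file input/output and run
metadata.  :func:`run_concordance` covers the cross-dataset overlap and
direction-concordance comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import pandas as pd

from .concordance import (
    ConcordanceResult,
    OverlapResult,
    direction_concordance,
    event_key,
    match_events,
    overlap_test,
)
from .events import (
    BackgroundCriteria,
    Direction,
    EventType,
    FilterCriteria,
    SplicingEvent,
    classify_direction,
    filter_significant,
    read_events,
    select_background,
    write_events,
)
from .motifs import Motif, build_count_matrices, load_compendium
from .posthoc import (
    MotifPosthocSummary,
    PosthocConfig,
    intervals_to_frame,
    posthoc_screen,
    summaries_to_frame,
)
from .regions import EventRegions, GenomeSequenceStore, RegionSpec, build_event_regions, load_genome, regions_to_bed
from .window_stats import MapConfig, WindowPValueSeries, enrichment_pvalues, summarize_min_p

logger = logging.getLogger(__name__)


def _package_version() -> str:
    try:
        return version("splicemaps")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class RunConfig:
    """Paths and stage parameters of one RNA-map run."""

    events_table: str
    genome_fasta: str
    motif_compendium: str
    out_dir: str
    event_type: str = "SE"
    direction: str = "both"  # spliced_in, spliced_out or both
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    background_criteria: BackgroundCriteria = field(default_factory=BackgroundCriteria)
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    map_config: MapConfig = field(default_factory=MapConfig)
    posthoc_config: PosthocConfig = field(default_factory=PosthocConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("spliced_in", "spliced_out", "both"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class MapResult:
    """All stage outputs of one RNA-map analysis."""

    significant_events: list[SplicingEvent]
    analysis_events: list[SplicingEvent]  # after the direction restriction
    background_events: list[SplicingEvent]
    regulated_regions: list[EventRegions]
    background_regions: list[EventRegions]
    pvalue_series: list[WindowPValueSeries]
    min_p_table: pd.DataFrame
    summaries: list[MotifPosthocSummary]
    ranking: pd.DataFrame
    selected_intervals: pd.DataFrame


def analyze_rna_map(
    events: Sequence[SplicingEvent],
    store: GenomeSequenceStore,
    motifs: Sequence[Motif],
    filter_criteria: FilterCriteria | None = None,
    background_criteria: BackgroundCriteria | None = None,
    region_spec: RegionSpec | None = None,
    map_config: MapConfig | None = None,
    posthoc_config: PosthocConfig | None = None,
    direction: str = "both",
) -> MapResult:
    """Run the full RNA-map analysis in memory.

    Stages: significance filter (optionally restricted to spliced-in or
    spliced-out events), background selection, region construction, motif
    scanning/window counting, per-window rank-sum p-values and the post-hoc
    FDP screen ranked by ph-FDP.
    """
    filter_criteria = filter_criteria or FilterCriteria()
    background_criteria = background_criteria or BackgroundCriteria()
    region_spec = region_spec or RegionSpec()
    map_config = map_config or MapConfig()
    posthoc_config = posthoc_config or PosthocConfig()

    significant = filter_significant(events, filter_criteria)
    if direction == "spliced_in":
        analysis = [ev for ev in significant if classify_direction(ev) is Direction.SPLICED_IN]
    elif direction == "spliced_out":
        analysis = [ev for ev in significant if classify_direction(ev) is Direction.SPLICED_OUT]
    else:
        analysis = list(significant)
    background = select_background(events, background_criteria)

    se_only = [ev for ev in analysis if ev.event_type is EventType.SE]
    bg_se = [ev for ev in background if ev.event_type is EventType.SE]
    regulated_regions = [build_event_regions(ev, store, region_spec) for ev in se_only]
    background_regions = [build_event_regions(ev, store, region_spec) for ev in bg_se]

    reg_matrices = build_count_matrices(
        regulated_regions, motifs, map_config.window_width, map_config.step
    )
    bg_matrices = build_count_matrices(
        background_regions, motifs, map_config.window_width, map_config.step
    )
    bg_index = {(m.motif_name, m.region_label): m for m in bg_matrices}
    series = []
    for reg_matrix in reg_matrices:
        key = (reg_matrix.motif_name, reg_matrix.region_label)
        if key not in bg_index:
            logger.warning("no background counts for %s; skipped", key)
            continue
        series.append(enrichment_pvalues(reg_matrix, bg_index[key], map_config))

    summaries = posthoc_screen(series, posthoc_config)
    return MapResult(
        significant_events=significant,
        analysis_events=analysis,
        background_events=background,
        regulated_regions=regulated_regions,
        background_regions=background_regions,
        pvalue_series=series,
        min_p_table=summarize_min_p(series),
        summaries=summaries,
        ranking=summaries_to_frame(summaries),
        selected_intervals=intervals_to_frame(summaries),
    )


def _write_tsv(frame: pd.DataFrame, path: Path, float_format: str = "%.6g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def run_map(config: RunConfig) -> MapResult:
    """File-level RNA-map run: reads the event table, genome and compendium,
    writes every stage output as TSV plus run metadata, and returns the
    in-memory result.  Reruns on identical inputs are byte-identical (no
    timestamps in any output)."""
    for path_name in ("events_table", "genome_fasta", "motif_compendium"):
        path = Path(getattr(config, path_name))
        if not path.exists():
            raise FileNotFoundError(f"{path_name}: {path} does not exist")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    events = read_events(config.events_table, config.event_type)
    store = load_genome(config.genome_fasta)
    motifs = load_compendium(config.motif_compendium)
    result = analyze_rna_map(
        events,
        store,
        motifs,
        config.filter_criteria,
        config.background_criteria,
        config.region_spec,
        config.map_config,
        config.posthoc_config,
        config.direction,
    )

    write_events(
        result.analysis_events,
        out_dir / "filtered_events.tsv",
        config.event_type,
        directions=[classify_direction(ev) for ev in result.analysis_events],
    )
    write_events(result.background_events, out_dir / "background_events.tsv", config.event_type)
    regions_to_bed(
        result.regulated_regions + result.background_regions, out_dir / "regions.bed"
    )

    profiles = pd.DataFrame(
        [
            {
                "motif": s.motif_name,
                "region": s.region_label,
                "window_offset": int(offset),
                "p_value": float(p),
            }
            for s in result.pvalue_series
            for offset, p in zip(s.window_offsets, s.pvalues)
        ],
        columns=["motif", "region", "window_offset", "p_value"],
    )
    _write_tsv(profiles, out_dir / "pvalue_profiles.tsv")
    _write_tsv(result.min_p_table, out_dir / "minp_summary.tsv")
    _write_tsv(result.ranking, out_dir / "phfdp_ranking.tsv")
    _write_tsv(result.selected_intervals, out_dir / "selected_intervals.tsv")

    metadata = {
        "package_version": _package_version(),
        "seed": config.seed,
        "event_type": config.event_type,
        "direction": config.direction,
        "filter_criteria": asdict(config.filter_criteria),
        "background_criteria": asdict(config.background_criteria),
        "region_spec": asdict(config.region_spec),
        "map_config": asdict(config.map_config),
        "posthoc_config": asdict(config.posthoc_config),
        "window_convention": "n_windows = region_length - window_width; "
        "a match belongs to a window when its start offset lies inside it",
        "n_events": len(events),
        "n_significant": len(result.significant_events),
        "n_analysis": len(result.analysis_events),
        "n_background": len(result.background_events),
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True) + "\n"
    )
    return result


def run_concordance(
    events_a: Sequence[SplicingEvent] | str | Path,
    events_b: Sequence[SplicingEvent] | str | Path,
    universe_size: int,
    out_dir: str | Path | None = None,
    event_type: str = "SE",
    filter_criteria: FilterCriteria | None = None,
) -> tuple[OverlapResult, ConcordanceResult]:
    """Overlap + direction concordance of two regulated event sets.

    Inputs may be parsed event lists or table paths (filtered on read).  The
    universe size N behind the expected overlap nA*nB/N must be supplied
    explicitly; there is no sensible default.
    """
    if universe_size is None or universe_size <= 0:
        raise ValueError("universe_size must be a positive integer")
    if isinstance(events_a, (str, Path)):
        events_a = filter_significant(read_events(events_a, event_type), filter_criteria)
    if isinstance(events_b, (str, Path)):
        events_b = filter_significant(read_events(events_b, event_type), filter_criteria)
    pairs = match_events(events_a, events_b)
    n_a = len({event_key(ev) for ev in events_a})
    n_b = len({event_key(ev) for ev in events_b})
    overlap = overlap_test(n_a, n_b, universe_size, len(pairs))
    concordance = direction_concordance(pairs)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report = {"overlap": asdict(overlap), "concordance": asdict(concordance)}
        (out_dir / "concordance.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    return overlap, concordance
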