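"""Event-table parsing and the significance/background/direction rules."""

from __future__ import annotations

import math

import pytest

from splicemaps.events import (
    BackgroundCriteria,
    Direction,
    EventType,
    FilterCriteria,
    SplicingEvent,
    classify_direction,
    filter_significant,
    read_events,
    select_background,
    select_validation_candidates,
    total_unique_reads,
    write_events,
)

from conftest import TOY_BACKGROUND, TOY_SIGNIFICANT, TOY_VALIDATION


def make_event(
    event_id="ev",
    delta_psi=0.2,
    fdr=0.01,
    inc_g1=(12, 10),
    skip_g1=(3, 5),
    inc_g2=(0, 0),
    skip_g2=(0, 0),
    psi_g1=(0.8, 0.9),
    psi_g2=(0.6, 0.7),
) -> SplicingEvent:
    return SplicingEvent(
        event_id=event_id,
        gene_id="g",
        event_type=EventType.SE,
        chrom="c1",
        strand="+",
        exon_start=400,
        exon_end=500,
        upstream_exon_end=100,
        downstream_exon_start=800,
        inc_counts_g1=list(inc_g1),
        skip_counts_g1=list(skip_g1),
        inc_counts_g2=list(inc_g2),
        skip_counts_g2=list(skip_g2),
        psi_g1=list(psi_g1) if psi_g1 is not None else None,
        psi_g2=list(psi_g2) if psi_g2 is not None else None,
        pvalue=0.001,
        fdr=fdr,
        delta_psi=delta_psi,
    )


class TestReadEvents:
    def test_parses_all_rows_with_replicates(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        assert len(events) == 8
        first = events[0]
        assert first.event_id == "E1"
        assert first.inc_counts_g1 == [12, 10]
        assert first.skip_counts_g1 == [3, 5]
        assert len(first.psi_g1) == 2

    def test_coordinates_taken_as_half_open(self, toy_table):
        ev = read_events(toy_table, EventType.SE)[0]
        assert (ev.exon_start, ev.exon_end) == (400, 500)
        assert (ev.upstream_exon_end, ev.downstream_exon_start) == (100, 800)

    def test_delta_psi_consistent_with_psi_means(self, toy_table):
        # E1: mean(0.8,0.9) - mean(0.5,0.58) = 0.31
        ev = read_events(toy_table, EventType.SE)[0]
        assert math.isclose(
            sum(ev.psi_g1) / 2 - sum(ev.psi_g2) / 2, ev.delta_psi, abs_tol=1e-9
        )

    def test_unknown_event_type_rejected(self, toy_table):
        with pytest.raises(ValueError, match="unknown event type"):
            read_events(toy_table, "XX")

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ID\tGeneID\nx\ty\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_events(path, EventType.SE)

    def test_malformed_row_names_row_and_column(self, tmp_path, toy_table):
        lines = toy_table.read_text().splitlines()
        fields = lines[1].split("\t")
        fields[8] = "12,notanumber"  # IJC_SAMPLE_1
        lines[1] = "\t".join(fields)
        bad = tmp_path / "malformed.tsv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 1, column IJC_SAMPLE_1"):
            read_events(bad, EventType.SE)

    def test_round_trip_is_byte_identical(self, tmp_path, toy_table):
        events = read_events(toy_table, EventType.SE)
        first = tmp_path / "first.tsv"
        write_events(events, first, EventType.SE)
        second = tmp_path / "second.tsv"
        write_events(read_events(first, EventType.SE), second, EventType.SE)
        assert first.read_bytes() == second.read_bytes()


class TestTotalUniqueReads:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(inc_g1=(12, 10), skip_g1=(3, 5), inc_g2=(0, 0), skip_g2=(0, 0)), 30),
            (dict(inc_g1=(0, 0), skip_g1=(0, 0), inc_g2=(0, 0), skip_g2=(0, 0)), 0),
            (dict(inc_g1=(5,), skip_g1=(2,), inc_g2=(4,), skip_g2=(4,)), 15),
        ],
    )
    def test_sums_all_counts(self, kwargs, expected):
        assert total_unique_reads(make_event(**kwargs)) == expected


class TestFilterSignificant:
    def test_toy_fixture_retained_set(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        assert [ev.event_id for ev in filter_significant(events)] == TOY_SIGNIFICANT

    def test_event_just_inside_all_thresholds_retained(self):
        ev = make_event(delta_psi=0.101, fdr=0.049, inc_g1=(8, 7), skip_g1=(0, 0))
        assert filter_significant([ev]) == [ev]

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(delta_psi=0.10),  # boundary dPSI excluded (strict)
            dict(fdr=0.05),  # boundary FDR excluded (strict)
            dict(inc_g1=(7, 7), skip_g1=(0, 0)),  # 14 reads < 15
        ],
    )
    def test_boundary_values_excluded(self, kwargs):
        assert filter_significant([make_event(**kwargs)]) == []

    def test_idempotent(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        criteria = FilterCriteria()
        once = filter_significant(events, criteria)
        assert filter_significant(once, criteria) == once

    def test_significant_and_background_disjoint_when_thresholds_separate(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        sig = {ev.event_id for ev in filter_significant(events)}
        bg = {ev.event_id for ev in select_background(events)}
        assert FilterCriteria().max_fdr < BackgroundCriteria().min_fdr
        assert not sig & bg


class TestSelectBackground:
    def test_toy_fixture_background_set(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        assert [ev.event_id for ev in select_background(events)] == TOY_BACKGROUND

    def test_mid_range_psi_retained(self):
        ev = make_event(fdr=0.9, psi_g1=(0.4, 0.5), psi_g2=(0.4, 0.5), delta_psi=0.0)
        assert select_background([ev]) == [ev]

    def test_extreme_low_psi_excluded(self):
        ev = make_event(fdr=0.9, psi_g1=(0.05, 0.05), psi_g2=(0.05, 0.05), delta_psi=0.0)
        assert select_background([ev]) == []

    def test_low_fdr_excluded(self):
        ev = make_event(fdr=0.4, psi_g1=(0.4, 0.5), psi_g2=(0.4, 0.5), delta_psi=0.0)
        assert select_background([ev]) == []

    def test_event_without_psi_skipped_with_warning(self, caplog):
        ev = make_event(fdr=0.9, psi_g1=None, psi_g2=None)
        with caplog.at_level("WARNING"):
            assert select_background([ev]) == []
        assert "no PSI values" in caplog.text


class TestDirection:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (0.2, Direction.SPLICED_IN),
            (-0.2, Direction.SPLICED_OUT),
            (0.0, Direction.UNCHANGED),
        ],
    )
    def test_sign_convention(self, delta, expected):
        assert classify_direction(make_event(delta_psi=delta)) is expected


class TestValidationCandidates:
    def test_toy_fixture_validation_set(self, toy_table):
        events = read_events(toy_table, EventType.SE)
        assert [ev.event_id for ev in select_validation_candidates(events)] == TOY_VALIDATION

    def test_one_condition_above_50_is_enough(self):
        ev = make_event(inc_g1=(26, 20), skip_g1=(3, 2), inc_g2=(5, 5), skip_g2=(0, 0))
        assert sum(ev.inc_counts_g1) + sum(ev.skip_counts_g1) == 51
        assert select_validation_candidates([ev]) == [ev]

    def test_exactly_50_excluded(self):
        ev = make_event(inc_g1=(25, 20), skip_g1=(3, 2), inc_g2=(25, 20), skip_g2=(3, 2))
        assert select_validation_candidates([ev]) == []

    def test_zero_reads_excluded(self):
        ev = make_event(inc_g1=(0, 0), skip_g1=(0, 0), inc_g2=(0, 0), skip_g2=(0, 0))
        assert select_validation_candidates([ev]) == []
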