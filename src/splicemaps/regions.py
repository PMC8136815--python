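"""Genomic sequence access and RNA-map region construction.

Around each cassette exon four fixed-length regions are analysed, labelled in
transcript (pre-mRNA 5'->3') orientation:

* ``R1`` — 3' end of the upstream exon + 5' start of the upstream intron,
* ``R2`` — 3' end of the upstream intron + 5' start of the cassette exon,
* ``R3`` — 3' end of the cassette exon + 5' start of the downstream intron,
* ``R4`` — 3' end of the downstream intron + 5' start of the downstream exon.

Each region is ``exonic_flank + intronic_flank`` nucleotides long (50 + 250 =
300 by default).  Minus-strand events are reverse-complemented so all region
sequences read 5'->3' along the transcript.  Regions whose flanking intron is
shorter than the intronic flank (or cassette exon shorter than the exonic
flank) are flagged invalid and excluded downstream, keeping the sliding
window family identical across events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pyfaidx import Fasta

from .events import EventType, SplicingEvent

REGION_LABELS = ("R1", "R2", "R3", "R4")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _clean(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


class GenomeSequenceStore:
    """Subsequence queries over a genome, by (contig, start, end, strand).

    Backed either by an in-memory mapping of contig name to sequence or by a
    ``pyfaidx`` FASTA index.  Minus-strand queries return the reverse
    complement; out-of-bounds queries raise.  ``U`` is mapped to ``T`` and
    sequences are upper-cased.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: _clean(seq) for name, seq in sequences.items()}
        self._lengths = {name: len(seq) for name, seq in self._seqs.items()}
        self._fasta: Fasta | None = None

    @classmethod
    def from_fasta(cls, fasta_path: str | Path) -> "GenomeSequenceStore":
        store = cls.__new__(cls)
        # pyfaidx rejects duplicate contig names while indexing
        fasta = Fasta(str(fasta_path), sequence_always_upper=True)
        store._fasta = fasta
        store._seqs = {}
        store._lengths = {name: len(fasta[name]) for name in fasta.keys()}
        return store

    def contig_length(self, contig: str) -> int:
        if contig not in self._lengths:
            raise KeyError(f"unknown contig {contig!r}")
        return self._lengths[contig]

    def contigs(self) -> list[str]:
        return list(self._lengths)

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Return the genomic subsequence, reverse-complemented for ``-``."""
        length = self.contig_length(contig)
        if not (0 <= start <= end <= length):
            raise ValueError(
                f"query {contig}:{start}-{end} outside contig bounds [0,{length})"
            )
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r}")
        if self._fasta is not None:
            seq = _clean(str(self._fasta[contig][start:end]))
        else:
            seq = self._seqs[contig][start:end]
        return reverse_complement(seq) if strand == "-" else seq


def load_genome(fasta_path: str | Path) -> GenomeSequenceStore:
    """Open a genome FASTA for subsequence queries (duplicate contig names
    are rejected by the underlying index)."""
    return GenomeSequenceStore.from_fasta(fasta_path)


@dataclass
class RegionSpec:
    """Split of each analysis region into exonic and intronic flanks (nt)."""

    exonic_flank: int = 50
    intronic_flank: int = 250

    def __post_init__(self) -> None:
        if self.exonic_flank <= 0 or self.intronic_flank <= 0:
            raise ValueError("flank lengths must be positive")

    @property
    def region_length(self) -> int:
        return self.exonic_flank + self.intronic_flank


@dataclass
class EventRegions:
    """The four transcript-oriented region sequences of one cassette exon."""

    event_id: str
    sequences: dict[str, str] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)
    # genomic footprint of each region: (chrom, start, end, strand)
    intervals: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)


def region_genomic_interval(
    event: SplicingEvent, label: str, spec: RegionSpec
) -> tuple[int, int]:
    """Genomic [start, end) of one region, before reverse-complementation.

    In transcript orientation the region always reads (exonic flank, intronic
    flank) or (intronic flank, exonic flank); on the minus strand the labels
    swap genomic sides so that R1..R4 still follow the transcript.
    """
    e, i = spec.exonic_flank, spec.intronic_flank
    uee, es = event.upstream_exon_end, event.exon_start
    ee, des = event.exon_end, event.downstream_exon_start
    if event.strand == "+":
        mapping = {
            "R1": (uee - e, uee + i),
            "R2": (es - i, es + e),
            "R3": (ee - e, ee + i),
            "R4": (des - i, des + e),
        }
    else:
        mapping = {
            "R1": (des - i, des + e),
            "R2": (ee - e, ee + i),
            "R3": (es - i, es + e),
            "R4": (uee - e, uee + i),
        }
    if label not in mapping:
        raise ValueError(f"unknown region label {label!r}")
    return mapping[label]


def _region_valid(event: SplicingEvent, label: str, spec: RegionSpec, contig_length: int) -> bool:
    e, i = spec.exonic_flank, spec.intronic_flank
    upstream_intron = event.exon_start - event.upstream_exon_end
    downstream_intron = event.downstream_exon_start - event.exon_end
    cassette = event.exon_end - event.exon_start
    # transcript-side intron/exon requirements per label
    if event.strand == "+":
        needs = {
            "R1": upstream_intron >= i,
            "R2": upstream_intron >= i and cassette >= e,
            "R3": downstream_intron >= i and cassette >= e,
            "R4": downstream_intron >= i,
        }
    else:
        needs = {
            "R1": downstream_intron >= i,
            "R2": downstream_intron >= i and cassette >= e,
            "R3": upstream_intron >= i and cassette >= e,
            "R4": upstream_intron >= i,
        }
    if not needs[label]:
        return False
    start, end = region_genomic_interval(event, label, spec)
    return 0 <= start and end <= contig_length


def build_event_regions(
    event: SplicingEvent,
    store: GenomeSequenceStore,
    spec: RegionSpec | None = None,
) -> EventRegions:
    """Extract the four analysis regions of one skipped-exon event.

    Only SE events have the exon/intron geometry the region layout assumes.
    Regions that would extend into a too-short intron or exon, or outside the
    contig, are marked invalid (sequence omitted) rather than truncated.
    """
    spec = spec or RegionSpec()
    if event.event_type != EventType.SE:
        raise ValueError(
            f"event {event.event_id}: regions are defined for SE events, "
            f"got {event.event_type.value}"
        )
    contig_length = store.contig_length(event.chrom)
    regions = EventRegions(event_id=event.event_id)
    for label in REGION_LABELS:
        ok = _region_valid(event, label, spec, contig_length)
        regions.valid[label] = ok
        if not ok:
            continue
        start, end = region_genomic_interval(event, label, spec)
        regions.intervals[label] = (event.chrom, start, end, event.strand)
        regions.sequences[label] = store.fetch(event.chrom, start, end, event.strand)
    return regions


def regions_to_bed(
    all_regions: Iterable[EventRegions], bed_path: str | Path
) -> None:
    """Export the genomic intervals of all valid regions as BED6 (0-based
    half-open, name = ``<event_id>:<label>``)."""
    lines = []
    for regions in all_regions:
        for label in REGION_LABELS:
            if not regions.valid.get(label):
                continue
            chrom, start, end, strand = regions.intervals[label]
            lines.append(
                f"{chrom}\t{start}\t{end}\t{regions.event_id}:{label}\t0\t{strand}"
            )
    Path(bed_path).write_text("\n".join(lines) + ("\n" if lines else ""))
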