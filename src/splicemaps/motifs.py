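"""Degenerate RBP motif representation, scanning and window counting.

Motifs are IUPAC-degenerate DNA strings (``U`` accepted and mapped to ``T``);
one RBP may have several alternative patterns.  Scanning reports every
overlapping match start on the transcript-oriented (sense) strand; ``N`` in
the scanned sequence matches nothing.  Matches are aggregated into a sliding
window count vector per region: with region length L, window width w and step
1 the family has exactly L - w windows (250 for 300/50), the convention that
produces the canonical 250-p-value family.  A match is assigned to a window
when its start offset lies inside the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .regions import REGION_LABELS, EventRegions

IUPAC_DNA: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

MIN_PATTERN_LENGTH = 4


def normalize_pattern(pattern: str) -> str:
    """Upper-case, map RNA U to DNA T, and validate IUPAC codes."""
    cleaned = pattern.strip().upper().replace("U", "T")
    if len(cleaned) < MIN_PATTERN_LENGTH:
        raise ValueError(f"pattern {pattern!r} shorter than {MIN_PATTERN_LENGTH} nt")
    for ch in cleaned:
        if ch not in IUPAC_DNA:
            raise ValueError(f"pattern {pattern!r}: invalid IUPAC code {ch!r}")
    return cleaned


def _pattern_to_regex(pattern: str) -> str:
    parts = []
    for ch in pattern:
        bases = IUPAC_DNA[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass
class Motif:
    """A named RBP binding motif given as one or more degenerate patterns."""

    name: str
    patterns: list[str]

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError(f"motif {self.name}: no patterns")
        self.patterns = [normalize_pattern(p) for p in self.patterns]

    @cached_property
    def _regex(self) -> re.Pattern:
        # lookahead makes overlapping matches visible; alternation across
        # patterns deduplicates shared start offsets for free
        body = "|".join(_pattern_to_regex(p) for p in self.patterns)
        return re.compile(f"(?=(?:{body}))")


def load_compendium(tsv_path: str | Path) -> list[Motif]:
    """Read a two-column (name, IUPAC pattern) TSV; multiple rows per name
    are merged into one motif.  Lines starting with ``#`` are comments."""
    grouped: dict[str, list[str]] = {}
    with open(tsv_path) as handle:
        for row_number, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"row {row_number}: expected 'name<TAB>pattern'")
            name, pattern = parts[0].strip(), parts[1].strip()
            try:
                pattern = normalize_pattern(pattern)
            except ValueError as exc:
                raise ValueError(f"row {row_number}: {exc}") from exc
            grouped.setdefault(name, []).append(pattern)
    return [Motif(name, patterns) for name, patterns in grouped.items()]


def bundled_compendium() -> list[Motif]:
    """The small example compendium shipped with the package (20 literature
    RBP motifs, including the RBFOX family element TGCATG)."""
    path = resources.files("splicemaps.data").joinpath("rbp_motifs.tsv")
    with resources.as_file(path) as p:
        return load_compendium(p)


def scan(sequence: str, motif: Motif) -> list[int]:
    """All 0-based start offsets where any of the motif's patterns matches.

    Overlapping matches are reported; offsets are sorted and deduplicated
    across patterns.  ``N`` in the sequence matches no pattern position.
    """
    seq = sequence.upper().replace("U", "T")
    return [m.start() for m in motif._regex.finditer(seq)]


def window_counts(
    match_offsets: Sequence[int],
    region_length: int,
    window_width: int = 50,
    step: int = 1,
) -> np.ndarray:
    """Count motif match starts per sliding window.

    Windows are [i, i + window_width) for i = 0, step, ...; with step 1 there
    are exactly region_length - window_width windows, so the last window
    starts at region_length - window_width - 1.  A match at offset s falls in
    window i iff i <= s < i + window_width.
    """
    if window_width >= region_length:
        raise ValueError("window_width must be smaller than region_length")
    if step < 1:
        raise ValueError("step must be >= 1")
    starts = np.arange(0, region_length - window_width, step)
    counts = np.zeros(len(starts), dtype=np.int64)
    for s in match_offsets:
        if not (0 <= s < region_length):
            raise ValueError(f"match offset {s} outside region [0,{region_length})")
        lo = np.searchsorted(starts, s - window_width + 1, side="left")
        hi = np.searchsorted(starts, s, side="right")
        counts[lo:hi] += 1
    return counts


@dataclass
class WindowCountMatrix:
    """events x windows motif match counts for one (motif, region label)."""

    motif_name: str
    region_label: str
    window_width: int
    step: int
    counts: np.ndarray
    window_offsets: np.ndarray
    event_ids: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]


def _batch_scan(sequences: list[str], motif: Motif, region_length: int) -> list[list[int]]:
    """Scan many equal-length sequences with one regex pass.

    Sequences are joined with an ``X`` separator (matching no IUPAC class) so
    matches cannot span boundaries; offsets are mapped back per sequence.
    """
    joined = "X".join(sequences)
    per_seq: list[list[int]] = [[] for _ in sequences]
    stride = region_length + 1
    for m in motif._regex.finditer(joined):
        pos = m.start()
        row, offset = divmod(pos, stride)
        per_seq[row].append(offset)
    return per_seq


def build_count_matrices(
    regions: Sequence[EventRegions],
    motifs: Iterable[Motif],
    window_width: int = 50,
    step: int = 1,
    region_labels: Sequence[str] = REGION_LABELS,
) -> list[WindowCountMatrix]:
    """One count matrix per (motif, region label) over all events whose
    region is valid; row order follows the input event order.  Mixed region
    lengths raise."""
    motifs = list(motifs)
    matrices: list[WindowCountMatrix] = []
    for label in region_labels:
        rows = [(r.event_id, r.sequences[label]) for r in regions if r.valid.get(label)]
        if not rows:
            continue
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise ValueError(f"mixed region lengths for {label}: {sorted(lengths)}")
        region_length = lengths.pop()
        if window_width >= region_length:
            raise ValueError("window_width must be smaller than region_length")
        event_ids = [eid for eid, _ in rows]
        sequences = [seq.upper().replace("U", "T") for _, seq in rows]
        starts = np.arange(0, region_length - window_width, step)
        for motif in motifs:
            counts = np.zeros((len(rows), len(starts)), dtype=np.int64)
            offsets = _batch_scan(sequences, motif, region_length)
            for i, match_list in enumerate(offsets):
                for s in match_list:
                    lo = np.searchsorted(starts, s - window_width + 1, side="left")
                    hi = np.searchsorted(starts, s, side="right")
                    counts[i, lo:hi] += 1
            matrices.append(
                WindowCountMatrix(
                    motif_name=motif.name,
                    region_label=label,
                    window_width=window_width,
                    step=step,
                    counts=counts,
                    window_offsets=starts,
                    event_ids=event_ids,
                )
            )
    return matrices
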