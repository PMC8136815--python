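"""Shared fixtures: a hand-checkable 8-event rMATS SE table, a small
deterministic genome, and a toy motif compendium — all generated at test
time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from splicemaps.events import SE_COLUMNS

# One synthetic contig: exon1 [0,100) | intron [100,400) | cassette [400,500)
# | intron [500,800) | exon3 [800,900).
GENOME_LAYOUT = {
    "upstream_exon_end": 100,
    "exon_start": 400,
    "exon_end": 500,
    "downstream_exon_start": 800,
    "contig_length": 900,
}


@pytest.fixture(scope="session")
def genome_sequence() -> str:
    rng = np.random.default_rng(42)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, GENOME_LAYOUT["contig_length"]))


@pytest.fixture()
def genome_fasta(tmp_path: Path, genome_sequence: str) -> Path:
    path = tmp_path / "genome.fa"
    lines = [">c1"] + [genome_sequence[i : i + 80] for i in range(0, len(genome_sequence), 80)]
    path.write_text("\n".join(lines) + "\n")
    return path


# The 8-event fixture.  Hand-derived truth under the default criteria
# (reads >= 15, |dPSI| > 0.10, FDR < 0.05 | FDR > 0.5 & maxPSI > 0.15 &
# minPSI < 0.85 | >50 reads in one condition):
#   significant        -> E1, E4, E8
#   background         -> E5
#   validation (>50)   -> E2, E4
# E2 sits exactly on the dPSI boundary (0.10), E3 has 14 reads, E6 fails
# maxPSI, E7 fails the background FDR rule, E8 has exactly 15 reads.
TOY_ROWS = [
    # id, IJC1, SJC1, IJC2, SJC2, Inc1, Inc2, PValue, FDR, dPSI
    ("E1", "12,10", "3,5", "0,0", "0,0", "0.8,0.9", "0.5,0.58", "0.001", "0.01", "0.31"),
    ("E2", "30,30", "10,10", "20,20", "20,20", "0.6,0.6", "0.5,0.5", "0.05", "0.2", "0.1"),
    ("E3", "4,3", "3,4", "0,0", "0,0", "0.8,0.8", "0.6,0.6", "0.001", "0.01", "0.2"),
    ("E4", "25,25", "5,5", "10,10", "10,10", "0.85,0.8", "0.5,0.55", "0.0001", "0.001", "0.3"),
    ("E5", "5,5", "5,5", "5,5", "5,5", "0.4,0.5", "0.45,0.5", "0.8", "0.9", "-0.025"),
    ("E6", "5,5", "5,5", "5,5", "5,5", "0.05,0.05", "0.05,0.05", "0.8", "0.9", "0"),
    ("E7", "8,7", "8,7", "8,7", "8,7", "0.45,0.5", "0.4,0.45", "0.3", "0.4", "0.05"),
    ("E8", "5,2", "2,4", "1,0", "1,0", "0.5,0.52", "0.62,0.64", "0.04", "0.049", "-0.12"),
]

TOY_SIGNIFICANT = ["E1", "E4", "E8"]
TOY_BACKGROUND = ["E5"]
TOY_VALIDATION = ["E2", "E4"]


def write_toy_table(path: Path) -> Path:
    lines = ["\t".join(SE_COLUMNS)]
    for row in TOY_ROWS:
        event_id, ijc1, sjc1, ijc2, sjc2, inc1, inc2, pv, fdr, dpsi = row
        lines.append(
            "\t".join(
                [
                    event_id,
                    f"gene_{event_id}",
                    "c1",
                    "+",
                    str(GENOME_LAYOUT["exon_start"]),
                    str(GENOME_LAYOUT["exon_end"]),
                    str(GENOME_LAYOUT["upstream_exon_end"]),
                    str(GENOME_LAYOUT["downstream_exon_start"]),
                    ijc1,
                    sjc1,
                    ijc2,
                    sjc2,
                    inc1,
                    inc2,
                    pv,
                    fdr,
                    dpsi,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def toy_table(tmp_path: Path) -> Path:
    return write_toy_table(tmp_path / "toy_SE.tsv")


@pytest.fixture()
def toy_compendium(tmp_path: Path) -> Path:
    path = tmp_path / "motifs.tsv"
    path.write_text("RBFOX\tTGCATG\nQKI\tACTAAY\nPTBP1\tTCTTC\nCELF1\tTGTGTG\n")
    return path
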