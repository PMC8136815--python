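"""Synthetic rMATS-style datasets with planted RBP motifs and full ground truth.

Each simulated cassette-exon event gets its own contig laid out as
exon - intron - cassette exon - intron - exon over i.i.d. background
nucleotides.  Regulated events receive a real splicing effect (|dPSI| above
an effect floor); background events get near-zero dPSI noise.  Replicate PSI
values follow a Beta distribution around the group mean; junction read
counts follow a negative-binomial depth model split into inclusion/skipping
by the replicate PSI.  Event-table p-values are produced by an actual exact
rank test on the replicate PSIs and converted to an FDR column with
Benjamini-Hochberg across events, so the table is internally consistent;
this fabricates the columns of the upstream splicing-quantification tool
without claiming to reproduce its count model.

Motif instances are *substituted* in place (sequence length is preserved so
the window family stays uniform) at a uniformly drawn transcript-relative
offset of a chosen region, with separate planting probabilities for the
regulated and background groups.  All randomness flows from one seed through
per-event substreams, so identical seeds give bit-identical outputs and any
subset of events is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .events import EventType, SplicingEvent, write_events
from .motifs import IUPAC_DNA, normalize_pattern
from .regions import (
    GenomeSequenceStore,
    RegionSpec,
    region_genomic_interval,
    reverse_complement,
)
from .window_stats import wilcoxon_rank_sum

_BASES = "ACGT"


@dataclass
class PlantingSpec:
    """Where and how often to substitute a motif into event regions.

    ``offset_range`` is inclusive, in transcript-oriented region coordinates
    of ``region_label``; the defaults emulate an RBFOX-style element in the
    proximal upstream intron, present in 60% of regulated and 10% of
    background events.
    """

    pattern: str = "TGCATG"
    region_label: str = "R2"
    offset_range: tuple[int, int] = (0, 200)
    p_regulated: float = 0.6
    p_background: float = 0.1

    def __post_init__(self) -> None:
        self.pattern = normalize_pattern(self.pattern)
        if not (0.0 <= self.p_regulated <= 1.0 and 0.0 <= self.p_background <= 1.0):
            raise ValueError("planting probabilities must lie in [0,1]")
        a, b = self.offset_range
        if a < 0 or b < a:
            raise ValueError("offset_range must satisfy 0 <= a <= b")


@dataclass
class PsiModel:
    """Group-mean PSI model: regulated events draw |dPSI| uniformly from
    [effect_floor, effect_ceiling]; background events get Normal(0,
    background_sd) dPSI noise; replicate PSIs are Beta around the group mean
    with the given concentration."""

    effect_floor: float = 0.2
    effect_ceiling: float = 0.4
    background_sd: float = 0.02
    concentration: float = 50.0


@dataclass
class DepthModel:
    """Per-replicate total junction reads ~ NegBin(mean, dispersion), with
    variance mean + dispersion * mean^2, split inclusion/skipping by PSI."""

    mean_reads: float = 80.0
    dispersion: float = 0.2


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic dataset."""

    n_regulated: int = 300
    n_background: int = 1000
    seed: int = 0
    replicates: int = 6
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    flank_exon_length: int = 150
    intron_length: int = 600
    cassette_length: int = 120
    planting: list[PlantingSpec] = field(default_factory=list)
    psi: PsiModel = field(default_factory=PsiModel)
    depth: DepthModel = field(default_factory=DepthModel)
    region_spec: RegionSpec = field(default_factory=RegionSpec)

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if min(self.base_composition) < 0:
            raise ValueError("base_composition must be non-negative")
        if min(self.flank_exon_length, self.intron_length, self.cassette_length) <= 0:
            raise ValueError("segment lengths must be positive")
        if self.intron_length < self.region_spec.intronic_flank:
            raise ValueError("intron_length must cover the intronic flank")
        if self.replicates < 2:
            raise ValueError("need at least two replicates per group")
        region_length = self.region_spec.region_length
        for spec in self.planting:
            if spec.offset_range[1] + len(spec.pattern) > region_length:
                raise ValueError(
                    f"planting range {spec.offset_range} incompatible with "
                    f"region length {region_length} for pattern {spec.pattern}"
                )


@dataclass
class TruthRecord:
    """Ground truth of one synthetic dataset."""

    seed: int
    regulated_ids: list[str]
    background_ids: list[str]
    planted: dict[str, list[tuple[str, int, str]]]  # event -> (region, offset, pattern)
    psi_means: dict[str, tuple[float, float]]  # event -> (mean g1, mean g2)


def resolve_iupac(pattern: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions uniformly at random to concrete bases."""
    out = []
    for ch in pattern.upper().replace("U", "T"):
        bases = IUPAC_DNA.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {ch!r}")
        out.append(bases if len(bases) == 1 else bases[rng.integers(len(bases))])
    return "".join(out)


def plant_motif(
    sequence: str,
    pattern: str,
    offset: int,
    rng: np.random.Generator | None = None,
) -> str:
    """Substitute a motif instance at ``offset`` (bases replaced in place;
    length preserved).  Degenerate positions are resolved at random from
    the compatible bases, deterministically for a seeded ``rng``."""
    if rng is None:
        rng = np.random.default_rng()
    concrete = resolve_iupac(pattern, rng)
    if offset < 0 or offset + len(concrete) > len(sequence):
        raise ValueError(
            f"offset {offset} with pattern length {len(concrete)} outside "
            f"sequence of length {len(sequence)}"
        )
    return sequence[:offset] + concrete + sequence[offset + len(concrete):]


def _event_coordinates(config: SyntheticConfig) -> tuple[int, int, int, int, int]:
    """Genomic layout of every synthetic contig (identical across events)."""
    f, i, c = config.flank_exon_length, config.intron_length, config.cassette_length
    upstream_exon_end = f
    exon_start = f + i
    exon_end = f + i + c
    downstream_exon_start = f + i + c + i
    contig_length = f + i + c + i + f
    return upstream_exon_end, exon_start, exon_end, downstream_exon_start, contig_length


def _draw_group_means(
    rng: np.random.Generator, regulated: bool, psi: PsiModel
) -> tuple[float, float]:
    if regulated and psi.effect_ceiling > 0:
        mid = rng.uniform(0.35, 0.65)
        delta = rng.uniform(psi.effect_floor, psi.effect_ceiling)
        if rng.random() < 0.5:
            delta = -delta
    else:
        mid = rng.uniform(0.2, 0.8)
        delta = rng.normal(0.0, psi.background_sd)
    g1 = float(np.clip(mid + delta / 2.0, 0.02, 0.98))
    g2 = float(np.clip(mid - delta / 2.0, 0.02, 0.98))
    return g1, g2


def _draw_replicate_psi(
    rng: np.random.Generator, mean: float, concentration: float, n: int
) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return np.clip(rng.beta(a, b, size=n), 1e-6, 1.0 - 1e-6)


def _draw_counts(
    rng: np.random.Generator, psi_reps: np.ndarray, depth: DepthModel
) -> tuple[list[int], list[int]]:
    # NB(mean mu, var mu + d*mu^2) == Gamma-Poisson with shape 1/d
    size = 1.0 / depth.dispersion
    prob = size / (size + depth.mean_reads)
    totals = rng.negative_binomial(size, prob, size=psi_reps.size)
    inc = rng.binomial(totals, psi_reps)
    return [int(v) for v in inc], [int(t - v) for t, v in zip(totals, inc)]


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[list[SplicingEvent], GenomeSequenceStore, TruthRecord]:
    """Generate events, genome and ground truth fully in memory.

    Event ids are ``REG_<i>`` / ``BG_<i>``; each event owns one contig of the
    same name.  Identical configs (including the seed) give identical output.
    """
    uee, es, ee, des, contig_length = _event_coordinates(config)
    n_total = config.n_regulated + config.n_background
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    base_p = np.asarray(config.base_composition, dtype=float)

    sequences: dict[str, str] = {}
    events: list[SplicingEvent] = []
    truth = TruthRecord(
        seed=config.seed,
        regulated_ids=[],
        background_ids=[],
        planted={},
        psi_means={},
    )
    raw_pvalues: list[float] = []

    for idx in range(n_total):
        regulated = idx < config.n_regulated
        event_id = f"REG_{idx:05d}" if regulated else f"BG_{idx - config.n_regulated:05d}"
        rng = np.random.default_rng(children[idx])

        seq_codes = rng.choice(4, size=contig_length, p=base_p)
        seq = np.frombuffer(_BASES.encode(), dtype="S1")[seq_codes].tobytes().decode()
        strand = "+" if rng.random() < 0.5 else "-"

        g1_mean, g2_mean = _draw_group_means(rng, regulated, config.psi)
        psi_g1 = _draw_replicate_psi(rng, g1_mean, config.psi.concentration, config.replicates)
        psi_g2 = _draw_replicate_psi(rng, g2_mean, config.psi.concentration, config.replicates)
        inc1, skip1 = _draw_counts(rng, psi_g1, config.depth)
        inc2, skip2 = _draw_counts(rng, psi_g2, config.depth)

        event = SplicingEvent(
            event_id=event_id,
            gene_id=f"gene_{event_id}",
            event_type=EventType.SE,
            chrom=event_id,
            strand=strand,
            exon_start=es,
            exon_end=ee,
            upstream_exon_end=uee,
            downstream_exon_start=des,
            inc_counts_g1=inc1,
            skip_counts_g1=skip1,
            inc_counts_g2=inc2,
            skip_counts_g2=skip2,
            psi_g1=[round(float(v), 6) for v in psi_g1],
            psi_g2=[round(float(v), 6) for v in psi_g2],
            pvalue=1.0,  # filled after the rank test below
            fdr=1.0,  # filled after BH across events
            delta_psi=0.0,
        )
        event.delta_psi = round(
            sum(event.psi_g1) / len(event.psi_g1) - sum(event.psi_g2) / len(event.psi_g2),
            6,
        )
        _, p = wilcoxon_rank_sum(
            event.psi_g1,
            event.psi_g2,
            alternative="two_sided",
            exact_max_n=2 * config.replicates,
        )
        raw_pvalues.append(p)

        # motif planting: substitute into the genome so that re-scanning the
        # transcript-oriented region finds the pattern at the drawn offset
        for spec in config.planting:
            p_plant = spec.p_regulated if regulated else spec.p_background
            if rng.random() >= p_plant:
                continue
            offset = int(rng.integers(spec.offset_range[0], spec.offset_range[1] + 1))
            concrete = resolve_iupac(spec.pattern, rng)
            gstart, gend = region_genomic_interval(event, spec.region_label, config.region_spec)
            if strand == "+":
                pos = gstart + offset
                insert = concrete
            else:
                pos = gend - offset - len(concrete)
                insert = reverse_complement(concrete)
            seq = seq[:pos] + insert + seq[pos + len(insert):]
            truth.planted.setdefault(event_id, []).append(
                (spec.region_label, offset, concrete)
            )

        sequences[event_id] = seq
        events.append(event)
        truth.psi_means[event_id] = (round(g1_mean, 6), round(g2_mean, 6))
        (truth.regulated_ids if regulated else truth.background_ids).append(event_id)

    adjusted = multipletests(raw_pvalues, method="fdr_bh")[1]
    for event, p_raw, q in zip(events, raw_pvalues, adjusted):
        event.pvalue = float(p_raw)
        event.fdr = float(q)

    return events, GenomeSequenceStore(sequences), truth


def write_fasta(sequences: dict[str, str], fasta_path: str | Path, width: int = 80) -> None:
    lines = []
    for name, seq in sequences.items():
        lines.append(f">{name}")
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(fasta_path).write_text("\n".join(lines) + "\n")


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path
) -> tuple[Path, Path, TruthRecord]:
    """Write the synthetic dataset to disk: ``events.tsv`` (rMATS SE
    dialect), ``genome.fa`` and ``truth.json``.  Byte-identical across reruns
    with the same config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events, store, truth = simulate_dataset(config)
    events_path = out_dir / "events.tsv"
    fasta_path = out_dir / "genome.fa"
    truth_path = out_dir / "truth.json"
    write_events(events, events_path, EventType.SE)
    write_fasta({ev.event_id: store.fetch(ev.chrom, 0, store.contig_length(ev.chrom)) for ev in events}, fasta_path)
    truth_path.write_text(json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n")
    return events_path, fasta_path, truth
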