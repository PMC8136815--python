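# Methods

## The RNA-map model

A cassette-exon (SE) event is an exon that is either included or skipped in
the mature transcript, quantified per replicate by PSI = inclusion reads /
(inclusion + skipping reads). Comparing two conditions gives a per-event
dPSI (mean PSI of group 1 / control minus mean PSI of group 2); events with
dPSI > 0 are called *spliced-in* (more included in control), dPSI < 0
*spliced-out*.

Regulated events are selected by three rules applied with strict
inequalities exactly as printed in standard practice: total junction-read
support >= 15, |dPSI| > 0.10, FDR < 0.05. "Support" is defined here as the
sum of inclusion + skipping counts over all replicates of both groups — the
simplest monotone measure; the threshold is configurable
(`FilterCriteria.min_unique_reads`). Background (unaffected) exons satisfy
FDR > 0.5 with max replicate PSI > 0.15 and min replicate PSI < 0.85,
pooling both groups; events with no usable PSI values are excluded rather
than imputed. RT-PCR validation candidates need > 50 supporting reads within
at least one condition.

Around each regulated or background SE event, four regions are read off the
genome in transcript orientation: R1 (upstream-exon 3' end into the upstream
intron), R2 (upstream-intron 3' end into the cassette exon), R3 (cassette
3' end into the downstream intron) and R4 (downstream-intron 3' end into the
downstream exon). Each region is exonic_flank + intronic_flank nt long; the
defaults, 50 + 250 = 300 nt, follow the established RNA-map convention of a
short exonic anchor plus the proximal intron, where most positional
splicing-regulatory signal lives. Events whose flanking intron is shorter
than the intronic flank (or cassette shorter than the exonic flank) are
dropped per region, not truncated or padded, so the window family is
identical for every analysed event. Minus-strand events are
reverse-complemented; labels follow the transcript, not the genome.

Motifs are IUPAC-degenerate DNA patterns (U accepted as T); scanning reports
every overlapping match start on the sense strand only, since RBPs bind the
pre-mRNA. Matches are aggregated into sliding-window counts: windows are
[i, i + w) for i = 0, 1, ..., and the family size is region_length - w
(= 250 for 300/50), matching the canonical 250-member p-value family; a
match belongs to a window when its *start* offset lies inside it. The
window convention is recorded in every run's metadata.

Per window, regulated counts are compared against background counts with a
one-sided ("greater", enrichment) Wilcoxon rank-sum test — positional
profiles report enrichment, not depletion; a two-sided mode is available.
Midranks handle the heavy ties of sparse count data. For pooled samples of
at most `exact_max_n` (default 10) tie-free observations the p-value is
exact, from the enumerated null distribution of the rank sum; otherwise a
normal approximation with tie-corrected variance and a 0.5 continuity
correction is used. A zero null variance (every observation tied) returns
p = 0.5 one-sided / 1.0 two-sided, the statistic sitting at its null mean.
The min-p summary records the family minimum and its window (ties broken at
the smallest index).

## Post-hoc FDP bounds

The family minimum of 250 correlated p-values is small even under the null,
so significance calls are instead made through post-hoc inference
(closed-testing style bounds that hold simultaneously over all candidate
selections). For one motif x region family of m = 250 window p-values, the
Simes / linear-template bound

    V(S) = min_{k=1..|S|} [ #{ p_i in S : p_i > alpha*k/m } + k - 1 ],

clipped to [0, |S|], upper-bounds the false positives in any subset S with
probability >= 1 - alpha simultaneously over all S. Its validity rests on
the Simes inequality, which holds under the positive dependence typical of
overlapping-window statistics; the sparse, discrete window counts make the
rank-sum p-values conservative in the relevant tail, adding slack.

All contiguous window intervals are evaluated (per-k indicator prefix sums;
the full 31 375-interval table for m = 250 takes ~50 ms). Intervals with
FDP bound strictly below `fdp_threshold` (default 0.25) are selected and
reduced to maximal intervals per region (no selected interval contained in
another); each motif's **ph-FDP** is the minimal bound over its whole
interval table, with 1.0 for families in which the Simes test does not
reject — in that case every interval bound provably equals its size, a fact
the screening fast path exploits (and a test verifies against the
exhaustive path).

Design choices that were genuinely open:

* **alpha (default 0.05)** is the confidence level of the whole screen.
  When `PosthocConfig.split_alpha` is set (default), `posthoc_screen`
  divides alpha equally across the motif x region families it scans.
  Without the split each family carries an individual level-alpha
  guarantee, and a 20-motif x 4-region screen accumulates false
  selections: simulated motif-null screens selected something in ~77% of
  replicates, each family nevertheless respecting its own level. With the
  split, the guarantee is simultaneous over every interval of every motif
  the user inspects, and the measured null screen selection rate drops to
  ~3–4%. Single-family functions (`simes_posthoc_bound`,
  `interval_bounds`) always use alpha directly.
* **Ranking ties.** ph-FDP saturates at 0, and occasionally an isolated
  null window also reaches bound 0. Motifs with equal ph-FDP are therefore
  ordered by the size of the largest interval attaining that bound
  (descending — the same certificate covering more windows is stronger
  evidence), with the motif name as the final deterministic key.
* The per-motif ph-FDP is the minimum bound over all intervals (not the
  bound of a pre-selected set), and selection uses a strict `<` at the
  threshold.

## Event-set statistics

Events are matched across datasets by exact coordinate identity (chromosome,
strand, event type, cassette bounds, flanking-intron bounds) after strand
normalization. Overlap significance is hypergeometric (upper tail of
P(K >= k)), with expected overlap nA*nB/N; the universe size N must be
supplied explicitly — e.g. all events quantified in both datasets — because
no default is defensible. Direction concordance classifies shared events as
similar/opposite by dPSI sign; zero-dPSI pairs are excluded from both counts
and reported separately. Two-proportion comparisons use the Pearson 2x2
chi-square without continuity correction by default.

## The synthetic-data generator

Each simulated event owns one contig laid out exon(150) – intron(600) –
cassette(120) – intron(600) – exon(150) over i.i.d. uniform nucleotides,
large enough to hold the 250-nt intronic flanks with room to spare. Strand
is random per event, exercising the reverse-complement path everywhere.

* **PSI model.** Regulated events draw |dPSI| ~ Uniform(0.2, 0.4) with
  random sign around a mid-PSI ~ Uniform(0.35, 0.65); background events get
  dPSI ~ Normal(0, 0.02) around mid-PSI ~ Uniform(0.2, 0.8). Replicate PSI
  is Beta-distributed around the group mean with concentration 50
  (replicate SD ~= 0.07 at PSI 0.5), a typical biological-replicate spread.
* **Depth model.** Per replicate, total junction reads ~ NegBin(mean 80,
  dispersion 0.2), split into inclusion/skipping by a Binomial draw at the
  replicate PSI, so counts and PSI are mutually consistent.
* **Replicates: 6 per group.** The event table's p-value is an *actual*
  exact two-sided rank test on the replicate PSIs, and its FDR column is
  Benjamini–Hochberg across events — fabricated columns, but internally
  consistent (this package does not reproduce any read-count likelihood
  model). An exact rank test on n vs n replicates has a p-value floor of
  2/C(2n, n): with 3 replicates the floor is 0.1 and no event could ever
  reach FDR < 0.05, so the generator defaults to 6 (floor 2/924 ~ 0.0022),
  the smallest round size at which clearly separated events survive BH at
  the simulated event counts.
* **Planting** substitutes (never inserts — lengths are preserved) a motif
  instance at a uniform offset of a configured region, with independent
  probabilities for regulated and background events; degenerate positions
  are resolved randomly. The truth record stores every planted offset, and
  a test re-scans each one from the emitted genome on both strands.
* **Determinism.** All randomness flows from one seed through per-event
  substreams (`SeedSequence.spawn`), so outputs are byte-identical across
  reruns and any subset of events is reproducible.

What the generator does *not* emulate: realistic base composition and
repeat structure, splice-site signals, intron-length distributions,
correlated motif co-occurrence, read-level noise, or any count-model
p-values. Passing tests therefore demonstrate the statistical machinery
(filtering rules, positional recovery, FDP control under the stated noise
model), not performance on real transcriptomes.

## Problem sizes and calibration experiments

The null-control experiment uses 200 simulated datasets of 150 regulated /
500 background events against the bundled 20-motif compendium (alpha 0.05,
threshold 0.25); the recovery experiment plants TGCATG in R2 offsets 0–200
at 60% vs 10% of 300/1000 events and requires, in at least 45 of 50
replicates, the planted motif first in the ranking, a selected interval
overlapping the planted block, and the min-p window inside it. These sizes
keep each experiment within a few minutes on one CPU while leaving the
binomial error bars well inside the asserted margins; the reproduction
script (`scripts/acceptance.py`) uses 100 and 10 replicates for the same
two quantities.

## Known limitations

* The Simes bound assumes positive dependence; adversarial dependence
  between windows could invalidate it, though window overlap makes positive
  association the expected regime.
* Normal-approximation rank-sum p-values in extreme tails are approximate;
  with very small event sets, use the exact mode (raise `exact_max_n`).
* Region construction is defined for SE events only; other event types are
  parsed for filtering and overlap statistics but carry degenerate flanking
  bounds where the geometry does not apply (A3SS/A5SS, RI).
* The alpha split across families is Bonferroni — conservative when
  families are positively correlated (e.g. motifs sharing sequence
  content).
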