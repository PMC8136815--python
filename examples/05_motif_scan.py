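"""Degenerate motif scanning and sliding-window counting on one region.

Plants a UGCAUG (RBFOX) element into a random 300-nt region, scans the
sequence, and shows which 50-nt windows of the 250-window family contain the
match.
"""

import numpy as np

from splicemaps import Motif, plant_motif, scan, window_counts

rng = np.random.default_rng(3)
region = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
region = plant_motif(region, "UGCAUG", offset=137, rng=rng)

motif = Motif("RBFOX", ["UGCAUG"])  # RNA notation accepted, stored as DNA
offsets = scan(region, motif)
counts = window_counts(offsets, region_length=300, window_width=50, step=1)

print(f"match offsets: {offsets}")
print(f"window family size: {len(counts)}")
covered = np.flatnonzero(counts)
print(f"windows containing a match: {covered.min()}..{covered.max()} "
      f"({len(covered)} windows)")
# A match at offset s is counted in every window whose start lies in
# (s-49)..s, so one interior match lights up exactly 50 windows.
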