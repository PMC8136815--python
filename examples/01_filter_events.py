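"""Filter a differential-splicing event table into regulated, background and
validation-candidate sets.

Generates a small synthetic rMATS-style table, then applies the three
standard rules: significance (>=15 supporting reads, |dPSI| > 10%,
FDR < 0.05), background (FDR > 0.5, replicate PSI away from 0/1), and
validation candidates (>50 reads in one condition).
"""

from splicemaps import (
    SyntheticConfig,
    classify_direction,
    filter_significant,
    select_background,
    select_validation_candidates,
    simulate_dataset,
)

events, _, truth = simulate_dataset(SyntheticConfig(n_regulated=80, n_background=240, seed=42))

significant = filter_significant(events)
background = select_background(events)
validation = select_validation_candidates(significant)
directions = [classify_direction(ev).value for ev in significant]

print(f"events total:          {len(events)}")
print(f"significant:           {len(significant)} "
      f"({directions.count('spliced_in')} spliced-in, "
      f"{directions.count('spliced_out')} spliced-out)")
print(f"background (unaffected): {len(background)}")
print(f"validation candidates:  {len(validation)}")
true_hits = sum(ev.event_id in set(truth.regulated_ids) for ev in significant)
print(f"truly regulated among significant: {true_hits}/{len(significant)}")
# The significant set should consist almost entirely of truly regulated
# events; background exons are those the knockdown left untouched.
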