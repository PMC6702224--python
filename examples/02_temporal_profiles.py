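"""Build temporal expression profiles and per-stage significance calls.

Counts are filtered (>= 10 reads in every sample), CPM-normalised,
log-transformed, ordered by log2(age in days + 280), smoothed over a
+/- 0.3 window on that scale, and z-scored; stage calls flag developmental
stages where a miRNA's mean z-score is significantly non-zero (two-sided
normal p < 0.05 with >= 2 samples in the stage).
"""

import numpy as np

import mirtemporal as mt

cfg = mt.CohortConfig(seed=1)
cohort = mt.generate_cohort(cfg)
counts = mt.generate_mirna_counts(cohort, cfg)

profiles = mt.build_profiles(counts, cohort, min_reads=10, window=0.3)
print(f"profiles: {profiles.n_features} miRNAs passing the expression filter, "
      f"{len(profiles.sample_ids)} samples ordered by transformed age")
print(f"transformed age range: {profiles.transformed_ages.min():.2f} .. "
      f"{profiles.transformed_ages.max():.2f} (log2 post-conception days)")

calls = mt.stage_significance(profiles)
sig = [c for c in calls if c.significant]
print(f"stage calls: {len(sig)} significant of {len(calls)} "
      f"({100 * len(sig) / len(calls):.1f}%)")
by_stage = {}
for c in sig:
    by_stage[c.stage] = by_stage.get(c.stage, 0) + 1
for stage, n in sorted(by_stage.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {stage:12s} {n} significant miRNA calls")
# With the structured templates most significant excursions land before
# puberty, mirroring the early-life concentration of miRNA expression change.
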