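"""Case/control differential expression with covariates and dose bins.

Fits a negative-binomial GLM per miRNA (log library-size offset; race,
sex, adult age bin and batch as covariates), tests the diagnosis
coefficient by likelihood ratio, adjusts with Benjamini-Hochberg, and runs
the antipsychotic-dose sensitivity analysis on cases binned by thirds of
the chlorpromazine-equivalent dose range.
"""

import numpy as np

import mirtemporal as mt

# two planted case/control effects on a flat background
cfg = mt.CohortConfig(
    seed=5, n_mirna=90,
    planted_de=(("miR-0001", 2.9), ("miR-0002", 2.3)),
)
cohort = mt.generate_cohort(cfg)
counts = mt.generate_mirna_counts(cohort, cfg)

# adults only: cases plus the >= 18 y controls
adults = cohort.subset(cohort.data["age_years"] >= 18)
sub = counts.select_samples(adults.sample_ids)

res = mt.nb_glm_test(sub, adults)
res.sort(key=lambda r: (r.fdr if np.isfinite(r.fdr) else 1.0))
print("top miRNAs by FDR (log2FC is case minus control):")
for r in res[:4]:
    print(f"  {r.feature_id}: log2FC={r.log2_fold_change:+.2f}  "
          f"p={r.p_value:.2e}  FDR={r.fdr:.3f}")
n_hits = sum(r.fdr < 0.05 for r in res if np.isfinite(r.fdr))
print(f"{n_hits} miRNAs at FDR < 0.05 (2 planted)")

dose = mt.dose_sensitivity(sub, adults.cases(), "cpze_daily")
top = [r for r in dose if r.feature_id == res[0].feature_id]
for r in top:
    print(f"dose {r.contrast} for {r.feature_id}: "
          f"log2FC={r.log2_fold_change:+.2f}  p={r.p_value:.2f}")
# Doses were drawn independently of expression, so the dose contrasts for
# the planted miRNAs should not be significant: the planted change is
# attributable to diagnosis, not medication.  A couple of small negative
# hits beyond the planted two can appear because counts are compositional:
# strongly upregulated miRNAs depress every other miRNA's relative share.
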