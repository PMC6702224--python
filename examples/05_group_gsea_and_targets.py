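"""Preranked GSEA of temporal groups and target-gene enrichment.

Ranks all miRNAs by case/control fold change, tests each temporal group
for concordant shift (running-sum enrichment score, permutation NES), then
calls co-regulated (CoR) genes of one group from a target map and tests a
gene set for over-representation among the group's targets.
"""

import numpy as np

import mirtemporal as mt
from mirtemporal.io import GeneSet, GeneSetCollection
from mirtemporal.synthetic import PlantedCoR, mirna_group_sets

cfg = mt.CohortConfig(
    seed=7,
    group_shift=((8, 1.0), (6, -1.0)),  # infancy-peak up, prepuberty-wave down
    planted_cor=PlantedCoR(group=6, genes=tuple(f"GENE{i + 1:04d}" for i in range(10))),
)
cohort = mt.generate_cohort(cfg)
counts = mt.generate_mirna_counts(cohort, cfg)

adults = cohort.subset(cohort.data["age_years"] >= 18)
sub = counts.select_samples(adults.sample_ids)
cpm = sub.values * 1e6 / sub.values.sum(axis=0, keepdims=True)
log2cpm = np.log2(cpm + 1.0)
is_case = (adults.data["diagnosis"] == "case").to_numpy()
lfc = log2cpm[:, is_case].mean(axis=1) - log2cpm[:, ~is_case].mean(axis=1)

groups = mirna_group_sets(cfg)
sets = GeneSetCollection.from_sets([GeneSet(n, m) for n, m in groups.items()])
gsea = mt.preranked_gsea(list(zip(sub.feature_ids, lfc)), sets, n_perm=1000, seed=8)
print("temporal-group GSEA against the case/control fold-change ranking:")
for r in sorted(gsea, key=lambda r: r.fdr):
    flag = " *" if r.fdr < 0.05 else ""
    print(f"  {r.set_name}: ES={r.es:+.2f}  NES={r.nes:+.2f}  "
          f"p={r.p_value:.3f}  FDR={r.fdr:.3f}{flag}")

tm = mt.generate_target_map(cfg)
cor = mt.cor_gene_test(tm, groups["Group6"])
hits = [r for r in cor if r.is_cor]
print(f"\nCoR genes of Group6: {len(hits)} called at FDR < 0.05 "
      f"and >= 2 distinct group miRNAs (10 planted)")

p = mt.set_targeting_test(
    tm, groups["Group6"],
    gene_set={r.gene_id for r in hits} | {"GENE0101", "GENE0102"},
    universe=tm.genes,
)
print(f"hypergeometric targeting p for a CoR-loaded gene set: {p:.2e}")
# The starred groups carry the planted concordant shifts; unshifted groups
# should hover near |NES| ~ 1 with large FDRs.
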