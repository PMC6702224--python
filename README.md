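# mirtemporal

Temporal profiling of microRNA expression in the developing human brain,
and its relationship to case/control dysregulation — as a tested, reusable
Python library.

Bulk small-RNA sequencing of postmortem dorsolateral prefrontal cortex
(DLPFC) across the lifespan shows that most miRNAs are preferentially
expressed during specific developmental windows before puberty, and that
in schizophrenia the infancy-enriched miRNAs tend to shift up while the
prepuberty-enriched ones shift down. `mirtemporal` implements the full
analysis chain behind that kind of study:

1. **Temporal profiles** — counts → expression filter (≥ 10 reads in every
   sample) → CPM → log₂(CPM+1) → samples ordered by post-conception age
   t = log₂(age in days + 280) → smoothing over ±0.3 on that scale →
   per-miRNA z-scores; per-stage significance calls from stage-mean
   z-scores (two-sided normal p < 0.05 with ≥ 2 samples in the stage).
2. **Trajectory clustering** — hierarchical Ward-2 clustering under
   correlation distance (1 − r) and dynamic time warping (DTW); cluster
   number chosen by the gap statistic,
   Gap(k) = E*[log W_k] − log W_k, with the one-standard-error rule.
3. **Cluster concordance** — weighted bipartite graph between the two
   clusterings; Index of Agreement IoA = (# non-crossing edges) /
   (# crossing edges); significance from an age-permutation null.
4. **Differential expression** — per-miRNA negative-binomial GLM
   (log-library offset; race, sex, adult age bin, batch covariates),
   likelihood-ratio test on diagnosis, Benjamini–Hochberg FDR, and
   medication/smoking sensitivity analyses (dose bins by thirds of the
   chlorpromazine-equivalent dose *range*).
5. **Group-level enrichment** — preranked GSEA of each temporal group
   against the fold-change ranking (running-sum ES, permutation NES);
   MRE (miRNA response element) enrichment per transcript via the
   hypergeometric contingency formula
   P = C(n₁₁+n₂₁, n₁₁)·C(n₁₂+n₂₂, n₁₂) / C(N, n₁₁+n₁₂);
   co-regulated (CoR) gene calls (MRE-enriched at FDR < 0.05 and targeted
   by ≥ 2 distinct group miRNAs); hypergeometric gene-set targeting tests
   and Kolmogorov–Smirnov enrichment of per-gene p-values.
6. **miRNA–mRNA correlation** — Pearson r for every predicted
   miRNA–target pair, classification at |r| > 0.49 and FDR < 0.05, and a
   shuffled-sample-label null for the significant-pair fractions.

Because raw data of such cohorts are generally not deposited, the package
ships a first-class **synthetic cohort generator** (`mirtemporal.synthetic`)
that emulates the study design — 109 lifespan controls (second trimester
to the mid-seventies) plus 34 adult cases, negative-binomial counts
following nine temporal group templates, batch effects, planted
case/control shifts, miRNA→mRNA coupling, and TargetScan-style target
maps with planted CoR genes — so every stage is testable end to end.

## Worked example

```bash
python examples/03_clustering_concordance.py
```

```
gap statistic selects k = 9 (planted groups: 9)
Index of Agreement (correlation vs DTW clustering): 4.50
null IoA mean 0.19, permutation p = 0.0050
```

The gap statistic recovers the nine planted temporal groups; the
correlation- and DTW-based clusterings agree far beyond the
age-permutation null (IoA 4.5 vs a null mean of 0.19; p at the floor of
200 permutations), i.e. the group structure is a property of the
trajectories, not of either distance.

Each script under `examples/` exercises one capability (cohort
simulation, profile building and stage calls, clustering and concordance,
differential expression and dose sensitivity, GSEA and CoR/targeting
tests, miRNA–mRNA correlation) and prints what the numbers mean.

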