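# Methods

This note documents the models, conventions and numerical choices behind
`mirtemporal`, and what the synthetic study conditions do and do not show
about real data.

## Temporal profiles

Ages are post-natal years; fetal samples carry negative ages bounded below
by −0.75 y so that post-conception age stays positive. The working time
axis is t = log₂(age·365.25 + 280) (days; 365.25 days/year, ~280
gestational days), which spreads the developmentally dense early-life
samples and compresses adulthood.

The profile pipeline is counts → expression filter → CPM → log₂(CPM+1) →
sort by t → smooth → z-score:

* **Expression filter**: a miRNA is "expressed" only if it has at least
  `min_reads` (default 10) mapped reads in *every* sample. This is strict
  by construction; it is the rule the rest of the pipeline assumes.
* **CPM** rescales each sample column to sum to 10⁶; a zero-depth column
  is an error, never silently dropped.
* **log₂(CPM+1)**: the pseudocount of 1 handles zeros; it is the only
  transform applied before smoothing.
* **Smoothing** replaces each sample's value by the mean over all samples
  within ±0.3 of its transformed age, endpoints inclusive and the sample
  itself included. The window is a half-width (±0.3, total 0.6); a total
  width of 0.3 is available by passing `window=0.15`. The neighbourhood
  is defined by age, not position, so the result is invariant to sample
  input order; boundary ties are deterministic because the endpoints are
  inclusive.
* **z-scores** use the sample (ddof = 1) standard deviation per feature.
  Zero-variance features get an all-zero row plus a `degenerate` flag
  rather than NaNs.

**Stage calls.** Developmental stages default to fetal (< 0 y), infant
(0–1), toddler (1–3), preschool (3–6), prepuberty (6–12), adolescent
(12–18), young adult (18–39), adult (40–60), senior (> 60); boundaries
are configurable, and the adult bins double as the age covariate of the
case/control models. The stage mean z̄ is converted to a two-sided normal
p = 2(1 − Φ(|z̄|)); a stage is significant only if p < 0.05 **and** it
holds ≥ 2 samples. Two-sided, because temporal groups show both high and
low excursions. z̄ is *not* rescaled by √n by default: smoothed z-scores
are strongly correlated within a stage, so treating z̄ as a single
standard normal draw is the conservative choice (an option restores the
√n scaling). Under flat-template nulls the empirical call rate is well
below the nominal 5% for exactly this reason — the calibration checks
assert the one-sided bound rate ≤ α + Monte-Carlo error, nothing tighter.

## Clustering and cluster number

Correlation distance is d = 1 − r across the age-ordered values
(zero-variance rows are excluded with a warning). DTW uses the classic
unconstrained dynamic program with |a−b| local cost; the default step
pattern is the plain path-sum (all steps weight 1), which is exactly what
the exhaustive path-enumeration oracle computes; a diagonal-weight-2
variant ("symmetric2", first cell counted once) and a Sakoe–Chiba band
are options.

Hierarchical clustering applies the Ward-2 Lance–Williams update to the
provided distances (for DTW this is an approximation, since DTW distances
are not Euclidean). Cutting uses `cut_tree`, which always yields exactly
k clusters; labels are renumbered 1..k in order of first appearance so
output is deterministic. Merge ties follow the nearest-neighbor-chain
order of the linkage algorithm.

**Gap statistic.** W_k = Σ_r (2 n_r)⁻¹ Σ_{i,j∈r} d²_ij under the same
distance used for clustering; Gap(k) = E*[log W_k] − log W_k; the
selected k is the smallest with Gap(k) ≥ Gap(k+1) − s_{k+1}
(one-standard-error rule, s from B reference draws, default B = 50). The
default reference distribution draws uniformly within the data's box in
its principal-axis (SVD) frame. The axis-aligned uniform box is available
as `reference="uniform"`, but it is a poor null for smoothed trajectories:
profiles occupy a thin subspace of sample space, the axis-aligned box
vastly overstates null dispersion, and the gap curve then keeps rising
past the true k so the one-SE rule never fires. The rotated box — the
second reference of the original gap-statistic proposal — matches the
data's effective dimensionality and recovers planted cluster numbers.

**Concordance.** The two clusterings are compared as a weighted bipartite
graph: one node per cluster on each side, edge weight = number of shared
features. Node orders come from an iterated weighted-barycenter heuristic
(ties by label). Two edges (i,j),(k,l) cross iff
(pos(i)−pos(k))·(pos(j)−pos(l)) < 0; an *edge* is "crossing" if it
crosses at least one other edge, and IoA = #non-crossing /
max(#crossing, 1) — edge counts, not weights, and the clamped denominator
keeps perfect agreement finite (identical k-cluster partitions give
IoA = k). The permutation null reorders each feature's values
independently across the age-ordered samples, re-clusters the permuted
data with the second method at fixed k (re-running the gap selection per
permutation is available but costs B× more), and scores IoA against the
*fixed* first clustering; p = (1 + #{null ≥ observed})/(n_perm + 1).

## Differential expression

Counts are modelled per miRNA as NB(μ, α) with
log μ = offset + Xβ, offset = log library size (column sums by default;
externally normalised sizes can be supplied). Covariates are dummy-coded
with the first sorted level as reference, except the interest column
whose reference is fixed (control), so the reported coefficient is case
vs control; log₂FC = β/ln 2, positive = upregulated in cases.

Dispersion is estimated in two steps: per-feature ML at Poisson-fitted
means, then shrinkage of log α toward a log-linear trend in log mean CPM
with weight df/(df + prior_df), prior_df = 10 by default (about ten
pseudo-features of trend information; with tens of samples the data term
dominates, with few samples the trend does). The diagnosis test is a
likelihood-ratio test (χ²₁) at the shrunken dispersion — more stable than
Wald at these sample sizes. Non-converged fits are flagged and their p
left missing, never set to 0. BH adjustment is the standard step-up,
clipped at 1.

**Dose sensitivity** bins cases by equal thirds of the dose *range*
(low/medium/high; subject-count tertiles would be different and are not
used), fits the NB GLM with the bin factor, and reports Wald contrasts
high-vs-low and high-vs-medium; a contrast against an empty range-bin is
skipped with a warning. The same binning is applied to lifetime, daily
and last chlorpromazine-equivalent dose. Smoking/cotinine analyses are
covariate swaps in the same design machinery (cotinine as a continuous
covariate), not separate code.

## Enrichment

**Preranked GSEA.** Features are ranked by score (fold change), ties
broken by id. The running sum gains |score|^w / Σ_hits |score|^w at each
member (w = 1) and loses 1/(N − N_h) at each non-member; ES is the
extremum. The null draws `n_perm` (default 1000) random same-size member
sets (gene-label permutation — phenotype permutation does not exist in
the preranked setting); NES = ES / mean(|null ES| of matching sign); the
nominal p is the matching-sign permutation tail with the +1 correction,
and FDR is BH across the tested sets. In the pipeline only temporal
groups with > 50 members are tested (`min_size=51`); smaller groups are
too volatile across cohorts.

**MRE enrichment / CoR genes.** Per transcript, the 2×2 table counts
binding sites of group vs non-group miRNAs in the tested transcript vs
all others. `mode="point"` returns the hypergeometric point probability
(the printed formula, kept for formula-level verification);
`mode="tail"`, the default test, returns the one-sided enrichment tail
P(X ≥ n₁₁) — a point probability alone is not a tail test. Degenerate
margins give p = 1. FDR is taken across all transcripts of a run; a gene
is a CoR gene iff its best transcript passes FDR < 0.05 and ≥ 2 distinct
group miRNAs target it (one heavily-sited miRNA is not co-regulation).

**Gene-set targeting** is the upper-tail hypergeometric probability of
the overlap between the genes targeted by ≥ 1 group miRNA (draws) and
the gene set (successes) within the universe of genes targeted by any
expressed miRNA. **KS enrichment** compares the per-gene enrichment
p-value distribution of a set against a background sample with the
two-sample Kolmogorov–Smirnov test (exact method for sets below 3, with
a warning); direction is read off the medians.

## miRNA–mRNA correlation

Pearson r is computed for every target-map pair present in both matrices
across the shared samples (≥ 4 required), on log₂(CPM+1) miRNA values vs
continuous mRNA values; two-sided p from the t distribution; BH-FDR over
all computable pairs (all target-map pairs, not just detected ones).
Pairs classify as positive (r > 0.49, FDR < 0.05), negative (r < −0.49,
FDR < 0.05) or none. The shuffled-label null permutes the mRNA matrix's
sample labels once per shuffle — a single permutation breaks every
pairing simultaneously — and records the class fractions per shuffle.

## Synthetic study conditions

The generator's defaults define the conditions under which the pipeline
is validated: 109 controls with ages stratified-uniformly on the
transformed age scale over −0.44 to 73.3 y (so every stage holds ≥ 2
samples, which the stage-call rule needs) plus 34 cases uniform over
18–72 y (cases are adults, as in a case/control postmortem design); nine
temporal templates (fetal highs and lows, infant and toddler peaks, a
prepubertal wave, an early-life plateau, amplitude 2 log₂ units);
270 miRNAs in nine equal groups — a deliberately scaled-down feature
count chosen for simulation throughput, not demographic fidelity;
per-miRNA baselines uniform on 5–9 log₂ CPM; log-normal library sizes
(median ≈ 2 M); NB dispersion 0.1 shared across miRNAs (the simplest
model consistent with the GLM stage); batch as a multiplicative
per-(batch, miRNA) log-normal offset with σ = 0.15 on two batches.

Counts are gamma–Poisson draws whose expected CPM follows each miRNA's
template; case-only planted effects (per-miRNA `planted_de` and
group-level `group_shift`) add to the case columns before the
compositional normalisation, so a very large planted effect slightly
depresses all other miRNAs' relative shares — visible in the examples
and real in sequencing data. The mRNA matrix is Gaussian; coupled genes
are slope × (miRNA log₂CPM) + noise, and `coupling_slope_for_r` returns
the slope that yields a chosen expected Pearson r (e.g. −0.71) for given
predictor spread and noise. The target map is a random bipartite
site-count table (edge density 2%, sites 1 + Poisson(0.3)); planted CoR
genes receive sites from 4 distinct group miRNAs, 4 sites each — an
excess calibrated so a planted gene genuinely satisfies the CoR
definition against the background density.

What the synthetic conditions do **not** emulate: raw reads and mapping,
RNA degradation (pH/PMI effects), cell-type composition and its drift
with age, realistic miRNA families with correlated sequences and shared
targets, mRNA temporal structure beyond miRNA coupling, and the paper's
actual demographic stage distribution. Passing tests therefore show that
the algorithms are implemented correctly and recover planted structure
under a faithful statistical emulation of the design — not that any
specific biological result would replicate.

## Problem sizes and determinism

All generators and permutation tests are deterministic given their seeds
(NumPy `SeedSequence` substreams per generator). The validation runs use
deliberately scaled sizes: 20 cohorts for cluster-number recovery (gap
B = 20, k ≤ 12), 200 replicate features at 40/arm for fold-change
recovery and 1000 for type-I error, 20 seeds for GSEA directionality,
200 permutations for the concordance tests on 90 × 143 (structured) and
60 × 80 (noise) profile sets, and 20 label shuffles for the correlation
null. Exact oracles (DTW path enumeration, BH step-up, hypergeometric
enumeration, direct KS evaluation) run at small n where enumeration is
feasible and are compared exactly or at 1e-9..1e-12 tolerances.
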