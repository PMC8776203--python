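# Methods

This note documents the statistical model behind `chronode`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical and design decisions a maintainer should
know about.

## Experimental design and data model

The package analyses a two-arm time course: cells treated with a stimulus
vs a solvent control, profiled at an ordered set of time points (default
4, 8, 24, 48 h) with replicate libraries per condition (default 3), i.e.
24 libraries. Counts for gene *g* in sample *i* are modeled as negative
binomial,

    y_gi ~ NB(mu_gi, phi_g),   Var = mu + phi * mu^2,
    mu_gi = r_{g,c(i)} * N_i,

where c(i) is the (time, arm) condition of sample *i*, N_i its effective
library size and r the condition's expression rate. phi = 0 degenerates to
Poisson.

## Normalization and filtering

* **Filtering**: genes are kept when their raw-library CPM reaches
  `min_cpm` (default 1) in at least `min_samples` samples (default: the
  smallest condition group size, 3). The rule is a transparent
  CPM-in-k-samples criterion; the boundary is inclusive and the filter is
  idempotent.
* **TMM factors**: per-sample scaling factors from doubly trimmed (30% on
  M, 5% on A), inverse-variance-weighted mean log-ratios against a
  reference sample (the one whose upper-quartile count fraction is closest
  to the mean upper quartile), renormalized to geometric mean 1. Genes
  with a zero count in either member of a pair are excluded from that
  pair. Note the delta-method weights make the factors only *first-order*
  invariant to rescaling one sample's counts: the scaled sample's
  binomial-variance term rescales while the reference's does not, so gene
  weights shift slightly (≲1% factor movement for a 7× scaling on a
  300-gene panel). The tests assert invariance at 2% for this reason.
* **CPM / log2CPM**: counts per million over effective (TMM-scaled)
  library sizes. log2CPM adds a prior count (default 2, scaled per sample
  by relative effective library size) so zero counts stay finite and
  downstream z-scores cannot blow up.
* **MDS distances**: for every sample pair, the root-mean-square of the
  `top_n` (default 500) largest absolute log2CPM differences, with the
  gene set re-selected per pair. Because the gene set differs per pair the
  triangle inequality is not guaranteed; the matrix is symmetric with a
  zero diagonal only. The choice of log2CPM with prior 2 as the
  per-gene quantity is a convention of this package.

## Dispersion estimation

A log-spaced grid (1e-6 … 10, 42 points) of candidate dispersions is
scored per gene by the Cox–Reid adjusted profile log-likelihood: condition
rates are fitted by Fisher scoring at each candidate phi and the
adjustment −½ Σ log I_group (I = Fisher information of the fitted group
log-rates) corrects the bias from plugging in estimated means. The
**common** dispersion maximizes the across-gene mean curve (with parabolic
refinement in log-phi); **tagwise** dispersions maximize each gene's curve
plus `prior_df` (default 10) times the mean curve — weighted-likelihood
shrinkage that pulls poorly informed genes toward the common value. On
simulated data the common estimate recovers planted phi = 0.2 within
±0.01 at 2,000 genes and falls below 0.01 for Poisson data.

This is a deliberate simplification of the quasi-likelihood pipeline used
with trended dispersions in the R ecosystem: no mean-dispersion trend, no
QL F-statistics, no robustification against outlier dispersions. The
trade-off buys a self-contained estimator that is verifiable from first
principles; with thousands of genes and a dispersion that does not vary
strongly with abundance (true of the simulator), the difference is
immaterial for the operating characteristics tested here.

## The threshold (TREAT-style) test

Per time point, the two arms are compared on offset-adjusted group rates
(a 0.5-count guard per group enters the reported log2FC and the Wald
plug-in rates only, never a likelihood). The null hypothesis is
|log2FC| ≤ log2(tau); the p-value sums the upper tails of the Wald
statistic at the two boundary nulls:

    p = min(1, Q((|L| - c)/se) + Q((|L| + c)/se)),   c = log2(tau),

with L the observed log2FC and se from the NB Fisher information of the
two group log-rates at the tagwise dispersion. Properties, all tested:
p = 1 exactly at L = 0; p ≥ 0.5 anywhere inside the null region; the
tau → 1 limit is the ordinary two-sided Wald test; p is monotone in |L|
at fixed se; swapping arm labels negates every log2FC and leaves p
unchanged. Because the null is composite, the test is conservative at the
boundary interior — on all-null simulations the raw positive rate at
alpha = 0.05 is ≈0.01.

**Significance rule**: a gene is significant at time t when its
BH-adjusted p (adjustment within each time point separately — each time
point is a separate pairwise contrast) is below alpha (default 0.05) *and*
the sum over time points of its cross-arm mean CPM exceeds `cpm_floor`
(default 25). The floor averages over both arms; the union of the
per-time significant sets is the target catalogue. Default thresholds:
tau = 1.5 at 4/8 h, tau = 2 at 24/48 h, alpha = 0.05, floor 25.

Power at these settings is dominated by the dispersion and replicate
number, not by sequencing depth: for phi = 0.1 and n = 3 the information
per group saturates at n/phi, giving se(log2FC) ≈ 0.37 regardless of
depth. A planted |log2FC| = 3 is then recovered essentially always, while
|log2FC| = 2 against tau = 2 (a one-log2 gap, z ≈ 2.7) has raw-p power
≈0.75–0.8 at late time points and ≈0.98 early — and materially less than
that through a per-time BH cut when true positives are rare. The
acceptance checks therefore measure power as the raw-p operating
characteristic at alpha, alongside the BH-based catalogue sizes.

## Classification

* **Timing**: primary iff significant at 4 or 8 h; else secondary.
* **Direction**: over time points with |FC| above `fc_threshold`
  (default 1.5): all positive → up, all negative → down, both → mixed.
  When nothing exceeds the threshold, the sign at the significant time
  points decides (avoids an undefined class).
* **Profile**: *discontinuous* when the gene is significant after an
  intermediate time point at which |FC| fell to or below the threshold;
  *persistent* when |FC| stays above threshold from first significance
  through the last time point; *transient* when the effect is gone (and
  not significant) at the last time point. Precedence is
  discontinuous > transient > persistent, mirroring the biology where a
  re-appearing response is a distinct phenomenon even when it is also
  early-and-late significant. A residual gene that fits none of the three
  clauses is called transient when not significant at the last time point
  and persistent otherwise.

Venn overlap counts are exact exclusive-region counts over the per-time
significant sets and always sum to the union size.

## Trajectory clustering and mechanism labels

Replicates are collapsed to the 8 condition means before z-scoring —
clustering all 24 samples would let replicate noise dominate the profile
shape; the condition-mean profile is what the four canonical clusters
describe. Constant profiles cannot be z-scored and are excluded with a
warning. k-means uses Lloyd's algorithm with k-means++ seeding, k = 4,
best of 25 restarts, up to 1000 iterations, deterministic under a seed.
(Lloyd replaces the Hartigan–Wong variant of R's default; both minimize
the same WCSS objective, and on tiny instances the restarted solution
attains the exhaustive-enumeration optimum — tested.)

Cluster labels are automatic: the arm with the larger centroid temporal
range drives the cluster (treated → direct, control → indirect; ties are
conservatively indirect), the direction is the treated-minus-control
offset for direct clusters and the control-arm drift (the response that
treatment suppresses) for indirect ones. Contingency between
classification axes (e.g. direction × mechanism) uses the two-sided
Fisher exact test with BH across the tables of a run; mixed-direction
genes are excluded from direction-axis tables, and a zero cell triggers
the Haldane 0.5 correction for the reported odds ratio.

## Enrichment

Classic per-term one-sided Fisher (hypergeometric upper tail) of the
target list against the tested-gene universe, flat GMT input. Terms
overlapping fewer than `min_sig` (default 5) significant genes are
excluded before BH. Graph-aware decorrelation of nested terms (weight01
style) is deliberately out of scope: it requires the ontology DAG as
external data and is orthogonal to the direction rule. Direction per
term: down when down:up > 2 among overlapping genes, up by the symmetric
rule, otherwise "affected"; mixed genes count in neither tally and an
empty denominator with a non-zero numerator counts as an infinite ratio.

## Genomics

BED semantics are 0-based half-open throughout. Colocalization anchors a
gene at its TSS-equivalent edge (start on +, end−1 on −) and reports the
signed distance to the nearest peak edge on the same chromosome (0 on
overlap), with a within-window flag. The default window is 1 Mb — half
the canonical 2 Mb upper bound of a topologically associated domain, the
genomic unit within which enhancer-promoter regulation is expected;
configurable because the TAD size range (100 kb–2 Mb) does not fix a
single number. Inputs must share one genome assembly; no liftover.

## Synthetic data generator

Each gene draws from its own deterministic substream
(`SeedSequence(seed).spawn(i)`), so identical (config, seed) runs are
bit-identical and extending the panel never perturbs earlier genes. Genes
are assigned trajectory archetypes: null; direct up/down (treated arm
steps by ±effect from the onset time, control flat); indirect up/down
(control drifts, treated flat — the DE contrast has the opposite sign);
transient (treated effect at the early time points only); discontinuous
(treated effect at 8 and 48 h, none at 24 h); mixed (up early, down
late). Effects are step functions at onset — the analysis only observes
four discrete time points, so smooth kinetics would add parameters
without adding observable structure.

Defaults emulate a filtered bulk experiment: 12,000 genes, 5.5% targets
(direct and indirect both common, indirect slightly dominant), baseline
log2CPM uniform on [−2, 9] (spanning the expression-filter boundary so
filtering is exercised), |log2FC| uniform on [0.8, 3] (the field has no
published effect-size distribution for such targets; this spans
borderline to strong), phi = 0.1, library sizes log-normal (10% CV)
around 5 × 10⁶.

**Identifiability constraint**: indirect (culture-drift) archetypes draw
their onset strictly after the first time point. A step drift already at
full effect at the first observation produces two flat arms with a
constant offset — *exactly* the same count distribution as a direct
effect of the opposite sign, since the pre-stimulation baseline is never
observed. Planted mechanism labels would be unidentifiable for such
genes and the generator's truth table would not be a valid recovery
oracle. Biologically this encodes that the ex vivo culture response
develops during culture rather than pre-dating the first sample.

What the simulator does **not** emulate: GC/length biases, read-level
noise, cell-type composition shifts within the mixed population,
mean-dispersion trends, correlated genes, or batch structure. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to the full messiness of
real libraries.

## Problem sizes used in tests and acceptance runs

Simulation-based checks use 2,000–6,000 genes: large enough that
empirical rates have small Monte-Carlo error (SE ≲ 0.3 percentage points
on a positive rate at 6,000 genes) and that the per-gene shrinkage and
BH behavior are in their many-genes regime, while keeping any single
check to seconds. The all-null error-control check runs five seeds at
6,000 genes; power and recovery checks use 2,000–4,000 genes with 10%
planted targets at fixed effect sizes (|log2FC| 2 or 3, baseline
CPM ≥ 50, phi = 0.1 — the strong-effect regime in which timing and
mechanism labels are decidable).

## Known limitations

* The Wald TREAT p-value is asymptotic; at very low counts (information
  per group ≪ 10) it can be mildly liberal relative to an exact test,
  though the composite-null construction keeps the overall operating
  characteristic conservative.
* No mean-dispersion trend: data with a strong trend would leave
  low-abundance genes under-dispersed in the model and slightly inflate
  their statistics.
* Mechanism labels are cluster-level; a gene in a mixed cluster inherits
  the cluster's label. With well-separated archetypes this is exact (the
  tests measure ≈100% agreement); with weak effects or k mismatched to
  the trajectory diversity it degrades gracefully but silently.
* The profile taxonomy formalizes narrative categories; its edge cases
  (e.g. sub-threshold fold change at the last time point while still
  significant there) follow the precedence rule above rather than any
  published boundary definition.
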