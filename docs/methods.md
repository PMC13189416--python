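# Methods

`temponmf` decomposes a two-condition differentiation time course — a
GCSF-conditioned neutrophil arm and an IL3 macrophage arm, sampled densely
after induction — into a small number of temporal *behaviors* (metagenes) by
non-negative matrix factorization, and provides the surrounding pipeline:
normalization, replicate QC, rank selection, robustness checks, gene
classification and TF-binding enrichment.  This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not establish.

## Sampling grid

Samples are taken every hour to 4 h after induction, every 4 h to 24 h, and
every 8 h to 168 h — 27 post-induction timepoints per condition.  The GCSF
arm adds the untreated baseline (−48 h, before cytokine conditioning) and
the post-conditioning 0 h point (29 columns); the IL3 arm adds its 0 h
baseline (28 columns).  The untreated sample is shared between the arms:
`average_replicates(..., share_baseline=True)` duplicates its averaged
column into the IL3 0 h slot when that slot has no samples of its own.

## Normalization

Size factors are median-of-ratios: for every gene with strictly positive
counts in all samples, the ratio of its count in sample *j* to its
geometric mean across samples is formed, and *s_j* is the median of these
ratios (computed in log space).  We additionally pin the factors to
geometric mean 1 — the convention used for normalization factors in edgeR —
which fixes the arbitrary global scale and makes the procedure exactly
idempotent: re-estimating factors on a normalized table returns 1 for
every sample.

Two properties of this family of estimators are worth stating precisely,
because they are often assumed and are not quite true:

* **Column-scale equivariance is only approximate.**  Multiplying one
  sample's column by *c* multiplies every per-gene geometric mean by
  *c*^(1/n), so the sample's size factor changes by *c*^(1−1/n), every
  other factor by *c*^(−1/n), and the whole normalized table by a global
  factor *c*^(1/n).  No ratio-to-geometric-mean scheme can do better: the
  sum of log size factors is structurally invariant, so a single factor
  cannot absorb the full log *c*.  The unit tests assert this exact
  transformation law.  For realistic *n* (tens of samples) the residual
  global factor is negligible.
* **The estimator assumes a stably expressed majority.**  The median is
  only anchored when most genes' ratios are stable across samples.  On
  data where every gene is strongly temporally regulated the median tracks
  the regulation and the "normalization" distorts the matrix (we observed
  factors spanning fifteen orders of magnitude on such an input).  Real
  transcriptomes satisfy the assumption; synthetic fixtures must be built
  to satisfy it too (below).

Genes whose normalized count stays below 5 in every sample are removed
(kept iff the row maximum is ≥ 5); replicates are then averaged
arithmetically per (condition, timepoint), the two condition blocks are
concatenated (GCSF block then IL3 block, time ascending), and each gene row
is divided by its maximum over *all* columns so every expressed gene peaks
at 1.  Max-scaling prevents a few highly expressed genes from dominating
the factorization; all-zero rows are left as zeros and the pre-scaling row
maxima are retained for thresholds defined on normalized counts.

## The factorization

The scaled G × T matrix X is approximated as X ≈ W H with W (G × M) and
H (M × T) non-negative: each gene's trajectory is a non-negative mixture of
M shared temporal behaviors.  Fitting alternates the multiplicative
(Frobenius) updates

    W ← W ∘ (X Hᵀ) ⊘ (W H Hᵀ)
    H ← H ∘ (Wᵀ X) ⊘ (Wᵀ W H)

with H updated against the freshly updated W, from entrywise Uniform[0, 1)
initializations.  Denominators are floored at ε = 1e-12 — this guards 0/0
without perturbing non-degenerate entries, so the update is exactly the
textbook rule wherever defined; entries that reach 0 stay 0.  Iteration
stops when the Frobenius gap F_k = ‖X − W H‖_F changes by less than θ
between successive iterations, with a 10,000-iteration safety cap.  A
Poisson-likelihood score Σ (X log(WH) − WH) is recorded per iteration as a
diagnostic trace; all stopping and reporting is Frobenius-based.

**Stopping threshold.**  θ defaults to 0.05, appropriate for genome-scale
matrices (tens of thousands of rows, where F is correspondingly large).
F scales like √G, so on the ~2,000-gene fixtures used in the tests the same
absolute θ halts on an early plateau long before the behaviors have
resolved; fixture-scale runs therefore use θ = 1e-4, at which the Frobenius
trace is flat and the recovered behaviors stop changing.  θ is a numerical
convergence knob, not a property of the data.

**Local minima.**  Multiplicative updates are only guaranteed not to
increase the objective; on exactly low-rank matrices they can stall in
poor stationary points.  `fit_restarts` runs several seeded starts and
keeps the lowest final F — the standard remedy, and the same logic that
motivates the robustness protocol below.

**Gauge.**  (W P D, D⁻¹ Pᵀ H) reconstructs the same matrix for any
permutation P and positive diagonal D.  All comparisons to reference
behaviors therefore first rescale fitted H rows to maximum 1 (absorbing D
into W) and then match rows by best Pearson correlation
(`match_behaviors`, a linear assignment); weight-based statements
(dominant behavior, top-gene lists) are made in this pinned gauge.

## Choosing the number of behaviors

`sweep_M` fits at each rank in a range (fresh seed per rank, seed + M) and
records (i) the RMSE ‖·‖_F/√(G·T) between the data and each
reconstruction and (ii) the RMSE between reconstructions at consecutive
ranks.  Each consecutive pair is keyed by its lower rank, so the curve at
M reads "how much the reconstruction changes when an (M+1)-th behavior is
added"; a strict interior local minimum marks a rank beyond which extra
behaviors mostly refit noise.  Plateaus (non-strict minima) are reported
separately.  On the default fixture with 5 planted behaviors the minimum
falls at M = 5 in most seeds.

`robustness` repeats the fit from n random starts (seed + run) and
compares all pairwise reconstruction RMSEs with the reconstruction-to-data
RMSEs; factorizations are considered robust when every pairwise value sits
below every to-data value, i.e. restarts disagree with each other far less
than any of them differs from the data.  The test suite runs this at
n = 20 (190 pairs) to keep runtimes at desk scale; the protocol is
n-independent.

## Replicate outlier detection

Standardized PCA (each gene to zero mean, unit variance over samples, as
with R's `prcomp(scale = TRUE)`; constant genes dropped) gives per-sample
scores.  Within each (condition, timepoint) group of N replicates, each
replicate's score on each of the top 4 PCs is converted to
z = |score − group mean| / population sd (divisor N), and a replicate is
flagged if any z exceeds 2.

This statistic has a hard ceiling: within a group of N, no single score
can exceed √(N−1), so with the usual 3–4 replicates the threshold of 2 is
*unreachable* and the detector can never flag anything — consistent with
time courses at such replication reporting no outliers by this method.
Conversely, for N ≥ 6 the threshold becomes reachable but the standardized
within-group configuration is scale-invariant and approximately Gaussian
(each PC score aggregates thousands of genes), so z > 2 also occurs by
chance at ~1.6–3% per (replicate, PC); across dozens of timepoint groups a
planted outlier is reliably *the top-z sample of its group* but never the
*only* flagged sample.  Both regimes are exercised in the tests; users
needing a calibrated detector should treat the z-threshold as a ranking
device, not a significance test.  The correlation-based view (pairwise
Pearson r between timepoints, 1 − r distance, complete-linkage
clustering, deterministic label-sorted tie-breaks) is provided as the
complementary check, and suspect timepoints can be removed with an
explicit exclude-timepoints configuration rather than a hard-coded list.

## Gene classification and reporting

Each gene's dominant behavior is the argmax of its weight row (ties to the
lowest behavior id; all-zero rows labeled "unexpressed" and displayed
last).  Behaviors are ordered by where their H row peaks — GCSF-peaking
before IL3-peaking, earlier before later, exact cross-block ties to GCSF —
and genes are grouped by ordered dominant behavior, descending dominant
weight within groups, ties by gene id, giving a deterministic display
permutation.  Per-behavior gene lists take the top n = 500 weights among
genes whose maximum *normalized* (pre-scaling) expression is at least 3 —
the floor is meaningful only before max-scaling.  TF co-expression modules
come from 1 − r clustering of the TF rows of the scaled matrix, annotated
with dominant behaviors.  Externally produced differential-expression
tables are filtered with strict thresholds padj < 0.05 and
|log2FC| > 0.58 (±50%).

## TSS-window enrichment

One representative transcript per gene (highest baseline expression in the
undifferentiated state; ties to the smallest transcript id) defines the
TSS.  The proximal window is the inclusive ±1 kb around it; the distal
window is ±50 kb minus the proximal zone.  Windows are strand-agnostic,
clipped at zero, and held as 0-based half-open intervals; a gene is bound
when any peak overlaps the window by ≥ 1 bp (sorted-sweep implementation,
verified against an all-pairs oracle).  For a gene set against a
background (all genes with normalized expression ≥ 5; the set must be a
subset), enrichment is (T_p/T_n)/(A_p/A_n) — bound fraction in the set
over bound fraction in the background — with significance from the
one-sided upper-tail Fisher's exact test on the set vs background-minus-set
2×2 table, computed by exact hypergeometric summation.  Raw p-values are
reported; Benjamini–Hochberg adjustment is available but off by default,
as the analysis is descriptive across many overlapping sets.

## The synthetic fixtures

The generator emulates the study design so every stage is testable without
sequencing data: behaviors are smooth logistic bumps/ramps on the real
sampling grid (pulse edges of half-width 2 h), placed in one or both
condition blocks and normalized to their amplitude; the default set of
five tiles both arms (a shared early-shutdown program, an early pulse per
arm, a shared 8–80 h pulse, a shared late rise from ~80 h).  Dynamic genes
get one dominant heavy-tailed weight (designated behavior = gene index mod
K) plus sparse sub-dominant weights; by default 55% of genes are *flat*
mixtures — non-negative least-squares projections of a constant trajectory
onto the planted behaviors, scaled by lognormal levels — mirroring the
stably expressed majority of a real transcriptome while keeping the matrix
exactly rank K.  Without such a majority the median-of-ratios assumption
fails and normalization itself corrupts the signal, so an all-dynamic
fixture is both unrealistic and self-defeating; the pure sparsity-1
variant used for exact-recovery checks accordingly skips the size-factor
stage.  Replicate noise is multiplicative LogNormal(0, CV) with CV = 0.1
by default (values kept as non-negative reals; no count rounding, since
downstream treats values as normalized abundances); planted outliers
multiply a random 30% gene subset of one sample by (1 + shift).  Toy
enrichment geometry spaces TSSs 150 kb apart (distal windows never
overlap), drops 200-bp peaks into proximal/distal windows independently at
the chosen foreground/background rates, and keeps the foreground a 5%
minority so the background's bound fraction stays near the nominal rate.
Defaults: 2,000 genes, 5 behaviors, 3 replicates, seed 20240101.

What passing these fixtures does *not* show: robustness to count noise
(the noise is lognormal, not negative-binomial), to batch effects or
library-composition bias, to unbalanced replication, or to behaviors
outside the planted taxonomy; and flat genes' "dominant" behavior is a
near-tie by construction, so recovery is scored on dynamic genes only.

## Problem sizes used in tests

Test and acceptance runs use the 2,000-gene fixture, rank sweeps 2..10
over 10 seeds, 20 robustness restarts, 500 null gene sets for the type-I
check, and exhaustive Fisher verification for backgrounds up to 60 genes —
sizes chosen so the full suite completes in minutes on one CPU while every
protocol is executed in full.
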