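# Methods

`txdist` assesses whether the transcriptome of a genetically modified (GM)
line is *substantially equivalent* to its untransformed background: are the
global expression changes caused by the modification larger than the
changes that occur naturally between accessions, or between groups of a
recombinant-inbred-line (RIL) population? The package answers this with a
bounded, rank-based distance between sample groups in a retained
principal-component subspace, judged by permutation, embedded in the
standard univariate machinery (per-gene ANOVA/Tukey, fold-change calls,
CV profiling, over-representation analysis) that characterizes *which*
genes changed.

## Data model

Expression data are log2-scale, probe-summarized intensity matrices
(genes × samples), the output of RMA-style normalization; the package does
not process raw array images. Samples carry a *group* label (genotype /
accession / RIL group) and a *batch* label (study of origin, or a finer
hybridization batch). Multiple studies are joined on their common genes
("meta data"); group contrasts are only ever computed within the joint,
batch-corrected matrix.

## Preprocessing

**Quantile normalization** forces every sample onto the common quantile
profile: at each rank, the target value is the mean across samples of the
rank-th order statistics. Ties within a sample receive the mean of the
target values their positions span, so ties remain ties and per-sample
rank order is preserved exactly.

**Meta-data assembly** intersects gene sets (gene order follows the first
study) rather than taking a union with missing values: the distance
analysis requires complete expression vectors. Sample IDs are prefixed
with the study label; batch labels default to the study label unless a
study supplies finer ones.

**Batch correction** is a per-gene mean shift: `x' = x − mean(batch) +
grand mean`. Per-gene grand means are preserved exactly, per-gene
per-batch means are equalized exactly, and the operation is idempotent.
This removes precisely the structure the synthetic generator injects
(per-batch, per-gene shared offsets), which makes the correction testable
to machine precision. It deliberately does not touch variances: scaling
corrections would distort the within-group replicate spread on which both
the univariate tests and the distance permutations rely. Note that the
offset *values* themselves are not identifiable from finite replicates —
what is exact is the removal of all between-batch mean structure.

**Probe exclusion** drops designated rows (typically the transgene
marker probes) before the multivariate stage, so the intended effect of
the modification cannot dominate the distance; absent IDs are reported
but not fatal.

## Per-gene inference

Each gene gets a one-way ANOVA across all groups and Tukey's HSD
(Tukey–Kramer for unequal group sizes) for every group pair. Pairwise
significance is read from the Tukey-adjusted p at α = 0.05. **No
across-gene multiplicity correction is applied**: the reported
counts/percentages are of genes individually significant at α, which is
the convention for this kind of global characterization (the multivariate
distance, not the per-gene list, carries the equivalence verdict).
Up/down calls additionally require |Δlog2| beyond log2 of the fold
threshold (default 2-fold). Fold changes are differences of group means
on the log2 scale, exponentiated; reported folds are half-up rounded to
one decimal, as are all percentages.

Degenerate genes (zero within-group variance) are defined to have
F = 0, p = 1 when all group means coincide, and p = 0 otherwise.

### Studentized-range numerics

The Tukey tail P(Q > q) is computed by Gauss–Legendre quadrature of the
classical double integral: the inner integral over the normal ordinate z
of k·φ(z)[Φ(z) − Φ(z − q·s)]^(k−1) on [−8, 8] (72 nodes), the outer over
the scale factor s ~ sqrt(χ²_df/df) on a ±10-SD bracket around 1
(40 nodes). This reproduces scipy's adaptively integrated implementation
to ≤1e-11 over the relevant (k, df, q) range while evaluating thousands
of gene×pair tails per second; scipy's implementation serves as the
independent oracle in the test suite. For k = 2 the exact identity
sf(q) = 2·T_df(−q/√2) is used, which also makes the two-group case
coincide with the equal-variance t-test.

### Descriptive statistics

Per-group coefficients of variation are 100·SD/mean on the analysis scale
(log2 by default; the scale is the caller's choice since a linear-scale
matrix can be supplied). Genes with non-positive means are flagged
invalid rather than silently dropped. The CV filter is strict (< threshold).
Scatter R² is the squared Pearson correlation of two per-gene profiles;
correlation ranking against a target gene sorts by |r| descending with
ties broken by gene ID, excluding the target itself.

## Over-representation analysis

For a test set of n genes in a reference universe of N (all probe IDs),
a category with K members in the universe and k in the test set gets two
one-sided hypergeometric tails: p_over = P(X ≥ k), p_under = P(X ≤ k),
X ~ Hypergeom(N, K, n). Categories are intersected with the universe
before testing; test genes outside the universe are dropped with a
warning. Benjamini–Hochberg control is applied separately per direction
(a category can be depleted in one line and enriched in another, and both
findings are reported).

## The transcriptome distance

### PCA

Genes are variables, samples observations. Each gene is centered across
samples; no unit-variance scaling (the data share a log2 scale, and
scaling would inflate the influence of near-constant genes). The
decomposition runs on the n × n kernel of the centered matrix, so 20k+
genes cost one matrix product; scores are the principal coordinates and
reproduce the samples' pairwise Euclidean distances exactly when all
n − 1 components are kept. Component signs are fixed by making the
largest-magnitude loading positive.

### Horn's parallel analysis

The retained dimension k is the length of the leading run of components
whose eigenvalue exceeds the 95th percentile (optionally the mean) of
eigenvalues of standard-normal matrices of the same shape, decomposed
identically, at the same rank. One adaptation: both spectra are
normalized to explained-variance fractions before comparison. The raw
comparison is scale-dependent — data with per-gene variance far below 1
(log2 replicate noise is ~0.15 SD) would never exceed unit-variance
random eigenvalues no matter how structured — whereas the fraction
comparison is invariant to the overall scale and identical in
distribution to the raw rule when the data are themselves standard
normal. The pipeline accepts a fixed k override.

### The statistic

Pool the two groups' samples (n = n₁ + n₂, each group ≥ 2), compute all
M = n(n−1)/2 pairwise Euclidean distances among retained-PC scores, rank
them ascending with midranks for ties, and set

    D = (r̄_between − r̄_within) / (M / 2)

where r̄ are mean ranks of between-group and within-group pairs. This is
the ANOSIM R statistic (Clarke 1993) applied to PC scores. It provably
satisfies every property the scale promises:

* D ∈ [−1, 1];
* D = 1 **iff** every between-group distance exceeds every within-group
  distance — no overlap of the groups in the hyper-plane;
* the permutation expectation of D is exactly 0, the reference point for
  completely overlapping (exchangeable) groups;
* D < 0 when between-group distances are systematically *smaller* than
  within-group distances, as in child/parent (partially nested)
  configurations;
* D is invariant under translation, rotation and uniform scaling of the
  score space, hence weighting components by explained *fraction* or
  explained *percentage* gives identical values.

One subtlety worth knowing: a perfectly symmetric nested configuration
with equal group sizes gives D ≈ 0, not D < 0 — the tight group's tiny
within-pairs and the wide group's large within-pairs average out.
Negative values arise from asymmetric nesting (e.g. a tight pair inside
a spread-out group), where within-pairs occupy both rank extremes while
between-pairs sit in the middle.

Two score variants feed the statistic: *intact* scores (retained columns
as-is) and *weighted* scores (each retained column multiplied by its
explained-variance fraction, discounting separation on minor axes). Both
are reported, intact above / weighted below the diagonal in the rendered
group-by-group table, starred where p < 0.05.

### Permutation significance

Group labels are permuted with group sizes fixed. When the number of
distinct balanced relabelings — C(n, n₁), halved when n₁ = n₂ because
swapping group names leaves D unchanged — is at most 10 000, the null is
enumerated exhaustively and p = #{D_perm ≥ D_obs}/#relabelings, observed
labeling included. The smallest attainable exact p is therefore
1/#relabelings: **0.1 for two groups of three**, which is why a 3 + 3
comparison can never be significant at 0.05 even at D = 1 — a property,
not a defect, of small-replicate designs, and the reason distances and
their significance are reported separately. Beyond the enumeration
threshold, 999 Monte-Carlo draws with the add-one correction
p = (1 + #{D_perm ≥ D_obs})/(1 + n_perm) are used. The default sidedness
is *greater* (the question is whether groups are separated); a two-sided
option compares |D|. Seeds are always recorded.

### Extreme-group selection

For RIL populations, the two most separated groups are picked by
projecting lines onto the first n_pcs components (3 for expression data,
2 for marker data, following common practice) and taking the lowest- and
highest-scoring `group_size` lines along the first of those components;
ties break by input order, so selection is deterministic.

## Synthetic data

The generators produce every input the pipeline consumes, so all stages
run and are tested without any external download.

**Expression studies** (`StudyConfig`): per-gene true means ~
N(8.0, 2.0²) log2 units (the spread of RMA-summarized intensities);
replicate noise N(0, 0.15²); groups of 3 replicates by default, the
realistic (and limiting) design for array studies; optional per-batch,
per-gene offsets N(0, 0.3²); spiked log2 effects added to a named group's
mean for chosen genes; and a configurable fraction of highly variable
genes whose replicate SD is set to mean × CV/100 with target CV drawn
uniformly from 40–70%. The 40% lower bound (rather than the 20%
flagging threshold itself) is a calibration choice: with n = 3 the
sample CV of a gene at true CV barely above 20% falls below the
threshold almost half the time, whereas from 40% upward the flagged
fraction empirically matches the configured fraction to ±0.01. Every
study returns a truth record (effects, offsets, high-CV genes) so tests
assert recovery against construction.

**Score geometries** (`GeometryConfig`): two groups in a low-dimensional
score space with known distance behaviour — `separated` (unit-spread
Gaussian clusters, centroids `separation` apart), `overlapping`
(identical law) and `nested` (shared centroid, 100× spread ratio).
These exercise the distance semantics directly, without a PCA in between.

**RIL populations** (`RILConfig`): genes partitioned into contiguous
blocks, one biallelic marker per block, independent Bernoulli(0.5) block
genotypes per line (no genetic map — only the group-level transcriptome
contrast matters downstream). A `polymorphic_fraction` of genes differs
between the parents; of the parent-equal genes, a `transgressive_fraction`
(default 0.15) nevertheless carries genotype-linked effects with random
sign, emulating transgressive segregation in expression.

What the generators do *not* emulate: probe-level effects (the pipeline
starts from summarized matrices), correlated gene modules and regulatory
structure, intensity-dependent noise, spatial/dye artifacts, linkage maps.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under idealized independence — not that any
particular real dataset would yield equivalent verdicts.

## Problem sizes

The bundled analyses run at desk scale: 2000 genes, studies of 6–9
samples, a 60-line RIL population with 40 markers, 100 parallel-analysis
iterations, exact permutation enumeration wherever group sizes allow
(always, for the bundled designs) and 999 Monte-Carlo draws otherwise.
The full analysis sequence completes in well under a minute; every stage
scales linearly in genes and the PCA is quadratic-cubic only in samples.

## Known limitations

* The exact algebraic form of the original hyper-plane distance this
  statistic stands in for is not published alongside its applications;
  the rank formulation here is fixed by the printed semantics (range,
  no-overlap maximum, overlap zero-point, negative nesting) and is the
  single most consequential interpretation in the package. Any
  replacement must pass the same semantic invariants, which are encoded
  as tests.
* Mean-shift batch correction cannot separate batch from group when the
  two are confounded (a group present in only one batch contributes its
  group signal to that batch's mean). The assembled designs here place
  every group within a single study-batch, where the correction is
  exact for between-study biases but group contrasts across studies
  remain partially entangled with study effects — the reason cross-study
  distances should be read against the natural baseline envelope rather
  than as absolute measurements.
* With three replicates per group the exact permutation floor (p = 0.1)
  makes significance unattainable; distances remain interpretable as
  effect sizes.
* CV on log2-scale data is smaller than linear-scale CV for the same
  biological variability; the 20% threshold is scale-specific. The
  scale choice is left to the caller (log2 in all bundled analyses).
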