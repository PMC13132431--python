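# Methods

## The model

The package treats genome-wide binding as occupancy of a fixed lattice of
half-open bins. For each of the tracks (here eleven proteins: TRB1–3, the
PEAT components UBP5/EPCR1/PWWP1, the NuA4 components HAM1/EPL1B, the PRC2
components CLF/SWN, and JMJ14), a bin is *bound* if at least one base of at
least one peak overlaps it. Peak significance scores from heterogeneous
upstream pipelines are made comparable by rank-normalizing each track into
deciles: with n bound bins and average ascending rank r(b),
decile(b) = ⌈10·r(b)/n⌉. The average-rank-then-ceiling rule means tied
scores always land in the same decile; with n divisible by 10 and distinct
scores every decile holds exactly n/10 bins. The ceiling is computed in
exact integer arithmetic on doubled midranks, so no floating-point rounding
can shift a boundary case.

Complex assignment is a threshold rule on occupancy only (decile > 0):
complex c with member set M_c and minimum m_c is assigned to a row when at
least m_c members are bound. The default scheme is PEAT = {UBP5, EPCR1,
PWWP1} with m = 2, NuA4 = {HAM1, EPL1B} with m = 2, PRC2 = {CLF, SWN} with
m = 2, JMJ14 = {JMJ14} with m = 1. Decile magnitude deliberately plays no
role in assignment — it encodes relative binding strength for display and
correlation only. The full category universe is the 2⁴ subsets of the four
complexes (15 non-empty labels plus "Unassigned"); a collapsed mode merges
subsets of three or more complexes into "Multi(3+)". No fixed category
count is assumed anywhere.

## The exact intersection test

The central statistic is the exact distribution of the intersection of m
sets drawn independently and uniformly (without replacement) from a
background of N elements. It is built by chaining hypergeometrics:

    X₁ = n₁;   X_k | X_{k−1} = j  ~  Hypergeom(N, j, n_k)

so the pmf of X_m is the m-fold chain. Fold enrichment compares the
observed intersection to its null expectation N·∏(n_j/N). For m = 2 the
chain collapses to the ordinary hypergeometric and the enrichment p-value
P(X ≥ obs) equals the one-sided Fisher test. Both tails are always
reported; they satisfy p_enrich + p_deplete = 1 + P(X = obs).

Numerics: all hypergeometric terms are evaluated in log space through
log-gamma, so backgrounds up to ~10⁶ rows are safe. The exponentiated pmf
is renormalized by its compensated (fsum) total — the dominant
floating-point residual is a constant factor shared by all entries — and
tail probabilities are accumulated on the smaller side of the observed
value, which keeps absolute tail error near 10⁻¹³ even at N = 10⁴. The
transition step only iterates over the reachable support, so pairwise tests
cost O(min(n₁, n₂)).

Grid tests (category × TRB combination, cluster × category) run one
pairwise exact test per label pair against the shared background and apply
Benjamini–Hochberg within the grid: one figure-style panel is one
multiplicity family. Cells are tagged enriched or depleted by fold ≷ 1 and
the directional p-value feeds the adjustment. Significance tiers are
configurable (defaults 10⁻⁴/10⁻³/10⁻² for binding grids,
5·10⁻⁴/5·10⁻³/0.05 for cluster grids, following the conventions of the
figures this analysis style comes from).

The 2×2 association test (differential expression × target status) uses
Fisher's exact test with the conditional maximum-likelihood odds ratio by
default; the cross-product (sample) estimator is available. A zero margin
leaves the OR undefined and p = 1.

Calibration note: as with any discrete exact test the inclusive p-value
P(X ≥ obs) is conservative — P(p ≤ α) ≤ α, with steps up to one pmf mass.
The test suite therefore checks calibration on the standard randomized
p-value P(X > obs) + U·P(X = obs), which is exactly uniform under the
null, and separately checks that the reported inclusive p-value is never
anti-conservative.

## Correlation

Track–track similarity is the Pearson correlation of decile columns over
all retained bins (zeros included — unbound is informative here), with
p-values from the t-transform on n−2 degrees of freedom. Restricting to
bound-only rows is a caller choice by subsetting the matrix first.
Zero-variance columns yield undefined correlations with a warning rather
than an error, since an empty track is a data problem, not a programming
error.

## Peak→gene annotation

A peak annotates to every gene whose body it overlaps by ≥ 1 bp — broad
chromatin-complex peaks frequently span several genes and all of them are
counted — and to every gene whose TSS (start on +, end−1 on −) lies within
a window of the peak interval (default ±2000 bp, distance 0 if the TSS is
inside the peak). With the window at 0 the rule reduces to pure body
overlap. Gene-level occupancy is binary (≥ 1 annotated peak per track) and
feeds the same complex rules as bins. Term over-representation is
ontology-agnostic: any gene→term map, one-sided hypergeometric per term,
BH across the term family. No DAG propagation or term-similarity reduction
is performed; the background is always an explicit parameter because the
appropriate universe (all annotated genes vs all expressed genes) is an
analysis decision, not a package default.

## Expression clustering

Counts are library-size scaled to the mean depth, transformed with
log2(x+1) as a variance-stabilizing stand-in, and centered per gene. An
externally produced normalized matrix (e.g. from a dedicated
differential-expression framework) can be supplied instead; differential
calling itself is out of scope and DEG lists are inputs.

Clustering is PAM (k-medoids) with Euclidean distance on the centered
profiles: deterministic BUILD initialization (start from the most central
point, then greedily add the point with the largest cost reduction)
followed by steepest-descent SWAP until no exchange improves the objective.
The objective never increases across sweeps and the result is deterministic
for a fixed input order. `PAM` is a scikit-learn-compatible estimator
(`fit`/`fit_predict`, `labels_`, `medoid_indices_`, `inertia_`,
`silhouette_`) and composes with sklearn model-selection tooling;
`pam_cluster` is the thin functional wrapper. With k="auto" the k in
[2, 10] maximizing mean silhouette is selected, ties to the smaller k.

## Blacklist filter

Coverage outlier windows (conventionally 200 bp) are flagged two-sided:
log10(count+1) outside median ± k·MAD with k = 5. The MAD uses the normal
consistency factor (1.4826); with the raw MAD, k = 5 would clip legitimate
Poisson-level scatter at typical window depths (~50 reads). An ε floor on
the MAD makes the all-equal case yield an empty blacklist. The stage is off
by default since published peak sets are normally pre-filtered.

## Synthetic studies

The generator emulates the statistical skeleton of a multi-track
co-occupancy study. Per complex, target bins are planted (a small
configurable fraction shared between complexes so multi-complex categories
exist); each member track binds targets with probability q_on = 0.9 and
background bins with q_off = 0.01; each TRB paralog binds complex-c targets
with preference π[trb, c] and elsewhere at π₀ = 0.01. Default preferences
mirror the biology the package was built around: TRB1 highest at PEAT/NuA4,
TRB2 at JMJ14, TRB3 at PRC2. Peak coordinates are jittered within the bin
with widths of 0.3–1.2 bin widths, so peaks can span bin boundaries; the
emitted Truth therefore records the bins each planted peak actually covers,
computed by direct floor arithmetic at generation time — an independent
path from the pipeline's own assignment machinery, which is what makes the
noiseless-recovery test (q_on = 1, q_off = 0, π₀ = 0 reproduces every
category and TRB combination exactly) a genuine end-to-end check. Scores
are Gamma(shape 2) with a 3× scale at planted sites, giving non-degenerate
deciles.

Expression: 7 genotypes (wild type, three single, three double mutants) × 3
replicates; 500 of 2000 genes are differential, split over five planted
archetype response vectors with entries of ±2 log2 units (a sign-flip
cluster, a trb1-up cluster, two doubles-down clusters, a doubles-only-up
cluster). The archetypes differ pairwise in at least two genotypes — with
entries restricted to {−2, 0, +2}, two patterns differing in a single
genotype are structurally merged by silhouette-based k selection no matter
how small the noise, so pairwise separability is part of the planted
design. Counts are negative binomial with dispersion 0.05 and per-gene
lognormal baselines around a mean of 100.

Default problem sizes are chosen so the full pipeline runs in seconds on
one core: 2 chromosomes × 1 Mb, 300-bp bins (6668 bins), 2000 genes, 500
DEGs, 200 terms. One caveat of the compact toy genome: genes sit a few
hundred bp apart, so a ±2000-bp TSS window annotates most genes to some
peak and gene-level bound fractions run far higher than in a real genome —
synthetic gene-level percentages are internally consistent but not
comparable to real-genome values. The generator also does not emulate peak
shape, read-level noise, chromatin domains, or correlated track artifacts;
passing recovery tests demonstrates the pipeline's correctness on the
planted model, not robustness to those real-data phenomena.

A statistical subtlety of the planted model worth knowing: when only one
paralog's preference is elevated at a complex and all other binding is
uniform, the expected fold enrichment is identical for *every* TRB
combination containing the preferred paralog (the uniform factors cancel
between category and background). Ordering assertions on planted
preferences are therefore made on the enrichment p-value — where the
singleton's much larger counts dominate — and on fold against combinations
lacking the preferred paralog.

## Parameters at a glance

| parameter | default | unit | rationale |
|---|---|---|---|
| bin_size | 300 | bp | standard tiling for these data; 500 bp equally supported |
| tss_window | 2000 | bp | conventional promoter window for peak→gene annotation |
| min members | 2 (1 for JMJ14) | tracks | complex called only on corroborated occupancy |
| blacklist k | 5 | MADs | conservative two-sided outlier cut |
| k (clusters) | 5, or auto over 2–10 | — | auto = max mean silhouette |
| q_on / q_off | 0.9 / 0.01 | prob | strong but imperfect planted occupancy |
| π₀ | 0.01 | prob | sparse background TRB binding |
| NB dispersion | 0.05 | — | typical bulk RNA-seq gene-wise dispersion |
| grid tiers | 1e-4/1e-3/1e-2 | q | significance stars for binding grids |

## Limitations

- The null model is uniform element sampling; spatially aware nulls
  (segment-preserving shuffles, GC/mappability matching) are out of scope,
  so enrichment against genomically clustered features will be liberal.
- The log2 stand-in transform is not a mean–variance-fitted VST; at very
  low counts residual variance trends remain (inject an external matrix if
  that matters).
- PAM is O(n²) in memory and time per sweep; it is intended for DEG-scale
  inputs (hundreds to a few thousand profiles), not whole-transcriptome
  clustering.
- Gene-level occupancy is binary; peak strength is not propagated to genes.
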