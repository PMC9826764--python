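# Methods

This note records the statistical models, defaults and design choices
behind `fibsig`, in enough detail to judge what a passing test suite does
and does not demonstrate.

## Differential expression: empirical-Bayes moderated t

Each cohort is a two-group (case/control) comparison on log-scale
intensities with no covariates. Per gene, the pooled variance s²_g has
d_g = n₁ + n₂ − 2 residual df. The hierarchical model places a scaled
inverse-χ²(d₀, s₀²) prior on the true variances; the hyperparameters are
fitted by moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2), whose
theoretical variance exceeds the sampling term ψ′(d_g/2) by ψ′(d₀/2).
ψ′ is inverted by bisection on d₀/2 ∈ (0.005, 5·10⁵] to tolerance 1e-8;
when the empirical spread does not exceed the sampling spread the prior is
degenerate (d₀ = ∞) and the statistic reduces to its normal limit. The
posterior variance s̃² interpolates s² and s₀², and t = Δ̄/√(s̃²(1/n₁+1/n₂))
is referred to t(d₀ + d_g). d₀ → 0 recovers the ordinary pooled t-test
exactly; the test suite verifies both limits, type-I calibration
(fraction p < 0.05 within [0.04, 0.06] at 10⁴ null genes), recovery of
planted (d₀, s₀²), and numerical agreement (atol 1e-6) with the reference
R implementation of the same estimator.

Raw p < 0.05 is the default significance rule (no multiplicity
adjustment), matching common practice for per-cohort gene-list extraction
before cross-cohort voting; Benjamini–Hochberg adjustment is available.
Duplicate gene rows (multi-probe symbols) are collapsed to the row with
the largest mean intensity before analysis.

## k-of-n pools and the exact intersection statistic

A gene enters a disease pool when significant in at least k of that
pool's n cohorts (k=7 of 9 for CD; k=4 of 5 for the other fibrotic
disorders). This membership filter is provably the union of full
intersections over all C(n,k)+…+C(n,n) cohort subsets (46 and 6
respectively); the equivalence is asserted against brute-force subset
enumeration. The signature is the intersection of the two pools.

The null distribution of an m-set intersection, for independent uniform
draws of fixed-size subsets from a background of N genes, is computed by
sequential hypergeometric conditioning: D₁ is a point mass at n₁ and
D_{j+1}(i′) = Σᵢ D_j(i)·P(Hypergeom(N, i, n_{j+1}) = i′). PMF values are
evaluated in log space and the distribution is checked to sum to 1 within
1e-9. For m = 2 this reduces to the hypergeometric upper tail (verified to
1e-12); for m = 3 it is verified against a 10⁵-draw Monte-Carlo oracle.
The background N defaults to the union of all genes measured across the
supplied cohorts — a published universe size is rarely available, and this
choice is reproducible and conservative; it is overridable.

## Count normalization and PCA

Median-of-ratios size factors: s_j = median over reference genes of
count_gj / geomean_g, with the reference restricted to genes whose counts
are positive in every sample (zero geometric means are excluded, the
standard convention). Counts are transformed as log₂(count/s_j + 1). PCA
is a gene-centered SVD over samples; variance fractions are σᵢ²/Σσ², and
components are sign-fixed so the first nonzero gene loading is positive.
A constant matrix yields zero variance fractions with a warning. PCA runs
on all genes by default; restriction to a gene set is available for
signature-restricted analyses.

## Co-expression modules

Gene–gene Pearson correlations (Spearman optional) are raised to a soft
power β into an unsigned adjacency |r|^β (signed variant available). β is
the smallest grid value whose scale-free fit index reaches 0.8, where the
index is the signed R² of log₁₀ frequency vs log₁₀ mean degree over ≥5
occupied equal-width degree bins (a positive slope counts against the
fit). Two guards matter in practice and are deliberate design choices:

* a candidate power must keep mean connectivity ≥ 2 — at high powers all
  adjacencies collapse toward zero and the fit index becomes an artifact
  of vanishing connectivity, creeping above target near the top of the
  grid;
* when no power qualifies (typical for signature-sized matrices of a few
  hundred genes, which are simply not scale-free), selection falls back to
  the conventional unsigned-network default β = 6 rather than an argmax,
  which would otherwise select the degenerate top of the grid.

The topological overlap TOM_ij = (l_ij + a_ij)/(min(kᵢ,kⱼ) + 1 − a_ij)
with l_ij = Σ_{u∉{i,j}} a_iu a_uj is clustered by average linkage on
1 − TOM with a static cut at height 0.9; clusters under 20 genes are
unassigned, survivors are relabelled M1, M2, … by size. The cut height
follows from an exact identity: for a uniform module of within-adjacency
a, TOM = a, so a static cut at h retains modules with a > 1 − h. At the
default β = 6, h = 0.9 admits modules with within-correlation ≥ 0.68 —
covering realistically strong co-expression — while uncorrelated genes
(TOM ≲ 0.01) remain far below the cut. A dynamic tree cut is out of
scope. Module eigengenes are the first right-singular vector of the
gene-standardized module submatrix, oriented to correlate positively with
mean module expression.

### Module-vs-stratum enrichment

For each tissue × condition stratum, genes are ranked by
(mean within stratum − overall mean)/overall sd (descending, ties broken
by symbol). A module is tested against this ranking with a weighted
Kolmogorov–Smirnov enrichment score (weight exponent 1 on |score|); the
null is gene-label permutation (matching preranked-GSEA semantics on a
class-derived ranking — sample permutation would break the paired
design), with NES = ES / mean(|ES_perm| of matching sign) and a
+1-smoothed tail p-value. Positive NES ⟺ module over-expressed in the
stratum.

## PPI hubs

The interaction network is read from STRING-dialect edge tables
(score ∈ [0,1000]; default confidence cutoff 400, "medium"; duplicate and
reversed pairs merged keeping the maximum score; self-loops dropped). The
module-induced subnetwork keeps isolated members as degree-0 nodes. Hubs
default to degree > mean + 1 sd of the module-node degrees — the rule is
deterministic and recovers planted hubs on scale-free graphs with high
recall; `top_k` (including all boundary ties, so k may be exceeded) and a
fixed degree threshold are available. The published 21-hub list is
packaged as a fixture and checked for containment in the module fixture;
reproducing it from a live interaction database is not attempted, since
the result depends on the database version and confidence cutoff, neither
of which is recoverable.

## Over-representation analysis

Hypergeometric upper-tail test per term, with the background defaulting
to the union of collection members and the query; term sizes outside
[10, 500] are skipped (recorded in the output). Benjamini–Hochberg q-values
use the step-up rule with monotonicity enforcement. Pathway databases
(Reactome/GO/KEGG) are user-supplied GMT inputs, not bundled.

## Synthetic data: what it emulates and what it does not

`simulate_cohorts` produces 9 CD-like and 5 other-disease log-intensity
cohorts (5000 genes, 10 vs 10 samples) with a 240-gene planted core
carried in any given cohort with probability 0.95, plus 200 CD-only and
600 other-only genes; carried effects shift cases by 2.0 on a noise sd of
0.7. The carriage probability below 1 is the point of the k-of-n design —
no cohort sees the full signature. These three values were fixed by a
design-time power calculation: detection power for a carried effect is
≈1 at n = 10 per group, so a core gene passes both votes with probability
P(Bin(9,.95) ≥ 7)·P(Bin(5,.95) ≥ 4) ≈ 0.97, giving headroom over the 0.9
recall the end-to-end tests demand, while weaker settings (e.g. unit
effect on unit noise, carriage 0.85) cap recall near 0.7 regardless of
implementation quality.

`simulate_paired_counts` emulates the validation cohort: 7 CD, 6 UC and
9 control patients, two samples each (ileal/sigmoid), negative-binomial
counts (dispersion 0.05, base mean 200, per-sample depth factors in
[0.5, 2]) over 241 signature genes plus 1800 unmodulated background genes
— the background keeps the planted module a small fraction of the library
so that median-of-ratios normalization is not distorted by composition, as
in real data. The 112-gene module shares a latent factor with mean 1 in
CD ileum and 0 elsewhere (loading 1.5 on the log mean), with a patient
random effect (sd 0.1) shared across a patient's two tissues and
per-sample jitter (sd 0.1). The noise sds are kept small relative to the
planted stratum's pull on the overall mean (7/44 ≈ 0.16) so that the NES
sign pattern — positive in CD ileum, negative in control strata — is a
property of the design rather than of a lucky seed.

`simulate_scale_free_network` grows a preferential-attachment graph whose
initial clique is the planted hub set, with STRING-like scores in
[400, 999].

What passing these tests does **not** show: the generators have Gaussian
cohort noise without batch or platform effects, no probe-level structure,
no global tissue effect outside the planted module (so the synthetic PC1
share is below the ~45% a real paired-biopsy cohort shows), and
independent background genes; real data violate all of these. Recovery
metrics here measure correctness of the machinery, not expected
performance on GEO cohorts.

## Determinism and problem sizes

All generators are pure functions of (spec, seed); pipeline stages derive
their seeds from a global seed by stable hashing, and two runs with equal
seeds produce byte-identical outputs (asserted). Every pipeline output
file carries a header comment with a config hash and the seed. The default
test-suite problem sizes — 10⁴-gene null calibrations, 10⁵-draw
Monte-Carlo checks, 100-replicate module recovery, 5000-gene end-to-end
runs — were chosen so the whole suite completes in well under a minute of
compute while keeping Monte-Carlo standard errors small relative to every
asserted tolerance.
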