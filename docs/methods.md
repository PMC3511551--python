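# Methods

This note documents the statistical content of `coexnet`: the eight
association measures and their null distributions, the coordination-network
and Triple-Link procedures, the evaluation arithmetic, the synthetic-data
model, and the numerical and design choices made where more than one
reasonable option existed.

## Association measures

All eight measures share one contract: two equal-length vectors of finite
expression values (log2 scale), an `AssociationResult` out, degenerate
inputs (constant vectors, all-tied ranks) raising a typed error rather than
returning NaN.  Two-sided tests are used throughout.  Symmetric measures
(Pearson, Spearman, Kendall, weighted rank, Hoeffding, dCov) satisfy
f(x,y) = f(y,x) exactly; Theil-Sen is a regression and is deliberately
asymmetric.

**Pearson / Spearman.**  r is computed from centered sums; ρ is r applied to
average ranks (ties get the mean of their positions, so the rank sum is
always n(n+1)/2).  Both p-values use t = r·√((n−2)/(1−r²)) with n−2 degrees
of freedom; for untied data ρ also equals the classical 1 − 6Σd²/(n(n²−1))
shortcut, which the tests assert.

**Kendall.**  τ is computed from sign products over all pairs; with ties the
τ-b normalization (C−D)/√((n₀−T_x)(n₀−T_y)) is used.  The p-value uses the
normal approximation on S = C−D with the tie-corrected null variance
(v₀−v_t−v_u)/18 + v₁ + v₂; without ties this reduces exactly to the
textbook Var(τ) = 2(2n+5)/(9n(n−1)), which the tests verify, and the null
calibration study confirms the empirical Var(τ) matches within 5% at n=50.

**Weighted rank.**  r_W = 1 − 6Σd_i²(2n+2−R_i−S_i)/(n⁴+n³−n²−n) weights
disagreements by rank position — a discordance among rank-1 items costs more
than the same discordance among rank-n items.  Exhaustive enumeration at
n = 4, 5, 6 confirms E[r_W] = 0 exactly under the permutation null and range
[−1, 1].  Rather than relying on a published asymptotic variance, the exact
permutation-null variance is computed at runtime in O(n²) from the first two
joint moments of sampling without replacement (enumeration-validated to
machine precision); the p-value is the normal tail at r_W/√Var.  With ties,
midranks enter the statistic and the untied variance is used — a documented
approximation.

**Hoeffding's D.**  With univariate ranks R_i, S_i and bivariate ranks
Q_i = 1 + #{j : x_j < x_i and y_j < y_i} (ties counted ½ for one
coordinate tied, ¼ for both),

    D1 = Σ(Q_i−1)(Q_i−2),  D2 = Σ(R_i−1)(R_i−2)(S_i−1)(S_i−2),
    D3 = Σ(R_i−2)(S_i−2)(Q_i−1),
    D  = 30·[(n−2)(n−3)D1 + D2 − 2(n−2)D3] / [n(n−1)(n−2)(n−3)(n−4)].

On this scale D = 1 for perfectly monotone data in either direction (D
measures dependence, not its sign) and untied D ∈ [−0.5, 1].  Enumeration at
n = 5, 6, 7 shows the permutation-null mean is exactly 0 and the variance is
exactly v_n = 2(n²+5n−32)/(9n(n−1)(n−3)(n−4)).  The default independence
test is the one-sided Cantelli bound p = v_n/(v_n + D²) for D > 0 (p = 1
otherwise): a rigorous upper bound given the exact null mean and variance
(enumeration confirms it dominates the exact permutation tail; a Markov-type
bound v_n/D does not and was rejected).  The bound compresses p-values into
a narrow range — with ~200 samples its floor is around 10⁻⁵ — so a
permutation p-value is available via `p_method="permutation"` for
calibration-sensitive comparisons.

**Distance covariance.**  dCov² is the mean elementwise product of the two
double-centered Euclidean distance matrices (the V-statistic form, hence
≥ 0, clipped at 0 against float cancellation).  The independence test
permutes one margin; permutations are batched via argsort of uniform draws
and the p-value uses the (count+1)/(n_perm+1) correction so p > 0 always.
An explicit seed is required and n_perm ≥ 99 enforced (coarser resolution is
a configuration error).  Within `associate_all` the per-pair seed is derived
by hashing the master seed with the sorted gene-id pair, so p-values cannot
depend on evaluation order or parallel scheduling.

**Theil-Sen and rank Theil-Sen.**  The slope is the median of all pairwise
slopes (pairs with equal x excluded — they carry no slope information); the
intercept is median(y_i − β̂x_i).  The estimator tolerates arbitrary
corruption of up to 1 − 1/√2 ≈ 29.3% of points: contaminating m of n points
corrupts all pairs touching them, and the median slope survives while intact
pairs C(n−m, 2) exceed half of C(n, 2); `theil_sen_breakdown` solves this
condition both finitely and asymptotically.  No exact small-sample null
distribution of the median slope is tractable, so the p-value follows the
reference-implementation convention: a one-sample Wilcoxon signed-rank test
that the slope multiset has median zero.  The slope multiset is internally
dependent, so this p is approximate and best used, as here, for ordering
gene lists.  Rank Theil-Sen is exactly Theil-Sen of the rank-transformed
data, making it monotone-invariant with slope 1 on any increasing untied
relationship.

## Ranking, coordination network, Triple-Link

`associate_all` pairs a query against every other gene, skipping and logging
degenerate partners, and sorts by (p ascending, |statistic| descending,
partner id ascending) — a total order, so two runs with the same inputs are
byte-identical.  `top_n` takes the list head.  The coordination matrix
stores |top₁₀₀(A) ∩ top₁₀₀(B)| when strictly greater than k_min = 30 and 0
otherwise ("more than k" is read strictly; ties at exactly k stay
disconnected).  The diagonal is fixed at 0 because a query never appears in
its own list.  Defaults n = 100, k = 30 are the standard operating point;
both are configurable.

Triple-Link's significance threshold is the mean plus one sample SD
(multiplier configurable) of the nonzero upper-triangle entries, computed
once on the full matrix, not per round — the criterion is matrix-level, and
genome-scale matrices are overwhelmingly zero, so zeros are excluded from
the statistics (including them would collapse the threshold toward zero and
make nearly every stored overlap "significant").  Decomposition repeats:
seed with the heaviest remaining edge (lexicographic tie-break); a third
member must have significant links to both seeds; members four onward need
at least three significant links into the cluster; growth ties resolve by
most significant links, then largest summed overlap, then id.  Emitted
clusters leave the matrix; pairs attracting no third member are emitted as
size-2 clusters; TFs never joined are singletons.  Cluster seed overlaps are
therefore non-increasing in extraction order — tighter coordination surfaces
earlier.

## Evaluation arithmetic

S/D/N labels: S if the two genes share at least one pathway id (genes are
multiply assigned, so "same pathway" means nonempty intersection), N if
either gene is unassigned, D otherwise.  Pairs reached from two different
query lists are deduplicated by sorted gene-id key (keeping the smallest p)
before tallies.  Top-100/500 counts always sum to the cutoff.  Slice
confusion compares the top window against one of three slices — the next
pairs, a slice centered on the list midpoint (start = ⌊(L−size)/2⌋,
0-based), or the last pairs.  For a top-100 window the slices hold 900 pairs
and slice counts are divided by 9 to put both windows on the same footing;
for a top-500 window the slices hold 500 pairs and are used directly.
Ratios with zero denominators are reported as missing, never as 0.
p-threshold fractions use strict p < t and the (0, 0) convention for an
empty retained set.

Normality uses Shapiro-Wilk (delegated to scipy; contract: W ∈ (0,1],
5 ≤ n ≤ 5000) with p < 0.01 read as non-normal.  The pair classification
puts (r, ρ) into group I (ρ−r > 0.1), II (|r−ρ| ≤ 0.1), or III (r−ρ > 0.1),
subdivided into 10 sign-pattern categories; boundary equality goes to
group II and r = 0 or ρ = 0 to the non-negative branch, making the
classification exhaustive and mutually exclusive.

## Synthetic data

`simulate_expression` plants pathway blocks: each block shares a latent
standard-normal factor across samples, passed through per-gene strictly
monotone links (linear, or exp/cubic/sinh for the nonlinear regimes; random
sign models co- and anti-regulation) plus N(0, noise_sd²) noise.  A
latent-factor-through-link construction rather than a multivariate-normal
draw is deliberate: monotone-nonlinear dependence is the regime that
separates rank methods from Pearson, and a Gaussian copula cannot produce
it.  Outliers replace entries with mean ± 6 SD spikes at `outlier_rate`;
marginals can be made lognormal to drive Shapiro-Wilk rejection.  All values
are affinely mapped into [3, 14], the usual span of RMA-normalized log2
intensities; the map is global and increasing, so it alters no pairwise
association.

`simulate_tf_coordination` plants `n_tf_groups` groups: group g's TFs load
on factor g plus λ·(global factor) with λ ~ U(0.5, 0.9), its
`targets_per_group` program genes on factor g alone, and a pool of
`n_common` genes on the global factor.  The commons matter: each TF's
top-100 tail (the ~53 slots left after its program and co-TFs) is drawn from
the same pool of 60 commons, so any two tails overlap by at least
2·53 − 60 = 46 by set size alone, independent of noise.  This yields the
weak promiscuous background of moderate overlaps that real TF coordination
networks exhibit — and that the mean-plus-SD threshold rule presupposes.
Without such a background the threshold is structurally unreachable by part
of every group (min ≤ mean < mean+SD over within-group entries alone) and
greedy growth stalls at pairs; with it, within-group overlaps (~85–100) sit
well above the threshold (~70–80) and cross-group overlaps (~45–55) well
below, and the planted partition is recovered with ARI 1.0 at zero noise.
"Moderate noise" in the recovery checks means noise_sd = 0.3 against
unit-variance latent signals.

Default sizes (n_genes = 1000, n_samples = 60, 5 groups × 8 TFs, 40 targets
per group, 60 commons) keep a full 40-query pipeline run under ~15 s while
leaving the overlap margins wide; the calibration studies use n = 50 with
5000 replicates (type-I error, Var(τ)) and n = 30 with 999 permutations and
1000 replicates (dCov uniformity), sizes at which the Monte-Carlo error is
small against the tested tolerances.

What passing these tests does *not* show: the generator draws samples
i.i.d., so it does not emulate inter-array batch effects, probe-level
artifacts, sample correlation structure (time series), or the heterogeneous
block sizes and overlapping pathway membership of curated databases.
Results on real compendia will differ in degree — in particular, real
coordination networks are sparser and their overlap distributions more
skewed than the planted ones.

## Numerical choices and limitations

- Correlations are clipped into [−1, 1] against rounding; |r| = 1 maps to
  p = 0 in the t reference.
- dCov² is clipped at 0; permutation comparisons use a 1e−15 slack so
  ties with the observed statistic count as extreme (conservative).
- The weighted-rank and Hoeffding null variances are exact only for untied
  data; with ties the statistics use midranks and the untied variances, a
  slight miscalibration in heavily tied data.
- The Hoeffding bound p is conservative by construction; rankings by it are
  monotone in D for fixed n, which is what list-cutting consumes.
- Theil-Sen on large vectors is O(n²) in memory and time per pair; the
  genome-wide drivers stream per query and never materialize an all-vs-all
  matrix.
- Triple-Link recomputing the threshold per round was considered and
  rejected: the single matrix-level criterion keeps extraction order
  meaningful and is the documented behavior; the multiplier (default 1) is
  exposed for stricter regimes.
- Gene ids are matched exactly after whitespace trimming, case preserved —
  probe-set ids and locus ids differ by case conventions and silent folding
  risks false joins.
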