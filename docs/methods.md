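# Methods

This note documents the statistical procedures implemented in
`pseudotempo`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Pseudo-bulk construction

Counts are summed over all cells sharing a (sample, cluster) combination;
the profile's pseudotime is the arithmetic mean of its member cells'
pseudotimes (the median is available via `pseudotime_stat="median"`; for
unimodal within-cluster pseudotime distributions the two differ little).
Cells with non-finite pseudotime — cells unreachable from the trajectory
root — are refused rather than silently dropped: the caller must decide
how to handle them. Profiles built from 30 or fewer cells are removed
(strictly greater-than comparison), because the mean pseudotime and the
summed counts of very small pools are unstable.

Aggregation uses the raw (pre-gene-filter) counts; expression filtering
happens afterwards at the pseudo-bulk level, so the library sizes entering
normalization reflect all aggregated reads of the retained genes.

## Filtering and normalization

Gene filtering follows the standard design-aware rule: keep genes whose
CPM exceeds `min_count / median(lib_size) * 1e6` in at least *k* samples,
*k* the size of the smallest blocking group (damped by
`large_n`/`min_prop` for very large groups), and whose total count is at
least `min_total`. Library sizes are recomputed on the retained genes.

TMM normalization: the reference sample is the one whose 75th-percentile
count fraction is closest to the mean of those fractions. For each sample,
gene-wise log2 count-fraction ratios (M) and average abundances (A)
against the reference are doubly trimmed (30% per tail on M, 5% per tail
on A) and averaged with inverse asymptotic binomial-variance weights;
factors are rescaled to geometric mean 1. Note that exact invariance to
uniform depth scaling of one library holds only for the unweighted trimmed
mean (`weighted=False`); the precision weights depend on absolute counts,
so the default weighted factor moves by O(1%) under depth scaling. All
tied ranks use the average-rank convention.

log-CPM uses a prior count scaled proportionally to each sample's
effective library size (mean-prior convention), so depth invariance is
exact only as counts dominate the prior. MDS coordinates come from
classical (Torgerson) scaling of leading-log-fold-change distances: the
root-mean-square of the `top` (default 500) largest absolute log-CPM
differences per sample pair.

## Spline design and QR re-parametrization

The natural cubic spline basis with `df` columns places `df−1` internal
knots at equally spaced quantiles of the observed pseudotimes
(linear-interpolation quantile definition — the Z2/Z3 values depend on
this choice) and boundary knots at the min/max. Construction: cubic
B-spline basis on the augmented knot vector, intercept column dropped
*before* projecting onto the null space of the two second-derivative
boundary constraints (the order matters for the exact basis values;
verified to machine precision against the standard reference
construction). Evaluation beyond the boundary knots extrapolates linearly.

`A = [1, t, X]` always has rank `df+1`, not `df+2`, because the natural
spline space plus intercept contains all linear functions. The columns are
orthonormalized in order by modified Gram–Schmidt (two passes), which
equals QR with a positive R diagonal — a convention that removes
implementation-dependent sign flips and makes
`Z1 = (t − t̄)/‖t − t̄‖` exactly, independent of every spline detail.
The dependent trailing direction is dropped; an error is raised only when
fewer than `df+1` independent directions exist.

Sample blocking uses treatment contrasts with the earliest developmental
stage as the reference (absorbed into the intercept). A second, raw-basis
design `[1, X, dummies]` is retained for curve prediction: it spans the
same column space but its coefficients apply directly to `X(new_t)`.

## Dispersion estimation

All dispersion estimation maximizes the Cox–Reid adjusted profile
likelihood APL(φ) = ℓ(φ; y, μ̂(φ)) − ½ log det(XᵀWX), W = diag(μ/(1+φμ)),
by bounded scalar optimization on log φ ∈ [log 1e-6, log 10]
(tolerance 1e-6). The GLM profile fits use vectorized IRLS across genes
(tolerance 1e-8, max 50 iterations, step-halving on deviance increase).

* **Common**: maximizes the APL summed over all expressed genes.
* **Trended**: genes are binned by average abundance (about one bin per
  150 genes, at most 20); the summed APL is maximized per bin and the bin
  maxima at their median abundances are interpolated by a monotone (PCHIP)
  cubic in log φ, clamped flat outside the fitted range. The smoother is
  deliberately simple; any smooth abundance trend is acceptable here and
  only the trend enters the QL fit.
* **Tagwise** (BCV diagnostic only): each gene maximizes its APL plus
  `prior_df / df_residual` times a locally shared APL (moving average over
  abundance-sorted neighbours, 5% window) on a log2 grid of multipliers of
  the trend, refined by quadratic interpolation. `prior_df` defaults
  to 20.

## Quasi-likelihood fit, calibration corrections, and the F-test

The QL fit fixes φ at the trend and estimates a per-gene quasi-dispersion
s² from the residual deviance. Three finite-count corrections keep the
test calibrated; each was added after a concrete miscalibration was traced
to its absence:

1. **Expected-unit-deviance correction.** NB residual deviances are not
   chi-square at finite counts: E[d] per observation exceeds 1 and tends
   to `2k(log k − ψ(k))`, `k = 1/φ`, in the large-mean limit. Each gene's
   deviance is divided by the mean expected unit deviance under its fitted
   model, computed exactly by summation on a (μ, φ) log-log grid and
   interpolated. Without this the QL denominator is inflated by ~5–7% and
   the F-test conservative.
2. **Effective residual df.** The calibrated dispersions are slightly
   under-dispersed relative to χ²(df)/df. When the observed spread of
   log s² falls below trigamma(df/2) (prior df → ∞), the bias correction
   applied to the prior trend is recomputed at the moment-matched
   effective df instead of the nominal one.
3. **Winsorization consistency.** The robust squeeze winsorizes the
   residual log-dispersions at the (0.05, 0.95) quantiles before moment
   matching; the winsorized variance is rescaled by the clamped-normal
   second moment so that, absent outliers, the prior df is not
   overestimated (over-shrinkage of genuinely variable genes inflates the
   far tail and hence the empirical FDR). Genes beyond the upper
   winsorization limit additionally receive an exponentially reduced
   gene-specific prior df, protecting outliers from over-moderation.

The squeeze itself is scaled-F moment matching on log dispersions: the
prior df solves `trigamma(d0/2) = var(e) − trigamma(df/2)` with
`e = log s² − ψ(df/2) + log(df/2)`, and the abundance trend of the prior
value is a lowess fit (span 0.4) of `e` on average log-CPM. The posterior
is the df-weighted average of raw and prior values, which always lies
between them. Residual df is `n − p`, reduced by the number of samples
whose fitted mean is effectively zero.

The quasi-F statistic for dropping `r` coefficients is
`F = (Δdeviance / r) / s²_posterior`, referred to F(r, df_residual +
df_prior); infinite prior df is capped at 1e8 (numerically the chi-square
limit). Tested coefficients are reported in log2 units (`logFC.Z*`), with
BH-adjusted FDR and a deterministic ordering in `top_table` (ascending
p, then descending F, then gene name — the reference ordering of tied
p-values is undefined, so ties are broken reproducibly).

On null NB simulations (22 samples, 2000 genes, φ ∈ {0.05, 0.2, 0.5})
the empirical type-I error sits within one binomial standard deviation of
nominal at α ∈ {0.01, 0.05}; these checks run in the acceptance suite.

## Trend summaries

Direction is the sign of the Z1 coefficient (zero counted as Down, the
boundary convention of the sign test on a continuous statistic being
immaterial). Fitted curves evaluate the raw-basis fit on 100 evenly spaced
grid points across the observed pseudotime range; the group effects are
averaged **including an implicit zero for the reference group**, and the
linear predictor is converted to log2 CPM as `(η + ln 1e6)/ln 2` — a
population-level CPM convention that deliberately omits the library-size
offset, so curves are comparable across genes but not anchored to any one
library's depth. Heatmap rows are standardized with denominator n−1;
constant rows are rejected. Gene-set average trends are unweighted means
over set members present in the matrix, smoothed by lowess (span 2/3).

## Directional enrichment

Over-representation uses the one-sided hypergeometric upper tail for each
direction separately, with the universe equal to all genes surviving
expression filtering (and identifier mapping, when identifiers are
filtered upstream); sets are intersected with the universe first. Raw
p-values are reported by default, matching the classical GO tools; BH
columns are available behind `adjust=True`. GO/KEGG retrieval is out of
scope — collections arrive as GMT files.

## Synthetic data generator

`simulate_cells` emulates the structure of a five-stage, five-cluster
single-trajectory experiment: cluster-specific overlapping pseudotime
windows on [0, 40], per-gene baseline abundances (log-normal), NB counts
via the gamma–Poisson mixture with per-gene dispersions (0.8 × lognormal,
σ = 0.4 — single-cell-scale overdispersion that aggregates to pseudo-bulk
dispersions near 0.01 at the default 80 cells per profile), log-normal
cell size factors (σ = 0.35, ~5000 reads/cell), per gene-and-sample
multiplicative effects (σ = 0.2 — the nuisance that makes sample blocking
necessary), 10 mitochondrial genes at 5% of reads, 3% planted "dead"
cells boosted to 50% mitochondrial content, and 5% doublets formed as
literal sums of two sampled parent cells. 10% of genes carry monotone
trends (alternating up/down; linear, sigmoid and smoothstep shapes) with
amplitude 2.5 on the natural-log scale across the trajectory — calibrated
once by pilot simulation so that end-to-end recovery has power well above
0.8, then frozen.

The generator does **not** emulate zero-inflation beyond NB sampling,
branching trajectories (single path only), ambient RNA, batch chemistry
effects, or empty droplets. Passing tests therefore demonstrate correct
statistical behaviour under the NB pseudo-bulk model, not robustness to
every artefact of real droplet data.

`simulate_pseudobulk` generates counts directly at the pseudo-bulk level
for fast engine tests, including the `"mammary"` preset that reuses the
22 retained pseudotimes, stage labels and library sizes of the example
data set. Problem sizes in the test suite (2000 genes × 22 samples for
calibration checks; 5 × 5 × 80 cells end-to-end) were chosen to give the
statistical gates adequate precision while keeping the whole suite around
half a minute.

All randomness flows through a single numpy Generator seeded from the
config; a fixed seed yields bitwise-identical data.

## Known limitations

* Behavioural, not bit-level, agreement with the reference R
  implementations: internal constants (APL weighting details,
  small-sample deviance adjustments, robustness iterations) differ, so
  dataset-level statistics can differ in the third significant digit even
  when every property-level check passes.
* The dispersion trend assumes enough genes per abundance bin (~150); on
  very small panels it falls back to the common dispersion.
* Pseudotime is consumed as given. Uncertainty in trajectory inference is
  not propagated into the tests.
* The QL F-test's accuracy degrades when most counts are below ~5 per
  profile; the expression filter is there to prevent that regime.
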