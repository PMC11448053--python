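# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices that were genuinely open, and what the
synthetic-data validation does and does not establish.

## Compositional core

Sequencing counts are compositional: only ratios between features carry
information. All β-diversity work therefore runs through the centred log-ratio
transform, `clr_i(x) = ln((x_i + pc)/g(x + pc))` with `g` the within-sample
geometric mean, and the **Aitchison distance** is the Euclidean distance
between CLR vectors. CLR rows sum to zero by construction and the distance is
invariant to per-sample scaling and to feature order.

*Zero replacement.* A pseudocount (default **1.0** on counts) is added before
the log; the choice is exposed as a parameter because no single convention is
canonical, and sensitivity to it should be checked on real data. Metabolite
intensities use `ln(1 + abundance/fecal_weight)` followed by per-feature mean
centring, which tolerates exact zeros without a tuning constant.

*Rarefaction* subsamples each sample without replacement
(multivariate-hypergeometric draw) to a common depth, default 25,000; samples
below depth are dropped and reported rather than errored on. A diagnostic
(`depth_robustness`) checks whether pairwise distances track |Δ read depth|
(Spearman, permutation p); CLR on rarefied counts should be near zero.

*Stability.* For each subject, one record per consecutive observed day pair
with `stability = 1/distance`. A zero interval distance (identical CLR
profiles) yields an absent stability rather than infinity; subjects with a
single sample are skipped with a warning.

## α-diversity and paired tests

Shannon defaults to **base 2** (bits), the common amplicon convention;
natural log is available. Faith's PD sums the branch lengths of the minimal
rooted subtree spanning the observed taxa **including the path to the root**
(stated explicitly because conventions differ). The paired Wilcoxon test
drops zero differences (reduced-sample convention) and in exact mode
enumerates all 2^n sign assignments (n ≤ 25); the normal approximation uses a
continuity correction, which keeps it within ~0.01 of the exact p at n = 15.
The repeated-measures ANOVA is the one-way within-subject decomposition
`F = MS_time / MS_(subject×time)` on a complete balanced grid, with no
sphericity correction (the result object says so).

## Permutation multivariate tests

PERMANOVA partitions squared distances with
`SS_total = (1/n) Σ_{i<j} d²_ij` and `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`,
`pseudo-F = (SS_between/(g−1)) / (SS_within/(n−g))`. Inference permutes group
labels with the `(1 + #{F* ≥ F}) / (1 + B)` convention; when the number of
distinct relabelings is ≤ 10,000 the null is enumerated exhaustively and the
p-value is exact. Defaults: B = 1,000.

PermDisp embeds samples by PCoA of the Gower-centred matrix. Negative
eigenvalues (non-Euclidean distances) are retained as "imaginary" axes:
squared distance to the group centroid is the positive-axis contribution
minus the negative-axis contribution, floored at zero (Anderson's
decomposition). A Cailliez-type additive correction is deliberately not used —
Aitchison distances are already Euclidean and the correction would distort
them. The test statistic is the one-way ANOVA F on distances to own-group
centroids; the p-value permutes group labels of those distances. The centroid
(not spatial median) is the default centre. Permutations are unrestricted
across samples; a repeated-measures design can pass strata by testing only a
chosen day subset (the pipeline pools the post-baseline days).

## Stability-vs-serum regression

The headline analysis regresses stability on the per-subject percent serum
change, `100·(end − baseline)/baseline`, by Gaussian-identity OLS. The default
unit is the **interval**: each consecutive-interval stability is one
observation and the subject's single serum change is repeated across their
intervals, so observations are correlated within subject — the result object
carries this caveat, and a subject-clustered standard-error p-value is
available as a labelled extension. A `subject_mean` mode (one point per
subject) is also provided. Both unadjusted and adjusted R² are reported.

Matched-pair randomization orders subjects by baseline serum, pairs
consecutive subjects (minimizing within-pair differences), flips a seeded
coin within each pair, and assigns an odd leftover by a fair coin; the
expected between-arm baseline difference is zero and the realized difference
is bounded by the largest within-pair gap.

## Principal response curves

Given a transformed samples×features matrix, two-group PRC (1) centres
features, (2) partials out the time main effect by regressing on time
dummies, (3) projects the residuals onto condition×time interaction dummies
excluding every baseline-condition column, and (4) takes the dominant
singular triplet of the fitted matrix. The right singular vector gives
unit-norm **species scores** `b_k`; the left side, scaled by the singular
value, is constant within each design cell and gives the **canonical
coefficients** `c_dt`, so the fitted first-axis response is `b_k·c_dt` with
baseline cells exactly zero. The sign is fixed by making the
largest-|coefficient| entry positive. `explained_variance_fraction` is the
first squared singular value over the total fitted sum of squares.

In single-group mode the condition factor *is* the day (first day as
baseline) and no time effect is partialled out; features are centred on the
**baseline-day cell mean** rather than the grand mean, so the curve reads
directly as change from baseline. First-axis significance is assessed by
permuting whole subjects between conditions (999 by default) with
max |canonical coefficient| as the statistic.

Cross-group comparison standardizes each arm's species scores to mean 0,
SD 1 (population SD — divide by n; stated because "standardized" alone is
ambiguous), plots placebo on x against treatment on y, and scores each
feature by its perpendicular distance from the line of equality,
`|y − x|/√2`. Quadrants use the convention Q1: x ≤ 0 < y (rises under
treatment only); the boundaries are measure-zero and do not affect selection.
Top-bin selection cuts an equal-width histogram of annotated features'
distances into `n_bins` (default 10) and returns features in the
`n_top_bins` (default 2) right-most bins, i.e. distance ≥ the
`(n_bins − n_top_bins)`-th edge; if all distances coincide the single
degenerate bin returns everything with a warning.

## Correlation screens and FDR

Per-feature CLR changes from the baseline day are correlated with a covariate
(serum change, or community distance from baseline) by Pearson or Spearman;
Spearman p-values are exact by rank-permutation enumeration when n ≤ 9.
Benjamini–Hochberg q-values use the step-up
`q(i) = min_{j≥i} m·p(j)/j`, capped at 1. The FDR family is the feature set
of one analysis run, not pooled across days. Constant features are flagged
and excluded from the family.

## Networks and rewiring

Microbe–metabolite coefficient matrices come from plain Pearson
cross-correlation or from **Ledoit–Wolf shrinkage partial correlation**: the
stacked [microbes; metabolites] covariance is shrunk, inverted, and
`ρ_ij = −P_ij/√(P_ii P_jj)` reported for cross pairs. The shrinkage estimator
stands in for debiased sparse partial correlation and the output metadata
records this. Networks keep edges with `threshold ≤ |ρ| ≤ 1` (default 0.75,
inclusive at both ends); nodes are endpoints of retained edges.

Two-state comparison reports Jaccard fractions over node and edge sets
(edge identity is presence/absence, ignoring weights) and the per-node Dn
score: with binary adjacency rows a₁, a₂ over the union node set and centroid
c = (a₁+a₂)/2, `Dn = ‖a₁−c‖ + ‖a₂−c‖`, which simplifies to the square root of
the neighborhood symmetric-difference size; the degree-corrected variant
divides by the union degree. Dn is zero iff the neighborhoods are identical.

## Synthetic trial generator

The generator emulates a two-arm supplement trial: 22 placebo / 21 treatment
subjects sampled on days 1, 7, 14 and 78, sequencing depth Poisson(25,000),
serum baseline ≈ 38 ± 15 ng/mL with a ≈ 33 ± 12 ng/mL treatment gain (placebo
drift SD 4 ng/mL), so the treated arm rises from roughly 40 to roughly 73
ng/mL.

Latent log-abundances follow an AR(1):
`λ_{t+1} = (1−h)·λ_t + h·λ_attractor + ε`, `ε ~ N(0, σ_subject² I)`, with the
homogenizing pull `h` (default 0.45) applied in the treatment arm only and
`σ_subject = drift_sd · (1 + coupling · %Δserum/100)` planting the inverse
stability–serum association as **variance scaling, not a mean shift** — the
recoverable truth is exactly the association the regression estimates.
Counts are softmax-multinomial draws, keeping the drift model linear on the
log scale with a controllable Aitchison geometry (overdispersion comes from
drift_sd rather than a Dirichlet layer). Metabolites are log-normal with
subject effects; responders add `effect·(day index)` in the treated arm.

Microbe–metabolite coupling is planted in the treatment arm only: the shared
latent factor for a coupled pair is the taxon's own **standardized latent
log-abundance** across treatment samples, and the metabolite loads on it with
a weight chosen to target the configured correlation. An earlier design that
added an external latent factor to both pair members inflated treatment-arm
compositional variance enough to erase the homogenization pattern; tying the
factor to the taxon's existing dynamics adds zero variance to the microbiome
while preserving the planted correlation.

*Calibration.* `homogenize = 0.45` is the smallest round value at which the
treatment arm's within-group distance visibly declines by the last day across
seeds: the decline must beat both the serum-coupled extra drift and a noise
floor contributed by rare taxa (CLR of pseudocounted zeros), which does not
shrink under the attractor pull. Defaults were fixed once after a variance
budget and a three-seed check, and are not tuned per analysis.

*What passing tests do not show.* The generator has no batch effects, no
read-level error, no taxonomic structure beyond a random join tree, no
heavy-tailed metabolite intensity distributions, and multinomial (not
Dirichlet-multinomial) counting noise. Recovery of planted signals here
validates the estimators' correctness and calibration, not their power on
real data, where effect sizes, zero-inflation and confounding are harsher.

## Problem sizes used in validation

The statistical checks run at desk scale, chosen to keep the full suite in
tens of seconds while leaving Monte-Carlo error well inside the asserted
bands: type-I calibration uses 1,000 replicate null trials of 12 independent
samples; dispersion size/power uses 500 replicates of 20 samples per group
(199 permutations each); sign-recovery and null-balance use 200 replicate
trials of 16 subjects; responder recovery uses 100 replicates of a
60-sample, 200-feature design. The end-to-end pattern check runs one
full-size default trial (43 subjects × 4 days, 150 taxa, 300 metabolites).

## Known limitations

- PRC is first-axis only; higher axes are out of scope.
- PERMANOVA is single-factor (with optional strata); no interaction designs
  or db-RDA.
- The shrinkage partial correlation is a stand-in, not the debiased sparse
  estimator; at p ≫ n its support recovery is conservative.
- Interval-mode stability regression ignores within-subject correlation by
  design (matching the univariable analysis it implements); use the
  cluster-robust option when inference matters.
- Reported q-values assume the tested features form the whole family; pooling
  across runs requires re-adjustment by the caller.
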