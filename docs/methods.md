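# Methods

This note documents the statistical model, the algorithmic and numerical
choices, the synthetic-data generator and the study conditions under which
the package's guarantees are tested. It complements the API docstrings; it
records design rationale, not results.

## Count model and quasi-likelihood testing

All four differential stages (bin-pair interactions, aggregated promoter
interactivity, TAD-boundary up/down contrasts, gene expression) share one
engine (`hicwaves.qlstats`).

**GLM.** Counts are negative-binomial with log link: `y_fi ~ NB(mu_fi,
phi_f)`, `log mu_fi = x_i' beta_f + o_fi`. The design is a one-way layout
(one indicator per condition group); offsets carry `log(lib_size)` plus
normalization. Fitting is batched IRLS across features (shared design,
per-feature weights), max 50 iterations, relative deviance tolerance 1e-8,
vectorized step-halving on deviance increase, linear predictor clamped to
[-30, 30]. All-zero features are pinned at the lower bound with zero
deviance and flagged converged; non-converged features keep their last
iterate and are flagged. `phi = 0` degenerates to Poisson. The NB deviance
uses the saturated-vs-fitted formula with `0*log 0 := 0`.

**NB dispersion.** The common dispersion maximizes the summed Cox-Reid
adjusted profile likelihood (penalty `0.5 * logdet(X'WX)`) over a fixed
log-spaced grid (1e-6 to 10, 15 points) with bounded local refinement;
features are deterministically thinned to 1000 (evenly across the
total-count ordering) for speed. The abundance-dependent trend evaluates the
per-feature APL on the same grid, smooths each grid column across abundance
by loess, and interpolates the per-feature maximizer quadratically on the
log scale; for large feature sets the trend is fitted on a 2000-feature
subsample and interpolated along abundance. The DIP stage uses a single
common dispersion with no trend, matching its design of few, strongly
aggregated features; the DI, DTB and DE stages use trends.

**QL moderation.** Raw quasi-dispersions `s2 = deviance / residual_df` are
squeezed toward a trend (loess of raw vs abundance, span 0.4, floored at
1e-10; a constant when trend is disabled). The prior df and scale come from
the scaled-F moment equations on `log(s2/trend)` (digamma/trigamma
moment-matching; trigamma inverted by Newton). When the raw values have no
between-feature variance the log-F bias correction is skipped and the prior
df is infinite, so equal raw values squeeze to themselves. The paper-style
"robust" variant is implemented as optional winsorization of the moment
inputs at the 5%/95% quantiles (off by default); the plain moment estimator
is the fully specified default. The squeezed value is the
`(prior_df, residual_df)`-weighted combination of trend and raw, hence
always between them.

**Tests.** The QL F-test uses the likelihood-ratio deviance of a single
contrast (the reduced design is the projection onto the contrast's null
space) over the squeezed dispersion, referred to `F(1, prior_df +
residual_df)`; an infinite prior df falls back to the chi-square limit.
TREAT tests `H0: |true log2FC| <= log2(threshold)` by combining the two
shifted one-sided moderated-t tails (`t_obs = sqrt(F)`, shift =
`log2(threshold) / se` with the LRT-consistent se, Wald se only when the LRT
is flat), capped at 1; at threshold 1 the construction reduces exactly to
the F-test. Zero-variance features cannot reject beyond a positive
threshold (p = 1). BH adjustment is the standard step-up with monotonicity,
applied within each transition separately because each transition is its own
result set. Patterns assign `sign(logFC)` at transitions with FDR strictly
below 5% and 0 elsewhere.

## Smoothing and normalization

`loess_fit` is an exact local-linear tricube smoother: each point is fitted
from its `ceil(span*n)` nearest neighbours (window widened to 3 when
smaller), with the window realized as the contiguous run in sorted x that
minimizes the maximum distance; the fit is the intercept of the weighted
regression on centred x, computed in closed form and vectorized in chunks.
It reproduces affine data exactly and matches a direct per-point WLS oracle
to 1e-8. For large inputs a `grid` option fits exactly at quantile points
and interpolates (the classical lowess "delta" shortcut); the normalization
and trend code uses grids (200 and 100 points), while the DIP
distance-abundance filter uses a 400-point grid over typically tens of
thousands of interactions. Optional robustness iterations reweight by the
lowess bisquare rule on residuals; the normalization uses two such
iterations so genuinely differential features do not drag the technical
trend.

Between-library normalization converts each library's log2CPM deviation (M)
from the per-observation mean abundance (A) into offsets via robust loess of
M on A, centred to sum to zero across libraries per observation, on the
natural-log scale (to be added to `log(lib_size)`). The DI stage computes
offsets separately for pairs closer than 1.5 Mb to the diagonal and all
others, because short-range contacts follow a different technical trend.
Strata under 50 observations fall back to a constant median offset. TMM
factors (30% M-trim, 5% A-trim, precision-weighted, geometric mean 1) scale
RNA-seq library sizes.

**Known limitation.** Any abundance-dependent normalization assumes that at
every abundance most features are non-differential. A step change spiked at
a mid-course transition moves a feature's *average* abundance by up to ~1.2
log2 (4 of 6 stages changed), so if a large fraction of features is spiked
they segregate toward the extremes of the M-vs-A trend and the offsets
absorb real signal. The recovery scenarios therefore either spike a modest
fraction (~10%, the regime of real data) at mid-course transitions, or spike
at the final transition (abundance shift ~0.4 log2) when a third of features
carries effects. Real analyses with a small differential fraction are
unaffected.

## Stage-specific procedures

**DI.** Pairs are dropped if diagonal, inter-chromosomal, or with total
count below 10 (a per-library switch exists; the total-count reading is the
default because the source rule is ambiguous). The background ligation rate
is the mean abundance of inter-chromosomal 1 Mb pairs, rescaled to the
working bin size by the bin-area ratio on the log2CPM scale (the scaling
convention is a documented choice); retained pairs must exceed it by
strictly more than log2(4). Clustering merges significant pairs adjacent in
the 2-D bin grid (8-neighbourhood, single linkage), partitions components on
a 500 kb tile grid so no bounding-box side exceeds 500 kb, scores each
cluster by the Sidak-corrected minimum member p (`1-(1-p_min)^m`), and
binary-searches the pair-level p threshold so that the mean cluster p — an
upper bound on the expected fraction of null clusters — stays at or below
5%. This is a fully specified replacement for delegating cluster-level FDR
control to an external tool.

**DIP.** Windows are TSS +/- 5 kb (strand-aware for asymmetric windows),
with user-supplied exclusion lists. Counting keeps every intra-chromosomal
(window, 10 kb second region) combination with at least one read; pairs with
both anchors inside one window measure local compaction, not promoter-distal
contact, and are dropped; a second region that is itself another promoter's
window is assigned to one promoter only (deterministic lower-start rule; a
switch allows double assignment). The abundance filter fits loess (span
0.05) of average log2CPM on `log10(span+1)` and keeps interactions strictly
above fit + k * mean|residual|, k=2 normally and k=3 for the stricter motif
analysis. Aggregated counts are treated as their own count data set (library
sizes = column totals) for filtering (CPM-equivalent of min.count 200 at the
median library size, in at least the smallest group's number of libraries;
total >= 200) and testing.

**DTB.** Up/down counts per 100 kb region (other anchor's midpoint within a
1 Mb flank before/after the region; regions within a flank of a chromosome
end dropped) enter one GLM per region over the 2n stacked observations:
n library-baseline indicators plus one per-stage coefficient on the upstream
observations, so each stage coefficient is that stage's natural-log up/down
ratio. The tested contrast is the ratio change between consecutive stages
(TREAT at 1.1; abundance filter at average log2CPM >= 1). Direction labels
compare fitted |log-ratio| across the transition: growing = strengthening,
shrinking = weakening. This interaction-GLM formulation is this package's
own realization of the published strategy, which defers to an external
user's guide; the signed contrast is tested and the absolute-size reading is
applied at the labelling step.

**Loops.** On the replicate-averaged matrix, the per-pixel expectation is
the diagonal (distance) mean times the mean observed/expected ratio in a
(2w+1)^2 ring with the centre row/column cross and an inner square excluded
(w=5, inner=1 by default; the window shrinks implicitly at matrix edges via
normalized convolution). Enrichment is `log2((obs+1)/(exp+1))` — log2 chosen
so the 0.5 cut-off is non-trivial — with thresholds enrichment > 0.5,
mean-across-libraries count > 5, anchors > 60 kb apart. The rule is a plain
threshold, not a significance test: it controls no noise level, so shallow
matrices yield many single-pixel calls; the recovery scenarios use deep
matrices (1e7 pairs/library) where planted loops are unambiguous.

**Enrichment stages.** Motif enrichment is a one-sided Fisher exact test of
binary hits in pattern anchors vs 1500 seeded control anchors sampled from
non-differential interactions, Bonferroni-corrected over all tests in the
invocation, with motifs of unexpressed TFs (RPKM < 1) removed first; the hit
matrix is an input (an optional PWM scanner is out of scope — scanning
internals are not part of the specified procedure). ChIP overlap uses the
Yates-corrected 2x2 chi-square (df 1); loop/DE association the uncorrected
2x3 chi-square (df 2). The gene-set association is a seeded set-label
permutation test (mean of centred gene statistics, two-sided with +1
correction, 10,000 permutations) — a deliberate replacement for a rotation
test, exact under exchangeability at these scales and answering the same
directional question.

**QC.** SCC smooths both matrices with a (2h+1) mean filter (h=3,
edge mode "nearest"), correlates each diagonal stratum up to 5 Mb and
combines with weights `N_k * sd_k(A) * sd_k(B)`; the diagonal itself is
excluded and zero-variance strata are skipped. Callers take the median over
chromosomes. MDS distances are the RMS of the 500 largest absolute log2
differences per library pair.

## Synthetic experiments

The generator emulates a six-stage, duplicate-replicate differentiation
study. Expected intra-chromosomal counts follow `depth * span^alpha` with
alpha = -1 (typical contact-decay slope), multiplied by TAD-block folds
(default blocks of fold 2.5-3, optionally rescaled per stage), focal loop
folds, and spike factors; counts are NB-sampled. Spikes are multiplicative
step changes from the named transition onward, mirroring the dominant
change-then-stable patterns of staged differentiation. Inter-chromosomal
1 Mb pairs carry a flat rate holding 5% of depth, so the background filter
is exercisable. The default genome is 2 x 50 Mb at 50 kb bins; tests and the
acceptance script scale chromosomes down (10-25 Mb) and cap enumerated spans
(2-5 Mb) to keep simulation minutes-scale; these sizes are stated per block
below.

Promoter-anchored contacts are generated at 10 kb for 200-300 genes with
bin-aligned TSSs: each promoter has 8 designed interacting anchors at
enhancer-like distances (30-300 kb) carrying 20-fold focal enrichment over
the decay — so a promoter's signal concentrates in strong distal contacts,
as real promoter interactomes do — plus a log-normal per-promoter
interactivity scale (sd 0.6 on the natural log), without which all
promoters would share one abundance and any designed effect would segregate
in A (see the normalization limitation above). The promoter table holds 10%
of the configured depth. Key NB dispersions: 0.02 for Hi-C counts (BCV 0.14,
in line with published bin-pair estimates from replicate Hi-C) and 0.01 for
expression (BCV 0.1, the standard figure for biological replicates of
genetically identical model organisms). Motif hits are binary labels on
designed anchors (background rate 0.1, planted motif at 0.5 in
spiked-promoter anchors); ChIP peaks cover spiked-up anchors at rate 0.4 vs
0.1 background; expression spikes can be coupled to promoter spikes to
design in the interactivity-expression correlation.

What the generator does *not* emulate: restriction-fragment statistics,
mappability or GC bias, copy-number variation, compartment-level structure,
or promoter-promoter contacts (excluded so each contact has one unambiguous
anchoring promoter). Passing tests therefore demonstrate statistical
correctness of the procedures under the stated count model, not robustness
to artefacts absent from the model.

## Test and acceptance problem sizes

Null error control uses 20 seeds per stage (10 in the acceptance script)
with 2 x 10-25 Mb genomes at depth 1e6; the false-discovery proportion is
averaged over transitions x seeds, with per-run FDP defined as 0 when
nothing is called. DIP recovery uses the full default genome (2 x 50 Mb,
depth 2e6), 100 of 300 promoters spiked 3-fold at the final transition. DI
recovery uses 2 x 20 Mb at depth 2e6 with 100 pairs spiked 3-fold at spans
150-500 kb (where Hi-C counts support fold-3 detection at duplicate
replication). DTB recovery attenuates one TAD block's enrichment 2-fold at
one transition. Loop recovery plants five 8-fold loops at depth 1e7. All
randomness flows from explicit seeds; identical seeds give byte-identical
tables.
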