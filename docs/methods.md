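# Methods

This note records the models, conventions and numerical choices behind
`deconvbench`, in the spirit of a package methods appendix.  Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Expression containers and preprocessing

Expression is held gene × unit with an explicit scale tag (`counts`,
`cpm`, `log`) so that every operation can assert its precondition rather
than silently mixing normalisations.  CPM normalisation rescales each
column with a nonzero total to 10⁶; all-zero columns are preserved at zero
(dropping units is an explicit filter, never a side effect of
normalisation).  The log transform is `log2(x + 1)` by default.
Pseudobulking is defined only on counts and sums member columns, so total
counts are conserved exactly and the operation commutes with column
permutation.

Low-expression filtering keeps genes whose mean RPKM exceeds a threshold
(default 0.1); when gene lengths are unavailable the mean CPM is used with
the same threshold semantics — with equal lengths the two rules select
identical gene sets, which is a tested invariant.  The original pipeline's
adaptive expression cutoff is not re-derived here; a fixed configurable
threshold is exposed instead.

Sample QC uses the median-absolute-deviation rule: within each stratum
(e.g. library type), a sample fails a metric when it lies beyond
median ± k·MAD (k = 3 by default, MAD scaled by the 1.4826 consistency
constant) in that metric's declared failing direction — low mapping rates
fail low, mitochondrial rates fail high.  A sample is dropped at ≥ d
failing metrics (d = 2 by default) and warned below that.  The warn/drop
boundary is configurable because no single convention is canonical;
observed drop decisions in real pipelines typically involve several
jointly failing metrics.

## Marker selection

The Mean Ratio of gene g for target type k is the mean linear-scale (CPM)
expression in k divided by the *highest* mean among the other types.
Conventions for degenerate cases: a positive target mean over a zero
non-target maximum gives +inf (a perfectly specific gene); zero over zero
gives 0.  Ranking is by descending ratio, ties broken by descending target
mean and then lexicographic gene id, making `rank_ratio` fully
deterministic.  The ratio is computed on linear CPM means, the
ratio-of-means reading of the statistic; computing on another assay scale
is possible by passing a differently normalised matrix, since the function
only requires a linear scale.

The one-vs-all statistic is a Welch two-sample t-test of the target type
against all remaining cells pooled, on log-scale expression, ranked by the
mean difference (log fold change) with ties broken by p-value.  Zero
variance in both groups is handled explicitly: equal means give t = 0,
p = 1; unequal constant groups give infinite t, reported as p = 0 with a
`degenerate` flag rather than NaN.

Marker-set rules: top-N sets take the N best-ranked genes per type and
*then* intersect with the common-gene universe (so sets can fall below N);
threshold sets take all genes with ratio strictly above the cutoff; the
MAD rule computes, per type, median + k·MAD over that type's ratios
strictly greater than 1 (k = 3 by default) and takes genes strictly above
it.  A type with no ratios above 1 yields an empty set with a warning
record, not an error.  Because a gene's ratio can exceed 1 for at most one
type (the strict maximum is unique), all threshold-based sets are pairwise
disjoint across types — asserted as a property test and an acceptance
criterion.

## Deconvolution

The signature matrix is the per-type mean CPM over the union of marker
genes, rows sorted by gene id for determinism.  The NNLS estimator solves
min‖y − Sw‖₂ subject to w ≥ 0 per sample and renormalises w to
proportions; it is scale-invariant in the bulk column and requires a
full-column-rank signature (checked).  The marker-ratio estimator averages
bulk/signature ratios over each type's markers, skipping zero-signature
terms; with perfectly specific markers it recovers the RNA-fraction
composition in closed form.  Both estimators fall back to uniform
proportions with a machine-readable warning when a solution is identically
zero, so batch runs never silently drop samples.

External methods are reached through a plug-in registry (`bulk, signature,
markers → ProportionTable`) rather than re-implemented; the two in-repo
estimators exist to exercise the harness and provide exactness guarantees
on noiseless data.

Cell-size adjustment is a post-hoc transform q_k ∝ p_k / s_k, renormalised
per sample.  It exactly inverts the RNA-fraction construction
p_k ∝ c_k·s_k (a tested algebraic identity at 1e-10), and equal sizes fix
every table.  Applying the adjustment inside an estimator would be
equivalent for these baselines since they are renormalised linear
estimators; post-hoc keeps the estimator contract method-agnostic.

Cell-type collapsing sums source columns into a merged column (e.g.
Oligo + OPC → OligoOPC to match an imaging panel); row sums are preserved
exactly, and a merged name may not collide with an existing unmerged
column.

## Evaluation

Accuracy metrics pool all (unit, cell type) pairs in the evaluated scope:
Pearson correlation, rmse, and rrmse = rmse / mean(truth in scope).  The
overall scope pools everything, matching the single-correlation-per-method
convention; per-stratum (library type × extraction) and per-cell-type
scopes are available.  Correlation is reported as missing, with a reason,
when either side has zero variance or fewer than two pairs.  The
within-block consistency metric is the relative standard deviation (sample
sd / mean, i.e. the coefficient of variation) of the summed neuronal
fraction across a block's samples; blocks with one sample are skipped and
a zero mean yields NaN.  The n−1 divisor is used for the standard
deviation.

Fisher enrichment builds the 2×2 table of marker-set versus target-set
membership within a declared gene universe and reports the one-sided
(greater) hypergeometric tail p together with the *sample* odds ratio
ad/bc (+inf when bc = 0 with a·d > 0); the convention is stated here and
in the output metadata because other implementations report the
conditional MLE.  BH adjustment is the standard step-up procedure with
monotonicity enforcement.

## Sensitivity experiments

Equal-proportion resampling draws, per replicate r, `n_per_type` cells of
every type without replacement using seed + r (documented so any replicate
is reproducible in isolation), rebuilds the signature from the subset, and
re-runs the estimator; the default `n_per_type` is the size of the rarest
type.  Reported summaries are the per-replicate tables, the renormalised
mean table, and the per-(sample, type) across-replicate sample standard
deviation.  Marker sets are held fixed across replicates (they describe
the biology, not the subsample).  Reference swapping harmonises label
vocabularies through an explicit mapping (e.g. merging endothelial and
pericyte labels) before building each signature, and only the reference
side is resampled or swapped — the bulk data are fixed.

## Synthetic-data generator

The generator defines the study conditions under which the toolkit is
validated.

*Reference*: baseline per-gene means are log-normal (log-mean 1, log-sd 1,
in arbitrary linear units); each type receives a disjoint block of planted
marker genes whose mean is multiplied by `marker_fold`; counts are
negative-binomial with inverse-dispersion 10 (variance μ + μ²/10, a
typical single-cell overdispersion scale).  Defaults follow a human
cortical setting: seven broad types (Astro, EndoMural, Micro, Oligo, OPC,
Excit, Inhib), excitatory neurons most common and microglia rarest in the
reference composition, and per-type RNA-content factors giving neurons
1.5–1.8× the RNA of glia.  Passing an existing truth object reuses its
expected means, producing technical-replicate references.

*Bulk*: each tissue block draws a cell-count composition (Dirichlet α = 5
across 7 types, or explicit) and contributes one sample per library type;
expected expression is bias·Σ_k c_k·s_k·μ_{gk} rescaled to a 10⁶ library
size, with Poisson counts by default (NB optional) — the mixing weights
c·s make the RNA-fraction / cell-fraction distinction explicit and
testable.  Library bias is multiplicative per gene per library type, the
simplest mechanism that reproduces differential quantification between
library preparations and its marker-enrichment consequences; the planted
configuration multiplies one type's markers by a chosen factor in one
library only.

*Segmented cells*: phenotypes are multinomial in the declared composition
(including an explicit `other` class for unlabeled cells); nuclear areas
are log-normal per type (median ≈ 22–55 µm², larger for neurons), puncta
counts Poisson per type.  Non-planted cells' areas are clipped just below
the π·(5 µm)² radius bound — emulating the segmentation size limit — so
that a configured oversize fraction is planted exactly and the
radius-filter count check is sharp.

What the generator does **not** emulate: gene–gene correlation, batch and
donor effects beyond round-robin donor labels, ambient RNA, doublets,
length-dependent or additive quantification biases, and
segmentation/phenotyping errors in the imaging data.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not performance on real tissue.

## Problem sizes and numerical choices

The test suite and acceptance script use deliberately compact problem
sizes chosen to make the statistical checks sharp while keeping runs
quick: the end-to-end recovery uses the full planted design (2,000 genes,
7 × 300 cells, 24 bulks); oracle-equivalence checks use ≤ 300 genes and
≤ 6 types over 50 random draws; the resampling experiment uses 200
replicates at three doubling subsample sizes; the imaging check uses a
50,000-cell section.  Tolerances: 1e-6 for noiseless NNLS recovery (the
active-set solver's accuracy), 1e-10 for the size-adjustment algebra
(pure floating-point arithmetic), 0.01–0.02 for multinomial/LLN
concentration checks at the stated n.  Ties and degenerate inputs are
resolved by the explicit conventions above rather than left to library
defaults.

## Known limitations

The in-repo estimators are baselines, not competitive methods; real
benchmarking of published deconvolution algorithms happens through the
plug-in contract.  The MAD marker rule can behave discontinuously when
many ratios are infinite (more than half the pool infinite makes the
threshold infinite, selecting nothing above it).  The QC warn/drop rule is
a configurable stand-in, not a canonical definition.  Proportion
denominators in the imaging pipeline are post-filter totals; whether
excluded oversized cells should count toward the denominator is a
convention, declared here.
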