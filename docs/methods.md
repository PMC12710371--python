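# Methods

This note records the statistical procedures `microdorm` implements, the
modeling choices behind the synthetic generator, and the numerical decisions
that a user auditing results should know about.

## Activity classification and dormancy

A physical sample contributes one DNA library (total community) and one
cDNA/RNA library (active community), linked by an explicit `pair_id` —
pairing is never inferred from sample-name conventions. Detection means
count ≥ 1 after rarefaction (configurable `presence_threshold`). Per pair,

- dormant fraction = 1 − |RNA| / |RNA ∪ DNA| over detected taxa,
- shared fraction = |RNA ∩ DNA| / |DNA|.

A pair with an empty union (or empty DNA set for the shared fraction) is
reported as *undefined*, never imputed as 0 or 1, and excluded from
summaries with a warning — imputation would bias dormancy means exactly in
the low-biomass samples where detection fails.

Core microbiomes use occupancy (fraction of samples with detection) within
each assay, over the samples retained after rarefaction, pooled across all
site types and seasons; the threshold is `≥ τ` with τ = 0.95 by default.
A taxon's activity frequency is the fraction of its DNA-detected
occurrences that are also RNA-detected (denominator: occurrences in the
total community); total-core taxa with activity frequency below 0.5
(configurable) are listed as "frequently inactive", and active-core taxa
missing from the total core are listed separately.

Caveats inherent to the operationalization (not corrected here): rRNA copy
number varies across taxa, relic DNA inflates the total community, and
detection is depth-limited, so the dormant fraction at finite depth is an
upper bound that includes "present but below RNA detection".

## Preprocessing

- **Rarefaction** subsamples each library without replacement
  (multivariate hypergeometric draw) to a fixed depth, dropping and logging
  shallower libraries. One seeded draw per table; repetition is the
  caller's choice. Marker-specific default depths follow common practice
  for 16S (13,407) and ITS2 (17,182) data of this design.
- **Square root + Wisconsin double standardization**, in the fixed order
  sqrt → divide each taxon row by its maximum → divide each sample column
  by its total, the convention of the classical ecology packages. All-zero
  taxon rows are dropped with a warning; an all-zero sample is an error.
- **CLR** uses log(x + pseudocount) centered per sample; the pseudocount
  default is 0.5 (half-count correction).
- **Taxonomy aggregation** sums counts within a rank, pooling groups below
  a mean-relative-abundance threshold into "other" and unmapped taxa into
  "unassigned"; totals are conserved.

## Community statistics

All permutation p-values are `(b + 1)/(m + 1)` with explicit seeds, so the
attainable minimum is `1/(m + 1)`.

- **Bray–Curtis**: Σ|x−y| / Σ(x+y) over taxa; verified against a literal
  double-loop oracle and, for the full standardization chain, against R
  vegan to 1e-10.
- **PCoA**: eigendecomposition of the Gower-centered squared-distance
  matrix; negative eigenvalues are reported as a diagnostic and their axes
  dropped. PCoA (deterministic, testable) stands in wherever an ordination
  feeds downstream regressions; NMDS adds a stress-minimization convergence
  ambiguity without changing the scientific question.
- **PERMANOVA**: sequential (Type-I) sums of squares in the order terms are
  given, via increments of tr(H·G) over cumulative hat matrices; pseudo-F
  against the residual; permutations shuffle design rows, freely or within
  the levels of a `strata` column (use site as stratum when testing season
  in nested designs — free permutation otherwise inflates significance).
  Output (SS, R², F) matches vegan `adonis2(by="terms")` exactly on frozen
  fixtures. A numerically zero residual yields F = ∞ so that degenerate
  fixtures keep exchangeable tie behavior.
- **Beta dispersion**: distance of each sample to its *group centroid* in
  the full PCoA space, subtracting squared distances along
  negative-eigenvalue axes (imaginary-part correction); one-way F on those
  distances with a label-permutation reference. Centroids (not spatial
  medians) are used; per-sample distances match vegan
  `betadisper(type="centroid")` to 1e-10.
- **Mantel / partial Mantel**: Pearson or Spearman (average ranks on ties)
  correlation of unfolded upper triangles; one-sided p by permuting the ids
  of the second matrix. The partial statistic is the first-order partial
  correlation; when the covariate matrix is identical to the distance
  matrix being tested (|r| = 1), the partial association is defined as 0.
- **Distance decay**: Mantel of community dissimilarity against log10
  geographic distance, overall and within seasons, with an optional partial
  test conditioning on an environmental distance matrix. Zero geographic
  distances are rejected rather than offset.

## Differential abundance

Counts are CLR-transformed; each taxon is fit by OLS with the block factor
(site, or pair for the assay contrast) as a fixed additive effect, and the
term of interest tested by its F statistic against a reference built by
permuting term labels *within blocks*; BH adjustment runs across the taxa
passing the prevalence filter (default 10%, a documented guess — the
appropriate cutoff is data-set specific). This is a deliberate, documented
replacement of bias-corrected mixed-model estimators (LinDA-style): a
fixed-block linear model with within-block permutation is closed-form,
exactly testable, and preserves the blocking structure; its taxon counts
are not comparable to mixed-model outputs and are not treated as such.

The active-vs-total screen uses assay as the term and pair as the block
(within-pair permutation = sign flips), and calls a taxon enriched only
when BH-adjusted p < α **and** |log2FC| ≥ log2(2) — the 2× rule; site/season
screens use significance alone. log2FC is the difference of CLR group means
rescaled to log2 (for >2 levels: max-minus-min spread, with the peak group
recorded). Note that permutation p-values are granular: with T tested taxa
and k true signals the smallest achievable BH-adjusted p is ≈
T/(k·(m+1)), so m must be chosen accordingly (the tests use m = 1999 at
T = 200–500).

The seasonal delta contrast computes, per site, the mean over plots of a
taxon group's relative-abundance change between two seasons and compares
site classes (e.g. warm vs cool, split at a configurable covariate
threshold) with a Welch t-test; each class needs ≥ 2 sites.

## Environment linkage

- **Index covariates**: collinear covariate groups (e.g. organic-matter
  variables, or pH + base saturation) are replaced by the first principal
  component of their standardized members, sign-fixed to correlate
  positively with the first-named member; scores are zero-mean,
  unit-variance.
- **Importance screening**: responses are averaged to plot level (sensor
  covariates are simply constant within a site), then a pluggable
  fit/predict regressor — default `RandomForestRegressor(n_estimators=300)`
  — is screened by permutation importance (mean MSE increase over
  `n_repeats` column shuffles) with partial-dependence curves on a 50-point
  grid spanning the 2.5th–97.5th covariate percentiles, so edge
  extrapolation does not dominate the threshold search. Tests use a
  deterministic linear stub; the tree ensemble is a dependency, not a
  contribution.
- **Threshold localization**: the grid interval holding the largest
  absolute first difference of the partial-dependence curve, reported only
  when that jump exceeds `min_jump` × IQR of the curve (default 0.1 — on a
  50-point grid a linear trend produces per-interval differences of ≈ 0.04
  IQR while a step or steep sigmoid concentrates ≳ 0.2 IQR into one or two
  intervals, so 0.1 separates the two regimes).
- **Scale dependence**: common-slope vs per-site-slope Gaussian OLS models
  (fixed effects, an intentional simplification of random-slope mixed
  models that preserves the within- vs among-site question). The reported
  statistic is the LRT 2(ℓB − ℓA) with df = n_sites − 1; the p-value uses
  the exact finite-sample F reference for this nested comparison, because
  the asymptotic χ² reference rejects at ≈ 3× nominal with 5 plots per
  site (measured at 17.5% for α = 5%).
- **Presence GLM**: binomial logistic regression (IRLS via statsmodels)
  with optional site blocking; complete separation is detected
  (single-covariate threshold check plus divergence checks) and flagged —
  no Wald inference is reported for separated fits.

## Synthetic generator

The generator emulates a 3 site-type × 3 site × 5 plot × 3 season design
(135 pairs, 270 libraries), chosen to match the field layout this kind of
paired survey uses. Per taxon *i*, true abundance in plot p and season t is

    λ = exp(base_i + a_i(site type) + b_i(site) + c_i(plot) + s_i(t)),

with independent Gaussian offsets per level (sd defaults 1.0 / 0.6 / 0.4;
base sd 1.5; seasonal population sd 0.25). Activity is Bernoulli per taxon
× sample with probability sigmoid(logit(δ_i) + season effect −
slope·organic-matter), where δ_i ~ U(0.3, 0.9) by default and the seasonal
activity effect has sd 1.5 on the logit scale — deliberately larger than
the population amplitude, encoding the design assumption that seasons
modulate activity more than standing abundance. RNA weights multiply λ by
the activity state, a log-normal intensity (sd 0.5, activity is graded, not
binary), and a planted RNA:DNA ratio for enriched taxa; both libraries are
fixed-depth multinomial draws (default 20,000), which induces
compositionality the way amplicon sequencing does.

Planted structure (recorded in a ground-truth ledger): core blocks with
target occupancy — present in a Bernoulli(occupancy) subset of samples,
with dampened hierarchical offsets (×0.25) and elevated baseline abundance
so detection tracks the planted occupancy rather than sampling noise —
including a "core but frequently inactive" block (occupancy 1.0, δ = 0.05)
and a non-core block (occupancy 0.5); enriched blocks with known RNA:DNA
ratio (default 10 taxa at 4×, always active). Environmental covariates are
drawn at site level (sensor variables: temperature, moisture) or plot level
(chemistry, vegetation), with plot coordinates placing sites km apart and
plots tens of meters apart — the hierarchical composition effects then
produce distance decay without a separate mechanism.

`expected_dormant_fraction` is an independent Monte-Carlo oracle that
re-draws single pairs from the same marginal model (fresh offsets each
replicate, no shared bookkeeping with `generate`) and is restricted to
parameter sets without planted blocks.

What the generator does **not** emulate: rRNA copy-number variation, relic
DNA, primer/PCR bias, taxon–taxon interactions, overdispersion beyond the
log-normal hierarchy, and uneven library depths (every library hits the
target depth exactly, so rarefaction is exercised by tests rather than
forced by the data). Passing recovery tests therefore demonstrates internal
consistency of the estimators under a plausible hierarchical model, not
robustness to those real-data artifacts. One consequence of deep, even
sequencing of a 500-taxon pool is that many *background* taxa are detected
nearly everywhere, so synthetic core-microbiome counts run much higher than
field surveys typically report; the planted-core recovery tests are
therefore phrased in terms of the planted blocks, not total counts.

## Numerical and design details

- Permutation ties count as exceedances (`F_perm ≥ F_obs − 1e-12`); a
  numerically zero PERMANOVA residual yields F = ∞ so ties remain
  exchangeable in degenerate fixtures.
- Integer counts are enforced before rarefaction; exactly-integral floats
  are coerced, anything else is an error naming the offending cell.
- BIOM support is JSON 1.0 (dense and sparse) behind the same reader
  interface as TSV; JSON reports carry a `schema_version` field.
- Per-stage seeds derive from the global seed by stage-name hashing
  (`stage_seed`), all below 2³¹.
- Test problem sizes: calibration batteries use 200 replicates at
  m = 199 permutations with 10–24 samples; recovery tests run the full
  135-pair default design; the headline-contrast property uses 50
  generator replicates with R² point estimates (m = 1 — the comparison
  needs no p-values).
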