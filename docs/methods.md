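# Methods

## Data model

A cohort is a samples × CpG-unit matrix of methylation fractions in
[0, 1] with an explicit missing mask, plus per-sample metadata (case /
control, control subtype, prior-tumour history, grade, stage, urinary
leukocyte count). A *CpG unit* is one or more neighbouring CpG
dinucleotides measured as a single value because they share a mass
fragment in EpiTYPER mass spectrometry; its canonical name is
`<amplicon>_CpG_<i[.j[.k]]>`, with numeric amplicon labels zero-padded to
two characters so the compact literature notation (`2_6`) and the
canonical form (`02_CpG_6`) name the same unit. The compact group
notation `"<amp>_<unit> and <unit> …"` is parsed and emitted by
`parse_target_notation` / `format_targets`. All tables are tab-delimited
UTF-8 with `NA` as the only missing token; write→read round-trips are
value-exact.

Exclusion rules are strict inequalities: specimens with more than
500 leukocytes/µL are removed (leukocyte DNA dilutes methylation;
specimens without a count are kept, since absence of evidence is not
exclusion), and CpG units with a missing fraction strictly above 5% are
dropped before imputation.

## Imputation

For a unit with missing cells, amplicon mates are ranked by |Pearson r|
on pairwise-complete observations (ties broken by column order; a mate
needs ≥ 3 jointly observed samples — an OLS degeneracy guard). For each
missing cell the best mate observed in that sample donates: one least
squares line per (target, donor) pair is fitted on their jointly observed
samples and its prediction, clipped to [0, 1], substitutes the value.
Ranking by *absolute* correlation is deliberate — a strong negative linear
relation predicts equally well. If no mate is observed for the sample the
target's observed mean is used, flagged in the imputation log. A unit
with no observed values at all is an error. Observed cells are never
touched, so imputation is idempotent. Whether the original workflow refit
the line per missing cell or per pair is unstated; this implementation
fits once per (target, donor) pair.

## ROC calibration

The classification rule is `value > t ⇒ positive`; the positive direction
is fixed to hypermethylation (the markers are hypermethylated in tumours)
and never auto-detected. Candidate thresholds are the distinct observed
scores plus ±∞ sentinels; duplicate operating points are merged keeping
the largest finite threshold, so published cut points remain directly
usable without interpolation conventions. Calibration at a specificity
floor (default ≥ 0.95, inclusive at the boundary false-positive count)
selects the point maximizing sensitivity, ties towards higher
specificity, then larger threshold. AUC is the Mann–Whitney probability
with ties counted half (computed via `sklearn.metrics.roc_auc_score`;
tests cross-check it against exhaustive pair counting). The floor is a
guarantee only on calibration data; on fresh controls the achieved
specificity fluctuates binomially around the (slightly conservative)
calibrated operating point, which the test suite checks against the exact
binomial 99% interval.

## Selection engines

**Cross-validated evaluation.** Stratified k-fold (default k = 10); in
each fold's training portion the majority class is randomly down-sampled
to the minority size before fitting, while held-out folds keep their
natural composition. Held-out predictions are pooled over folds into one
confusion table rather than averaging per-fold ratios: each sample then
contributes exactly once and the specificity estimate does not degrade
when a fold holds few controls — with 100 controls and k = 3, per-fold
specificity rests on ~33 controls and its noise destabilizes the argmax
over the elimination trace.

**Tuning.** Exhaustive grid search, every point scored on the identical
CV partition; ties resolve to the smaller model (fewer boosting rounds,
then smaller depth / smaller mtry). Default grids — forests:
mtry ∈ {1, 2, 3, 5, 8} at 500 trees; boosted trees:
rounds ∈ {6, 10, 25, 50, 100} × depth ∈ {1, 2, 4, 6} at learning rate
0.3. The grids cover the winning settings reported for the original
cohort (mtry 2–3; rounds 6–10 at depth 2–4).

**Importance.** Forests: mean decrease in accuracy with permutation on
*out-of-bag* samples — for each tree, accuracy on its out-of-bag rows is
compared before and after shuffling one feature (one shuffle per tree by
default; the trees supply the averaging). Out-of-bag evaluation is
essential: on training rows an overfit forest memorizes noise columns, so
permuting them costs as much accuracy as permuting genuine markers and
elimination order becomes arbitrary. Boosted trees: total split gain per
feature normalized to sum to one; features unused by any split score
exactly zero.

**Recursive feature elimination.** Per iteration: tune on the current
feature set, retrain on the whole cohort at the tuned settings, compute
importance, and drop the least important feature — for boosted trees, all
zero-importance (unused) features drop in the same step; for forests,
ties break to the earliest column. The loop runs until no feature is
left; the feature set of the trace record with the best criterion value
is selected, ties towards fewer features. With a single-point grid the
tuning step is criterion-free, so the accuracy- and specificity-optimized
selections can be derived from one trace; the pipeline does this and the
equality with two independent runs is asserted in tests.

**LASSO.** Features are standardized; a 50-point geometric penalty path
descends from λ_max = max_j |x_jᵀ(y − ȳ)|/n (the smallest penalty that
zeroes every coefficient) over three decades. k-fold cross-validated
binomial deviance selects the *largest* λ within one standard error of
the minimum; features with non-zero coefficients in the full-data fit at
that λ are selected. Fits use liblinear with C = 1/(nλ) and a large
intercept scaling so the intercept is effectively unpenalized. No
down-sampling and an unweighted likelihood, matching the procedure this
implements.

## Validation

A previously selected feature set is validated with fixed
hyperparameters (no nested re-tuning): controls split ⌊2n/3⌋ train /
remainder test (111 controls → 74/37), cases randomly subsampled to the
same absolute counts, so every split is balanced. Per split, accuracy,
sensitivity, specificity and AUC are computed on the test set; predicted
case-probabilities from all splits are pooled into one ROC, yielding the
pooled AUC and the sensitivity at the specificity floor. LASSO-selected
sets are validated with an unpenalized logistic model.

## Consensus and or-panels

Candidates are the intersection of all selected sets. A panel is a set
of (CpG, threshold) pairs with the rule *positive iff any member's value
strictly exceeds its threshold* — monotone by construction: panel
sensitivity ≥ every member's, panel specificity ≤ every member's. All
2^k − 1 subsets (capped at k = 20) are evaluated, ranked by overall
specificity then sensitivity; panels under the floor stay in the report
but flagged. The best panel maximizes sensitivity among floor-satisfying
panels, ties towards higher specificity, then fewer members. Metrics are
also stratified by prior-tumour history for cases *and* controls
(urological controls may carry a history; population controls by
definition do not); an empty stratum reports NaN, never zero.

`methylpanel.published` freezes the original study's printed selection
lists, panel report and decision thresholds (0.435 for 02_CpG_6/*ALOX5*,
0.465 for 35_CpG_7/*TRPS1*). Re-running the package's set arithmetic and
ranking on those printed inputs reproduces the published consensus
{02_CpG_6, 35_CpG_7, 78_CpG_2.3}, the overlap counts (7 shared BT
targets, 42 shared RF targets) and the published best panel
({02_CpG_6, 35_CpG_7}: 61% sensitivity at 95% specificity). The printed
CpG-count discrepancy in the source (65 retained units vs "64 potentially
diagnostic sites") is left to the data: retained counts are always
computed from realized missingness, never hard-coded.

## Synthetic cohorts

`synthetic_data.generate` draws values from a latent Gaussian factor
model mapped through the inverse logit: unit *c* of sample *i* has latent
`b_c + s·(√ρ f_{i,a(c)} + √(1−ρ) ε_{i,c}) + δ_{i,c}` with one standard
normal factor per amplicon, baseline `b_c` uniform on the logit of
[0.15, 0.45], latent scale *s* = 1 and within-amplicon correlation
ρ = 0.7. Planted units get δ = effect_size in cases (default 1.5, the
shift implied by a per-marker AUC of ~0.85), multiplied by
history_attenuation (default 0.5) for the 40% of cases under
surveillance for a prior tumour — recurrences are small and shed little
DNA. Missingness is completely at random (default 1% per unit; by
default five units are raised to 10% so the >5% exclusion rule has work
to do). Metadata mirrors the study: ~40/111 of controls are population
controls (never with tumour history), urological controls carry history
at rate 0.3, leukocyte counts stay below the exclusion bound. The
default cohort is 251 cases / 111 controls over 10 amplicons of 7 units.

What the generator does *not* emulate: mass-spectrometric error
structure, leukocyte-dilution mechanics, informative missingness, or
real between-amplicon correlation structure. Passing tests therefore
demonstrate the correctness and stability of the *procedure*, not
clinical performance on real urine.

`make_imputation_fixture` builds a 12-sample cohort in which one unit is
an exact affine function (y = 0.5x + 0.1) of an amplicon mate and missing
where x = 0.6, so imputation accuracy is checkable to 1e-9.

## The reduced study profile

`pipeline.scaled_study_config` fixes the conditions for routine
end-to-end experiments: 65 units over 10 amplicons
(1 + 1 + 1 + 9·6 + 8), 200 cases / 100 controls, effect 1.5,
single-point grids (mtry 3 at 30 trees; 10 rounds at depth 2), 3-fold
CV, 50 validation splits. The three planted markers occupy the
single-unit amplicons deliberately: a unit sharing an amplicon with a
shifted unit is *conditionally informative* — regressing out the shared
factor raises the effective shift from δ to δ/√(1−ρ²) — so selectors
legitimately co-select such siblings, and only with singleton amplicons
does the planted set coincide with the full recoverable signal.

Under these frozen conditions the five-selector consensus equals the
planted set in 16 of 20 seeds. The four misses are genuine method
behaviour, not defects: specificity-optimized boosted-tree selection
sometimes finds its cross-validated optimum at a one- or two-marker
panel (maximizing specificity intrinsically favours minimal,
conservative panels), and with 100 controls one noise amplicon's latent
factor occasionally acquires a chance association with the label that
all of its units inherit coherently — real in-sample signal that every
selector picks up, polluting the intersection. Both effects shrink with
cohort size and both are worth knowing about before trusting a consensus
set from a cohort of this size.

## Known limitations

* Exhaustive panel enumeration is exponential and capped at 20
  candidates; consensus sets are small by design.
* The per-CpG thresholds are calibrated and evaluated on the same cohort
  in the pipeline's report; out-of-cohort operating points need external
  validation data.
* The forest out-of-bag importance relies on scikit-learn's internal
  bootstrap-index helpers (wrapped with a signature-compatibility shim).
* Determinism is guaranteed per platform/library-version; cross-version
  bit-identity of tree ensembles is not.
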