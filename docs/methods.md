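# Methods

This note documents the statistical procedures implemented in
`markerforest`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the numerical conventions used where a choice had to be made.

## Data model

A `FeatureMatrix` holds nonnegative normalized abundances of mass features
(rows) across samples (columns) plus an explicit boolean missing mask.  A
mass feature is identified as `FRACTION_RETENTION_MZ` (e.g.
`POL_3402.72_191`): the chemical fraction (VOC — headspace volatiles, POL —
polar soluble extract, SOL — hydrolysed solid residue), the retention time
(VOC, minutes) or retention index (POL/SOL, unitless), and the nominal m/z.
One compound typically yields several redundant mass features through
electron-impact fragmentation; an optional `compound_group` key links them.
Missing cells carry no abundance (`NaN`) until imputation; after imputation
the original mask is retained as provenance.  In the delimited-text dialect,
an empty cell, `NA`, and — by default — a literal `0` all denote missing,
because exported instrument tables conflate "not detected" with zero.

## Pipeline stages and conventions

**Normalization.**  `value / (sample_amount × istd_abundance)` per sample.
The two divisors (sample weight in mg or g, internal-standard abundance in
arbitrary units) enter as a simple product, which makes normalization
commute with global rescaling; units are declared once per matrix and
treated as opaque scalars.

**Replicate averaging (100 % rule).**  Technical replicates of a batch are
averaged arithmetically, but only when the feature is observed in *every*
replicate of that batch; otherwise the batch value is "not detected".  This
conservative rule removes signals at the edge of detectability.

**Detection limits and imputation.**  The per-fraction detection limit is
estimated as the minimal observed normalized abundance of that fraction.
The estimate is taken on the *full replicate-level* matrix — all features,
all samples — before any feature filtering or batch averaging, for two
reasons: censoring physically operates on individual chromatograms, and the
post-averaging minimum is biased upward (batch means that survive the 100 %
rule average values that all cleared the limit), by ~50 % in sparse
fractions.  Missing cells are then replaced by their fraction's limit
(left-censored imputation); the operation is idempotent.

**Minimum-observation filter.**  A feature is kept when it has ≥ 10
observations over the complete replicate-level sample set *and* is observed
in 100 % of the samples of at least one class.  Applied before batch
averaging: a marker unique to an 8-batch class has 40 replicate
observations but only 8 batch observations.

**ANOVA ranking.**  One-way fixed-effects F-test per feature on the imputed
matrix, pass at p < 1e-5.  Deliberately used for ranking only: no normality
or homoscedasticity checks and no multiple-testing correction, as the
p-values never support inferential claims.  Features without any variance
are flagged degenerate and never pass (they are uninformative, not
"insignificant").

**Redundancy reduction.**  Same-fraction features whose retentions differ by
≤ 1.0 (RI units / minutes) and whose jointly observed values correlate at
Pearson r ≥ 0.8 are single-linkage grouped.  Both thresholds are exposed in
the configuration; they are this package's defaults, not values with an
external source.  Per group the most significant member is kept, ties broken
by fewest missing values, then lexicographic feature id.

**Repeated random forests.**  Classification forests (scikit-learn) with
10 000 trees and mtry = min(500, p) by default, trained on a random half of
the samples (stratified by class, so small classes are always represented;
unstratified draws are available and fail hard after bounded retries if a
class is never covered).  Per repeat the held-out half yields (i) a
confusion matrix and (ii) permutation MDA: the drop in held-out accuracy
when one feature's column is shuffled, averaged over a configurable number
of permutation rounds and computed via one stacked prediction per round so
the iterated selection loop stays fast.  MDG is the impurity importance of
the fitted forest.  Aggregation reports per-feature mean ± SE of both
measures over repeats, ranks by mean MDA (ties lexicographic), and the
Pearson r² between the two aggregated measures; a stability check declares
the aggregate converged when successive r² values differ by ≤ 0.01 and the
top-10 rank sets coincide (both tolerances are package defaults).

A property worth knowing: with perfectly redundant markers and error-free
classification, held-out permutation MDA is identically zero — permuting
one feature never hurts while its partner is intact.  MDA is therefore a
measure of *marginal* necessity; graded MDA values require imperfect
redundancy or imperfect separation, as in the processed-food scenario.

**Take-the-top-variable-out selection.**  Iteratively: train the repeated
forests on the remaining features, record the mean overall held-out error,
select the rank-1 MDA feature plus every same-compound feature within the
top-30 window, remove them, and stop once the error exceeds 33 % (or after
12 iterations, or when < 2 features remain).  A nonpositive ceiling stops
after the first iteration.  During this loop mtry should stay well below p,
mirroring the regime where thousands of candidate features exceed the
per-node search width; with mtry = p the deterministic split choice masks
redundant partners completely and they are never co-removed.

**Confusion aggregation.**  Per model and class, FNR = FN/(FN+TP) over true
members and FDR = FP/(FP+TP) over predicted members; averages and maxima
across models, overall error as percent mean ± sample sd.  A class never
predicted by some model has an undefined FDR there; such models are excluded
from that class's FDR average and counted (`n_fdr_defined`) rather than
treated as zero.

**Min/Max ratio.**  After detection-limit substitution,
`min(target-class values) / max(all other values)` per feature and target
class.  The statistic is invariant under global rescaling (limits
recomputed) and equals 1 for an all-missing feature.  Ratios are computed on
the batch-averaged matrix.  Marker selection pools (compound, class) best
ratios into a single ranking and keeps the top 15 above 10-fold; pooling —
rather than a per-class quota — is the natural reading when classes differ
in marker richness.

**Rule trees.**  Depth ≤ 3 threshold rules fitted by exhaustive search at
each node over candidate features and midpoints between consecutive
observed values, minimizing training misclassifications; a node is split
only if that strictly reduces errors (ties prefer fewer rules, then the
earlier candidate feature).  Thresholds therefore lie strictly between two
observed values; the midpoint convention is this package's choice.

**Correlation screen.**  Pearson r between feature abundance and the
percentage of added ingredient, over samples with a known percentage; pass
at r² > 0.450.  Undefined correlations (zero variance) are flagged and
excluded from pass lists, not coerced to zero.

**PCA overview.**  Impute → per-feature ratio to the median across all
samples → log10 → mean-center per feature → PCA without variance scaling.
Explained variance is reported in percent.  The median is taken across all
samples even when a subset is plotted; a zero median is a hard error since
the ratio is undefined.

## Synthetic data

`generate_seed_dataset` emulates a three-class raw-seed study:
chia/linseed/sesame with 12/8/8 independently sourced batches (28 total) and
5 technical replicates each.  Compounds fall into four categories — per
class one *unique* marker (mean 20× its fraction's detection limit in-class,
absent outside) and one *enriched* marker (5-fold lower outside), 30
*shared* background compounds (log-uniform means at 5–100× limit, identical
across classes) and 20 *noise* compounds whose means are log-uniform at
1–4× the limit.  The near-limit noise cloud is deliberate: real GC-MS
matrices crowd the detection limit, which is what makes the
minimal-observed-abundance estimator a good limit estimate; without it the
estimator overshoots.  Every compound is rendered as redundant co-eluting
features (first response factor 1.0, further fragments at 0.3–0.9) and
values are products of the class mean with lognormal batch, replicate and
feature noise.  Values below the fraction limit become missing
(left-censoring).  With all sigmas at zero the matrix is exactly the mean ×
response products, giving closed-form Min/Max ratios used as test oracles.

Noise scales: σ_batch = 0.15, σ_replicate = 0.10, σ_feature = 0.05 (natural
log).  The batch scale is set so that the batch-level *minimum* of a marker
planted at 20× the limit remains comfortably above the 10-fold selection
threshold across 8–12 batches (the minimum of n lognormal draws sits
exp(−E[max z]·σ) below the mean); a substantially larger batch CV would be
incompatible with the marker-gap design the generator is meant to realize.

`generate_cookie_dataset` mixes a wheat-cookie background (40 compounds,
identical across classes) with the seed compounds scaled by the added
percentage: 93 profiles — control n = 5, chia 28, linseed 30, sesame 30 —
from flour additions at 5/10/15/20 % and whole-seed additions at 10/20 %,
POL fraction only (the processed-food iteration profiles a single
fraction).  One unique marker per class is heat-labile and lost in baking,
which is why processing-dependent markers matter: each class also gains one
*processing product* whose abundance is proportional to the added
percentage.  Noise here is σ_batch = 0.05 and σ_replicate = 0.15: each
bakery product is pooled and ground before analysis, so aliquot
(replicate) noise dominates and the per-product factor is small.  This also
keeps the scenario honest for selection: with a large per-product batch
factor, forests learn product signatures from background compounds through
replicates shared between training and held-out halves, and the selection
error never crosses the 33 % ceiling.

What the generator does *not* emulate: chromatographic drift, co-elution
interference beyond redundancy groups, realistic mass spectra,
retention-index calibration error, or correlated missingness beyond
left-censoring.  Passing recovery tests therefore show that the statistics
identify the planted structure under the stated noise model — not that they
are robust to every artifact of real chromatography.

## Problem sizes in tests and the acceptance script

The spec-level defaults (10 000 trees) are kept as API defaults; the test
suite and `scripts/acceptance.py` run the same procedures with 150–300
trees, 5–12 repeats and matrices of one to two hundred features — sizes at
which the forests' behaviour on these data is already stable, chosen so the
full suite completes in about a minute.  The take-top-out runs use
mtry = 14 ≪ p for the reason given above.  All randomness flows from a
single integer seed; repeated runs are bit-identical.

## Known limitations

- Min/Max yields only "positive" markers; a compound absent from exactly
  one class is invisible to it.
- Permutation MDA under-ranks perfectly redundant features (see above);
  the take-top-out loop compensates by re-ranking after each removal, but a
  compound can require two iterations when its partner is masked.
- The iterative RF selection is not exhaustive: percent-correlated general
  markers can be overlooked (the correlation screen exists for exactly this
  gap, and the acceptance workflow augments the final matrix with its top
  hits).
- No hyperparameter tuning of the forests, no FDR control on the ANOVA
  ranking, and no nonparametric test alternatives — all deliberately out of
  scope.
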