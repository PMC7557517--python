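# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the limits of what the package's
self-checks demonstrate.

## Location classes and recoding

Source records carry nine location codes. Analysis uses four classes in a
fixed reporting order — HOME, STREET, PUBLIC, OTHER — because the rarer
codes (farm, recreation, industry, school, and the home/apartment
distinction) are individually too sparse to predict. The collapse is:
home, apartment, mobile home → HOME; street/highway → STREET; other public
place → PUBLIC; recreation, industry, school, farm → OTHER. Farm has no
canonical destination; OTHER is the conservative choice (it is not
residential, and at <1% prevalence its placement cannot matter much), and
the map is configurable. Unknown-level covariates (race "not stated",
intent "unknown") are retained as explicit levels and never imputed — only
the location code is modeled.

## Text features

*Tokenizer.* Narratives are uppercased; digit runs collapse to a single
`<NUM>` placeholder (so ages and dates cannot enter the vocabulary);
alphabetic runs are kept in order; punctuation separates tokens.

*Vocabulary filters.* A term survives in a corpus if its total count is at
least `min_count` (default 10) **and** its document fraction is at least
`min_doc_fraction` (default 0, i.e. disabled — a literal "1% of records"
document filter is far more aggressive than a count-10 filter at
surveillance scale and would leave implausibly few terms, so the count
filter is the binding default; both are config-exposed). The **shared**
scope is the intersection of the two corpora's survivors, the **all**
scope their union. Shared-scope features guarantee by construction that
the classifier's columns exist in both the fitting domain (coded records)
and the application domain (missing-code records).

*TF-IDF.* entry(d,t) = tf(t,d) · ln(N/df(t)), document frequencies frozen
from the fitting corpus (the training split), no smoothing — a term in
every fitting document receives idf exactly 0 — and rows L2-normalized
(all-zero rows stay zero). An in-vocabulary term never seen in the fitting
corpus is assigned df = 1 and logged. A smoothed-idf variant and an
unnormalized variant are config-exposed.

*n-grams.* Unigrams plus adjacent bigrams (`A_B`), passed through the same
frequency filters and the same TF-IDF weighting.

*Embeddings.* GloVe — weighted least-squares factorization of the log
co-occurrence matrix, min(1, (x/x_max)^α) weighting — trained on the
pooled corpus (unsupervised, so pooling coded and missing-code narratives
leaks no labels). Defaults: symmetric window 5 with 1/distance weighting,
dimension 50, 15 epochs of full-batch AdaGrad (learning rate 0.05),
x_max = 10, α = 0.75, deterministic given the seed. Documents are the
unweighted mean of their in-vocabulary token vectors; a document with no
in-vocabulary tokens becomes the zero vector and is logged.

## Classifiers and evaluation

Coded records are split 70/30 by simple random sampling (sizes round(0.7n)
and the remainder; a stratified-by-class option exists but is off by
default, matching plain random sampling). Four families are supported:

| family | implementation | default grid |
|---|---|---|
| lasso multinomial | L1 multinomial logistic regression (saga) | C ∈ {0.3, 1, 3} |
| SVM | one-vs-rest linear SVM + Platt scaling | C ∈ {0.3, 1} |
| feed-forward net | 1 hidden layer (32 units), adam, early stopping | single point |
| boosted trees | gradient-boosted trees, softprob | depth 3, 100 rounds |

Hyperparameters are chosen by 5-fold stratified CV maximizing mean fold
accuracy, macro one-vs-rest AUC breaking ties, then the model is refit on
the full training split. Class probabilities are always reported in the
fixed class order; argmax ties break to the earlier class. Evaluation
derives accuracy and per-class precision/recall from the 4×4 confusion
matrix (these identities are asserted on every report, not sampled), and
AUC is the macro average of the one-vs-rest ROC areas over classes present
in the test set. An empty predicted column yields precision 0 with a
warning. The grid runner produces the 4 × 6 (family × scope/construction)
table and flags the best cell by test accuracy with AUC tie-break.

The feed-forward net uses learning-rate 0.01 with adam: at the package's
desk scales the library default (0.001) can stall under early stopping
before the loss starts moving, which surfaces as majority-class collapse.

## National estimation

Every record gets a location — observed where coded, predicted by the best
model where missing (provenance retained). The per-location estimate is
Σ case weights / number of calendar years in the configured range
(including years a hospital contributed nothing); shares are over reported
rows, so the adjusted (4-class) and unadjusted (4-class + UNKNOWN) tables
conserve total mass exactly.

*Hospital-replacement correction.* Mid-series replacement of a low-volume
hospital by a high-volume one inflates weighted counts from the event year
onward. The correction rescales the affected hospital's case weights in
each post-event year by (prior-year weighted level)/(that year's level),
returning its expected annual contribution to the pre-event level; factors
are logged for audit, and other hospitals are never touched. Rescaling
weights (rather than deleting or imputing record rows) has the same
expectation and keeps the record set intact.

*Bootstrap.* "Survey + model" variance is realized as a stratified-PSU
bootstrap: each replication resamples hospitals with replacement within
stratum (a single-PSU stratum enters as fixed, with a warning), refits the
preferred model at its already-selected hyperparameters on the resampled
coded records, re-predicts the resampled missing records, and recomputes
the estimates; CIs are percentile intervals (normal-approximation not
implemented). Hyperparameter re-selection is *not* repeated inside
replications, and by default the featurization (vocabulary and document
frequencies) is frozen from the original data with only the classifier
refit per replication — vocabulary refitting is available via
`refit_vocabulary=True` and changes little at these scales, since the
frequency filters select nearly the same terms in every resample. Within
bootstrap replications the lasso runs at a looser tolerance (1e-3, 200
iterations); at these problem sizes it reaches the same solutions as the
strict setting.

*χ² comparison.* The adjusted and unadjusted location distributions are
compared by Pearson χ² on counts rescaled to the unweighted sample size
(effective-n convention; population-scale weights would otherwise inflate
the statistic arbitrarily), df = 3, two-sided, α = 0.05. The unadjusted
UNKNOWN mass is dropped and renormalized by default (pooling into OTHER is
an option). The χ² here answers "did adjustment move the distribution more
than sampling noise at the observed sample size would" — a descriptive
convention, since the two distributions share records.

*Stratified tables.* Within-location weighted estimates and shares by
intent, race, or sex, for adjusted and unadjusted modes.

## Synthetic worlds

The generator emulates the surveillance structure the pipeline targets.
Defaults (the package's study conditions): 20 000 records, 23 years
(1993–2015), 100 hospitals in five strata (volume shares small 4.0%,
medium 6.5%, large 14.5%, very large 71.7%, children's 3.3%, matching the
published sample margins), true location shares (0.30, 0.50, 0.15, 0.05),
~45% missingness, 3% BB-gun/non-GSW exclusion flags.

* **Narratives** are bag-of-token samples: an age/sex prefix
  (`24YOM GSW ...`), 5–9 tokens each drawn from a location-indicative list
  (probability 0.35 per slot; disjoint lists per class, e.g. HUSBAND /
  BEDROOM for home, DRIVEBY / CAR for street, STORE / BAR for public,
  HUNTING / SCHOOL for other) or a shared background list (SHOT, GSW, PT,
  ...), plus occasional intent tokens (ASSAULT, ACCIDENTLY/ACCIDENTALLY,
  SELFINFL) and a body-part token. This is deliberately not linguistic
  realism; it reproduces the *statistical* situation — a location signal
  carried by a modest set of indicative terms against a shared background.
* **Covariates** are drawn conditionally on location (street injuries
  ~88% assault; home injuries split assault/unintentional with more
  self-harm; race/sex mixes location-dependent; age, disposition, body
  part near the published margins) so that covariate-driven missingness
  induces genuine location-dependent selection.
* **Case weights** are lognormal by stratum, larger for low-volume strata,
  independent of location given stratum.
* **Missingness** is Bernoulli from a logistic model on stratum, intent
  and body part; the intercept is solved by bisection so the realized rate
  hits the 45% target. The default mechanism omits the true location —
  missingness is then ignorable given the text, which carries the
  location signal — and a non-ignorable mode adds direct location effects
  (street +1.2, home −0.8 logits) to demonstrate the known-records-only
  estimator's bias. The masking step never alters narratives.
* **Replacement events** multiply a hospital's annual volume from an event
  year onward (extra records resampled from that hospital-year with fresh
  ids, Poisson counts, truth propagated), logging the events so the
  correction can be scored.

All randomness flows from the single config seed. Per-stage seeds in the
pipeline derive from the global seed by hashing the stage name, so stages
can be rerun in isolation.

## What the self-checks do and do not show

Recovery and coverage are demonstrated on the generator's easy regime:
disjoint indicative vocabularies give classifiers 95%+ accuracy, so the
adjusted estimator's bias is small by construction and the experiments
verify the *plumbing* (featurization, fitting, imputation, weighting,
variance propagation), not classification difficulty. Real narrative text
is harder (misspellings, shared location terms across classes, narratives
with no location cue); accuracy there is an empirical question the
package answers on whatever data it is given, not a property these tests
establish. Likewise the bootstrap-coverage experiment (100 worlds of
1 500 records, B = 200, checking the street-share CI) uses worlds without
PSU-level location effects; strong hospital-level clustering of locations
would stress the PSU bootstrap differently.

Problem sizes used by the shipped experiments: the recovery study runs at
the full default scale (n = 20 000) in ignorable and non-ignorable modes;
the CI example world uses n = 5 000 with B = 200; the coverage experiment
uses 100 worlds of n = 1 500 with B = 200 (coverage is a proportion and
does not depend on world size; these sizes keep the whole experiment in
the minutes range on one CPU).

## Known limitations

* The bootstrap treats the within-stratum PSU draw as the only design
  stage; finite-population corrections and Taylor-series linearization
  are out of scope.
* Calibration of predicted probabilities is not analyzed beyond
  normalization; class-share estimates use hard argmax assignments, not
  probability mass (with ~97% imputation accuracy the difference is
  negligible, but it would matter near the decision boundary).
* The χ² convention (effective-n scaling, shared records between the two
  distributions) is descriptive, not a strict two-sample test.
* Time trends are intentionally not modeled or reported; annual volumes
  enter only through the mean-annual divisor and the replacement
  correction.
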