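# injloc

**Classify where nonfatal gunshot injuries happen from emergency-department
narratives, and turn the classifications into survey-weighted national
estimates.**

## The problem

National firearm-injury surveillance (NEISS-FISS: a stratified probability
sample of ~100 US emergency departments, 1993–2015, with case weights that
scale visits to national counts) records where each gunshot injury occurred
— home/apartment, street/highway, other public place, or other — but almost
half of the location codes are missing. Estimates built only from coded
records are misleading if missingness is related to where the injury
happened. Every record does, however, carry a free-text coder narrative
("24YOM GSW L LEG DRIVEBY ..."), and that text is highly informative about
the location.

`injloc` implements the full analysis for epidemiologists and injury
researchers:

1. **Featurize** narratives with TF-IDF (tf·ln(N/df), L2-normalized rows),
   unigram+bigram n-grams, and corpus-trained GloVe embeddings, over either
   the *shared* vocabulary (terms surviving frequency filters in both the
   missing-location and coded corpora) or the *all* vocabulary (their
   union).
2. **Classify** the four-class location with multinomial models — lasso
   (L1) multinomial logistic regression, one-vs-rest linear SVM with Platt
   scaling, a single-hidden-layer feed-forward network, and gradient-
   boosted trees — each tuned by 5-fold cross-validated accuracy on a 70/30
   train/test split of the coded records, and compared on a
   4 family × 6 feature-set grid (accuracy, per-class precision/recall,
   macro one-vs-rest AUC).
3. **Impute** the missing codes with the best model and combine predicted
   and observed locations with the case weights into mean annual national
   estimates per location, ŷ_ℓ = Σ_i∈ℓ w_i / (number of years).
4. **Quantify uncertainty** with a stratified-PSU bootstrap: hospitals are
   resampled with replacement within stratum and the classifier is refit
   inside each of the (default 500) replications, composing survey
   sampling variance with model variance; 95% CIs are percentile
   intervals.
5. **Diagnose selection**: Spearman correlation of ranked word frequencies
   and top-k vocabulary overlap between the missing and coded corpora, and
   the highest-|coefficient| words per location from the sparse model.
6. A χ² test compares the adjusted and unadjusted location distributions
   on effective-sample-size-scaled counts.

Because real surveillance microdata are restricted, the package ships a
first-class **synthetic world generator** with known ground truth —
location-conditional narrative vocabulary, covariates correlated with
location, a stratified PSU design with case weights, covariate-dependent
(~45%) missingness in ignorable and non-ignorable modes, and mid-series
hospital-replacement volume jumps with a prior-year-level correction — so
every estimator can be scored against truth.

## Worked example

```python
from injloc import GeneratorConfig
from injloc.studies import analyze_world

res = analyze_world(GeneratorConfig(n_records=5000, years=(2000, 2009), seed=7))
print(f"masked location codes : {res['masked_fraction']:.1%}")
print(f"test-set accuracy     : {res['test_accuracy']:.3f}")
print(f"imputation accuracy   : {res['imputation_accuracy']:.3f}")
print(f"{'location':8s} {'true':>6s} {'adjusted':>9s} {'known-only':>11s}")
for c in ("HOME", "STREET", "PUBLIC", "OTHER"):
    print(f"{c:8s} {res['true_shares'][c]:6.3f} "
          f"{res['adjusted_shares'][c]:9.3f} {res['known_only_shares'][c]:11.3f}")
```

prints

```
masked location codes : 44.9%
test-set accuracy     : 0.956
imputation accuracy   : 0.977
location   true  adjusted  known-only
HOME      0.300     0.301       0.330
STREET    0.500     0.503       0.470
PUBLIC    0.150     0.152       0.151
OTHER     0.050     0.044       0.049
```

Reading: 45% of the location codes were masked; the lasso + shared-word
TF-IDF classifier labels held-out coded records with 95.6% accuracy and
the masked records with 97.7% accuracy (scored against the generator's
truth table). The text-adjusted shares recover the true population shares
to within a fraction of a percentage point, while the known-records-only
estimator overstates the home share and understates the street share —
the same qualitative distortion that motivates adjusting national
surveillance estimates with narrative text.

There is also a CLI for file-based runs:

```bash
injloc run-all --config config.yaml --seed 1 --outdir runs/demo
injloc simulate --seed 1 --outdir runs/sim     # records.csv + truth.csv
injloc diagnose --records runs/sim/records.csv --outdir runs/diag
```

`run-all` executes simulate → featurize → train → evaluate → diagnose →
impute → estimate → report, writing each stage's CSV artifacts and a
manifest (config hash, per-stage seeds, artifact checksums); reruns with
the same config and seed are byte-identical.

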