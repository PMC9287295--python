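# Methods

## Problem and scope

Statins carry the strongest guideline recommendation in atherosclerotic
cardiovascular disease (ASCVD), yet a large share of ASCVD patients have no
statin prescription, and the *reasons* — side-effects, patient preference,
clinicians deferring therapy because lipids "look controlled" — live almost
exclusively in free-text notes. `statinscope` implements the full analysis
pipeline for this problem: a deterministic structured-data phenotyping
cascade, construction of per-patient statin-mention documents from notes, a
binary use/nonuse text classifier, a two-step multiclass classifier for the
reason for nonuse, and the evaluation and reporting protocol around them.
Because real EHR extracts of this kind cannot be redistributed, the package
ships a synthetic EHR generator with exact ground truth at every stage; all
tests and the acceptance run operate on generated cohorts.

## Phenotyping cascade

Patients pass through four ordered screens:

1. **Engagement**: at least two *distinct* encounter dates carrying an
   ASCVD diagnosis code; same-day duplicates count once. The earliest ASCVD
   date is the index diagnosis; patients whose ASCVD codes span two or more
   base categories (coronary, cerebrovascular, peripheral) are polyvascular.
2. **Prescription**: a statin prescription is *active* when (a) its closed
   date interval covers the index date, (b) it starts within 30 days after
   the index date, or (c) it is open-ended and started at most 183 days
   before the index date. Calendar phrases ("1 month", "6 months") are fixed
   at 30 and 183 days, boundary day inclusive, so the rule is exactly
   testable; the generator plants ±1-day boundary prescriptions on both
   sides of each limit.
3. **Structured allergy**: any allergy substance matching the statin
   dictionary. The screen order matters: an actively prescribed patient with
   a recorded statin allergy counts as prescribed.
4. **Note screen**: any accepted statin term in a note dated within the
   closed window [index, index + 30 days] places the patient in the NLP
   dataset; otherwise the patient has no statin documentation at all.

The cascade accounting table computes each count against its parent
denominator and validates that children sum to parents at every split.

## Dictionary matching and documents

The shipped dictionary contains the drug-class generics, common US brand
names, and the bare token "statin". Matching is case-insensitive substring
matching with two safeguards: a match whose maximal alphabetic token is on
the exclusion list ("nystatin", "sandostatin") is rejected, and overlapping
candidates are resolved longest-leftmost. Sentence segmentation is
deterministic and rule-based: a terminator (`.`, `!`, `?`, or newline)
followed by whitespace and a capital/digit ends a sentence, with a guard
list of clinical abbreviations; decimals and dotted dates never split
because no whitespace follows their internal periods. The mention document
concatenates, in (note date, note id, sentence index) order, every
in-window sentence with at least one accepted match. No negation or
assertion handling is done at extraction time — polarity is deliberately
left to the classifier, which sees use and nonuse statements drawn from the
same sentence population.

## Classifiers

All models are written against a pluggable encoder-backend contract
(`fit(texts, labels, hyperparameters) -> head`, `head.score(texts) ->
P(positive)`), deterministic given the seed. The default backend is fully
self-contained: lowercased word 1–2-gram TF-IDF features feeding a linear
model trained by SGD on the logistic loss. The hyperparameter set mirrors
what one would tune for a fine-tuned contextual encoder — learning rate
(SGD initial step, default 0.5 with an adaptive schedule), number of epochs
(SGD passes, default 150, run to completion for determinism), weight decay
(L2 penalty, default 1e-5), and an Adam epsilon that only applies to
Adam-trained backends. A second self-contained backend (hashed n-grams)
exercises the backend-swap contract in tests; a `pretrained` slot exists
for a clinical BERT-style encoder behind the same contract but requires the
optional torch/transformers stack and ships unimplemented beyond the
adapter.

* **Binary use/nonuse**: one head, positive class = use documented,
  decision threshold 0.5, no calibration.
* **Two-step reason model**: five one-vs-rest heads (multi-category
  annotations are positive for each of their categories), then a
  300-tree random forest mapping the 5-vector of probabilities to a single
  final category. The forest is trained on *out-of-fold* stage-1
  probabilities (stratified k-fold, k = min(5, smallest class count)) so it
  never learns from optimistically in-sample scores. Ties in the
  reconciler's class probabilities break by the fixed category order:
  muscle, other side-effect, perceived lipid control, patient preference,
  nonspecific. Annotations with several categories reduce to a *primary*
  label — the first category in that fixed order — wherever a single target
  is needed.
* **Multilabel model**: the same five heads read independently at a 0.5
  threshold per head; an empty predicted set falls back to the argmax head.

## Evaluation and statistics

* 80/20 stratified patient split (train = floor(0.8 n)); 10-fold stratified
  cross-validation for hyperparameter selection by mean fold AUC, ties
  resolved in grid order.
* Precision, recall, F1 at threshold 0.5; AUC as the rank statistic
  (probability a positive outranks a negative, ties credited 0.5).
  Multiclass aggregation is support-weighted one-vs-rest for all four
  metrics ("weighted macro-average" read as support weighting).
* Confidence intervals: percentile bootstrap (not BCa), resampling
  (truth, score) pairs at the patient level, default B = 1000; degenerate
  one-class resamples are redrawn, and the metric is declared undefined if
  bad draws ever outnumber B.
* Cohen's kappa is computed directly from the contingency marginals so the
  degenerate conventions are explicit (perfect agreement returns 1 even
  when chance agreement is 1); tests cross-check it against scikit-learn.
* Contingency tests: Pearson chi-square without continuity correction,
  switching to the two-sided Fisher exact test for 2×2 tables with any
  expected count below 5; larger sparse tables keep chi-square with a
  warning flag.
* Odds ratios: maximum-likelihood logistic regression (statsmodels), Wald
  95% CIs, one single-covariate fit per column for unadjusted ORs and a
  joint fit for adjusted ORs. Constant covariates are dropped with a
  warning; perfect separation raises an error naming the covariate.

## Synthetic cohort: what it emulates and what it does not

The generator draws each patient's true disposition from a configurable
mixture whose defaults reproduce the published cohort-selection proportions
conditional on inclusion (60.6% prescribed, 1.4% structured allergy, 31.1%
no statin terms, 7.0% NLP dataset split 39/61 use/nonuse), on top of a 15%
engagement-screen failure slice chosen as a realistic rate for a
two-encounter rule. Reason categories among nonusers follow the published
reason distribution (muscle 16.1%, other side-effect 16.9%, perceived lipid
control 11.4%, preference 13.4%, nonspecific 42.2%); 10% of nonusers carry
two categories, mirroring the non-mutually-exclusive annotation scheme.
Note text is template-based — one template family per category, seeded by
real chart excerpts, mixed with statin-free distractor sentences
(Poisson-distributed, mean 3 per note) and "nystatin"-style trap sentences
at rate 0.15. One RNG stream is keyed by (seed, patient index) so
per-patient output is reproducible under reordering.

Because templates are designed to be unambiguous, passing tests show that
the *pipeline machinery* is correct — extraction finds exactly the planted
sentences, the cascade recovers every planted disposition, the classifiers
recover planted labels at AUCs near 1, permuted labels collapse to chance.
They do not show that any backend reaches the published discrimination
(binary AUC 0.94, weighted two-step AUC 0.88) on real clinical prose, whose
lexical variety, negation scope, and copy-forward artifacts the templates
deliberately do not model. Real-data performance claims require the
pretrained backend and access to real notes.

## Numerical and formatting choices

* Dates are day-granularity ISO-8601; all intervals closed.
* Percent formatting rounds half-up at the printed precision; cascade rows
  use whole percents for the large splits and one decimal for the allergy
  and note-screen rows, matching conventional CONSORT reporting. (The
  source cohort's "40%" for 22,296/56,530 is not reproducible under any
  fixed rounding rule — the arithmetic gives 39.4% — and is treated as a
  reporting anomaly.)
* Small-cell suppression pools any cell at or below 10 (the stricter of
  the two published phrasings) into a designated pooled column, preserving
  row and grand totals.
* End-to-end runs write JSON with sorted keys and fixed float precision so
  a fixed seed yields byte-identical report artifacts.
* Problem sizes in tests and the acceptance run: the default cohort is
  n = 2000 patients (≈ 105 NLP-dataset documents), the reason-model unit
  tests use an NLP-only cohort of n = 600, and the mixture goodness-of-fit
  check uses n = 5000 — sizes at which every stochastic assertion holds
  with wide margin while the whole suite stays fast.

## Known limitations

* The ICD/RxNorm code lists and intensity map are representative stand-ins,
  not the comprehensive lists a production phenotype would use.
* Sentence segmentation is rule-based and will mis-split prose outside its
  guard list; it is exact on generated text.
* The reconciler's out-of-fold stacking, the primary-label reduction, and
  the 0.5 binary threshold are reasonable defaults for design points the
  underlying protocol leaves open; all are explicit and configurable in
  code.
* Bootstrap CIs are percentile-based and resample the evaluation set only;
  models are not refit per resample.
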