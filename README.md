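# statinscope

EHR phenotyping and clinical-NLP pipeline for characterizing **statin
nonuse — and its documented reasons — in ASCVD cohorts**.

Statins carry the strongest guideline recommendation in atherosclerotic
cardiovascular disease (ASCVD), yet many ASCVD patients have no statin
prescription, and the reasons (side-effects, patient preference, clinicians
deferring therapy because LDL "looks controlled") are recorded only in
free-text notes. `statinscope` is aimed at clinical informatics and
cardiology outcomes researchers who want to measure this gap in their own
EHR: it combines a deterministic computable phenotype over structured data
with text classifiers over statin-mention sentences, plus the full
evaluation and reporting protocol around them.

## What it computes

1. **Cohort cascade** — every patient is routed, in order, through an
   engagement screen (≥ 2 distinct encounter dates with an ASCVD code; the
   earliest is the index diagnosis), a prescription-activity screen (active
   at index, new within 30 days, or open-ended within a 183-day lookback),
   a structured-allergy screen, and a note screen (any dictionary statin
   term within 30 days after index → the NLP dataset).
2. **Statin-mention documents** — case-insensitive dictionary matching with
   "nystatin"-style trap exclusion, rule-based sentence segmentation, and
   concatenation of matching sentences in chronological order.
3. **Classifiers** — a binary use/nonuse model; a two-step reason model
   (five one-vs-rest heads whose probability 5-vector is reconciled to one
   of {muscle side-effect, other side-effect, perceived lipid control,
   patient preference, nonspecific} by a random forest); and a simple
   multilabel variant. All run on a pluggable text-encoder contract; the
   default backend is a self-contained TF-IDF + SGD-logistic model.
4. **Evaluation & statistics** — stratified 80/20 split, 10-fold CV tuning,
   precision/recall/F1/rank-AUC with support-weighted macro-averages,
   1000-rep percentile-bootstrap CIs, Cohen's kappa, chi-square/Fisher
   tests, and unadjusted/adjusted logistic odds ratios.
5. **Reports** — cascade accounting with parent-denominator percentages,
   reason prevalence and stratified tables (by ASCVD type, race/ethnicity)
   with chi-square tests and small-cell suppression (cells ≤ 10 pooled).

Real extracts of this kind are private, so the package includes a synthetic
EHR generator (`statinscope.synthetic_ehr`) with exact ground truth at
every cascade stage; see `docs/methods.md` for what it does and does not
emulate.

## Worked example

```bash
statinscope run-all --n 2000 --seed 7 --out run/
```

generates a 2000-patient cohort, phenotypes it, extracts mention documents,
trains and evaluates the classifiers, applies them across the NLP dataset,
and writes all artifacts under `run/`. The cascade it prints:

```
screened                               2,000  /   2,000    100%
excluded: <2 ASCVD encounters            285  /   2,000     14%
ASCVD cohort                           1,715  /   2,000     86%
statin prescription present            1,026  /   1,715     60%
no statin prescription                   689  /   1,715     40%
structured statin allergy                 15  /     689    2.2%
no prescription, no allergy              674  /     689   97.8%
no statin terms in notes                 569  /     674   84.4%
statin terms present (NLP dataset)       105  /     674     16%
```

Each row counts against its parent denominator: of 1,715 engaged ASCVD
patients, 40% lack a statin prescription; of those, 2.2% have a structured
statin allergy; of the remainder, 16% (105 patients) have statin terms in
their notes and form the NLP dataset. Applying the trained models across
those 105 patients yields (from `run/reason_prevalence.json`):

```json
{
  "n_nlp_dataset": 105,
  "n_use_documented": 37,
  "n_nonuse": 68,
  "pct_use_documented": "35%",
  "reason_counts": {
    "MUSCLE": 13, "OTHER_SIDE_EFFECT": 13, "PERCEIVED_LIPID_CONTROL": 11,
    "PATIENT_PREFERENCE": 9, "NONSPECIFIC": 22
  }
}
```

i.e. 35% of NLP-dataset patients are actually using a statin (documented in
notes despite no structured prescription), and the 68 nonusers split across
the five reason categories, nonspecific documentation being the most
common. The held-out evaluation (`run/eval_report.json`) reports binary AUC
1.0 (95% CI 1.0–1.0) on this synthetic cohort — templates are designed to
be separable, so this checks machinery, not clinical difficulty.

Individual stages are also available as subcommands (`simulate`, `cohort`,
`extract`, `train`, `evaluate`) and as plain library calls.

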