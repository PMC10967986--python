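# pronocase

Grammatical-case analysis of first-person pronouns in clinical interview
transcripts, and its use for detecting suicidal ideation.

## The problem

In Cantonese (as in Mandarin), the first-person singular pronoun (FPSP) has a
single surface form, 我 — whether it means *I*, *me*, or *my* is decided by
syntax alone. Elevated FPSP use is a long-studied marker of the self-focused
attention that accompanies depression and suicidality, but the grammatical
*case* of the pronoun carries distinct psychology: a nominal subject
(subjective case, self-as-actor) is not the same signal as a direct object
(objective case, self-as-target). `pronocase` implements a complete pipeline
for studying this distinction in speaker-tagged clinical interview
transcripts from a depression cohort:

1. **corpus_io** — read transcripts (plain `INT:`/`PAR:` text or JSON-lines)
   and a participant metadata CSV; filter interviewer speech; derive binary
   clinical labels (current depression: HDRS-17 total ≥ 8; suicidal ideation:
   suicide-item rating ≥ 2 on its 1–5 scale).
2. **annotation** — tokenized, CTB-POS-tagged, dependency-parsed utterances
   (Chinese Stanford-Dependencies-style labels), with a deterministic
   template annotator for testing/synthesis and an optional HanLP adapter.
3. **features** — classify each FPSP token into subjective
   (`nsubj`/`nsubjpass`/`top`), objective (`dobj`), dative (`iobj`) or
   possessive (`assmod`, incl. the 我+嘅 genitive construction) case, and
   compute 12 feature percentages per participant: total FPSP and its four
   cases, first-person plural pronouns, verbs, prepositions, temporal nouns,
   etcetera particles, interjections, passive markers — each as
   100 × count / total tokens.
4. **stats** — crude and covariate-adjusted binomial logistic regressions.
   For feature *x* and outcome *y*, odds ratios are per percentage-point:
   OR = e^β, 95% CI = e^(β ± 1.96·SE), two-sided Wald *p*. Adjustment sets:
   {age, gender, current depression} for suicidal ideation; {age, gender,
   lifetime affective disorder} for depression.
5. **evaluation** — imbalanced-classification harness: stratified nested
   5-fold CV; SMOTE doubling of the minority (suicidal) class inside each
   training portion; grid search targeting inner-fold ROC AUC; five model
   families (logistic regression, RBF SVM, gradient boosting, random forest,
   decision tree); pooled out-of-fold scores summarized as AUC with DeLong
   95% CI and *p* vs 0.5, plus accuracy, sensitivity, specificity, PPV, NPV
   and F1 from the thresholded confusion matrix.
6. **synthetic_data** — since the clinical transcripts themselves are not
   publicly deposited, a calibrated generator emulates the cohort: 319
   participants, ~12% suicidal-ideation prevalence, near-complete depression
   co-occurrence in the suicidal group, group-conditional feature rates from
   truncated normals, and parsed token streams rendered from a template
   grammar (including pro-drop of subject pronouns).
7. **cli** — one subcommand per stage.

## Worked example

```sh
pronocase simulate --out ds --seed 42
pronocase extract  --corpus ds/corpus --metadata ds/metadata.csv --out features.csv
pronocase associate --features features.csv --metadata ds/metadata.csv --out assoc
pronocase evaluate  --features features.csv --metadata ds/metadata.csv --out eval --seed 42
```

On this synthetic cohort (319 participants, 39 with suicidal ideation) the
crude association table (`assoc/crude_associations.csv`) contains, among
others:

```
        feature  non_suicidal_mean  suicidal_mean  odds_ratio  ci_low  ci_high  p_value
 objective_fpsp              0.239          0.344       7.605   1.852   31.231    0.005
subjective_fpsp              2.079          2.096       1.013   0.757    1.354    0.933
   interjection              4.924          3.669       0.735   0.613    0.881    0.001
```

Read: each additional percentage point of objective-FPSP use multiplies the
odds of suicidal ideation by ≈7.6 (the generator plants a 0.15 pp group
difference on a feature whose within-group SD is ≈0.22 pp, so a large
per-unit OR is the calibrated truth here, not an artifact), while subjective
FPSP — whose group means barely differ — is null. `eval/model_metrics.csv`
holds the screening panel, e.g.

```
              model   auc  auc_ci_low  auc_ci_high  accuracy  sensitivity  specificity
logistic_regression 0.724       0.644        0.805     0.843        0.936        0.179
```

with sensitivity/PPV oriented toward the majority (non-suicidal) class by
default; pass `--positive-class suicidal` for the clinical orientation.

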