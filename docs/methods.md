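# Methods

This note documents the models, numerical choices and known limitations of
`pronocase`, in the order the pipeline runs.

## Labels and cohort structure

Current depression is defined as an HDRS-17 total of 8 or above; suicidal
ideation as a rating of 2 or above on the suicide-risk interview item, which
is scored on five progressive levels 1–5. The standard convention for this
item is a 0–4 scale; a `h11_zero_based` switch remaps the scale and shifts
the cut-off to ≥ 1 accordingly, so both conventions yield the same
partition. Label derivation is deterministic and monotone in both ratings.

## Case classification

FPSP tokens (surface 我 by default) are classified from their dependency
relation: `nsubj`, `nsubjpass` and `top` → subjective; `dobj` → objective;
`iobj` → dative; `assmod` → possessive. Possessive is additionally
recognized structurally whenever the pronoun governs a genitive particle
(嘅/的) while modifying a nominal, so backends that label that edge
generically still classify correctly. Because the four case percentages
must partition the total FPSP percentage exactly (an invariant the tests
enforce to machine precision), no token may be left unclassified: relations
outside the anchored set fall back to **objective** (`pobj` and all
remaining relations; conjuncts inherit their coordination head's case). The
objective default reflects the self-as-target reading of non-subject
positions; fallback use is counted per transcript so heavy reliance on the
rule is visible.

Token totals include punctuation (`PU`) by default — the denominator is
"all tokens identified" — with a `TagMap(count_punctuation=False)` switch.
The verb class is the full CTB verb family {VV, VC, VE, VA}; prepositions
{P}, temporal nouns {NT}, etcetera particles {ETC}, interjections {IJ},
passive markers {LB, SB}. All tag sets are configurable.

## Logistic regression and inference

Associations are binomial logistic regressions fit by maximum likelihood
(statsmodels Logit; Newton, BFGS fallback). Features enter on their natural
percentage scale, so odds ratios are per percentage-point increase.
Inference is Wald-based: OR = e^β, 95% CI = e^(β ± 1.96·SE), two-sided
p-values from β/SE against the standard normal. The Wald CI is symmetric on
the log-odds scale by construction.

Quasi-complete separation is a *structural* feature of this cohort (almost
every suicidal participant is also depressed), so separation produces a
flagged fit plus a `SeparationWarning`, never a refusal: a fit whose
optimizer stalls with exploding coefficients (|β| > 5 without convergence,
or |β| > 15, or non-finite SEs) is reported with the flag set. An optional
Firth (Jeffreys-prior) bias-reduced fit is available behind `firth=True`
for stable estimates under separation; the default remains unpenalized
because the extreme published interval widths indicate unpenalized fits.

Degenerate inputs fail fast with informative errors: single-class outcomes
and constant predictors are rejected before fitting.

## Evaluation harness

Stratified 5-fold outer cross-validation (per-fold class counts within ±1;
scikit-learn's stratified splitter behind the module surface). Within each
outer training portion, in order: (1) SMOTE doubles the minority class —
each synthetic sample is x_i + u·(x_nn − x_i), u ~ U(0,1), x_nn one of the
k = 5 nearest minority neighbors by Euclidean distance; majority rows are
never altered; (2) grid search maximizes mean inner 5-fold AUC, ties broken
by grid declaration order, degenerate single-class inner folds skipped with
a warning; (3) the winner is refit on the augmented training portion and
scores the held-out fold. Every sample is scored exactly once out-of-fold;
metrics are computed from the pooled scores rather than averaged per fold,
which keeps the confusion counts integer-consistent with the cohort size.

All classifiers are scikit-learn estimators wrapped in a standardization
pipeline; default grids are deliberately small (LR: C ∈ {0.01, 0.1, 1, 10};
SVM-RBF: C ∈ {0.1, 1, 10} × γ ∈ {scale, 0.1}; GB: 50/100 trees × depth
2/3; RF: 100 trees × depth {3, 5, ∞}; DT: depth {2, 3, 5, ∞}).

AUC is the Mann–Whitney statistic with half credit for ties; its variance
is DeLong's structural-component estimator, giving a 95% CI
(AUC ± 1.96·SE, truncated to [0, 1]) and a two-sided test against 0.5. The
implementation matches R's `pROC::ci.auc(method = "delong")` exactly.

The positive class for sensitivity/PPV defaults to the **majority
(non-suicidal)** class: the published screening panel is arithmetically
self-consistent only under that orientation (its accuracy, PPV and NPV
reconstruct exactly from its sensitivity, specificity and the 281/38 class
sizes), so the default reproduces that layout. For clinical use flip with
`positive_class="suicidal"`; AUC is orientation-invariant. The class
threshold is 0.5 on predicted probability (configurable); nested (per-outer-
fold) tuning is used rather than a single tuning pass on the full data.

## Synthetic data generator

The generator's defaults are the study conditions: 319 participants,
suicidal prevalence 38/319, P(depressed | suicidal) = 37/38,
P(depressed | non-suicidal) = 83/281, group-conditional age
(50.95 ± 15.24 / 53.46 ± 11.16, truncated to 18–65), gender and
lifetime-diagnosis margins, and group-conditional feature percentages with
the published per-group means/SDs. Ratings (HDRS totals, suicide-item
levels) are drawn so that label derivation reproduces the intended labels
with zero discrepancies. Transcript lengths are uniform on 500–3000 tokens,
emulating 15–30-minute interviews.

Per-participant feature rates are drawn from normals truncated at zero —
honoring the mean/SD parameterization directly rather than re-fitting a
nonnegative family — with the documented consequence that for features
whose mean is within about one SD of zero (possessive, dative, FPPP,
etcetera, passive marker, and to a lesser degree objective FPSP) the
realized mean exceeds the nominal location parameter; e.g. the cohort mean
of total FPSP comes out near 2.6–2.7% rather than the nominal 2.23%.
Depression is generated conditionally on suicidal status; age and gender
are independent of the linguistic features given group.

Token streams are rendered from the template grammar of the annotation
module: sentence templates are drawn i.i.d. with probabilities solved in
closed form so that the *expected* token composition equals the
participant's target rates (dedicated low-contamination templates per
feature, a bare-verb filler absorbing the verb budget left after the verbs
embedded in pronoun templates, and noun padding — partly punctuated —
filling the remainder). Pro-drop is emulated by a per-sentence probability
(default 0.3) of omitting the subject pronoun; the mix compensates by
inflating the subject-template intensity by 1/(1 − d), so realized
subjective rates still match their targets. Unreachable combinations (verb
rate below the verbs embedded in pronoun templates; rates exceeding 100%)
raise a generation error. Identical seeds produce byte-identical corpora.

What the generator does *not* emulate: realistic Cantonese discourse,
interviewer-question effects, correlation among linguistic features within
a participant, or correlation of features with age/gender. The last two
matter for interpretation: with independent features at the published group
separations, the joint signal is much stronger than in the real data — the
synthetic nested-CV AUCs land around 0.7–0.85, well above the published
0.54–0.57 range — so passing evaluation tests demonstrates harness
correctness and calibration, not real-world detectability.

## Simulation studies and problem sizes

Calibration checks run on the generator's rate-level fast path (cohort +
truncated-normal rates, no token rendering, which only adds multinomial
noise): 200 replicates at n = 319 for coverage of the generator-implied
crude OR, and 1000 replicates for null CI coverage of OR = 1 across all 12
features. The generator-implied OR is defined as the population logistic
projection of the generator's group-conditional law — the root of the
population score equations computed by quadrature — because truncation
means the induced P(group | rate) is not exactly logistic; with laws far
from the truncation point and equal SDs this reduces to the Gaussian
closed form exp((μ₁ − μ₀)/σ²), a reduction the tests verify.

End-to-end rendering self-consistency (generate → annotate → extract →
compare against the generator's per-participant targets) runs at 12
participants × 1500–2500 tokens, with count-scale bounds of 3 multinomial
SEs plus a +3 allowance where expected counts are so small that the normal
approximation is skewed.

One calibration property does **not** hold and is deliberately left
failing rather than weakened: over 50 label-shuffled nested-CV replicates,
the DeLong CI of the pooled null AUC contains 0.5 only ~86–88% of the
time, not ≥ 90%. The pooled null AUC is unbiased (mean ≈ 0.494), but its
empirical SD (≈ 0.064) exceeds the mean DeLong SE (≈ 0.050) by ~26%:
DeLong conditions on a fixed scoring function and cannot account for
model-refitting variance across folds, and no unbiased estimator of
cross-validation variance exists. The corresponding test documents this
known limitation of applying iid AUC inference to pooled cross-validated
scores.

## Known limitations

- The template annotator covers a fixed sentence inventory; real transcripts
  require the HanLP backend (or any backend meeting the parser contract and
  label dialect), which is excluded from the default test suite because it
  needs a model download.
- Wald intervals on quasi-separated fits are unstable by nature; the
  separation flag and the Firth option are the provided mitigations.
- No multiple-testing correction is applied across the 12 feature
  associations, matching the analysis design this package reimplements.
- SMOTE's Euclidean neighborhoods treat all 12 features on their raw
  percentage scales; features with large scales (verbs, interjections)
  dominate the neighbor structure.
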