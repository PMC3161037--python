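# Methods

## Problem and model

The package scores candidates for chemotherapy rechallenge: patients who
experienced a serious adverse drug reaction (ADR) and may be given the same
drug again. The two outcomes are *negative rechallenge* (NR — the ADR does
not recur) and *positive rechallenge* (it recurs). For a patient's
attribute vector `F = {F1, ..., Fn}` the classifier computes, under
conditional independence of the attributes given the outcome,

```
P(NR | F) = P(NR) Π_i P(Fi | NR) / [ P(NR) Π_i P(Fi | NR) + P(PR) Π_i P(Fi | PR) ]
```

* **Continuous attributes** use Gaussian class-conditional densities. The
  source method does not state its continuous-attribute treatment; Gaussian
  is the standard Naïve Bayes choice and is consistent with the published
  predictor table reporting exactly a per-class mean ± SD. Discretization
  is a possible alternative reading and is not implemented.
* **Categorical/binary attributes** use per-class category frequencies with
  additive smoothing `alpha` over the schema's full category list. The
  default is `alpha = 0` because the published probability table contains
  exact zeros (e.g. bleomycin and rituximab among positive-rechallenge
  cases), which only an unsmoothed fit produces; `alpha = 1` is the robust
  choice for real use.
* **Missing values** drop the attribute's factor from the product (a
  missing-at-random assumption); a record missing every selected attribute
  is scored at the prior. If *both* classes have zero likelihood (possible
  with `alpha = 0`), the score falls back to the prior and a
  `PriorFallbackWarning` is emitted.
* Posteriors are computed in log space; the complementary posteriors sum to
  1 to ~1e-16 and the log-space path agrees with the direct probability
  product wherever the latter does not underflow (tested at 1e-9).

Numerical guards: fitted or loaded standard deviations are floored at 1e-6
native units so a zero-variance column cannot yield a degenerate density;
sample SDs use the n−1 denominator (at the study's class sizes the printed
SDs cannot discriminate the two estimators, so the conventional one is
used).

## Decision rule and evaluation

A record is predicted negative iff `P(NR|F) > t`; a score exactly at the
threshold predicts positive, the conservative side, because the negative
call is what sanctions re-administration. Sensitivity = fraction of true
NR patients predicted NR; specificity = fraction of true PR patients
predicted PR. The ROC detection target is therefore negative rechallenge,
fixed rather than configurable to prevent a silent axis flip from
inverting a treatment recommendation. AUC is trapezoidal ROC area, which
with 0.5 credit for tied scores equals exhaustive Mann–Whitney pair
concordance; the test suite verifies this equivalence against a pair
enumeration oracle and scikit-learn. Reported tables render rates as whole
percentages; stored values keep full precision.

## Train/test protocol

`split_cohort` replicates the study's deliberately *overlapping* protocol:
from the non-validation pool, `n_train` records (24 of 35 in the original)
are sampled without replacement as the training set, while the **entire**
pool serves as the testing set that computes wrapper fitness — so training
records are also test records, and the wrapper AUC is an optimistic,
in-sample-leaning estimate. Records tagged `validation` (the study's
later-era cases) are excluded from both. This is a faithfulness choice,
not a methodological endorsement.

## Genetic-algorithm wrapper

Chromosomes are bit masks over the schema (1–L attributes, non-empty
enforced by repair: an all-zero mask gets one uniformly chosen bit turned
on). Fitness = test-set AUC of the Naïve Bayes model fitted on the
training view. Published settings, used as defaults: population 80, 100
generations, crossover rate 0.95, mutation rate 0.05, 5 restarts,
roulette-wheel selection. Where the published description is silent the
package chooses canonical operators and documents them:

* **single-point crossover** (the canonical bit-string operator of that
  era); with probability `rate`, tails are swapped at a uniform cut in
  `[1, L−1]`.
* **per-bit mutation**: the 5% rate is read per bit, giving ≈ 2.65
  expected flips on a 53-bit chromosome.
* **generational replacement** with **elitism 1** (the unmodified best
  individual survives), which makes per-run best fitness monotone;
  elitism is configurable to 0 for strict fidelity to the undocumented
  original.
* **initialization density 0.5** per bit.
* Runs `r = 0..n_runs−1` use independent generators seeded `seed + r`;
  the winner is the fittest individual over all generations of all runs,
  ties broken by fewer selected attributes, then earlier run.

Because Naïve Bayes factorizes and the train/test views are fixed during
the search, each attribute's per-class log-likelihood contribution to each
test record is precomputed once; a chromosome's fitness is then a column
sum plus an AUC, and repeated chromosomes hit a cache. This is an exact
speed-up (tested to agree with fit-then-score at 1e-12) that brings a
full-default 5-run search to seconds on one CPU.

The original study finally *refined the GA-selected subset by expert
assessment* down to 8 clinical predictors. That judgement step is manual
by nature; the package exposes it as a user-supplied subset (e.g.
`--subset age,chemo_drug,...`) and never automates it.

## Attribute schema and derivations

The study mined 53 attributes; their exhaustive catalogue was published
only in a supplement that is not available, so the default schema is a
reconstruction from the published attribute groups: 33 collected fields
(demographics, medical conditions, medications, 13 laboratory parameters),
7 individual comorbidity indicators, and 13 derived attributes — elderly
(age ≥ 65), polypharmacy (> 5 concurrent medications), comorbidity count
(over hypertension, diabetes, hyperlipidemia, psoriasis, GERD, asthma,
other allergic disorders), and abnormal-laboratory flags for 10 labs.
The schema is data (JSON-serializable), so a site can supply its exact
catalogue; age is kept both as a continuous attribute and as the derived
elderly binary, and the selector may pick either or both.

Abnormal-lab flags compare a value against a reference interval. The
original laboratory panels' ranges are unstated, so the package ships
conventional adult intervals (e.g. WBC 4–10 ×10⁹/L, albumin 35–50 g/L) as
an overridable configuration table — they are a deployment setting, not
part of the method.

The cohort file dialect is fixed for reproducibility: UTF-8 CSV, comma
delimiter, missing token `NA`, case-insensitive outcome labels, columns in
schema order with `rechallenge_status` last.

## Synthetic cohorts

`published_spec()` encodes the published testing-set descriptive
statistics: per-class Gaussians for age, albumin, RBC and platelet;
per-class proportions for nine chemotherapeutic drugs and three
abnormal-lab flags; and an inferred 17-negative / 18-positive composition.
The composition is not printed anywhere — it is inferred from the unit
fractions in the proportion columns (0.059 = 1/17, 0.056 = 1/18,
0.278 = 5/18) and is overridable. The printed drug columns sum to 1.001
and 1.002 at three decimals; the spec renormalizes each vector and the
residual (≤ 0.2%) shifts the worked-example carboplatin posterior from
0.16697 to 0.16711.

`generate_cohort` draws every attribute independently per class: the
published table gives marginals only, and the classifier assumes
independence anyway. Consequently synthetic cohorts lack the attribute
correlations, outliers, informative missingness and cohort-selection
effects of real rechallenge patients — passing tests demonstrate the
*software* recovers known distributions and known planted predictors, not
that the model generalizes clinically. Sampling is untruncated by default
so that refitting recovers the printed parameters (means within 3 standard
errors at 10⁴ records/class); opt-in physiological floors
(`PHYSIOLOGICAL_FLOORS`: age ≥ 18, labs > 0) resample out-of-range draws
at the cost of a documented mean bias (≈ +6 platelet units, ≈ +0.8 years
of age at the printed SDs). `planted_signal_spec()` builds the standard
wrapper-selection benchmark: one perfectly separating binary attribute
among class-independent N(0,1) distractors.

`published_model()` is a fixture, not a fit: the published 8-predictor
parameter table read directly into a `NaiveBayesModel` (priors 17/35 and
18/35, `alpha = 0`). The original fitted model was released only as a
hosted service, so this reconstruction stands in for it.

## Problem sizes used in checks

Distribution-recovery checks use 10,000 records per class (mean standard
errors ≈ 0.15 years for age); null-AUC checks use 300 per class; the
planted-signal selection experiment uses 100-record cohorts (50/50) with
20 noise attributes, split 70 train / 100 test under the overlapping
protocol, searched at full published GA defaults over 5 seeds.

## Known limitations

* The 53-attribute default schema is a best-effort reconstruction; the
  exact original catalogue is unrecoverable from the published text.
* The published headline validation numbers (AUC 0.767 on 11 held-out
  cases; 100%/20% and 67%/80% at thresholds 0.01 and 0.8) depend on the
  unreleased 46-patient cohort and cannot be reproduced from marginals;
  the package reports instead what the reconstructed model achieves on
  cohorts drawn from its own published class-conditionals.
* Gaussian class-conditionals are an assumption; heavy-tailed or skewed
  labs (platelet SD ≈ 150 on mean ≈ 330) are imperfectly Gaussian in
  reality.
* No probability calibration, no confidence intervals on AUC, two outcome
  classes only.
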