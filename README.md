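# rechallenge

Decision support for re-administering a chemotherapeutic drug after a
serious adverse drug reaction (ADR).

When a cancer patient suffers a serious ADR, clinicians must often decide
whether to *rechallenge* — give the same drug again — because effective
alternatives are scarce. The outcome is either a **negative rechallenge**
(the ADR does not recur; the favourable case) or a **positive rechallenge**
(it recurs). There are no standard guidelines for this call, so this
package implements a data-driven second opinion: a probabilistic score for
negative rechallenge that clinicians can threshold according to treatment
goals (a low threshold for curative intent, where withholding a useful drug
is the greater harm; a high threshold for palliative intent, where avoiding
a repeat ADR dominates).

## Method

For patient attributes `F = {F1, ..., Fn}` (mixed continuous and
categorical), a two-class **Naïve Bayes** model scores

```
P(NR | F) ∝ P(NR) · Π_i P(Fi | NR)
```

with Gaussian class-conditional densities `N(μ_c, σ_c²)` for continuous
attributes (per-class sample mean/SD, n−1 denominator) and category
probability tables with optional Laplace smoothing for categorical ones.
Missing values drop out of the product. The record is predicted negative
iff `P(NR | F) > t` for a clinician-chosen threshold `t`; a tie predicts
positive (the conservative call).

Predictive attribute subsets are found by a **genetic-algorithm wrapper**:
bit-string chromosomes over the attribute schema, fitness = AUC of the
Naïve Bayes model fitted on the training view and scored on the testing
view, roulette-wheel selection, single-point crossover (rate 0.95), per-bit
mutation (rate 0.05), elitism 1, population 80, 100 generations, best of 5
independently seeded runs. AUC is the trapezoidal area under the ROC curve,
equal to the Mann–Whitney concordance P(score_neg > score_pos) with ties
credited 0.5. Sensitivity is the fraction of true negative-rechallenge
patients predicted negative; specificity the fraction of true
positive-rechallenge patients predicted positive.

Because no patient-level rechallenge cohort is publicly available, the
package ships a synthetic-cohort generator (`rechallenge.cohortsim`) whose
default parameters are the published per-class descriptive statistics of
the 8 clinical predictors (age, chemotherapeutic drug, albumin, RBC,
platelet, and abnormal WBC/ALT/AP flags), plus a ready-made
`published_model()` fixture built from the same table. See
`docs/methods.md` for the model's assumptions and the generator's limits.

## Worked example

```
$ rechallenge fixture --what model --out model.json
$ rechallenge simulate --seed 7 --out cohort.csv
simulated 35 records (17 negative / 18 positive) -> cohort.csv
$ rechallenge evaluate --model model.json --cohort cohort.csv --thresholds 0.01,0.8
Score = posterior probability of NEGATIVE rechallenge (ADR does not recur); predict negative iff score > threshold.
n = 35    AUC = 0.918
 threshold  sens%  spec%   TP   FN   TN   FP
      0.01    100     11   17    0    2   16
       0.8     65    100   11    6   18    0
```

The simulated cohort reproduces the testing-set composition (17 negative /
18 positive). At the low threshold 0.01 no negative-rechallenge patient is
missed (sensitivity 100%) at the cost of many false negatives-to-come
(specificity 11% here); at 0.8 the model vetoes rechallenge for every
recurring case (specificity 100%) while still endorsing 65% of the safe
ones. In the library:

```python
>>> from rechallenge import PatientRecord, posterior_negative, published_model
>>> model = published_model()
>>> posterior_negative(model, PatientRecord(values={"chemo_drug": "carboplatin"}))
0.1671107962906614
```

A patient whose only known attribute is carboplatin — a drug far more
frequent among positive-rechallenge cases (27.8% vs 5.9%) — gets a low
probability of negative rechallenge (0.167).

Attribute selection and training run the same way from the shell:

```
$ rechallenge select --cohort cohort.csv --n-train 24 --seed 2 --out ga.json
$ rechallenge train --cohort cohort.csv --subset ga.json --alpha 1 --out fitted.json
```

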