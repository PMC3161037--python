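"""Synthetic cohorts with the class-conditional structure of the published
testing set, and a reconstruction of the published 8-predictor model.

The original 46-patient cohort (chemotherapy patients rechallenged after a
serious adverse drug reaction at a single cancer centre) was never
deposited, but the descriptive statistics of the 35-case testing set were
published per outcome class: Gaussian mean/SD for age, albumin, red blood
cell and platelet levels, and per-class proportions for the
chemotherapeutic drug and three abnormal-laboratory flags.  This module
turns those marginals into

* :func:`published_spec` — a :class:`CohortSpec` reproducing the printed
  class-conditional parameters with the inferred 17-negative /
  18-positive composition,
* :func:`generate_cohort` — a seeded sampler producing schema-valid
  cohorts from any spec, and
* :func:`published_model` — a ready-made Naive Bayes model whose
  parameters are the printed table itself, standing in for the
  unavailable fitted model.

The testing-set composition is not printed anywhere; 17/18 is inferred
from the unit fractions in the proportion columns (0.059 = 1/17,
0.056 = 1/18, 0.278 = 5/18) and can be overridden.  Printed drug columns
sum to 1.001 and 1.002 because of rounding; the spec renormalizes them and
the residual is documented in the methods note.

Generated records are drawn independently per attribute (the published
table gives marginals only, and Naive Bayes assumes independence anyway),
so synthetic cohorts carry none of the attribute correlations of real
patients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .naive_bayes import NaiveBayesModel
from .schema import (
    BINARY, CATEGORICAL, CONTINUOUS, NEGATIVE, NO, POSITIVE, YES,
    AttributeSchema, AttributeSpec, Cohort, PatientRecord, binary,
)

#: Printed testing-set statistics: per class (negative, positive) mean and SD.
TABLE_CONTINUOUS: dict[str, dict[str, tuple[float, float]]] = {
    "age":      {NEGATIVE: (47.7, 14.9),  POSITIVE: (55.4, 14.2)},
    "albumin":  {NEGATIVE: (35.7, 4.6),   POSITIVE: (30.9, 5.6)},
    "rbc":      {NEGATIVE: (4.06, 0.58),  POSITIVE: (3.69, 0.81)},
    "platelet": {NEGATIVE: (331.41, 153.62), POSITIVE: (324.39, 150.86)},
}

#: Printed drug proportions per class (not yet renormalized; the negative
#: column sums to 1.001 and the positive to 1.002 at printed precision).
TABLE_DRUG: dict[str, dict[str, float]] = {
    "oxaliplatin": {NEGATIVE: 0.294, POSITIVE: 0.278},
    "carboplatin": {NEGATIVE: 0.059, POSITIVE: 0.278},
    "bleomycin":   {NEGATIVE: 0.059, POSITIVE: 0.000},
    "rituximab":   {NEGATIVE: 0.235, POSITIVE: 0.000},
    "paclitaxel":  {NEGATIVE: 0.118, POSITIVE: 0.167},
    "docetaxel":   {NEGATIVE: 0.059, POSITIVE: 0.111},
    "trastuzumab": {NEGATIVE: 0.118, POSITIVE: 0.056},
    "cetuximab":   {NEGATIVE: 0.000, POSITIVE: 0.056},
    "gemcitabine": {NEGATIVE: 0.059, POSITIVE: 0.056},
}

#: Printed probability of an abnormal laboratory flag per class.
TABLE_ABNORMAL: dict[str, dict[str, float]] = {
    "abnormal_wbc":                      {NEGATIVE: 0.118, POSITIVE: 0.444},
    "abnormal_alanine_aminotransferase": {NEGATIVE: 0.118, POSITIVE: 0.278},
    "abnormal_alkaline_phosphatase":     {NEGATIVE: 0.176, POSITIVE: 0.556},
}

#: Inferred class composition of the 35-case testing set.
N_NEGATIVE_TESTING = 17
N_POSITIVE_TESTING = 18

PUBLISHED_PREDICTORS = (
    "age", "chemo_drug", "albumin", "rbc", "platelet",
    "abnormal_wbc", "abnormal_alkaline_phosphatase",
    "abnormal_alanine_aminotransferase",
)

#: Optional physiological floors: pass as ``CohortSpec.lower_bounds`` to
#: resample values at or below the floor.  Not applied by default because
#: truncating the printed Gaussians biases their class-conditional means
#: (notably platelet, whose printed SD puts ~1.6% of mass below zero).
PHYSIOLOGICAL_FLOORS = {"age": 18.0, "albumin": 0.0, "rbc": 0.0, "platelet": 0.0}


@dataclass
class CohortSpec:
    """Class-conditional sampling distributions for a two-class cohort.

    ``continuous`` maps attribute -> class -> (mean, sd); ``categorical``
    maps attribute -> class -> {category: probability} (each vector summing
    to 1).  ``n_noise`` appends that many class-independent standard-normal
    attributes named ``noise_01``.., useful as distractors in
    attribute-selection experiments.  ``lower_bounds`` lists per-attribute
    physiological floors enforced by resampling.
    """

    n_negative: int
    n_positive: int
    continuous: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    categorical: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    n_noise: int = 0
    lower_bounds: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_negative < 0 or self.n_positive < 0 or self.n_noise < 0:
            raise ValidationError("counts must be non-negative")
        for name, by_class in self.continuous.items():
            for cls, (_, sd) in by_class.items():
                if sd <= 0:
                    raise ValidationError(f"{name!r}/{cls}: sd must be positive")
        for name, by_class in self.categorical.items():
            for cls, probs in by_class.items():
                if any(p < 0 for p in probs.values()):
                    raise ValidationError(f"{name!r}/{cls}: negative probability")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValidationError(
                        f"{name!r}/{cls}: probabilities sum to {sum(probs.values())}, not 1")

    @property
    def noise_names(self) -> tuple[str, ...]:
        return tuple(f"noise_{i + 1:02d}" for i in range(self.n_noise))

    def schema(self) -> AttributeSchema:
        """Schema of the cohorts this spec generates (spec order: continuous,
        categorical, then noise attributes)."""
        attrs = [AttributeSpec(name, CONTINUOUS) for name in self.continuous]
        for name, by_class in self.categorical.items():
            cats = tuple(next(iter(by_class.values())).keys())
            kind = BINARY if set(cats) == {NO, YES} else CATEGORICAL
            cats = (NO, YES) if kind == BINARY else cats
            attrs.append(AttributeSpec(name, kind, cats))
        attrs.extend(AttributeSpec(name, CONTINUOUS) for name in self.noise_names)
        return AttributeSchema(tuple(attrs))

    def to_json(self) -> dict:
        return {
            "n_negative": self.n_negative,
            "n_positive": self.n_positive,
            "continuous": {n: {c: list(ms) for c, ms in bc.items()}
                           for n, bc in self.continuous.items()},
            "categorical": self.categorical,
            "n_noise": self.n_noise,
            "lower_bounds": self.lower_bounds,
            "seed": self.seed,
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "CohortSpec":
        return cls(
            n_negative=int(data["n_negative"]),
            n_positive=int(data["n_positive"]),
            continuous={n: {c: (float(ms[0]), float(ms[1])) for c, ms in bc.items()}
                        for n, bc in data.get("continuous", {}).items()},
            categorical={n: {c: {k: float(p) for k, p in probs.items()}
                             for c, probs in bc.items()}
                         for n, bc in data.get("categorical", {}).items()},
            n_noise=int(data.get("n_noise", 0)),
            lower_bounds={k: float(v) for k, v in data.get("lower_bounds", {}).items()},
            seed=int(data.get("seed", 0)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "CohortSpec":
        return cls.from_json(json.loads(Path(path).read_text()))


def _renormalized(probs: Mapping[str, float]) -> dict[str, float]:
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def published_spec(n_negative: int = N_NEGATIVE_TESTING,
                   n_positive: int = N_POSITIVE_TESTING,
                   n_noise: int = 0, seed: int = 0,
                   lower_bounds: Mapping[str, float] | None = None) -> CohortSpec:
    """The published testing-set statistics as a sampling spec.

    Continuous parameters are exactly as printed and sampled untruncated so
    that fitted parameters recover the printed values; pass
    ``lower_bounds=PHYSIOLOGICAL_FLOORS`` for clinically plausible (but
    slightly biased) records.  The drug probability vectors are
    renormalized (printed columns sum to 1.001/1.002); abnormal flags
    become ``no``/``yes`` binaries with the printed probability of ``yes``.
    """
    categorical: dict[str, dict[str, dict[str, float]]] = {
        "chemo_drug": {
            cls: _renormalized({d: TABLE_DRUG[d][cls] for d in TABLE_DRUG})
            for cls in (NEGATIVE, POSITIVE)
        }
    }
    for flag, by_class in TABLE_ABNORMAL.items():
        categorical[flag] = {
            cls: {NO: 1.0 - p, YES: p} for cls, p in by_class.items()
        }
    return CohortSpec(
        n_negative=n_negative,
        n_positive=n_positive,
        continuous={n: dict(bc) for n, bc in TABLE_CONTINUOUS.items()},
        categorical=categorical,
        n_noise=n_noise,
        lower_bounds=dict(lower_bounds) if lower_bounds else {},
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a labelled cohort from ``spec`` (deterministic under its seed).

    Continuous values are Gaussian per class, resampled while at or below
    the attribute's physiological floor; categorical values are drawn from
    the class's probability vector; noise attributes are standard normal
    draws shared across classes.  Negative-class records come first.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema()
    records: list[PatientRecord] = []
    for cls, n in ((NEGATIVE, spec.n_negative), (POSITIVE, spec.n_positive)):
        columns: dict[str, list] = {}
        for name, by_class in spec.continuous.items():
            mean, sd = by_class[cls]
            draws = rng.normal(mean, sd, size=n)
            floor = spec.lower_bounds.get(name)
            if floor is not None:
                for _ in range(1000):
                    bad = draws <= floor
                    if not bad.any():
                        break
                    draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                else:
                    raise ValidationError(
                        f"{name!r}: cannot satisfy lower bound {floor} by resampling")
            columns[name] = [float(v) for v in draws]
        for name, by_class in spec.categorical.items():
            cats = list(schema[name].categories)
            p = np.array([by_class[cls].get(c, 0.0) for c in cats])
            idx = rng.choice(len(cats), size=n, p=p / p.sum())
            columns[name] = [cats[i] for i in idx]
        for name in spec.noise_names:
            columns[name] = [float(v) for v in rng.normal(0.0, 1.0, size=n)]
        for i in range(n):
            records.append(PatientRecord(
                values={name: columns[name][i] for name in schema.names},
                label=cls,
            ))
    return Cohort(schema, records)


def published_model(n_negative: int = N_NEGATIVE_TESTING,
                    n_positive: int = N_POSITIVE_TESTING) -> NaiveBayesModel:
    """The published 8-predictor Naive Bayes model, rebuilt from the printed
    parameter table.

    Priors are the inferred testing-set composition (17/35, 18/35); the
    Gaussian and categorical parameters are the printed values (drug
    vectors renormalized so each table sums to 1); no smoothing, so
    categories printed as 0.000 (bleomycin, rituximab among positives;
    cetuximab among negatives) retain genuinely zero likelihood.  This
    fixture stands in for the original fitted model, which was not
    released in parameter form.
    """
    spec = published_spec(n_negative, n_positive)
    n = n_negative + n_positive
    model = NaiveBayesModel(
        schema=spec.schema(),
        subset=PUBLISHED_PREDICTORS,
        prior_negative=n_negative / n,
        prior_positive=n_positive / n,
        continuous_params={name: dict(bc) for name, bc in spec.continuous.items()},
        categorical_params={name: {c: dict(p) for c, p in bc.items()}
                            for name, bc in spec.categorical.items()},
        smoothing_alpha=0.0,
    )
    # subset in schema order
    schema = model.schema
    model.subset = tuple(sorted(PUBLISHED_PREDICTORS, key=schema.index))
    model.validate()
    return model


def planted_signal_spec(n_negative: int = 50, n_positive: int = 50,
                        n_noise: int = 20, seed: int = 0) -> CohortSpec:
    """A cohort spec with one perfectly class-separating binary attribute
    (``signal``: always ``yes`` for negative rechallenge, always ``no`` for
    positive) plus ``n_noise`` class-independent distractors — the standard
    benchmark for checking that wrapper attribute selection recovers a
    known predictor."""
    return CohortSpec(
        n_negative=n_negative,
        n_positive=n_positive,
        categorical={"signal": {
            NEGATIVE: {NO: 0.0, YES: 1.0},
            POSITIVE: {NO: 1.0, YES: 0.0},
        }},
        n_noise=n_noise,
        seed=seed,
    )
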