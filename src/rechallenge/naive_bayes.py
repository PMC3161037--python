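"""Mixed-type Naive Bayes classifier for rechallenge-outcome scoring.

Given an attribute set ``F = {F1 ... Fn}`` the model computes the posterior
probability that a patient has a *negative rechallenge* (the adverse
reaction does not recur) under the usual conditional-independence
assumption:

    P(NR | F) = P(NR) * prod_i P(Fi | NR) / P(F)

Continuous attributes use Gaussian class-conditional densities
parameterized by the per-class sample mean and standard deviation
(consistent with the mean +/- SD form in which clinical predictor tables
are reported); categorical and binary attributes use class-conditional
category probability tables with optional additive (Laplace) smoothing.
Missing values simply drop the attribute's factor from the product — a
missing-at-random treatment that lets the model score incomplete charts.

All posterior computation happens in log space; with ``smoothing_alpha=0``
an unobserved category legitimately yields a zero likelihood (log-density
``-inf``), which eliminates that class unless the other class is equally
impossible, in which case the model falls back to the prior and warns.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateFitError, ModelFormatError, ValidationError
from .schema import (
    LABELS, NEGATIVE, POSITIVE, AttributeSchema, Cohort, PatientRecord,
)

MODEL_FORMAT_VERSION = 1

#: Lower bound applied to every fitted or loaded standard deviation, in the
#: attribute's native units, so a zero-variance training column cannot
#: produce a degenerate density.
SD_FLOOR = 1e-6

_LOG_2PI = math.log(2.0 * math.pi)


class PriorFallbackWarning(UserWarning):
    """Both classes had zero likelihood; the posterior fell back to the prior."""


@dataclass
class NaiveBayesModel:
    """Fitted parameters of the two-class mixed-type Naive Bayes model.

    Attributes
    ----------
    schema
        The attribute schema records are validated against.
    subset
        Names of the attributes the model uses, in schema order.
    prior_negative, prior_positive
        Class priors; must sum to 1.
    continuous_params
        ``{attribute: {class: (mean, sd)}}`` in native units.
    categorical_params
        ``{attribute: {class: {category: probability}}}``; each table sums
        to 1.
    smoothing_alpha
        Pseudocount used at fit time (0 = maximum likelihood).
    """

    schema: AttributeSchema
    subset: tuple[str, ...]
    prior_negative: float
    prior_positive: float
    continuous_params: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    categorical_params: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    smoothing_alpha: float = 0.0

    def validate(self) -> None:
        if not self.subset:
            raise ValidationError("model subset is empty")
        if not (0.0 < self.prior_negative < 1.0 and 0.0 < self.prior_positive < 1.0):
            raise ValidationError("class priors must lie strictly inside (0, 1)")
        if abs(self.prior_negative + self.prior_positive - 1.0) > 1e-9:
            raise ValidationError("class priors must sum to 1")
        for name in self.subset:
            spec = self.schema[name]
            if spec.is_continuous:
                params = self.continuous_params.get(name)
                if params is None:
                    raise ValidationError(f"missing continuous params for {name!r}")
                for cls in LABELS:
                    _, sd = params[cls]
                    if sd <= 0:
                        raise ValidationError(f"{name!r}/{cls}: sd must be positive")
            else:
                table = self.categorical_params.get(name)
                if table is None:
                    raise ValidationError(f"missing categorical params for {name!r}")
                for cls in LABELS:
                    probs = table[cls]
                    if any(p < 0 for p in probs.values()):
                        raise ValidationError(f"{name!r}/{cls}: negative probability")
                    if abs(sum(probs.values()) - 1.0) > 1e-9:
                        raise ValidationError(f"{name!r}/{cls}: probabilities must sum to 1")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "schema": self.schema.to_json(),
            "subset": list(self.subset),
            "prior_negative": self.prior_negative,
            "prior_positive": self.prior_positive,
            "continuous_params": {
                name: {cls: list(ms) for cls, ms in by_class.items()}
                for name, by_class in self.continuous_params.items()
            },
            "categorical_params": self.categorical_params,
            "smoothing_alpha": self.smoothing_alpha,
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "NaiveBayesModel":
        if not isinstance(data, Mapping) or "format_version" not in data:
            raise ModelFormatError("not a model document (no format_version)")
        if data["format_version"] != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {data['format_version']!r}; "
                f"this package reads version {MODEL_FORMAT_VERSION}")
        try:
            return cls(
                schema=AttributeSchema.from_json(data["schema"]),
                subset=tuple(data["subset"]),
                prior_negative=float(data["prior_negative"]),
                prior_positive=float(data["prior_positive"]),
                continuous_params={
                    name: {cls: (float(ms[0]), float(ms[1])) for cls, ms in by_class.items()}
                    for name, by_class in data["continuous_params"].items()
                },
                categorical_params={
                    name: {cls: {c: float(p) for c, p in probs.items()}
                           for cls, probs in by_class.items()}
                    for name, by_class in data["categorical_params"].items()
                },
                smoothing_alpha=float(data["smoothing_alpha"]),
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ModelFormatError(f"malformed model document: {exc}") from exc


def save_model(model: NaiveBayesModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_json(), indent=2) + "\n")


def load_model(path) -> NaiveBayesModel:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    return NaiveBayesModel.from_json(data)


# -- fitting ---------------------------------------------------------------

def fit(cohort: Cohort, subset: Sequence[str], smoothing_alpha: float = 0.0,
        ) -> NaiveBayesModel:
    """Fit the model on the labelled records of ``cohort``.

    Callers implementing the train/test protocol pass the training view
    (``cohort.train_view``).  Priors are empirical class frequencies.
    Continuous parameters are the per-class sample mean and standard
    deviation (n-1 denominator) over non-missing values; categorical tables
    are per-class category frequencies with additive smoothing
    ``smoothing_alpha`` over the schema's full category list.

    Raises
    ------
    DegenerateFitError
        If a class is absent from the training records, or a selected
        continuous attribute has no observed value within a class.
    """
    if not subset:
        raise DegenerateFitError("attribute subset is empty")
    if smoothing_alpha < 0:
        raise ValueError("smoothing_alpha must be non-negative")
    schema = cohort.schema
    subset = tuple(sorted(set(subset), key=schema.index))
    records = [r for r in cohort.records if r.label in LABELS]
    by_class = {cls: [r for r in records if r.label == cls] for cls in LABELS}
    for cls, recs in by_class.items():
        if not recs:
            raise DegenerateFitError(f"no {cls}-rechallenge records in the training data")

    n = len(records)
    model = NaiveBayesModel(
        schema=schema,
        subset=subset,
        prior_negative=len(by_class[NEGATIVE]) / n,
        prior_positive=len(by_class[POSITIVE]) / n,
        smoothing_alpha=smoothing_alpha,
    )
    for name in subset:
        spec = schema[name]
        if spec.is_continuous:
            params = {}
            for cls, recs in by_class.items():
                obs = np.array([r.get(name) for r in recs if r.get(name) is not None],
                               dtype=float)
                if obs.size == 0:
                    raise DegenerateFitError(
                        f"continuous attribute {name!r} entirely missing in class {cls}")
                mean = float(obs.mean())
                sd = float(obs.std(ddof=1)) if obs.size > 1 else 0.0
                params[cls] = (mean, max(sd, SD_FLOOR))
            model.continuous_params[name] = params
        else:
            table = {}
            k = len(spec.categories)
            for cls, recs in by_class.items():
                obs = [r.get(name) for r in recs if r.get(name) is not None]
                total = len(obs) + smoothing_alpha * k
                if total == 0:
                    # no observations and no smoothing: uniform fallback
                    table[cls] = {c: 1.0 / k for c in spec.categories}
                    continue
                table[cls] = {
                    c: (obs.count(c) + smoothing_alpha) / total for c in spec.categories
                }
            model.categorical_params[name] = table
    model.validate()
    return model


# -- scoring ---------------------------------------------------------------

def log_likelihood(model: NaiveBayesModel, record: PatientRecord, cls: str) -> float:
    """Class-conditional log-density of ``record`` under ``cls``.

    The sum over the model's selected attributes of the log Gaussian density
    (continuous) or log category probability (categorical/binary); missing
    values contribute nothing.  Continuous factors are densities, not
    probabilities, so individual terms may be positive.  Returns ``-inf``
    when some factor has zero probability.
    """
    if cls not in LABELS:
        raise ValueError(f"unknown class {cls!r}")
    record.validate(model.schema)
    total = 0.0
    for name in model.subset:
        value = record.get(name)
        if value is None:
            continue
        spec = model.schema[name]
        if spec.is_continuous:
            mean, sd = model.continuous_params[name][cls]
            z = (float(value) - mean) / sd
            total += -0.5 * (z * z + _LOG_2PI) - math.log(sd)
        else:
            p = model.categorical_params[name][cls].get(value, 0.0)
            total += math.log(p) if p > 0 else -math.inf
    return total


def posterior_negative(model: NaiveBayesModel, record: PatientRecord) -> float:
    """Posterior probability of negative rechallenge, computed in log space.

    If both classes have zero likelihood (possible with ``alpha=0`` when a
    record combines categories unseen in either class) the data carry no
    usable evidence; the prior is returned and a
    :class:`PriorFallbackWarning` is emitted.
    """
    ll_neg = log_likelihood(model, record, NEGATIVE)
    ll_pos = log_likelihood(model, record, POSITIVE)
    a = math.log(model.prior_negative) + ll_neg
    b = math.log(model.prior_positive) + ll_pos
    if a == -math.inf and b == -math.inf:
        warnings.warn(
            "zero likelihood under both classes; returning the prior",
            PriorFallbackWarning, stacklevel=2)
        return model.prior_negative
    if a == -math.inf:
        return 0.0
    if b == -math.inf:
        return 1.0
    # p = 1 / (1 + exp(d)) with d the log posterior odds against negative,
    # evaluated on the side that cannot overflow
    d = b - a
    if d >= 0:
        e = math.exp(-d) if d < 745 else 0.0
        return e / (1.0 + e)
    e = math.exp(d) if d > -745 else 0.0
    return 1.0 / (1.0 + e)


def predict(model: NaiveBayesModel, record: PatientRecord, threshold: float) -> str:
    """Classify a record at a clinician-chosen score threshold.

    Returns ``negative`` iff the posterior strictly exceeds ``threshold``.
    A score exactly at the threshold is classified ``positive`` — the
    conservative call, since predicting negative rechallenge is what
    sanctions re-administration of the drug.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return NEGATIVE if posterior_negative(model, record) > threshold else POSITIVE
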