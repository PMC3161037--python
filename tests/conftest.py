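"""Shared fixtures: small schemas, random cohorts and oracle helpers."""

import numpy as np
import pytest

from rechallenge import (
    AttributeSchema, AttributeSpec, Cohort, PatientRecord,
    NEGATIVE, POSITIVE, default_schema,
)
from rechallenge.schema import BINARY, CATEGORICAL, CONTINUOUS, NO, YES


@pytest.fixture(scope="session")
def schema53():
    return default_schema()


@pytest.fixture
def mini_schema():
    """One attribute of each kind — enough for most classifier tests."""
    return AttributeSchema((
        AttributeSpec("age", CONTINUOUS),
        AttributeSpec("chemo_drug", CATEGORICAL, ("carboplatin", "other")),
        AttributeSpec("abnormal_wbc", BINARY, (NO, YES)),
    ))


def random_cohort(schema: AttributeSchema, n: int, rng: np.random.Generator,
                  missing_rate: float = 0.1, with_labels: bool = True) -> Cohort:
    """Random schema-valid cohort with missing values sprinkled in."""
    records = []
    for _ in range(n):
        values = {}
        for spec in schema:
            if rng.random() < missing_rate:
                values[spec.name] = None
            elif spec.is_continuous:
                values[spec.name] = float(np.round(rng.normal(50, 20), 6))
            else:
                values[spec.name] = str(rng.choice(spec.categories))
        label = str(rng.choice([NEGATIVE, POSITIVE])) if with_labels else "unknown"
        records.append(PatientRecord(values=values, label=label))
    return Cohort(schema, records)


def pairwise_auc(scores, labels) -> float:
    """Independent AUC oracle: exhaustive Mann-Whitney pair enumeration.

    Fraction of (negative-rechallenge, positive-rechallenge) pairs in which
    the negative case outscores the positive one, ties credited 0.5.
    """
    neg = [s for s, l in zip(scores, labels) if l == NEGATIVE]
    pos = [s for s, l in zip(scores, labels) if l == POSITIVE]
    assert neg and pos
    total = 0.0
    for a in neg:
        for b in pos:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(neg) * len(pos))
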