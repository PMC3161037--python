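"""Clinical attribute schema, derivation rules and cohort I/O.

The tool scores patients who suffered a serious adverse drug reaction (ADR)
on a chemotherapeutic agent and are candidates for *rechallenge*
(re-administration of the same drug).  The outcome label is

* ``negative`` — the ADR does **not** recur on re-administration (the
  favourable outcome the classifier scores), or
* ``positive`` — the ADR recurs.

A cohort is a flat table: one row per patient, one column per attribute,
plus the rechallenge outcome.  Attributes are *continuous* (numeric),
*categorical* (a closed set of labels) or *binary* (a two-label special
case, stored as ``no``/``yes``).  Several attributes are not collected
directly but derived from raw fields by fixed clinical rules
(:func:`derive_attributes`): an elderly flag, a polypharmacy flag, a
comorbidity count, and abnormal-laboratory flags against reference
intervals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BINARY = "binary"
_KINDS = (CONTINUOUS, CATEGORICAL, BINARY)

NEGATIVE = "negative"
POSITIVE = "positive"
UNKNOWN = "unknown"
LABELS = (NEGATIVE, POSITIVE)

TRAIN = "train"
TEST = "test"
VALIDATION = "validation"

LABEL_COLUMN = "rechallenge_status"
SPLIT_COLUMN = "split_tag"
MISSING_TOKEN = "NA"

#: ``no``/``yes`` category pair used by every binary attribute.
NO, YES = "no", "yes"
_BINARY_CATEGORIES = (NO, YES)

#: Comorbidity fields counted by the comorbidity-count derivation.
COMORBIDITY_FIELDS = (
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "psoriasis",
    "gerd",
    "asthma",
    "allergic_disorder",
)

#: Conventional adult reference intervals (low, high) in the units routinely
#: reported by hospital laboratories.  A value strictly outside the interval
#: sets the corresponding ``abnormal_*`` flag.  The table is configuration,
#: not a constant of the method: pass an override to
#: :func:`derive_attributes` to match a local laboratory panel.
DEFAULT_REFERENCE_INTERVALS: dict[str, tuple[float, float]] = {
    "wbc": (4.0, 10.0),                      # x10^9/L
    "rbc": (3.8, 5.8),                       # x10^12/L
    "platelet": (150.0, 450.0),              # x10^9/L
    "neutrophil": (2.0, 7.5),                # x10^9/L
    "lymphocyte": (1.0, 4.0),                # x10^9/L
    "serum_creatinine": (45.0, 110.0),       # umol/L
    "alkaline_phosphatase": (40.0, 130.0),   # U/L
    "alanine_aminotransferase": (10.0, 55.0),  # U/L
    "aspartate_aminotransferase": (10.0, 45.0),  # U/L
    "albumin": (35.0, 50.0),                 # g/L
}

ELDERLY_AGE_CUTOFF = 65.0       # elderly: age >= 65 years
POLYPHARMACY_CUTOFF = 5.0       # polypharmacy: more than 5 concomitant drugs


@dataclass(frozen=True)
class AttributeSpec:
    """Declaration of one attribute.

    Parameters
    ----------
    name
        Unique identifier, used as the CSV column header.
    kind
        ``continuous``, ``categorical`` or ``binary``.
    categories
        Allowed labels; required (>= 2) for categorical/binary, empty for
        continuous.
    derived_from
        Names of the raw source field(s) when this attribute is computed by
        a derivation rule rather than collected.
    """

    name: str
    kind: str
    categories: tuple[str, ...] = ()
    derived_from: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.name:
            raise SchemaError("attribute name must be non-empty")
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown attribute kind {self.kind!r} for {self.name!r}")
        if self.kind == CONTINUOUS and self.categories:
            raise SchemaError(f"continuous attribute {self.name!r} must not list categories")
        if self.kind in (CATEGORICAL, BINARY) and len(self.categories) < 2:
            raise SchemaError(f"{self.kind} attribute {self.name!r} needs >= 2 categories")
        if self.kind == BINARY and len(self.categories) != 2:
            raise SchemaError(f"binary attribute {self.name!r} needs exactly 2 categories")

    @property
    def is_continuous(self) -> bool:
        return self.kind == CONTINUOUS


def binary(name: str, derived_from: tuple[str, ...] = ()) -> AttributeSpec:
    """Shorthand for a ``no``/``yes`` binary attribute."""
    return AttributeSpec(name, BINARY, _BINARY_CATEGORIES, derived_from)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of :class:`AttributeSpec` with unique names."""

    attributes: tuple[AttributeSpec, ...]

    def __post_init__(self):
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate attribute names: {dupes}")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    def __len__(self) -> int:
        return len(self.attributes)

    def __iter__(self):
        return iter(self.attributes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> AttributeSpec:
        try:
            return self.attributes[self._index[name]]
        except KeyError:
            raise SchemaError(f"unknown attribute {name!r}") from None

    def index(self, name: str) -> int:
        if name not in self._index:
            raise SchemaError(f"unknown attribute {name!r}")
        return self._index[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def to_json(self) -> dict:
        return {
            "attributes": [
                {
                    "name": a.name,
                    "kind": a.kind,
                    "categories": list(a.categories),
                    "derived_from": list(a.derived_from),
                }
                for a in self.attributes
            ]
        }

    @classmethod
    def from_json(cls, data: Mapping) -> "AttributeSchema":
        try:
            attrs = tuple(
                AttributeSpec(
                    name=a["name"],
                    kind=a["kind"],
                    categories=tuple(a.get("categories", ())),
                    derived_from=tuple(a.get("derived_from", ())),
                )
                for a in data["attributes"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema document: {exc}") from exc
        return cls(attrs)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "AttributeSchema":
        return cls.from_json(json.loads(Path(path).read_text()))


def default_schema() -> AttributeSchema:
    """Reconstructed default schema of 53 attributes.

    The original study mined 53 attributes spanning demographics, medical
    conditions, medication usage and laboratory parameters; the published
    article enumerates the collected groups but not the exhaustive
    catalogue, so this default reconstructs it from the stated groups and
    derivation rules.  Category lists for free-text-coded fields (cancer
    type, ADR symptoms, ...) are pragmatic closed sets ending in ``other``.
    The schema is data: load a replacement from JSON to use a site-specific
    catalogue.
    """
    a = []
    # demographics
    a.append(AttributeSpec("age", CONTINUOUS))
    a.append(AttributeSpec("gender", CATEGORICAL, ("female", "male")))
    a.append(AttributeSpec("ethnicity", CATEGORICAL, ("chinese", "malay", "indian", "other")))
    a.append(AttributeSpec("weight", CONTINUOUS))
    # medical conditions
    a.append(binary("drug_allergy"))
    a.append(AttributeSpec(
        "cancer_type", CATEGORICAL,
        ("breast", "colorectal", "lung", "lymphoma", "nasopharyngeal", "ovarian", "other"),
    ))
    a.append(AttributeSpec("cancer_malignancy", CATEGORICAL, ("solid", "haematological")))
    a.append(binary("comorbidity_present", derived_from=COMORBIDITY_FIELDS))
    a.append(AttributeSpec(
        "adr_symptoms", CATEGORICAL,
        ("rash", "anaphylaxis", "fever", "dyspnea", "hypotension", "other"),
    ))
    a.append(binary("hospitalization_prior_adr"))
    a.append(AttributeSpec(
        "adr_organ_system", CATEGORICAL,
        ("skin", "respiratory", "cardiovascular", "gastrointestinal",
         "haematological", "neurological", "other"),
    ))
    a.append(AttributeSpec("adr_onset", CATEGORICAL, ("immediate", "delayed")))
    a.append(AttributeSpec(
        "adr_type", CATEGORICAL,
        ("hypersensitivity", "cytopenia", "hepatotoxicity", "other"),
    ))
    # individual comorbidities
    for name in COMORBIDITY_FIELDS:
        a.append(binary(name))
    # medications
    a.append(AttributeSpec("n_cycles", CONTINUOUS))
    a.append(AttributeSpec("n_doses", CONTINUOUS))
    a.append(AttributeSpec("chemo_drug", CATEGORICAL, CHEMO_DRUGS + ("other",)))
    a.append(AttributeSpec(
        "chemo_drug_class", CATEGORICAL,
        ("platinum", "taxane", "monoclonal_antibody", "cytotoxic_antibiotic",
         "antimetabolite", "other"),
    ))
    a.append(AttributeSpec("n_concurrent_medications", CONTINUOUS))
    a.append(binary("dose_reduction_on_rechallenge"))
    a.append(binary("rechallenge_same_day"))
    # laboratory parameters
    for name in ("wbc", "rbc", "platelet", "neutrophil", "lymphocyte", "monocyte",
                 "eosinophil", "basophil", "serum_creatinine", "alkaline_phosphatase",
                 "alanine_aminotransferase", "aspartate_aminotransferase", "albumin"):
        a.append(AttributeSpec(name, CONTINUOUS))
    # derived attributes
    a.append(binary("elderly", derived_from=("age",)))
    a.append(binary("polypharmacy", derived_from=("n_concurrent_medications",)))
    a.append(AttributeSpec("comorbidity_count", CONTINUOUS, derived_from=COMORBIDITY_FIELDS))
    for lab in DEFAULT_REFERENCE_INTERVALS:
        a.append(binary(f"abnormal_{lab}", derived_from=(lab,)))
    schema = AttributeSchema(tuple(a))
    assert len(schema) == 53
    return schema


#: Chemotherapeutic agents with published class-conditional proportions.
CHEMO_DRUGS = (
    "oxaliplatin", "carboplatin", "bleomycin", "rituximab", "paclitaxel",
    "docetaxel", "trastuzumab", "cetuximab", "gemcitabine",
)


@dataclass
class PatientRecord:
    """One patient's attribute values plus the rechallenge outcome.

    ``values`` maps attribute name to a float (continuous) or a category
    label (categorical/binary); ``None`` marks a missing value.  ``label``
    is ``negative``, ``positive`` or ``unknown`` (prediction-time records
    only).  ``split_tag`` optionally places the record in the ``train``,
    ``test`` or ``validation`` partition.
    """

    values: dict[str, float | str | None] = field(default_factory=dict)
    label: str = UNKNOWN
    split_tag: str | None = None

    def get(self, name: str):
        return self.values.get(name)

    def validate(self, schema: AttributeSchema, row: int | None = None) -> None:
        if self.label not in (*LABELS, UNKNOWN):
            raise ValidationError(f"unknown label {self.label!r}", row)
        if self.split_tag not in (None, TRAIN, TEST, VALIDATION):
            raise ValidationError(f"unknown split tag {self.split_tag!r}", row)
        for name, value in self.values.items():
            if name not in schema:
                raise ValidationError(f"value for unknown attribute {name!r}", row)
            if value is None:
                continue
            spec = schema[name]
            if spec.is_continuous:
                if not isinstance(value, (int, float)) or isinstance(value, bool) \
                        or not math.isfinite(float(value)):
                    raise ValidationError(
                        f"attribute {name!r}: expected finite number, got {value!r}", row)
            elif value not in spec.categories:
                raise ValidationError(
                    f"attribute {name!r}: {value!r} not in categories {spec.categories}", row)


@dataclass
class Cohort:
    """A schema plus a list of validated patient records."""

    schema: AttributeSchema
    records: list[PatientRecord]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for i, rec in enumerate(self.records):
            rec.validate(self.schema, row=i)

    def __len__(self) -> int:
        return len(self.records)

    def label_counts(self) -> dict[str, int]:
        counts = {NEGATIVE: 0, POSITIVE: 0, UNKNOWN: 0}
        for rec in self.records:
            counts[rec.label] += 1
        return counts

    def labelled(self) -> "Cohort":
        return Cohort(self.schema, [r for r in self.records if r.label in LABELS])

    def with_tag(self, *tags: str) -> "Cohort":
        """Records whose split tag is one of ``tags``."""
        return Cohort(self.schema, [r for r in self.records if r.split_tag in tags])

    @property
    def train_view(self) -> "Cohort":
        return self.with_tag(TRAIN)

    @property
    def test_view(self) -> "Cohort":
        """The testing pool: under the overlapping protocol this is every
        record tagged ``train`` or ``test``."""
        return self.with_tag(TRAIN, TEST)


def derive_attributes(
    record: PatientRecord,
    schema: AttributeSchema,
    reference_intervals: Mapping[str, tuple[float, float]] | None = None,
) -> PatientRecord:
    """Populate the derived attributes of one record from its raw fields.

    Rules (recomputed from the raw sources on every call, so the operation
    is idempotent):

    * ``elderly`` — age >= 65 years;
    * ``polypharmacy`` — more than 5 concurrent medications;
    * ``comorbidity_count`` / ``comorbidity_present`` — count of ``yes``
      over the comorbidity fields (hypertension, diabetes, hyperlipidemia,
      psoriasis, GERD, asthma, other allergic disorders); fields not
      recorded count as absent;
    * ``abnormal_<lab>`` — lab value strictly outside its reference
      interval.

    A missing source (missing age, missing lab value) leaves the derived
    flag missing.  Raw fields are never modified.
    """
    intervals = dict(DEFAULT_REFERENCE_INTERVALS)
    if reference_intervals:
        intervals.update(reference_intervals)

    values = dict(record.values)

    def as_number(name):
        v = record.get(name)
        if v is None:
            return None
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            raise ParseError(f"attribute {name!r}: expected a number, got {v!r}")
        return float(v)

    if "elderly" in schema:
        age = as_number("age")
        values["elderly"] = None if age is None else (YES if age >= ELDERLY_AGE_CUTOFF else NO)
    if "polypharmacy" in schema:
        n_meds = as_number("n_concurrent_medications")
        values["polypharmacy"] = (
            None if n_meds is None else (YES if n_meds > POLYPHARMACY_CUTOFF else NO)
        )
    count = sum(1 for f in COMORBIDITY_FIELDS if record.get(f) == YES)
    if "comorbidity_count" in schema:
        values["comorbidity_count"] = float(count)
    if "comorbidity_present" in schema:
        values["comorbidity_present"] = YES if count > 0 else NO
    for lab, (low, high) in intervals.items():
        flag = f"abnormal_{lab}"
        if flag not in schema or lab not in schema:
            continue
        v = as_number(lab)
        values[flag] = None if v is None else (YES if (v < low or v > high) else NO)

    derived = PatientRecord(values=values, label=record.label, split_tag=record.split_tag)
    derived.validate(schema)
    return derived


def _parse_value(token: str, spec: AttributeSpec, missing_token: str, row: int):
    if token == "" or token.strip().upper() == missing_token.upper():
        return None
    token = token.strip()
    if spec.is_continuous:
        try:
            return float(token)
        except ValueError:
            raise ParseError(f"row {row}: attribute {spec.name!r}: "
                             f"cannot parse {token!r} as a number") from None
    if token not in spec.categories:
        raise ValidationError(
            f"attribute {spec.name!r}: {token!r} not in categories {spec.categories}", row)
    return token


def read_cohort(
    path,
    schema: AttributeSchema,
    missing_token: str = MISSING_TOKEN,
    labels_required: bool = True,
    allow_missing_columns: bool = False,
) -> Cohort:
    """Read a cohort CSV validated against ``schema``.

    The header must contain every schema attribute (order-insensitive)
    unless ``allow_missing_columns`` is set (absent columns then read as
    missing — useful for raw files that lack the derived attributes).  The
    ``rechallenge_status`` column is parsed case-insensitively from
    ``negative``/``positive``; an optional ``split_tag`` column restores
    partition tags.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    columns = set(frame.columns)
    missing_cols = [n for n in schema.names if n not in columns]
    if missing_cols and not allow_missing_columns:
        raise ValidationError(f"missing columns: {missing_cols}")
    unknown = columns - set(schema.names) - {LABEL_COLUMN, SPLIT_COLUMN}
    if unknown:
        raise ValidationError(f"columns not in schema: {sorted(unknown)}")
    if labels_required and LABEL_COLUMN not in columns:
        raise ValidationError(f"missing required column {LABEL_COLUMN!r}")

    records = []
    for row, rec in enumerate(frame.itertuples(index=False)):
        rowmap = dict(zip(frame.columns, rec))
        values = {}
        for spec in schema:
            if spec.name in rowmap:
                values[spec.name] = _parse_value(rowmap[spec.name], spec, missing_token, row)
            else:
                values[spec.name] = None
        label = UNKNOWN
        if LABEL_COLUMN in rowmap:
            token = rowmap[LABEL_COLUMN].strip().lower()
            if token in LABELS:
                label = token
            elif token in ("", missing_token.lower(), UNKNOWN):
                label = UNKNOWN
            else:
                raise ValidationError(f"unknown label {rowmap[LABEL_COLUMN]!r}", row)
        split_tag = None
        if SPLIT_COLUMN in rowmap:
            token = rowmap[SPLIT_COLUMN].strip().lower()
            split_tag = token if token in (TRAIN, TEST, VALIDATION) else None
        records.append(PatientRecord(values=values, label=label, split_tag=split_tag))
    return Cohort(schema, records)


def write_cohort(cohort: Cohort, path, missing_token: str = MISSING_TOKEN) -> None:
    """Write a cohort CSV: schema-order columns, label last, split tags in a
    trailing ``split_tag`` column when any record carries one."""
    cohort.validate()
    has_split = any(r.split_tag is not None for r in cohort.records)
    columns = list(cohort.schema.names) + [LABEL_COLUMN] + ([SPLIT_COLUMN] if has_split else [])

    def fmt(value):
        if value is None:
            return missing_token
        if isinstance(value, float):
            return repr(value) if not value.is_integer() else str(int(value))
        return str(value)

    rows = []
    for rec in cohort.records:
        row = [fmt(rec.get(name)) for name in cohort.schema.names]
        row.append(rec.label if rec.label in LABELS else missing_token)
        if has_split:
            row.append(rec.split_tag if rec.split_tag else missing_token)
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def split_cohort(cohort: Cohort, n_train: int, seed: int) -> Cohort:
    """Assign split tags replicating the overlapping train/test protocol.

    Records already tagged ``validation`` are held out untouched.  From the
    remaining pool, ``n_train`` records are sampled without replacement
    (seeded) and tagged ``train``; every other pool record is tagged
    ``test``.  The testing pool is the *entire* eligible set — training
    records are deliberately also test records, mirroring the original
    study design in which all 35 pre-validation cases scored the models
    that 24 of them had trained.
    """
    eligible = [i for i, r in enumerate(cohort.records) if r.split_tag != VALIDATION]
    if n_train > len(eligible):
        raise ValidationError(
            f"n_train={n_train} exceeds the eligible pool of {len(eligible)} records")
    rng = np.random.default_rng(seed)
    train_idx = set(rng.choice(len(eligible), size=n_train, replace=False).tolist())
    records = []
    for i, rec in enumerate(cohort.records):
        if rec.split_tag == VALIDATION:
            tag = VALIDATION
        else:
            tag = TRAIN if eligible.index(i) in train_idx else TEST
        records.append(PatientRecord(values=dict(rec.values), label=rec.label, split_tag=tag))
    return Cohort(cohort.schema, records)
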