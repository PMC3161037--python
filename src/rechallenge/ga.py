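"""Genetic-algorithm wrapper feature selection maximizing Naive Bayes AUC.

Each candidate attribute subset is a bit-string chromosome over the schema
(one bit per attribute, at least one set).  Fitness of a chromosome is the
AUC of a Naive Bayes model fitted on the training view and scored on the
testing view.  Defaults reproduce the published search settings: population
80, 100 generations, single-point crossover at rate 0.95, per-bit mutation
at rate 0.05, roulette-wheel (fitness-proportional) parent selection with
generational replacement, repeated over 5 independently initialized runs;
the best subset across runs wins, ties broken toward fewer attributes.

Because Naive Bayes factorizes over attributes and the train/test views are
fixed during the search, every attribute's per-class log-likelihood
contribution on each test record can be precomputed once
(:class:`FitnessEvaluator`); a chromosome's fitness then reduces to a
column-sum and an AUC, and identical chromosomes are served from a cache.
This is an exact optimization — it changes no fitness value, only the cost
of computing it.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, UndefinedMetricError
from .evaluation import auc
from .naive_bayes import SD_FLOOR, fit, posterior_negative
from .schema import LABELS, NEGATIVE, POSITIVE, AttributeSchema, Cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeSubset:
    """A chromosome: an ordered bit mask over the schema's attributes."""

    mask: tuple[bool, ...]

    def __post_init__(self):
        if not any(self.mask):
            raise ValueError("attribute subset must select at least one attribute")

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def n_selected(self) -> int:
        return sum(self.mask)

    def names(self, schema: AttributeSchema) -> tuple[str, ...]:
        if len(self.mask) != len(schema):
            raise ValueError("mask length does not match schema size")
        return tuple(n for n, bit in zip(schema.names, self.mask) if bit)

    @classmethod
    def from_names(cls, schema: AttributeSchema, names: Sequence[str]) -> "AttributeSubset":
        wanted = set(names)
        unknown = wanted - set(schema.names)
        if unknown:
            raise ValueError(f"names not in schema: {sorted(unknown)}")
        return cls(tuple(n in wanted for n in schema.names))

    @classmethod
    def from_array(cls, bits: np.ndarray) -> "AttributeSubset":
        return cls(tuple(bool(b) for b in bits))

    def to_array(self) -> np.ndarray:
        return np.array(self.mask, dtype=bool)


@dataclass(frozen=True)
class GAConfig:
    """Search settings; the defaults are the published ones."""

    population_size: int = 80
    generations: int = 100
    crossover_rate: float = 0.95
    mutation_rate: float = 0.05       # per-bit flip probability
    n_runs: int = 5
    elitism: int = 1
    seed: int = 0
    smoothing_alpha: float = 0.0

    def __post_init__(self):
        for name in ("population_size", "generations", "n_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must lie in [0, population_size)")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_json(self) -> dict:
        return {k: getattr(self, k) for k in (
            "population_size", "generations", "crossover_rate", "mutation_rate",
            "n_runs", "elitism", "seed", "smoothing_alpha")}

    @classmethod
    def from_json(cls, data) -> "GAConfig":
        return cls(**data)


@dataclass
class GAResult:
    """Outcome of a full multi-run search."""

    best_subset: AttributeSubset
    best_fitness: float
    #: per run: {"best": [per-generation best], "mean": [per-generation mean]}
    per_run_history: list[dict[str, list[float]]]
    run_seeds: list[int]
    config: GAConfig

    def to_json(self) -> dict:
        return {
            "best_subset_mask": [int(b) for b in self.best_subset.mask],
            "best_fitness": self.best_fitness,
            "per_run_history": self.per_run_history,
            "run_seeds": self.run_seeds,
            "config": self.config.to_json(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2) + "\n")


# -- fitness ---------------------------------------------------------------

def fitness(subset: AttributeSubset, train: Cohort, test: Cohort,
            smoothing_alpha: float = 0.0) -> float:
    """AUC on ``test`` of a Naive Bayes model fitted on ``train``.

    Degenerate fits (e.g. an attribute entirely missing within a class)
    yield fitness 0 with a logged warning rather than aborting the search.
    """
    names = subset.names(train.schema)
    try:
        model = fit(train, names, smoothing_alpha)
        records = [r for r in test.records if r.label in LABELS]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # prior fallback is fine mid-search
            scores = [posterior_negative(model, r) for r in records]
        return auc(scores, [r.label for r in records])
    except (DegenerateFitError, UndefinedMetricError) as exc:
        logger.warning("fitness set to 0 for a degenerate chromosome: %s", exc)
        return 0.0


class FitnessEvaluator:
    """Precomputed per-attribute log-likelihood contributions on the test set.

    For every attribute the per-class Naive Bayes parameters depend only on
    the (fixed) training view, so each attribute's additive contribution to
    each test record's class log-likelihood is computed once at
    construction.  ``fitness_of_mask`` then sums the selected columns, adds
    the log priors, converts to posterior scores and returns their AUC.
    Attributes whose fit is degenerate are flagged; any chromosome touching
    one scores 0, matching :func:`fitness`.
    """

    def __init__(self, train: Cohort, test: Cohort, smoothing_alpha: float = 0.0):
        schema = train.schema
        if test.schema is not schema and test.schema != schema:
            raise ValueError("train and test views must share a schema")
        self.schema = schema
        self.smoothing_alpha = smoothing_alpha
        train_records = [r for r in train.records if r.label in LABELS]
        test_records = [r for r in test.records if r.label in LABELS]
        by_class = {c: [r for r in train_records if r.label == c] for c in LABELS}
        if not train_records or any(not v for v in by_class.values()):
            raise DegenerateFitError("both classes required in the training view")
        if not test_records:
            raise UndefinedMetricError("no labelled records in the test view")
        self.test_labels = [r.label for r in test_records]
        if NEGATIVE not in self.test_labels or POSITIVE not in self.test_labels:
            raise UndefinedMetricError("both classes required in the test view")

        n_train = len(train_records)
        self.log_prior = {
            c: math.log(len(by_class[c]) / n_train) for c in LABELS
        }
        m, L = len(test_records), len(schema)
        # contrib[cls][i, j]: log-likelihood term of attribute j for test record i
        self.contrib = {c: np.zeros((m, L)) for c in LABELS}
        self.invalid = np.zeros(L, dtype=bool)
        log_2pi = math.log(2.0 * math.pi)
        with np.errstate(divide="ignore"):
            for j, spec in enumerate(schema):
                name = spec.name
                test_vals = [r.get(name) for r in test_records]
                present = np.array([v is not None for v in test_vals])
                if spec.is_continuous:
                    x = np.array([v if v is not None else 0.0 for v in test_vals],
                                 dtype=float)
                    for c in LABELS:
                        obs = np.array(
                            [r.get(name) for r in by_class[c] if r.get(name) is not None],
                            dtype=float)
                        if obs.size == 0:
                            self.invalid[j] = True
                            break
                        mean = obs.mean()
                        sd = max(obs.std(ddof=1) if obs.size > 1 else 0.0, SD_FLOOR)
                        z = (x - mean) / sd
                        ll = -0.5 * (z * z + log_2pi) - math.log(sd)
                        self.contrib[c][:, j] = np.where(present, ll, 0.0)
                else:
                    cats = list(spec.categories)
                    code = {cat: i for i, cat in enumerate(cats)}
                    xi = np.array([code[v] if v is not None else 0 for v in test_vals])
                    k = len(cats)
                    for c in LABELS:
                        obs = [r.get(name) for r in by_class[c] if r.get(name) is not None]
                        total = len(obs) + smoothing_alpha * k
                        if total == 0:
                            probs = np.full(k, 1.0 / k)
                        else:
                            counts = np.array([obs.count(cat) for cat in cats], dtype=float)
                            probs = (counts + smoothing_alpha) / total
                        ll = np.log(probs)[xi]
                        self.contrib[c][:, j] = np.where(present, ll, 0.0)
        self._cache: dict[bytes, float] = {}
        self._warned_invalid = False

    def scores_of_mask(self, bits: np.ndarray) -> np.ndarray:
        """Posterior-negative scores of every test record under the subset."""
        a = self.contrib[NEGATIVE][:, bits].sum(axis=1) + self.log_prior[NEGATIVE]
        b = self.contrib[POSITIVE][:, bits].sum(axis=1) + self.log_prior[POSITIVE]
        with np.errstate(invalid="ignore", over="ignore"):
            d = b - a
            p = np.where(d >= 0,
                         np.exp(np.minimum(-d, 0)) / (1.0 + np.exp(np.minimum(-d, 0))),
                         1.0 / (1.0 + np.exp(np.minimum(d, 0))))
        # both-classes-impossible records carry no evidence: fall back to prior
        both_impossible = np.isneginf(a) & np.isneginf(b)
        if both_impossible.any():
            p = np.where(both_impossible, math.exp(self.log_prior[NEGATIVE]), p)
        return p

    def fitness_of_mask(self, bits: np.ndarray) -> float:
        key = np.packbits(bits).tobytes()
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if bool(self.invalid[bits].any()):
            if not self._warned_invalid:
                logger.warning("chromosomes selecting degenerate attributes score 0")
                self._warned_invalid = True
            value = 0.0
        else:
            value = auc(self.scores_of_mask(bits), self.test_labels)
        self._cache[key] = value
        return value


# -- GA operators ----------------------------------------------------------

def roulette_select(population: Sequence[tuple[AttributeSubset, float]],
                    rng: np.random.Generator) -> AttributeSubset:
    """Fitness-proportional selection of one individual.

    Sampling probability is fitness_i / sum(fitness); when every fitness is
    zero the draw is uniform.
    """
    fits = np.array([f for _, f in population], dtype=float)
    if (fits < 0).any():
        raise ValueError("roulette selection requires non-negative fitness")
    total = fits.sum()
    if total <= 0:
        idx = int(rng.integers(len(population)))
    else:
        idx = int(np.searchsorted(np.cumsum(fits), rng.random() * total, side="right"))
        idx = min(idx, len(population) - 1)
    return population[idx][0]


def _roulette_index(fits: np.ndarray, total: float, rng: np.random.Generator) -> int:
    if total <= 0:
        return int(rng.integers(fits.size))
    idx = int(np.searchsorted(np.cumsum(fits), rng.random() * total, side="right"))
    return min(idx, fits.size - 1)


def crossover(parent_a: AttributeSubset, parent_b: AttributeSubset,
              rate: float, rng: np.random.Generator,
              ) -> tuple[AttributeSubset, AttributeSubset]:
    """Single-point crossover: with probability ``rate`` swap the tails at a
    uniformly chosen cut in [1, L-1]; otherwise return copies."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents must have equal mask lengths")
    a, b = parent_a.to_array(), parent_b.to_array()
    ca, cb = _crossover_arrays(a, b, rate, rng)
    return _repaired(ca, rng), _repaired(cb, rng)


def _crossover_arrays(a: np.ndarray, b: np.ndarray, rate: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    L = a.size
    if L < 2 or rng.random() >= rate:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, L))
    ca = np.concatenate([a[:cut], b[cut:]])
    cb = np.concatenate([b[:cut], a[cut:]])
    return ca, cb


def mutate(subset: AttributeSubset, rate: float,
           rng: np.random.Generator) -> AttributeSubset:
    """Flip each bit independently with probability ``rate``; an all-zero
    result is repaired by switching one uniformly chosen bit back on."""
    bits = _mutate_array(subset.to_array(), rate, rng)
    return _repaired(bits, rng)


def _mutate_array(bits: np.ndarray, rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    return bits ^ (rng.random(bits.size) < rate)


def _repair_array(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not bits.any():
        bits = bits.copy()
        bits[int(rng.integers(bits.size))] = True
    return bits


def _repaired(bits: np.ndarray, rng: np.random.Generator) -> AttributeSubset:
    return AttributeSubset.from_array(_repair_array(bits, rng))


# -- the search ------------------------------------------------------------

def run_ga(config: GAConfig, train: Cohort, test: Cohort) -> GAResult:
    """Multi-run GA search for the attribute subset maximizing test AUC.

    Run ``r`` uses an independent generator seeded ``config.seed + r``:
    initial chromosomes set each bit with probability 0.5 (repaired if
    empty); each generation keeps the ``elitism`` fittest unchanged and
    fills the rest with roulette-selected parent pairs passed through
    crossover and mutation.  The overall winner is the fittest individual
    seen in any generation of any run; exact ties prefer fewer selected
    attributes, then the earlier run.

    Fully deterministic for a fixed config: repeated calls return
    bit-identical results, and ``best_fitness`` always equals the
    recomputed AUC of ``best_subset`` on the same views.
    """
    evaluator = FitnessEvaluator(train, test, config.smoothing_alpha)
    L = len(train.schema)
    run_seeds = [config.seed + r for r in range(config.n_runs)]
    histories: list[dict[str, list[float]]] = []
    best_bits: np.ndarray | None = None
    best_fit = -1.0
    best_count = L + 1
    for run_idx, run_seed in enumerate(run_seeds):
        rng = np.random.default_rng(run_seed)
        pop = rng.random((config.population_size, L)) < 0.5
        pop = np.stack([_repair_array(row, rng) for row in pop])
        history = {"best": [], "mean": []}
        for gen in range(config.generations):
            fits = np.array([evaluator.fitness_of_mask(row) for row in pop])
            gen_best = int(fits.argmax())
            history["best"].append(float(fits[gen_best]))
            history["mean"].append(float(fits.mean()))
            for i in np.nonzero(fits == fits[gen_best])[0]:
                cnt = int(pop[i].sum())
                if (fits[i] > best_fit
                        or (fits[i] == best_fit and cnt < best_count)):
                    best_fit = float(fits[i])
                    best_bits = pop[i].copy()
                    best_count = cnt
            logger.debug("run %d gen %d best %.4f mean %.4f",
                         run_idx, gen, history["best"][-1], history["mean"][-1])
            if gen == config.generations - 1:
                break
            order = np.argsort(-fits, kind="stable")
            children = [pop[i].copy() for i in order[:config.elitism]]
            total = float(fits.sum())
            while len(children) < config.population_size:
                pa = pop[_roulette_index(fits, total, rng)]
                pb = pop[_roulette_index(fits, total, rng)]
                ca, cb = _crossover_arrays(pa, pb, config.crossover_rate, rng)
                for child in (ca, cb):
                    if len(children) < config.population_size:
                        child = _repair_array(_mutate_array(child, config.mutation_rate, rng), rng)
                        children.append(child)
            pop = np.stack(children)
        histories.append(history)
    assert best_bits is not None
    return GAResult(
        best_subset=AttributeSubset.from_array(best_bits),
        best_fitness=best_fit,
        per_run_history=histories,
        run_seeds=run_seeds,
        config=config,
    )
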