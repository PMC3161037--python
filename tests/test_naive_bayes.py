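"""Mixed-type Naive Bayes: fitting, log-likelihoods, posteriors, round trips.

Hand-computed expectations come from direct Bayes arithmetic; densities are
cross-checked against scipy.stats.norm, which the implementation does not
use.
"""

import json
import math

import numpy as np
import pytest
from scipy import stats

from rechallenge import (
    Cohort, NaiveBayesModel, PatientRecord, PriorFallbackWarning,
    NEGATIVE, POSITIVE,
    fit, load_model, log_likelihood, posterior_negative, predict, save_model,
)
from rechallenge.errors import DegenerateFitError, ModelFormatError
from conftest import random_cohort


def cohort_with_drug_counts(schema, n_neg, n_pos, carb_pos=0, carb_neg=0):
    records = []
    for i in range(n_neg):
        records.append(PatientRecord(
            values={"chemo_drug": "carboplatin" if i < carb_neg else "other"},
            label=NEGATIVE))
    for i in range(n_pos):
        records.append(PatientRecord(
            values={"chemo_drug": "carboplatin" if i < carb_pos else "other"},
            label=POSITIVE))
    return Cohort(schema, records)


def two_category_model(mini_schema, p_carb_neg, p_carb_pos,
                       prior_neg=17 / 35) -> NaiveBayesModel:
    return NaiveBayesModel(
        schema=mini_schema,
        subset=("chemo_drug",),
        prior_negative=prior_neg,
        prior_positive=1 - prior_neg,
        categorical_params={"chemo_drug": {
            NEGATIVE: {"carboplatin": p_carb_neg, "other": 1 - p_carb_neg},
            POSITIVE: {"carboplatin": p_carb_pos, "other": 1 - p_carb_pos},
        }},
    )


class TestFit:
    def test_priors_are_class_frequencies(self, mini_schema):
        cohort = cohort_with_drug_counts(mini_schema, 17, 18)
        model = fit(cohort, ("chemo_drug",))
        assert model.prior_negative == pytest.approx(17 / 35, abs=1e-15)
        assert model.prior_positive == pytest.approx(18 / 35, abs=1e-15)

    def test_carboplatin_class_conditional_frequency(self, mini_schema):
        # 5 carboplatin among 18 positive-rechallenge cases, no smoothing
        cohort = cohort_with_drug_counts(mini_schema, 17, 18, carb_pos=5, carb_neg=1)
        model = fit(cohort, ("chemo_drug",), smoothing_alpha=0.0)
        p = model.categorical_params["chemo_drug"][POSITIVE]["carboplatin"]
        assert round(p, 3) == 0.278
        assert model.categorical_params["chemo_drug"][NEGATIVE]["carboplatin"] \
            == pytest.approx(1 / 17)

    def test_laplace_smoothing_closed_form(self, mini_schema):
        # all n observations in one of k categories, alpha=1 -> (n+1)/(n+k)
        n, k = 7, 2
        cohort = cohort_with_drug_counts(mini_schema, n, 3, carb_neg=n)
        model = fit(cohort, ("chemo_drug",), smoothing_alpha=1.0)
        assert model.categorical_params["chemo_drug"][NEGATIVE]["carboplatin"] \
            == pytest.approx((n + 1) / (n + k), abs=1e-15)

    def test_continuous_params_use_sample_sd(self, mini_schema):
        values = [40.0, 50.0, 66.0]
        records = [PatientRecord(values={"age": v}, label=NEGATIVE) for v in values]
        records += [PatientRecord(values={"age": v + 5}, label=POSITIVE) for v in values]
        model = fit(Cohort(mini_schema, records), ("age",))
        mean, sd = model.continuous_params["age"][NEGATIVE]
        assert mean == pytest.approx(np.mean(values))
        assert sd == pytest.approx(np.std(values, ddof=1))

    def test_missing_values_ignored_in_fit(self, mini_schema):
        records = [PatientRecord(values={"age": 40.0}, label=NEGATIVE),
                   PatientRecord(values={"age": None}, label=NEGATIVE),
                   PatientRecord(values={"age": 60.0}, label=NEGATIVE),
                   PatientRecord(values={"age": 50.0}, label=POSITIVE),
                   PatientRecord(values={"age": 52.0}, label=POSITIVE)]
        model = fit(Cohort(mini_schema, records), ("age",))
        assert model.continuous_params["age"][NEGATIVE][0] == pytest.approx(50.0)

    def test_absent_class_is_degenerate(self, mini_schema):
        cohort = cohort_with_drug_counts(mini_schema, 5, 0)
        with pytest.raises(DegenerateFitError):
            fit(cohort, ("chemo_drug",))

    def test_all_missing_continuous_in_one_class_is_degenerate(self, mini_schema):
        records = [PatientRecord(values={"age": 40.0}, label=NEGATIVE),
                   PatientRecord(values={"age": None}, label=POSITIVE)]
        with pytest.raises(DegenerateFitError, match="age"):
            fit(Cohort(mini_schema, records), ("age",))

    def test_duplicating_one_class_leaves_other_class_params_unchanged(self, mini_schema):
        rng = np.random.default_rng(2)
        cohort = random_cohort(mini_schema, 40, rng)
        extra = next(r for r in cohort.records if r.label == POSITIVE)
        bigger = Cohort(mini_schema, cohort.records + [extra])
        a = fit(cohort, mini_schema.names)
        b = fit(bigger, mini_schema.names)
        assert a.continuous_params["age"][NEGATIVE] == b.continuous_params["age"][NEGATIVE]
        assert a.categorical_params["chemo_drug"][NEGATIVE] \
            == b.categorical_params["chemo_drug"][NEGATIVE]

    def test_zero_variance_column_gets_sd_floor(self, mini_schema):
        records = [PatientRecord(values={"age": 50.0}, label=NEGATIVE)] * 3 \
            + [PatientRecord(values={"age": 60.0}, label=POSITIVE)] * 3
        model = fit(Cohort(mini_schema, records), ("age",))
        assert model.continuous_params["age"][NEGATIVE][1] == pytest.approx(1e-6)


class TestLogLikelihood:
    def test_empty_subset_is_zero(self, mini_schema):
        model = NaiveBayesModel(schema=mini_schema, subset=(),
                                prior_negative=0.5, prior_positive=0.5)
        rec = PatientRecord(values={"age": 50.0})
        assert log_likelihood(model, rec, NEGATIVE) == 0.0
        assert log_likelihood(model, rec, POSITIVE) == 0.0

    def test_gaussian_mode_value(self, mini_schema):
        model = NaiveBayesModel(
            schema=mini_schema, subset=("age",), prior_negative=0.5,
            prior_positive=0.5,
            continuous_params={"age": {NEGATIVE: (50.0, 3.0), POSITIVE: (60.0, 3.0)}})
        rec = PatientRecord(values={"age": 50.0})
        assert log_likelihood(model, rec, NEGATIVE) \
            == pytest.approx(math.log(1 / (3.0 * math.sqrt(2 * math.pi))), abs=1e-12)

    def test_gaussian_density_matches_scipy(self, mini_schema):
        model = NaiveBayesModel(
            schema=mini_schema, subset=("age",), prior_negative=0.5,
            prior_positive=0.5,
            continuous_params={"age": {NEGATIVE: (47.7, 14.9), POSITIVE: (55.4, 14.2)}})
        for value in (20.0, 47.7, 88.0):
            rec = PatientRecord(values={"age": value})
            assert log_likelihood(model, rec, POSITIVE) \
                == pytest.approx(stats.norm.logpdf(value, 55.4, 14.2), abs=1e-10)

    def test_record_missing_all_selected_attributes(self, mini_schema):
        model = two_category_model(mini_schema, 0.2, 0.4)
        rec = PatientRecord(values={"age": 50.0})  # no chemo_drug
        assert log_likelihood(model, rec, NEGATIVE) == 0.0

    def test_zero_probability_category_gives_minus_inf(self, mini_schema):
        model = two_category_model(mini_schema, 0.0, 0.4)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        assert log_likelihood(model, rec, NEGATIVE) == -math.inf


class TestPosterior:
    def test_symmetry_gives_half(self, mini_schema):
        model = two_category_model(mini_schema, 0.3, 0.3, prior_neg=0.5)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        assert posterior_negative(model, rec) == pytest.approx(0.5, abs=1e-15)

    def test_published_carboplatin_hand_arithmetic(self, mini_schema):
        # priors 17/35 vs 18/35, P(carb|neg)=0.059, P(carb|pos)=0.278
        model = two_category_model(mini_schema, 0.059, 0.278)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        expected = (17 / 35 * 0.059) / (17 / 35 * 0.059 + 18 / 35 * 0.278)
        post = posterior_negative(model, rec)
        assert post == pytest.approx(expected, abs=1e-12)
        assert round(post, 3) == 0.167

    def test_two_attribute_hand_arithmetic(self, mini_schema):
        model = two_category_model(mini_schema, 0.2, 0.5, prior_neg=0.4)
        model.subset = ("age", "chemo_drug")
        model.continuous_params = {"age": {NEGATIVE: (45.0, 10.0),
                                           POSITIVE: (60.0, 12.0)}}
        rec = PatientRecord(values={"age": 52.0, "chemo_drug": "other"})
        num = 0.4 * stats.norm.pdf(52.0, 45.0, 10.0) * 0.8
        den = num + 0.6 * stats.norm.pdf(52.0, 60.0, 12.0) * 0.5
        assert posterior_negative(model, rec) == pytest.approx(num / den, abs=1e-12)

    def test_zero_likelihood_eliminates_class(self, mini_schema):
        model = two_category_model(mini_schema, 0.059, 0.0)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        assert posterior_negative(model, rec) == 1.0

    def test_both_classes_impossible_falls_back_to_prior(self, mini_schema):
        model = two_category_model(mini_schema, 0.0, 0.0)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        with pytest.warns(PriorFallbackWarning):
            assert posterior_negative(model, rec) == pytest.approx(17 / 35)

    @pytest.mark.parametrize("seed", range(8))
    def test_posteriors_sum_to_one(self, mini_schema, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(mini_schema, 30, rng)
        model = fit(cohort, mini_schema.names, smoothing_alpha=1.0)
        for rec in random_cohort(mini_schema, 20, rng).records:
            p_neg = posterior_negative(model, rec)
            # positive posterior via the same model with classes swapped
            swapped = NaiveBayesModel(
                schema=mini_schema, subset=model.subset,
                prior_negative=model.prior_positive,
                prior_positive=model.prior_negative,
                continuous_params={a: {NEGATIVE: v[POSITIVE], POSITIVE: v[NEGATIVE]}
                                   for a, v in model.continuous_params.items()},
                categorical_params={a: {NEGATIVE: v[POSITIVE], POSITIVE: v[NEGATIVE]}
                                    for a, v in model.categorical_params.items()},
            )
            assert p_neg + posterior_negative(swapped, rec) \
                == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= p_neg <= 1.0

    def test_log_space_agrees_with_direct_product(self, mini_schema):
        """On instances where the direct probability product does not
        underflow, the log-space posterior matches it to 1e-9."""
        rng = np.random.default_rng(4)
        cohort = random_cohort(mini_schema, 50, rng, missing_rate=0.0)
        model = fit(cohort, mini_schema.names, smoothing_alpha=1.0)
        for rec in cohort.records[:20]:
            joint = {}
            for cls, prior in ((NEGATIVE, model.prior_negative),
                               (POSITIVE, model.prior_positive)):
                product = prior
                for name in model.subset:
                    spec = mini_schema[name]
                    v = rec.get(name)
                    if spec.is_continuous:
                        mu, sd = model.continuous_params[name][cls]
                        product *= stats.norm.pdf(v, mu, sd)
                    else:
                        product *= model.categorical_params[name][cls][v]
                joint[cls] = product
            direct = joint[NEGATIVE] / (joint[NEGATIVE] + joint[POSITIVE])
            assert posterior_negative(model, rec) == pytest.approx(direct, abs=1e-9)


class TestPredict:
    @pytest.mark.parametrize("p_neg,threshold,expected", [
        (0.9, 0.8, NEGATIVE),   # above threshold -> negative
        (0.5, 0.5, POSITIVE),   # tie -> positive (conservative)
        (0.1, 0.8, POSITIVE),
    ])
    def test_threshold_semantics(self, mini_schema, p_neg, threshold, expected):
        # a model whose posterior for carboplatin equals p_neg by construction
        model = two_category_model(mini_schema, p_neg, 1 - p_neg, prior_neg=0.5)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        assert posterior_negative(model, rec) == pytest.approx(p_neg, abs=1e-15)
        assert predict(model, rec, threshold) == expected

    def test_threshold_zero_predicts_negative_when_score_positive(self, mini_schema):
        model = two_category_model(mini_schema, 0.05, 0.95, prior_neg=0.5)
        rec = PatientRecord(values={"chemo_drug": "carboplatin"})
        assert predict(model, rec, 0.0) == NEGATIVE


class TestSerialization:
    def test_round_trip_to_full_precision(self, mini_schema, tmp_path):
        rng = np.random.default_rng(9)
        model = fit(random_cohort(mini_schema, 25, rng), mini_schema.names,
                    smoothing_alpha=0.5)
        path = tmp_path / "model.json"
        save_model(model, path)
        assert load_model(path) == model

    def test_published_fixture_round_trip(self, tmp_path):
        from rechallenge import published_model
        model = published_model()
        path = tmp_path / "published.json"
        save_model(model, path)
        assert load_model(path) == model

    def test_corrupted_file_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_version_mismatch_raises(self, mini_schema, tmp_path):
        model = two_category_model(mini_schema, 0.2, 0.4)
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_model_round_trip(self, mini_schema, tmp_path, seed):
        rng = np.random.default_rng(seed)
        cohort = random_cohort(mini_schema, 15 + seed, rng, missing_rate=0.3)
        model = fit(cohort, mini_schema.names, smoothing_alpha=float(seed % 2))
        path = tmp_path / f"m{seed}.json"
        save_model(model, path)
        assert load_model(path) == model
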