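"""Element raters: ladders, cut-points, aspect max rule, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortage_impact import (CostThresholds, ElementProfile, RaterConfig,
                             RatingError, ThresholdError,
                             compute_cost_thresholds,
                             rate_alternative_product, rate_costs,
                             rate_disease, rate_n_patients, rate_record,
                             rate_susceptibility)

ratings = st.sampled_from([1, 2, 3])


class TestAlternativeProduct:
    @pytest.mark.parametrize("category,expected", [
        ("generic_substitution", 1),
        ("therapeutic_substitution", 2),
        ("unlicensed_product", 2),
        ("no_therapy", 3),
    ])
    def test_solution_ladder(self, category, expected):
        assert rate_alternative_product(category) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(RatingError, match="solution_category"):
            rate_alternative_product("import")

    def test_ladder_is_configurable(self):
        config = RaterConfig(solution_ladder={
            "generic_substitution": 1, "therapeutic_substitution": 2,
            "unlicensed_product": 3, "no_therapy": 3})
        assert rate_alternative_product("unlicensed_product", config) == 3


class TestDisease:
    @pytest.mark.parametrize("severity,expected", [
        ("mild", 1), ("moderate", 2), ("severe", 3), ("multi_class", 2),
        (0.05, 1), (0.10, 1), (0.2, 2), (0.30, 2), (0.31, 3), (0.95, 3),
    ])
    def test_grades_and_weights(self, severity, expected):
        assert rate_disease(severity) == expected

    def test_weight_outside_unit_interval_rejected(self):
        with pytest.raises(RatingError, match=r"\[0, 1\]"):
            rate_disease(1.2)


class TestSusceptibility:
    def test_adults_without_signals_rate_low(self):
        r = rate_susceptibility(20, 60, frozenset())
        assert r.value == 1
        assert r.aspects == {"vulnerability": 1, "trust": 1}

    def test_media_attention_dominates_adult_ages(self):
        r = rate_susceptibility(20, 60, {"media_attention"})
        assert r.value == 3
        assert r.aspects["trust"] == 3

    def test_child_only_population_is_vulnerable(self):
        r = rate_susceptibility(0, 12, frozenset())
        assert r.value == 3
        assert r.aspects["vulnerability"] == 3

    @pytest.mark.parametrize("age_min,age_max,expected", [
        (0, 40, 2),      # children among adults
        (40, 80, 2),     # elderly among adults
        (70, 90, 3),     # elderly only
        (19, 64, 1),     # adults only
    ])
    def test_vulnerability_age_rules(self, age_min, age_max, expected):
        r = rate_susceptibility(age_min, age_max, frozenset())
        assert r.aspects["vulnerability"] == expected

    def test_contact_notes_alone_rate_moderate(self):
        r = rate_susceptibility(20, 60, {"patient_contact_notes"})
        assert r.aspects["trust"] == 2
        assert r.value == 2


class TestCostThresholds:
    def test_hand_checked_quartiles(self):
        t = compute_cost_thresholds([50, 80, 100, 120, 300])
        assert t.q1 == pytest.approx(80.0)
        assert t.q3 == pytest.approx(120.0)
        assert t.method_label == "linear"

    def test_degenerate_spread(self):
        t = compute_cost_thresholds([100.0] * 6)
        assert t.q1 == t.q3 == 100.0

    def test_fewer_than_four_ratios_rejected(self):
        with pytest.raises(ThresholdError, match="explicit"):
            compute_cost_thresholds([100, 200])

    def test_missing_ratios_ignored(self):
        t = compute_cost_thresholds([50, None, 80, 100, 120, 300, None])
        assert (t.q1, t.q3) == (80.0, 120.0)

    def test_at_most_quarter_of_ratios_beyond_each_threshold(self):
        rng = np.random.default_rng(5)
        ratios = rng.lognormal(np.log(100), 0.6, size=401)
        t = compute_cost_thresholds(ratios)
        assert np.mean(ratios > t.q3) <= 0.25
        assert np.mean(ratios < t.q1) <= 0.25


class TestRateCosts:
    thresholds = CostThresholds(80.0, 120.0)

    def test_high_ratio_dominates(self):
        r = rate_costs(100.0, 300.0, self.thresholds, alternative_rating=2)
        assert r.value == 3
        assert r.aspects == {"medicine_cost": 3, "personnel_cost": 2}

    def test_mid_ratio_with_low_personnel(self):
        r = rate_costs(100.0, 100.0, self.thresholds, alternative_rating=1)
        assert r.value == 2
        assert r.aspects == {"medicine_cost": 2, "personnel_cost": 1}

    @pytest.mark.parametrize("ratio,expected", [
        (79.9, 1), (80.0, 2), (120.0, 2), (120.1, 3)])
    def test_boundaries_are_moderate(self, ratio, expected):
        r = rate_costs(100.0, ratio, self.thresholds, alternative_rating=1)
        assert r.aspects["medicine_cost"] == expected

    def test_missing_prices_fall_through_to_personnel(self):
        r = rate_costs(None, None, None, alternative_rating=3)
        assert r.value == 3
        assert "medicine_cost" not in r.aspects

    def test_zero_original_price_omits_medicine_cost(self, caplog):
        with caplog.at_level("WARNING"):
            r = rate_costs(0.0, 50.0, self.thresholds, alternative_rating=2)
        assert r.value == 2
        assert "medicine_cost" not in r.aspects

    def test_thresholds_required_when_priced(self):
        with pytest.raises(ThresholdError):
            rate_costs(100.0, 100.0, None, alternative_rating=1)


class TestNPatients:
    def test_hospital_without_count_is_moderate(self):
        assert rate_n_patients(None, hospital_product=True,
                               orphan_indication=False) == 2

    @pytest.mark.parametrize("hospital", [True, False])
    def test_orphan_indication_overrides(self, hospital):
        assert rate_n_patients(500_000, hospital, True) == 1

    @pytest.mark.parametrize("count,expected", [
        (1, 1), (1_000, 1), (1_001, 2), (99_999, 2), (100_000, 3),
        (500_000, 3)])
    def test_count_thresholds(self, count, expected):
        assert rate_n_patients(count, False, False) == expected

    def test_no_information_rejected(self):
        with pytest.raises(RatingError, match="n_patients"):
            rate_n_patients(None, False, False)


class TestRateRecord:
    thresholds = CostThresholds(80.0, 120.0)

    def test_high_impact_composition(self, make_record):
        record = make_record(
            solution_category="therapeutic_substitution",
            disease_severity="severe", age_min=0.0, age_max=12.0,
            price_original=100.0, price_alternative=300.0,
            users_prior_year=None, hospital_product=True)
        profile = rate_record(record, self.thresholds)
        assert profile.as_tuple() == (2, 3, 3, 3, 2)

    def test_low_impact_composition(self, make_record):
        record = make_record(
            solution_category="generic_substitution",
            disease_severity="mild", age_min=20.0, age_max=60.0,
            price_original=100.0, price_alternative=100.0,
            users_prior_year=None, orphan_indication=True)
        profile = rate_record(record, self.thresholds)
        # costs = max(medicine 2, personnel 1) = 2
        assert profile.as_tuple() == (1, 1, 1, 2, 1)

    def test_prerated_record_bypasses_raters(self, make_record):
        record = make_record(
            rating_alternative_product=2, rating_disease=3,
            rating_susceptibility=3, rating_costs=2, rating_n_patients=2,
            solution_category=None, disease_severity=None)
        profile = rate_record(record, thresholds=None)
        assert profile.as_tuple() == (2, 3, 3, 2, 2)

    def test_rater_errors_name_the_element(self, make_record):
        record = make_record(disease_severity=None)
        with pytest.raises(RatingError, match="disease"):
            rate_record(record, self.thresholds)

    def test_deterministic(self, make_record):
        record = make_record()
        a = rate_record(record, self.thresholds)
        b = rate_record(record, self.thresholds)
        assert a == b


class TestProfileInvariants:
    def test_element_must_equal_max_of_aspects(self):
        with pytest.raises(ValueError, match="max of aspects"):
            ElementProfile(1, 1, 1, 1, 1,
                           aspects={"vulnerability": 2, "trust": 1})

    def test_personnel_cost_tracks_alternative(self):
        with pytest.raises(ValueError, match="personnel_cost"):
            ElementProfile(1, 1, 1, 2, 1, aspects={"personnel_cost": 2,
                                                   "medicine_cost": 1})

    @given(vulnerability=ratings, trust=ratings, bump=st.booleans())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_raising_an_aspect_never_lowers_the_element(self, vulnerability,
                                                        trust, bump):
        flags = ({"media_attention"} if trust == 3
                 else {"patient_contact_notes"} if trust == 2
                 else frozenset())
        ages = {1: (20, 60), 2: (10, 60), 3: (0, 12)}[vulnerability]
        base = rate_susceptibility(*ages, flags)
        if bump and trust < 3:
            higher = rate_susceptibility(*ages, {"media_attention"})
            assert higher.value >= base.value
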