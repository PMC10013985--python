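"""Cohort statistics: sample size, characterisation, tests, summaries."""

import numpy as np
import pandas as pd
import pytest

from shortage_impact import (CohortCharacteristics, SampleSizeParams,
                             ShortageDataError, characterize, compare_strata,
                             draw_sample, rating_distribution,
                             representativeness_test, required_sample_size,
                             stratified_scores, yearly_trends)
from shortage_impact.simulate import GeneratorSpec, generate


def params(n, confidence=0.95, margin=0.05, proportion=0.5):
    return SampleSizeParams(population_size=n, confidence=confidence,
                            margin=margin, proportion=proportion)


class TestSampleSize:
    @pytest.mark.parametrize("n_pop,expected", [
        (1844, 319),          # the study's own calculation
        (1_000_000_000, 385),  # ~uncorrected Cochran n0
        (100, 80),            # strong finite-population correction
    ])
    def test_finite_population_correction(self, n_pop, expected):
        assert required_sample_size(params(n_pop)) == expected

    def test_monotone_in_margin_and_population(self):
        assert (required_sample_size(params(1844, margin=0.10))
                < required_sample_size(params(1844, margin=0.05)))
        assert (required_sample_size(params(500))
                <= required_sample_size(params(5000)))
        assert (required_sample_size(params(1844, confidence=0.90))
                <= required_sample_size(params(1844, confidence=0.99)))

    def test_converges_to_uncorrected_for_large_population(self):
        big = required_sample_size(params(10 ** 9))
        bigger = required_sample_size(params(10 ** 10))
        assert big == bigger == 385

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            params(1844, margin=0.0)


@pytest.fixture(scope="module")
def cohort():
    return generate(GeneratorSpec(n=400, seed=2)).cohort


class TestDrawSample:
    def test_sample_of_everything_is_the_cohort(self, cohort):
        s = draw_sample(cohort, len(cohort), seed=1)
        assert {r.shortage_id for r in s} == {r.shortage_id for r in cohort}

    def test_same_seed_same_sample(self, cohort):
        a = draw_sample(cohort, 50, seed=9)
        b = draw_sample(cohort, 50, seed=9)
        assert [r.shortage_id for r in a] == [r.shortage_id for r in b]

    def test_unique_ids_without_replacement(self, cohort):
        s = draw_sample(cohort, 324, seed=4)
        ids = [r.shortage_id for r in s]
        assert len(set(ids)) == 324

    def test_oversampling_rejected(self, cohort):
        with pytest.raises(ShortageDataError):
            draw_sample(cohort, len(cohort) + 1, seed=0)


class TestCharacterize:
    def test_published_oral_share(self):
        chars = CohortCharacteristics.from_counts(
            {"route": {"oral": 1046, "other": 1844 - 1046}})
        table = chars.tables["route"]
        oral = table.loc[table["category"] == "oral", "pct"].iloc[0]
        assert oral == pytest.approx(56.7, abs=0.05)

    def test_small_cohort_arithmetic(self, make_record):
        from shortage_impact import Cohort
        records = [make_record(shortage_id=f"s{i}", product_name=f"p{i}",
                               route="oral" if i < 2 else "parenteral")
                   for i in range(4)]
        chars = characterize(Cohort(records=records))
        table = chars.tables["route"]
        assert table.set_index("category").loc["oral", "pct"] == 50.0

    def test_population_only_when_no_sample(self):
        synth = generate(GeneratorSpec(n=100, seed=1))
        chars = characterize(synth.cohort)
        assert chars.sample_n is None
        assert "sample_count" not in chars.tables["route"].columns

    def test_sample_columns_aligned_to_population(self):
        synth = generate(GeneratorSpec(n=200, seed=1))
        sample = draw_sample(synth.cohort, 50, seed=3)
        chars = characterize(synth.cohort, sample)
        t = chars.tables["atc_class"]
        assert t["sample_count"].sum() == 50
        assert chars.sample_n == 50


class TestRepresentativeness:
    def test_exactly_proportional_sample_gives_zero(self):
        pop = CohortCharacteristics.from_counts(
            {"year": {2012: 400, 2013: 600}})
        sample = CohortCharacteristics.from_counts(
            {"year": {2012: 40, 2013: 60}})
        res = representativeness_test(pop, sample, "year")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_year_statistic(self):
        # expected counts 68.0 / 77.1 / 82.6 / 96.3 for a 324-case sample
        pop = CohortCharacteristics.from_counts(
            {"year": {2012: 387, 2013: 439, 2014: 470, 2015: 548}})
        sample = CohortCharacteristics.from_counts(
            {"year": {2012: 58, 2013: 77, 2014: 77, 2015: 112}})
        res = representativeness_test(pop, sample, "year")
        assert res.df == 3
        assert res.statistic == pytest.approx(4.41, abs=0.02)
        assert 0.15 < res.p_value < 0.30

    def test_single_category_is_degenerate(self):
        pop = CohortCharacteristics.from_counts({"route": {"oral": 100}})
        sample = CohortCharacteristics.from_counts({"route": {"oral": 10}})
        with pytest.raises(ShortageDataError, match="df"):
            representativeness_test(pop, sample, "route")

    def test_small_expected_counts_flagged(self):
        pop = CohortCharacteristics.from_counts(
            {"atc_class": {"N": 990, "P": 10}})
        sample = CohortCharacteristics.from_counts(
            {"atc_class": {"N": 99, "P": 1}})
        res = representativeness_test(pop, sample, "atc_class")
        assert any("expected count < 5" in n for n in res.notes)


def scored_frame(scores, stratum=None, name="g"):
    df = pd.DataFrame({"overall": scores})
    if stratum is not None:
        df[name] = stratum
    return df


class TestStratifiedScores:
    def test_single_record(self):
        s, = stratified_scores(scored_frame([8], ["N"], "atc_class"),
                               "atc_class")
        assert (s.median, s.q1, s.q3, s.n) == (8, 8, 8, 1)

    def test_odd_count_median(self):
        s, = stratified_scores(scored_frame([4, 8, 12], ["N"] * 3,
                                            "atc_class"), "atc_class")
        assert s.median == 8

    def test_even_count_midpoint(self):
        s, = stratified_scores(scored_frame([36, 36, 54, 72], ["L"] * 4,
                                            "atc_class"), "atc_class")
        assert s.median == 45.0

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ShortageDataError):
            stratified_scores(scored_frame([1, 2]), "atc_class")


class TestCompareStrata:
    def test_identical_groups_have_zero_statistic(self):
        df = scored_frame([5, 5, 5, 5], ["a", "a", "b", "b"])
        results = compare_strata(df, "g")
        assert results[0].statistic == 0.0
        assert results[0].p_value == 1.0

    def test_hand_computed_kruskal_wallis(self):
        df = scored_frame([1, 2, 3, 4], ["a", "a", "b", "b"])
        omnibus = compare_strata(df, "g")[0]
        assert omnibus.statistic == pytest.approx(2.4)
        assert omnibus.df == 1

    def test_three_strata_give_three_dunn_pairs(self):
        df = scored_frame(list(range(9)), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        results = compare_strata(df, "g")
        dunn = [r for r in results if r.name == "Dunn"]
        assert len(dunn) == 3
        assert {frozenset(r.groups) for r in dunn} == {
            frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))}

    def test_rank_based_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(1, 244, size=60).astype(float)
        strata = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        raw = compare_strata(scored_frame(scores, strata), "g")
        cubed = compare_strata(scored_frame(scores ** 3, strata), "g")
        assert raw[0].statistic == pytest.approx(cubed[0].statistic)
        assert raw[0].p_value == pytest.approx(cubed[0].p_value)

    def test_adjustment_labels_and_ordering(self):
        rng = np.random.default_rng(1)
        df = scored_frame(rng.normal(size=30),
                          ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        none = {r.groups: r.p_value for r in compare_strata(df, "g",
                                                            adjust="none")[1:]}
        bonf = {r.groups: r.p_value for r in compare_strata(df, "g")[1:]}
        holm = {r.groups: r.p_value
                for r in compare_strata(df, "g", adjust="holm")[1:]}
        for pair in none:
            assert none[pair] <= holm[pair] <= bonf[pair]
            assert bonf[pair] == pytest.approx(min(1.0, none[pair] * 3))

    def test_fewer_than_two_strata_rejected(self):
        with pytest.raises(ShortageDataError):
            compare_strata(scored_frame([1, 2], ["a", "a"]), "g")


def small_scored():
    cols = ["rating_alternative_product", "rating_disease",
            "rating_susceptibility", "rating_costs", "rating_n_patients"]
    df = pd.DataFrame([(3, 1, 1, 1, 1), (1, 1, 1, 1, 1)], columns=cols)
    df["direct_high"] = [True, False]
    df["indirect_high"] = [False, False]
    return df


class TestRatingDistribution:
    def test_all_low_cohort(self):
        df = small_scored().iloc[[1]]
        dist = rating_distribution(df)
        assert (dist.element_pct[1] == 100.0).all()
        assert dist.shares["high_on_ge1"] == 0.0
        assert dist.shares["low_on_all"] == 100.0

    def test_half_high_on_alternative(self):
        dist = rating_distribution(small_scored())
        assert dist.element_pct.loc["alternative_product", 3] == 50.0
        assert dist.shares["high_on_ge1"] == 50.0
        assert dist.shares["high_on_ge2"] == 0.0

    def test_percentages_sum_to_100_per_element(self):
        synth = generate(GeneratorSpec(n=500, seed=8))
        from shortage_impact import ShortageImpactModel
        dist = ShortageImpactModel(synth.cohort).fit().rating_distribution()
        sums = dist.element_pct.sum(axis=1)
        assert np.allclose(sums, 100.0)
        assert (dist.shares["high_on_ge1"]
                >= dist.shares["high_on_ge2"])


class TestYearlyTrends:
    def test_single_year(self):
        df = small_scored()
        df["overall"] = [3, 1]
        df["year"] = 2013
        trends = yearly_trends(df)
        assert len(trends.score_summaries) == 1
        assert trends.score_summaries[0].stratum == 2013

    def test_identical_years_have_identical_medians(self):
        df = pd.concat([small_scored(), small_scored()], ignore_index=True)
        df["overall"] = [3, 1, 3, 1]
        df["year"] = [2012, 2012, 2013, 2013]
        trends = yearly_trends(df)
        medians = {s.stratum: s.median for s in trends.score_summaries}
        assert medians[2012] == medians[2013]

    def test_constant_generator_years_close(self):
        synth = generate(GeneratorSpec(n=2000, seed=12))
        from shortage_impact import ShortageImpactModel
        res = ShortageImpactModel(synth.cohort).fit()
        trends = res.yearly_trends()
        medians = [s.median for s in trends.score_summaries]
        assert max(medians) - min(medians) <= 6  # resampling wobble on 1-243
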