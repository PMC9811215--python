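"""Scoring semantics: per-question points, zone/category relative scores,
NA exclusion, traffic lights and cross-farm aggregation."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beat.assessment import (
    Answer, Assessment, ScoringError, aggregate_scores, score_category,
    score_question, score_zone, traffic_light,
)
from beat.questionnaire import Zone

from conftest import make_toy_questionnaire, random_assessment, \
    uniform_assessment


class TestScoreQuestion:
    def test_full_compliance_scores_one(self, toy_questionnaire):
        q = toy_questionnaire.questions[0]
        assert score_question(q, Answer(q.question_id, "full")) == 1.0

    def test_no_compliance_scores_zero(self, toy_questionnaire):
        q = toy_questionnaire.questions[0]
        assert score_question(q, Answer(q.question_id, "none")) == 0.0

    def test_na_returns_none(self, toy_questionnaire):
        q = toy_questionnaire.questions[0]
        assert score_question(q, Answer(q.question_id, None)) is None

    def test_unknown_option_errors(self, toy_questionnaire):
        q = toy_questionnaire.questions[0]
        with pytest.raises(KeyError):
            score_question(q, Answer(q.question_id, "bogus"))


class TestZoneAndCategoryScores:
    def test_fully_compliant_zone_scores_one(self, questionnaire):
        asmt = uniform_assessment(questionnaire, "f1", "full")
        for zone in Zone:
            assert score_zone(questionnaire, asmt, zone).relative == 1.0

    def test_all_zero_assessment_scores_zero(self, questionnaire):
        asmt = uniform_assessment(questionnaire, "f1", "none")
        for zone in Zone:
            assert score_zone(questionnaire, asmt, zone).relative == 0.0

    def test_na_excluded_from_both_sides(self, toy_questionnaire):
        # half NA, rest fully compliant -> relative exactly 1
        answers = []
        for i, q in enumerate(toy_questionnaire.questions):
            answers.append(
                Answer(q.question_id, "full" if i % 2 else None)
            )
        asmt = Assessment("f1", date(2020, 1, 1), answers)
        zs = score_zone(toy_questionnaire, asmt, Zone.GREEN)
        assert zs.relative == 1.0
        assert zs.n_na == 1 and zs.n_answered == 1

    def test_all_na_zone_errors(self, toy_questionnaire):
        answers = [Answer(q.question_id, None)
                   for q in toy_questionnaire.questions]
        asmt = Assessment("f1", date(2020, 1, 1), answers)
        with pytest.raises(ScoringError, match="no scorable"):
            score_zone(toy_questionnaire, asmt, Zone.RED)

    def test_category_equals_zone_for_single_category_zone(
        self, toy_questionnaire, rng
    ):
        # the toy instrument has exactly one category per zone
        asmt = random_assessment(toy_questionnaire, rng)
        for zone in Zone:
            try:
                zs = score_zone(toy_questionnaire, asmt, zone)
            except ScoringError:
                continue
            cs = score_category(toy_questionnaire, asmt, f"cat_{zone.value}")
            assert cs.relative == pytest.approx(zs.relative)

    def test_relative_matches_brute_force(self, questionnaire, rng):
        asmt = random_assessment(questionnaire, rng)
        for zone in Zone:
            zs = score_zone(questionnaire, asmt, zone)
            num = den = 0.0
            for q in questionnaire.questions_in_zone(zone):
                a = asmt.answer_for(q.question_id)
                if a is None or a.is_na:
                    continue
                num += q.option(a.option_id).points
                den += max(o.points for o in q.options)
            assert zs.relative == pytest.approx(num / den)
            assert zs.attained <= zs.attainable

    def test_answer_order_irrelevant(self, questionnaire, rng):
        asmt = random_assessment(questionnaire, rng)
        shuffled = Assessment(
            asmt.farm_id, asmt.date,
            [asmt.answers[i]
             for i in rng.permutation(len(asmt.answers))],
        )
        for zone in Zone:
            assert score_zone(questionnaire, asmt, zone) == score_zone(
                questionnaire, shuffled, zone
            )

    def test_zone_attained_is_sum_of_category_attained(
        self, questionnaire, rng
    ):
        asmt = random_assessment(questionnaire, rng, na_prob=0.0)
        for zone in Zone:
            zs = score_zone(questionnaire, asmt, zone)
            parts = [
                score_category(questionnaire, asmt, c.category_id)
                for c in questionnaire.categories_in_zone(zone)
            ]
            assert zs.attained == pytest.approx(
                sum(p.attained for p in parts)
            )

    def test_upgrade_never_decreases_scores(self, questionnaire, rng):
        asmt = random_assessment(questionnaire, rng, na_prob=0.0)
        before = {z: score_zone(questionnaire, asmt, z).relative
                  for z in Zone}
        # upgrade one random non-best answer to a strictly better option
        upgradable = []
        for a in asmt.answers:
            q = questionnaire.question(a.question_id)
            if q.option(a.option_id).points < q.max_points:
                upgradable.append(a)
        target = upgradable[int(rng.integers(len(upgradable)))]
        q = questionnaire.question(target.question_id)
        better = max(q.options, key=lambda o: o.points)
        new_answers = [
            Answer(a.question_id, better.option_id)
            if a.question_id == target.question_id else a
            for a in asmt.answers
        ]
        upgraded = Assessment(asmt.farm_id, asmt.date, new_answers)
        for zone in Zone:
            assert score_zone(
                questionnaire, upgraded, zone
            ).relative >= before[zone] - 1e-12

    def test_replicating_questions_leaves_relative_unchanged(self, rng):
        # scale-free: k-fold replication multiplies attained and attainable
        # by k, leaving the ratio untouched
        q1 = make_toy_questionnaire(n_questions_per_zone=2)
        q3 = make_toy_questionnaire(n_questions_per_zone=6)
        asmt1 = random_assessment(q1, rng, na_prob=0.0)
        by_choice = {a.question_id: a.option_id for a in asmt1.answers}
        answers3 = []
        for q in q3.questions:
            base = f"{q.category_id}_q{(int(q.question_id.split('_q')[-1]) - 1) % 2 + 1}"
            answers3.append(Answer(q.question_id, by_choice[base]))
        asmt3 = Assessment("f1", date(2020, 1, 1), answers3)
        for zone in Zone:
            assert score_zone(q3, asmt3, zone).relative == pytest.approx(
                score_zone(q1, asmt1, zone).relative
            )


class TestTrafficLight:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.0, "green"), (0.0, "red"), (0.55, "amber"),
         (0.4, "amber"), (0.7, "green"), (0.399, "red")],
    )
    def test_default_thresholds(self, value, expected):
        assert traffic_light(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ScoringError):
            traffic_light(1.2)

    def test_custom_thresholds(self):
        assert traffic_light(0.55, (0.2, 0.6)) == "amber"
        assert traffic_light(0.65, (0.2, 0.6)) == "green"

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(0, 1, allow_nan=False),
        b=st.floats(0, 1, allow_nan=False),
    )
    def test_monotone_in_relative(self, a, b):
        lo, hi = min(a, b), max(a, b)
        order = {"red": 0, "amber": 1, "green": 2}
        assert order[traffic_light(lo)] <= order[traffic_light(hi)]


class TestAggregation:
    def test_identical_scores_mean_one_sd_zero(self):
        scores = pd.DataFrame(
            {
                "farm_id": ["a", "b", "c"],
                "country": ["NL", "NL", "NL"],
                "category_id": ["bedding_materials"] * 3,
                "zone": ["green"] * 3,
                "relative": [1.0, 1.0, 1.0],
            }
        )
        out = aggregate_scores(scores, "country")
        assert out.loc[0, "mean"] == 1.0
        assert out.loc[0, "sd"] == 0.0

    def test_single_farm_sd_is_na(self):
        scores = pd.DataFrame(
            {"farm_id": ["a"], "country": ["CY"], "zone": ["red"],
             "relative": [0.5]}
        )
        out = aggregate_scores(scores, "country")
        assert out.loc[0, "mean"] == 0.5
        assert math.isnan(out.loc[0, "sd"])

    def test_overall_mean_pools_farms(self, rng):
        rel = rng.random(30)
        scores = pd.DataFrame(
            {
                "farm_id": [f"f{i}" for i in range(30)],
                "country": ["NL"] * 10 + ["CY"] * 5 + ["GR"] * 15,
                "zone": ["green"] * 30,
                "relative": rel,
            }
        )
        out = aggregate_scores(scores, "overall")
        assert out.loc[0, "mean"] == pytest.approx(rel.mean())
        assert out.loc[0, "n"] == 30

    def test_empty_table_rejected(self):
        with pytest.raises(ScoringError):
            aggregate_scores(pd.DataFrame(), "country")
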