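"""Shared fixtures: the packaged instrument, a small synthetic instrument,
and random-assessment builders."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from beat.assessment import Answer, Assessment
from beat.questionnaire import (
    AnswerOption, Question, Questionnaire, RiskCategory, Zone,
    load_questionnaire, packaged_questionnaire_path,
)


@pytest.fixture(scope="session")
def questionnaire() -> Questionnaire:
    return load_questionnaire(packaged_questionnaire_path())


def make_toy_questionnaire(n_questions_per_zone: int = 2) -> Questionnaire:
    """One category per zone, graded 0/0.5/1 options."""
    categories, questions = [], []
    for zone in Zone:
        cid = f"cat_{zone.value}"
        categories.append(RiskCategory(cid, zone, zone.value))
        for i in range(n_questions_per_zone):
            qid = f"{cid}_q{i+1}"
            questions.append(
                Question(
                    qid, cid, f"toy question {qid}",
                    (
                        AnswerOption("full", "full compliance", 1.0),
                        AnswerOption("half", "partial", 0.5),
                        AnswerOption("none", "no compliance", 0.0),
                    ),
                    allow_na=True,
                )
            )
    return Questionnaire("toy", "1", categories, questions)


@pytest.fixture
def toy_questionnaire() -> Questionnaire:
    return make_toy_questionnaire()


def uniform_assessment(q: Questionnaire, farm_id: str,
                       which: str) -> Assessment:
    """Every question answered with its best (``"full"``) or worst
    (``"none"``) option by points."""
    answers = []
    for question in q.questions:
        ranked = sorted(question.options, key=lambda o: o.points)
        opt = ranked[-1] if which == "full" else ranked[0]
        answers.append(Answer(question.question_id, opt.option_id))
    return Assessment(farm_id, date(2020, 1, 1), answers)


def random_assessment(q: Questionnaire, rng: np.random.Generator,
                      farm_id: str = "farm", na_prob: float = 0.1
                      ) -> Assessment:
    answers = []
    for question in q.questions:
        if question.allow_na and rng.random() < na_prob:
            answers.append(Answer(question.question_id, None))
        else:
            opt = question.options[int(rng.integers(len(question.options)))]
            answers.append(Answer(question.question_id, opt.option_id))
    return Assessment(farm_id, date(2020, 1, 1), answers)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240501)
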