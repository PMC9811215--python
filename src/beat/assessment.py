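"""Farm assessments and relative biosecurity scores.

A farm answers the questionnaire once per assessment date.  Every chosen
option contributes its compliance points (0-1); the points per zone (or per
risk category) are summed and divided by the attainable maximum, giving the
*relative score* on the same 0-1 scale.  1 means full compliance, 0 none.
Questions answered "not applicable" are excluded from both the numerator and
the denominator, so structurally inapplicable items (e.g. outdoor runs on an
indoor-only farm) do not depress the score.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .questionnaire import Question, Questionnaire, Zone

__all__ = [
    "NA",
    "FarmProfile",
    "Answer",
    "Assessment",
    "ZoneScore",
    "CategoryScore",
    "ScoringError",
    "score_question",
    "score_zone",
    "score_category",
    "score_all",
    "traffic_light",
    "aggregate_scores",
    "load_assessments",
    "write_assessments",
    "score_table",
]

#: marker for a "not applicable" answer
NA = None

DEFAULT_THRESHOLDS = (0.4, 0.7)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class FarmProfile:
    farm_id: str
    country: str
    n_houses: int = 1
    construction_year: Optional[int] = None
    veterinarian_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_houses < 1:
            raise ScoringError(f"farm {self.farm_id!r}: n_houses must be >= 1")


@dataclass(frozen=True)
class Answer:
    question_id: str
    option_id: Optional[str]  # None marks "not applicable"

    @property
    def is_na(self) -> bool:
        return self.option_id is None


@dataclass
class Assessment:
    farm_id: str
    date: Date
    answers: list[Answer] = field(default_factory=list)

    def __post_init__(self) -> None:
        qids = [a.question_id for a in self.answers]
        if len(set(qids)) != len(qids):
            dupes = sorted({q for q in qids if qids.count(q) > 1})
            raise ScoringError(
                f"assessment {self.farm_id}@{self.date}: multiple answers "
                f"for questions {dupes}"
            )
        self._by_question = {a.question_id: a for a in self.answers}

    def answer_for(self, question_id: str) -> Optional[Answer]:
        return self._by_question.get(question_id)

    def validate_against(self, q: Questionnaire) -> None:
        for a in self.answers:
            question = q.question(a.question_id)  # KeyError if unknown
            if a.is_na:
                if not question.allow_na:
                    raise ScoringError(
                        f"question {a.question_id!r} does not allow NA"
                    )
            else:
                question.option(a.option_id)


@dataclass(frozen=True)
class ZoneScore:
    zone: Zone
    attained: float
    attainable: float
    relative: float
    n_answered: int
    n_na: int


@dataclass(frozen=True)
class CategoryScore:
    category_id: str
    zone: Zone
    attained: float
    attainable: float
    relative: float
    n_answered: int
    n_na: int


def score_question(q: Question, a: Answer) -> Optional[float]:
    """Points of the chosen option; ``None`` for a not-applicable answer."""
    if a.question_id != q.question_id:
        raise ScoringError(
            f"answer for {a.question_id!r} scored against {q.question_id!r}"
        )
    if a.is_na:
        if not q.allow_na:
            raise ScoringError(f"question {q.question_id!r} does not allow NA")
        return None
    return q.option(a.option_id).points


def _score_questions(
    questions: Sequence[Question], asmt: Assessment, where: str
) -> tuple[float, float, int, int]:
    attained = attainable = 0.0
    n_answered = n_na = 0
    for question in questions:
        answer = asmt.answer_for(question.question_id)
        if answer is None or answer.is_na:
            n_na += answer is not None
            continue
        attained += score_question(question, answer)
        attainable += question.max_points
        n_answered += 1
    if n_answered == 0:
        raise ScoringError(f"no scorable questions in {where}")
    return attained, attainable, n_answered, n_na


def score_zone(q: Questionnaire, asmt: Assessment, zone: Zone) -> ZoneScore:
    """Relative score of one zone: attained / attainable over answered items."""
    attained, attainable, n_ans, n_na = _score_questions(
        q.questions_in_zone(zone), asmt, f"zone {zone.value}"
    )
    return ZoneScore(zone, attained, attainable, attained / attainable,
                     n_ans, n_na)


def score_category(
    q: Questionnaire, asmt: Assessment, category_id: str
) -> CategoryScore:
    cat = q.category(category_id)
    attained, attainable, n_ans, n_na = _score_questions(
        q.questions_in_category(category_id), asmt, f"category {category_id}"
    )
    return CategoryScore(category_id, cat.zone, attained, attainable,
                         attained / attainable, n_ans, n_na)


def score_all(
    q: Questionnaire, asmt: Assessment
) -> tuple[list[ZoneScore], list[CategoryScore]]:
    """Score every zone and category that has at least one scorable answer."""
    zone_scores, cat_scores = [], []
    for zone in q.zones:
        try:
            zone_scores.append(score_zone(q, asmt, zone))
        except ScoringError:
            continue
    for cat in q.categories:
        try:
            cat_scores.append(score_category(q, asmt, cat.category_id))
        except ScoringError:
            continue
    return zone_scores, cat_scores


def traffic_light(
    relative: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify a relative score as ``red``/``amber``/``green``.

    Defaults: red below 0.4, amber in [0.4, 0.7), green at or above 0.7.
    """
    lo, hi = thresholds
    if not 0.0 <= lo <= hi <= 1.0:
        raise ScoringError(f"invalid thresholds {thresholds}")
    if not 0.0 <= relative <= 1.0 or math.isnan(relative):
        raise ScoringError(f"relative score {relative} outside [0, 1]")
    if relative < lo:
        return "red"
    if relative < hi:
        return "amber"
    return "green"


def aggregate_scores(
    scores: pd.DataFrame, group_by: str = "country"
) -> pd.DataFrame:
    """Mean and sample SD of farm-level relative scores.

    ``scores`` needs columns ``farm_id``, ``relative`` and a grouping key
    (``country``) plus whatever identifies the item (``zone`` and/or
    ``category_id``).  ``group_by='overall'`` pools all farms; otherwise the
    mean is taken per country.  The pooled "overall" mean weights every farm
    equally (it is not a mean of country means).  A single-farm group gets
    SD ``NaN``.
    """
    if scores.empty:
        raise ScoringError("empty score table")
    item_cols = [c for c in ("zone", "category_id") if c in scores.columns]
    if group_by == "overall":
        keys = item_cols
    else:
        if group_by not in scores.columns:
            raise ScoringError(f"missing grouping column {group_by!r}")
        keys = [group_by] + item_cols
    if not keys:
        raise ScoringError("no item columns (zone/category_id) to group on")
    out = (
        scores.groupby(keys, observed=True)["relative"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


# ---------------------------------------------------------------------------
# I/O: answers file = one row per (farm, date, question); empty option = NA

_ANSWER_COLUMNS = ["farm_id", "date", "question_id", "option_id"]


def load_assessments(path: Union[str, Path]) -> list[Assessment]:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(_ANSWER_COLUMNS) - set(frame.columns)
    if missing:
        raise ScoringError(f"answers file missing columns {sorted(missing)}")
    out = []
    for (farm_id, date_str), grp in frame.groupby(
        ["farm_id", "date"], sort=True
    ):
        answers = [
            Answer(row.question_id, row.option_id or None)
            for row in grp.itertuples()
        ]
        out.append(Assessment(farm_id, Date.fromisoformat(date_str), answers))
    if not out:
        raise ScoringError("answers file contains no rows")
    return out


def write_assessments(
    assessments: Iterable[Assessment], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANSWER_COLUMNS)
        for asmt in assessments:
            for a in asmt.answers:
                writer.writerow(
                    [asmt.farm_id, asmt.date.isoformat(), a.question_id,
                     a.option_id or ""]
                )


def load_farms(path: Union[str, Path]) -> list[FarmProfile]:
    """Read a farm roster (columns farm_id, country[, n_houses,
    construction_year, veterinarian_id])."""
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    if not {"farm_id", "country"} <= set(frame.columns):
        raise ScoringError("farms file needs farm_id and country columns")
    return [
        FarmProfile(
            farm_id=row.farm_id,
            country=row.country,
            n_houses=int(getattr(row, "n_houses", "") or 1),
            construction_year=(
                int(row.construction_year)
                if getattr(row, "construction_year", "") else None
            ),
            veterinarian_id=getattr(row, "veterinarian_id", "") or None,
        )
        for row in frame.itertuples()
    ]


def score_table(
    q: Questionnaire,
    assessments: Sequence[Assessment],
    farms: Optional[Sequence[FarmProfile]] = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-farm zone and category score tables for a whole cohort.

    Returns ``(zone_table, category_table)``; each row carries attained,
    attainable, relative and traffic light.  If ``farms`` is given, a
    ``country`` column is joined in.
    """
    country = {f.farm_id: f.country for f in farms} if farms else {}
    zone_rows, cat_rows = [], []
    for asmt in assessments:
        asmt.validate_against(q)
        zscores, cscores = score_all(q, asmt)
        for zs in zscores:
            zone_rows.append(
                {
                    "farm_id": asmt.farm_id,
                    "country": country.get(asmt.farm_id, ""),
                    "zone": zs.zone.value,
                    "attained": zs.attained,
                    "attainable": zs.attainable,
                    "relative": zs.relative,
                    "n_answered": zs.n_answered,
                    "n_na": zs.n_na,
                    "traffic_light": traffic_light(zs.relative, thresholds),
                }
            )
        for cs in cscores:
            cat_rows.append(
                {
                    "farm_id": asmt.farm_id,
                    "country": country.get(asmt.farm_id, ""),
                    "zone": cs.zone.value,
                    "category_id": cs.category_id,
                    "attained": cs.attained,
                    "attainable": cs.attainable,
                    "relative": cs.relative,
                    "n_answered": cs.n_answered,
                    "n_na": cs.n_na,
                    "traffic_light": traffic_light(cs.relative, thresholds),
                }
            )
    return pd.DataFrame(zone_rows), pd.DataFrame(cat_rows)
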