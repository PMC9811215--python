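"""Data model and I/O for the zone-based biosecurity questionnaire.

The instrument follows the FAO 3-zone farm layout: a high-risk external
*red* zone, a medium-risk *orange* service zone and the access-restricted
*green* zone holding the broiler house, plus the two transition zones
(*red-orange*, *orange-green*) covering the crossings between them.  Each
zone groups thematic risk categories; each category groups questions; each
question offers predefined answer options scored on a 0-1 compliance scale
(1 = fully compliant, 0 = no compliance).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

__all__ = [
    "Zone",
    "AnswerOption",
    "Question",
    "RiskCategory",
    "Questionnaire",
    "QuestionnaireError",
    "load_questionnaire",
    "write_questionnaire",
    "max_points",
    "packaged_questionnaire_path",
]


class QuestionnaireError(ValueError):
    """Raised for malformed or internally inconsistent questionnaire input."""


class Zone(enum.Enum):
    """The five farm zones, ordered inside-out (green = broiler house)."""

    GREEN = "green"
    ORANGE_GREEN = "orange_green"
    ORANGE = "orange"
    RED_ORANGE = "red_orange"
    RED = "red"

    @property
    def order(self) -> int:
        return _ZONE_ORDER[self]

    def __lt__(self, other: "Zone") -> bool:
        if not isinstance(other, Zone):
            return NotImplemented
        return self.order < other.order

    @classmethod
    def parse(cls, text: str) -> "Zone":
        key = text.strip().lower().replace("-", "_").replace(" ", "_")
        try:
            return cls(key)
        except ValueError:
            raise QuestionnaireError(f"unknown zone label: {text!r}") from None


_ZONE_ORDER = {
    Zone.GREEN: 0,
    Zone.ORANGE_GREEN: 1,
    Zone.ORANGE: 2,
    Zone.RED_ORANGE: 3,
    Zone.RED: 4,
}

ZONES_INSIDE_OUT = tuple(sorted(Zone, key=lambda z: z.order))


@dataclass(frozen=True)
class AnswerOption:
    """One predefined answer with its compliance points in [0, 1]."""

    option_id: str
    text: str
    points: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.points <= 1.0:
            raise QuestionnaireError(
                f"option {self.option_id!r}: points {self.points} outside [0, 1]"
            )


@dataclass(frozen=True)
class Question:
    question_id: str
    category_id: str
    text: str
    options: tuple[AnswerOption, ...]
    allow_na: bool = True

    def __post_init__(self) -> None:
        if len(self.options) < 2:
            raise QuestionnaireError(
                f"question {self.question_id!r}: needs at least 2 options"
            )
        ids = [o.option_id for o in self.options]
        if len(set(ids)) != len(ids):
            raise QuestionnaireError(
                f"question {self.question_id!r}: duplicate option ids"
            )
        pts = [o.points for o in self.options]
        # a question must discriminate: a best (full-compliance) option and
        # at least one strictly worse one
        if max(pts) != 1.0:
            raise QuestionnaireError(
                f"question {self.question_id!r}: best option scores "
                f"{max(pts)}, expected a full-compliance option with 1.0"
            )
        if min(pts) >= 1.0:
            raise QuestionnaireError(
                f"question {self.question_id!r}: all options score 1.0, "
                "question cannot discriminate"
            )

    @property
    def max_points(self) -> float:
        return max(o.points for o in self.options)

    def option(self, option_id: str) -> AnswerOption:
        for o in self.options:
            if o.option_id == option_id:
                return o
        raise KeyError(
            f"question {self.question_id!r} has no option {option_id!r}"
        )


@dataclass(frozen=True)
class RiskCategory:
    category_id: str
    zone: Zone
    label: str


@dataclass
class Questionnaire:
    name: str
    version: str
    categories: list[RiskCategory] = field(default_factory=list)
    questions: list[Question] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def category(self, category_id: str) -> RiskCategory:
        try:
            return self._category_index[category_id]
        except KeyError:
            raise KeyError(f"unknown category {category_id!r}") from None

    def question(self, question_id: str) -> Question:
        try:
            return self._question_index[question_id]
        except KeyError:
            raise KeyError(f"unknown question {question_id!r}") from None

    def questions_in_category(self, category_id: str) -> list[Question]:
        self.category(category_id)
        return [q for q in self.questions if q.category_id == category_id]

    def questions_in_zone(self, zone: Zone) -> list[Question]:
        cats = {c.category_id for c in self.categories if c.zone == zone}
        return [q for q in self.questions if q.category_id in cats]

    def categories_in_zone(self, zone: Zone) -> list[RiskCategory]:
        return [c for c in self.categories if c.zone == zone]

    @property
    def zones(self) -> list[Zone]:
        return sorted({c.zone for c in self.categories}, key=lambda z: z.order)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if not self.questions:
            raise QuestionnaireError("no questions")
        cat_ids = [c.category_id for c in self.categories]
        if len(set(cat_ids)) != len(cat_ids):
            dupes = {c for c in cat_ids if cat_ids.count(c) > 1}
            raise QuestionnaireError(f"duplicate category ids: {sorted(dupes)}")
        q_ids = [q.question_id for q in self.questions]
        if len(set(q_ids)) != len(q_ids):
            dupes = {q for q in q_ids if q_ids.count(q) > 1}
            raise QuestionnaireError(f"duplicate question ids: {sorted(dupes)}")
        self._category_index = {c.category_id: c for c in self.categories}
        self._question_index = {q.question_id: q for q in self.questions}
        for q in self.questions:
            if q.category_id not in self._category_index:
                raise QuestionnaireError(
                    f"question {q.question_id!r} references unknown "
                    f"category {q.category_id!r}"
                )
        answered_cats = {q.category_id for q in self.questions}
        empty = set(self._category_index) - answered_cats
        if empty:
            raise QuestionnaireError(
                f"categories without questions: {sorted(empty)}"
            )
        missing_zones = set(Zone) - {c.zone for c in self.categories}
        if missing_zones:
            raise QuestionnaireError(
                "zones without categories: "
                f"{sorted(z.value for z in missing_zones)}"
            )


# ---------------------------------------------------------------------------
# I/O

_COLUMNS = [
    "zone",
    "category_id",
    "category_label",
    "question_id",
    "question_text",
    "option_id",
    "option_text",
    "points",
    "allow_na",
]

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(text: str, line: int) -> bool:
    key = text.strip().lower()
    if key in _TRUE:
        return True
    if key in _FALSE:
        return False
    raise QuestionnaireError(f"line {line}: invalid boolean {text!r}")


def load_questionnaire(path: Union[str, Path]) -> Questionnaire:
    """Read and validate a questionnaire definition file.

    Two equivalent on-disk forms are accepted: a CSV table with one row per
    answer option (columns ``zone, category_id, category_label, question_id,
    question_text, option_id, option_text, points, allow_na``), or a YAML
    tree (``.yaml``/``.yml``) with the same content nested by category and
    question.  Both are validated against the same invariants.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        return _load_yaml(path)
    return _load_csv(path)


def _load_csv(path: Path) -> Questionnaire:
    categories: dict[str, RiskCategory] = {}
    # question_id -> (category_id, text, allow_na, [options])
    questions: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise QuestionnaireError("no questions")
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise QuestionnaireError(
                f"missing columns: {sorted(missing)} (header row mandatory)"
            )
        n_rows = 0
        for row in reader:
            line = reader.line_num
            n_rows += 1
            try:
                zone = Zone.parse(row["zone"])
                points = float(row["points"])
            except QuestionnaireError:
                raise
            except (TypeError, ValueError) as exc:
                raise QuestionnaireError(
                    f"line {line}: malformed row ({exc})"
                ) from None
            cid = row["category_id"].strip()
            cat = RiskCategory(cid, zone, row["category_label"].strip())
            prev = categories.setdefault(cid, cat)
            if prev.zone != cat.zone:
                raise QuestionnaireError(
                    f"line {line}: category {cid!r} assigned to two zones"
                )
            qid = row["question_id"].strip()
            rec = questions.setdefault(
                qid,
                {
                    "category_id": cid,
                    "text": row["question_text"].strip(),
                    "allow_na": _parse_bool(row["allow_na"], line),
                    "options": [],
                },
            )
            if rec["category_id"] != cid:
                raise QuestionnaireError(
                    f"line {line}: question {qid!r} assigned to two categories"
                )
            rec["options"].append(
                AnswerOption(row["option_id"].strip(),
                             row["option_text"].strip(), points)
            )
    if n_rows == 0:
        raise QuestionnaireError("no questions")
    qs = [
        Question(qid, rec["category_id"], rec["text"],
                 tuple(rec["options"]), rec["allow_na"])
        for qid, rec in questions.items()
    ]
    return Questionnaire(
        name=path.stem, version="1", categories=list(categories.values()),
        questions=qs,
    )


def _load_yaml(path: Path) -> Questionnaire:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or not doc.get("categories"):
        raise QuestionnaireError("no questions")
    categories, questions = [], []
    for cat in doc["categories"]:
        zone = Zone.parse(cat["zone"])
        categories.append(
            RiskCategory(cat["category_id"], zone, cat.get("label", ""))
        )
        for q in cat.get("questions", []):
            opts = tuple(
                AnswerOption(o["option_id"], o.get("text", ""),
                             float(o["points"]))
                for o in q.get("options", [])
            )
            questions.append(
                Question(q["question_id"], cat["category_id"],
                         q.get("text", ""), opts,
                         bool(q.get("allow_na", True)))
            )
    return Questionnaire(
        name=str(doc.get("name", path.stem)),
        version=str(doc.get("version", "1")),
        categories=categories,
        questions=questions,
    )


def write_questionnaire(q: Questionnaire, path: Union[str, Path]) -> None:
    """Serialize to the CSV form (one row per answer option)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for question in q.questions:
            cat = q.category(question.category_id)
            for opt in question.options:
                writer.writerow(
                    [
                        cat.zone.value,
                        cat.category_id,
                        cat.label,
                        question.question_id,
                        question.text,
                        opt.option_id,
                        opt.text,
                        repr(opt.points),
                        str(question.allow_na).lower(),
                    ]
                )


def max_points(q: Questionnaire, zone: Zone) -> float:
    """Attainable points in a zone: sum of each question's best option.

    This is the denominator of the relative score for a fully answered zone.
    """
    questions = q.questions_in_zone(zone)
    if not questions:
        raise QuestionnaireError(f"zone {zone.value!r} has no questions")
    return float(sum(question.max_points for question in questions))


def packaged_questionnaire_path() -> Path:
    """Path of the questionnaire instrument shipped with the package."""
    return Path(__file__).parent / "data" / "questionnaire.csv"
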