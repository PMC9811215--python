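"""Tailor-made farm health plans and intervention accounting.

A health plan lists SMART interventions (Specific, Measurable, Achievable,
Relevant, Time-bound) drafted by farmer and veterinarian from the zone
scores.  Each intervention carries the zone and risk category it addresses,
an estimated implementation horizon (short / medium / long term), a cost
class (low / medium / high) and, after follow-up, whether it was realized.

This module computes the standard cohort summaries: intervention counts per
zone, the term-by-cost cross-tabulation with realization percentages, and
per-group realization rates.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .questionnaire import Questionnaire, Zone, ZONES_INSIDE_OUT

__all__ = [
    "TERMS",
    "COSTS",
    "Intervention",
    "HealthPlan",
    "PlanError",
    "suggest_targets",
    "zone_totals",
    "crosstab_term_cost",
    "realization_rate",
    "load_plans",
    "write_plans",
]

TERMS = ("short", "medium", "long")
COSTS = ("low", "medium", "high")


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class Intervention:
    intervention_id: str
    farm_id: str
    zone: Zone
    category_id: str
    description: str
    term: str
    cost: str
    realized: bool
    date_planned: Optional[Date] = None
    date_evaluated: Optional[Date] = None

    def __post_init__(self) -> None:
        if self.term not in TERMS:
            raise PlanError(
                f"intervention {self.intervention_id!r}: term {self.term!r} "
                f"not in {TERMS}"
            )
        if self.cost not in COSTS:
            raise PlanError(
                f"intervention {self.intervention_id!r}: cost {self.cost!r} "
                f"not in {COSTS}"
            )


@dataclass
class HealthPlan:
    farm_id: str
    interventions: list[Intervention] = field(default_factory=list)
    created_from: Optional[str] = None  # assessment reference

    def __post_init__(self) -> None:
        ids = [iv.intervention_id for iv in self.interventions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PlanError(
                f"plan for {self.farm_id!r}: duplicate intervention ids {dupes}"
            )

    def validate_against(self, q: Questionnaire) -> None:
        for iv in self.interventions:
            cat = q.category(iv.category_id)
            if cat.zone != iv.zone:
                raise PlanError(
                    f"intervention {iv.intervention_id!r}: zone "
                    f"{iv.zone.value!r} does not match category "
                    f"{iv.category_id!r} ({cat.zone.value})"
                )


def _all_interventions(plans: Iterable[HealthPlan]) -> list[Intervention]:
    return [iv for plan in plans for iv in plan.interventions]


def suggest_targets(
    scores: pd.DataFrame, k: int, perfection_filter: float = 1.0
) -> list[str]:
    """Rank candidate intervention targets: the k lowest-scoring categories.

    ``scores`` needs columns ``category_id``, ``zone``, ``relative``.
    Categories at or above ``perfection_filter`` (default 1.0: already fully
    compliant) are excluded.  Ties are broken by zone, inside-out (green
    first), then by ``category_id``.  This is a ranking aid only; the SMART
    intervention text is authored by farmer and veterinarian.
    """
    if k < 1:
        raise PlanError("k must be >= 1")
    eligible = scores[scores["relative"] < perfection_filter].copy()
    zone_rank = {z.value: z.order for z in Zone}
    eligible["_zone_rank"] = [
        zone_rank[z.value if isinstance(z, Zone) else str(z)]
        for z in eligible["zone"]
    ]
    ranked = eligible.sort_values(
        ["relative", "_zone_rank", "category_id"], kind="mergesort"
    )["category_id"].tolist()
    if k > len(ranked):
        warnings.warn(
            f"requested k={k} targets but only {len(ranked)} imperfect "
            "categories exist; returning all",
            stacklevel=2,
        )
        return ranked
    return ranked[:k]


def zone_totals(plans: Iterable[HealthPlan]) -> dict[Zone, int]:
    """Planned interventions per zone across all plans (zeros included)."""
    counts = {zone: 0 for zone in ZONES_INSIDE_OUT}
    for iv in _all_interventions(plans):
        counts[iv.zone] += 1
    return counts


def crosstab_term_cost(plans: Iterable[HealthPlan]) -> pd.DataFrame:
    """3x3 term-by-cost table of counts and realization percentages.

    Rows are terms (short/medium/long), columns costs (low/medium/high);
    each cell holds ``n_planned`` and ``percent_realized`` (rounded to a
    whole number; ``NaN`` when nothing was planned in the cell).
    """
    rows = []
    ivs = _all_interventions(plans)
    for term in TERMS:
        for cost in COSTS:
            cell = [iv for iv in ivs if iv.term == term and iv.cost == cost]
            n = len(cell)
            pct = (
                round(100.0 * sum(iv.realized for iv in cell) / n)
                if n else float("nan")
            )
            rows.append(
                {"term": term, "cost": cost, "n_planned": n,
                 "percent_realized": pct}
            )
    return pd.DataFrame(rows)


def realization_rate(
    plans: Iterable[HealthPlan],
    group_by: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Percent of planned interventions realized, to one decimal.

    ``group_by`` maps ``farm_id`` to a group label (typically the country);
    when omitted, a single ``overall`` rate is returned.  A group with no
    planned interventions yields ``NaN`` with a warning.
    """
    tallies: dict[str, list[int]] = {}
    for plan in plans:
        group = group_by.get(plan.farm_id, "?") if group_by else "overall"
        planned, realized = tallies.setdefault(group, [0, 0])
        tallies[group][0] = planned + len(plan.interventions)
        tallies[group][1] = realized + sum(
            iv.realized for iv in plan.interventions
        )
    out = {}
    for group, (planned, realized) in sorted(tallies.items()):
        if planned == 0:
            warnings.warn(f"group {group!r} has no planned interventions",
                          stacklevel=2)
            out[group] = float("nan")
        else:
            out[group] = round(100.0 * realized / planned, 1)
    return out


# ---------------------------------------------------------------------------
# I/O

_PLAN_COLUMNS = [
    "intervention_id", "farm_id", "zone", "category_id", "description",
    "term", "cost", "realized", "date_planned", "date_evaluated",
]


def load_plans(path: Union[str, Path]) -> list[HealthPlan]:
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = set(_PLAN_COLUMNS[:8]) - set(frame.columns)
    if missing:
        raise PlanError(f"plans file missing columns {sorted(missing)}")
    plans = []
    for farm_id, grp in frame.groupby("farm_id", sort=True):
        ivs = []
        for row in grp.itertuples():
            realized = row.realized.strip().lower()
            if realized not in {"true", "false"}:
                raise PlanError(
                    f"intervention {row.intervention_id!r}: realized must be "
                    f"true/false, got {row.realized!r}"
                )
            ivs.append(
                Intervention(
                    intervention_id=row.intervention_id,
                    farm_id=farm_id,
                    zone=Zone.parse(row.zone),
                    category_id=row.category_id,
                    description=getattr(row, "description", ""),
                    term=row.term,
                    cost=row.cost,
                    realized=realized == "true",
                    date_planned=(
                        Date.fromisoformat(row.date_planned)
                        if getattr(row, "date_planned", "") else None
                    ),
                    date_evaluated=(
                        Date.fromisoformat(row.date_evaluated)
                        if getattr(row, "date_evaluated", "") else None
                    ),
                )
            )
        plans.append(HealthPlan(farm_id, ivs))
    return plans


def write_plans(plans: Iterable[HealthPlan], path: Union[str, Path]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PLAN_COLUMNS)
        for plan in plans:
            for iv in plan.interventions:
                writer.writerow(
                    [
                        iv.intervention_id, iv.farm_id, iv.zone.value,
                        iv.category_id, iv.description, iv.term, iv.cost,
                        str(iv.realized).lower(),
                        iv.date_planned.isoformat() if iv.date_planned else "",
                        iv.date_evaluated.isoformat()
                        if iv.date_evaluated else "",
                    ]
                )
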