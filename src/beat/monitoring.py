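"""Per-cycle flock monitoring: antimicrobial use, footpad lesions, mortality.

Each broiler house is followed for four production cycles — cycles 1-2
before the health-plan interventions, cycles 3-4 after.  For every cycle
the record holds whether the flock was treated with antimicrobials and for
how many days, the footpad-lesion class counts scored at slaughter, the
cumulative mortality and basic slaughter parameters.

Footpad lesions are scored per bird in three severity classes (0 = none,
1 = mild, 2 = severe); the flock-level score is the weighted prevalence

    100 * (w0*n0 + w1*n1 + w2*n2) / (n0 + n1 + n2)

with default weights (0, 0.5, 2), giving the conventional 0-200 scale used
in slaughterhouse welfare surveillance.  The weights are configurable.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_FOOTPAD_WEIGHTS",
    "FootpadRecord",
    "ProductionCycle",
    "MonitoringError",
    "phase_of_cycle",
    "flock_footpad_score",
    "amu_summary",
    "flock_treatment_prevalence",
    "load_cycles",
    "write_cycles",
    "cycles_frame",
]

DEFAULT_FOOTPAD_WEIGHTS = (0.0, 0.5, 2.0)

PRE_CYCLES = (1, 2)
POST_CYCLES = (3, 4)


class MonitoringError(ValueError):
    pass


def phase_of_cycle(cycle_index: int) -> str:
    """'pre' for cycles 1-2 (before interventions), 'post' for 3-4."""
    if cycle_index in PRE_CYCLES:
        return "pre"
    if cycle_index in POST_CYCLES:
        return "post"
    raise MonitoringError(f"cycle_index must be 1-4, got {cycle_index}")


def flock_footpad_score(
    n_class0: int,
    n_class1: int,
    n_class2: int,
    weights: tuple[float, float, float] = DEFAULT_FOOTPAD_WEIGHTS,
) -> float:
    """Weighted footpad-lesion prevalence of a flock on the 0-200 scale."""
    counts = (n_class0, n_class1, n_class2)
    if any(c < 0 for c in counts):
        raise MonitoringError(f"negative class counts {counts}")
    total = sum(counts)
    if total == 0:
        raise MonitoringError("no scored birds (all class counts zero)")
    if any(w < 0 for w in weights):
        raise MonitoringError(f"negative weights {weights}")
    return 100.0 * sum(w * c for w, c in zip(weights, counts)) / total


@dataclass(frozen=True)
class FootpadRecord:
    n_class0: int
    n_class1: int
    n_class2: int

    def flock_score(
        self, weights: tuple[float, float, float] = DEFAULT_FOOTPAD_WEIGHTS
    ) -> float:
        return flock_footpad_score(
            self.n_class0, self.n_class1, self.n_class2, weights
        )


@dataclass(frozen=True)
class ProductionCycle:
    farm_id: str
    cycle_index: int
    start_month: int
    amu_used: bool
    amu_days: int
    footpad: FootpadRecord
    mortality_pct: float
    slaughter_age_days: Optional[int] = None
    slaughter_weight_g: Optional[float] = None

    def __post_init__(self) -> None:
        phase_of_cycle(self.cycle_index)  # raises on bad index
        if not 1 <= self.start_month <= 12:
            raise MonitoringError(
                f"start_month must be 1-12, got {self.start_month}"
            )
        if self.amu_days < 0:
            raise MonitoringError(f"negative amu_days {self.amu_days}")
        if not self.amu_used and self.amu_days != 0:
            raise MonitoringError(
                f"farm {self.farm_id} cycle {self.cycle_index}: amu_days "
                f"{self.amu_days} > 0 but amu_used is false"
            )
        if self.mortality_pct < 0:
            raise MonitoringError(f"negative mortality {self.mortality_pct}")

    @property
    def phase(self) -> str:
        return phase_of_cycle(self.cycle_index)


def cycles_frame(
    cycles: Sequence[ProductionCycle],
    country: Optional[Mapping[str, str]] = None,
    footpad_weights: tuple[float, float, float] = DEFAULT_FOOTPAD_WEIGHTS,
) -> pd.DataFrame:
    """Flatten cycle records into a DataFrame (one row per farm-cycle)."""
    rows = []
    for c in cycles:
        rows.append(
            {
                "farm_id": c.farm_id,
                "country": country.get(c.farm_id, "") if country else "",
                "cycle_index": c.cycle_index,
                "phase": c.phase,
                "start_month": c.start_month,
                "amu_used": c.amu_used,
                "amu_days": c.amu_days,
                "footpad_score": c.footpad.flock_score(footpad_weights),
                "mortality_pct": c.mortality_pct,
                "slaughter_age_days": c.slaughter_age_days,
                "slaughter_weight_g": c.slaughter_weight_g,
            }
        )
    return pd.DataFrame(rows)


def amu_summary(
    cycles: Sequence[ProductionCycle],
    country: Mapping[str, str],
) -> pd.DataFrame:
    """Antimicrobial use per country and cycle.

    For each (country, cycle) cell: the number of farms that treated the
    flock, and the median and mean treatment days among those treating
    farms only (mean to one decimal).  Cells with no treating farm report
    count 0 and ``NaN`` summaries, so non-users never shift the medians.
    """
    frame = cycles_frame(cycles, country)
    rows = []
    countries = sorted(frame["country"].unique())
    for ctry in countries:
        for cycle in (1, 2, 3, 4):
            cell = frame[
                (frame["country"] == ctry) & (frame["cycle_index"] == cycle)
            ]
            users = cell[cell["amu_used"]]
            rows.append(
                {
                    "country": ctry,
                    "cycle_index": cycle,
                    "phase": phase_of_cycle(cycle),
                    "n_farms_with_amu": len(users),
                    "median_days": (
                        float(users["amu_days"].median()) if len(users)
                        else float("nan")
                    ),
                    "mean_days": (
                        round(float(users["amu_days"].mean()), 1)
                        if len(users) else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def flock_treatment_prevalence(
    cycles: Sequence[ProductionCycle],
    country: Mapping[str, str],
) -> dict[str, int]:
    """Percent of flock-cycles treated with antimicrobials, per country.

    The denominator is all observed farm-cycles of the group (complete
    follow-up is four cycles per farm; missing cycles simply do not appear
    in either numerator or denominator).  Percentages are truncated to
    whole numbers, the convention used in cohort reports of this kind.
    """
    frame = cycles_frame(cycles, country)
    if frame.empty:
        raise MonitoringError("no cycles provided")
    out = {}
    for ctry, grp in frame.groupby("country", sort=True):
        n_expected = 4 * grp["farm_id"].nunique()
        if len(grp) < n_expected:
            warnings.warn(
                f"{ctry}: {n_expected - len(grp)} farm-cycles missing; "
                "prevalence computed over observed cycles only",
                stacklevel=2,
            )
        out[str(ctry)] = int(100.0 * grp["amu_used"].sum() / len(grp))
    return out


# ---------------------------------------------------------------------------
# I/O: cycle log = one row per farm-cycle

_CYCLE_COLUMNS = [
    "farm_id", "cycle_index", "start_month", "amu_used", "amu_days",
    "footpad_class0", "footpad_class1", "footpad_class2",
    "mortality_pct", "slaughter_age_days", "slaughter_weight_g",
]


def load_cycles(path: Union[str, Path]) -> list[ProductionCycle]:
    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = set(_CYCLE_COLUMNS[:9]) - set(frame.columns)
    if missing:
        raise MonitoringError(f"cycle log missing columns {sorted(missing)}")
    cycles = []
    for row in frame.itertuples():
        amu_used = row.amu_used.strip().lower()
        if amu_used not in {"true", "false"}:
            raise MonitoringError(
                f"farm {row.farm_id}: amu_used must be true/false, "
                f"got {row.amu_used!r}"
            )
        cycles.append(
            ProductionCycle(
                farm_id=row.farm_id,
                cycle_index=int(row.cycle_index),
                start_month=int(row.start_month),
                amu_used=amu_used == "true",
                amu_days=int(row.amu_days),
                footpad=FootpadRecord(
                    int(row.footpad_class0),
                    int(row.footpad_class1),
                    int(row.footpad_class2),
                ),
                mortality_pct=float(row.mortality_pct),
                slaughter_age_days=(
                    int(row.slaughter_age_days)
                    if getattr(row, "slaughter_age_days", "") else None
                ),
                slaughter_weight_g=(
                    float(row.slaughter_weight_g)
                    if getattr(row, "slaughter_weight_g", "") else None
                ),
            )
        )
    return cycles


def write_cycles(
    cycles: Iterable[ProductionCycle], path: Union[str, Path]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CYCLE_COLUMNS)
        for c in cycles:
            writer.writerow(
                [
                    c.farm_id, c.cycle_index, c.start_month,
                    str(c.amu_used).lower(), c.amu_days,
                    c.footpad.n_class0, c.footpad.n_class1, c.footpad.n_class2,
                    repr(float(c.mortality_pct)),
                    c.slaughter_age_days if c.slaughter_age_days is not None
                    else "",
                    repr(float(c.slaughter_weight_g))
                    if c.slaughter_weight_g is not None else "",
                ]
            )
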