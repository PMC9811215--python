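"""Published summary tables of the three-country pilot cohort.

The instrument was piloted on 35 broiler houses — 13 in the Netherlands
(NL), 7 in Cyprus (CY) and 15 in Greece (GR) — followed for four
production cycles.  The farm-level raw data were never published; what is
available are the cohort summary tables: per-category intervention counts
and mean relative scores per country, the term-by-cost intervention
cross-tabulation, and per-cycle antimicrobial-use counts.  This module
ships those tables and expands the count tables back into record lists so
the accounting functions can be exercised against the published margins.

Because the per-category table and the term-by-cost table are independent
margins of the intervention list (and are not mutually consistent to the
last unit), each expansion fills the fields the *other* margin would
provide with labelled placeholders; expanded records are only meaningful
for the margin they came from.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .health_plan import HealthPlan, Intervention
from .monitoring import FootpadRecord, ProductionCycle
from .questionnaire import Zone

__all__ = [
    "COUNTRIES",
    "N_FARMS",
    "intervention_counts",
    "category_scores",
    "term_cost_counts",
    "amu_counts",
    "interventions_as_plans",
    "term_cost_as_plans",
    "amu_as_cycles",
    "farm_country_map",
]

_DATA = Path(__file__).parent / "data"

COUNTRIES = ("NL", "CY", "GR")
N_FARMS = {"NL": 13, "CY": 7, "GR": 15}


def intervention_counts() -> pd.DataFrame:
    """Planned/realized interventions per country, zone and risk category."""
    return pd.read_csv(_DATA / "cohort_interventions.csv")


def category_scores() -> pd.DataFrame:
    """Mean relative score per risk category, per country and overall."""
    return pd.read_csv(_DATA / "cohort_category_scores.csv")


def term_cost_counts() -> pd.DataFrame:
    """Interventions per (term, cost) cell with realization percentage."""
    return pd.read_csv(_DATA / "cohort_term_cost.csv")


def amu_counts() -> pd.DataFrame:
    """Farms with antimicrobial use per country and cycle, with treatment
    day summaries among users."""
    return pd.read_csv(_DATA / "cohort_amu.csv")


def interventions_as_plans() -> list[HealthPlan]:
    """Expand the per-category counts into one pooled plan per country.

    Term and cost were not recorded in this margin; they are filled with
    the placeholder ``short``/``low`` and must not be cross-tabulated.
    """
    frame = intervention_counts()
    plans = []
    for country, grp in frame.groupby("country", sort=False):
        ivs = []
        for row in grp.itertuples():
            for i in range(int(row.planned)):
                ivs.append(
                    Intervention(
                        intervention_id=f"{country}-{row.category_id}-{i+1}",
                        farm_id=country,
                        zone=Zone.parse(row.zone),
                        category_id=row.category_id,
                        description="expanded from published category counts",
                        term="short",
                        cost="low",
                        realized=i < int(row.realized),
                    )
                )
        plans.append(HealthPlan(farm_id=str(country), interventions=ivs))
    return plans


def term_cost_as_plans() -> list[HealthPlan]:
    """Expand the term-by-cost counts into a single pooled plan.

    The realized count per cell is recovered as ``round(planned *
    pct / 100)``; zone and category were not recorded in this margin and
    are filled with a fixed placeholder category.
    """
    frame = term_cost_counts()
    ivs = []
    for row in frame.itertuples():
        planned = int(row.planned)
        realized = (
            int(round(planned * float(row.realized_pct) / 100.0))
            if planned and pd.notna(row.realized_pct) else 0
        )
        for i in range(planned):
            ivs.append(
                Intervention(
                    intervention_id=f"{row.term}-{row.cost}-{i+1}",
                    farm_id="pooled",
                    zone=Zone.GREEN,
                    category_id="purchased_animals",
                    description="expanded from published term-cost counts",
                    term=row.term,
                    cost=row.cost,
                    realized=i < realized,
                )
            )
    return [HealthPlan(farm_id="pooled", interventions=ivs)]


def amu_as_cycles() -> list[ProductionCycle]:
    """Expand the antimicrobial-use counts into farm-cycle records.

    For each (country, cycle) cell the first ``n_farms_with_amu`` farms of
    the country are flagged as treated, with the published median as the
    per-farm treatment days; the remaining farms are untreated.  Which
    farms carry the flag is arbitrary — prevalences and user counts are
    exact, per-farm day values are representative only.  Footpad counts,
    start months and mortality are neutral placeholders.
    """
    frame = amu_counts()
    cycles = []
    for row in frame.itertuples():
        n_farms = int(row.n_farms)
        n_amu = int(row.n_farms_with_amu)
        days = max(1, int(round(float(row.median_days))))
        for i in range(n_farms):
            treated = i < n_amu
            cycles.append(
                ProductionCycle(
                    farm_id=f"{row.country}-{i+1:02d}",
                    cycle_index=int(row.cycle_index),
                    start_month=1,
                    amu_used=treated,
                    amu_days=days if treated else 0,
                    footpad=FootpadRecord(100, 0, 0),
                    mortality_pct=0.0,
                )
            )
    return cycles


def farm_country_map() -> dict[str, str]:
    """farm_id -> country for the expanded records of this module."""
    mapping = {c: c for c in COUNTRIES}
    for country, n in N_FARMS.items():
        for i in range(n):
            mapping[f"{country}-{i+1:02d}"] = country
    mapping["pooled"] = "pooled"
    return mapping
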