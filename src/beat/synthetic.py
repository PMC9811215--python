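"""Synthetic farm cohorts with the statistical structure the analyses assume.

The generator emulates a three-country broiler cohort: per-farm zone
compliance drawn from zone-specific Beta distributions and converted into
questionnaire answers; health-plan interventions drawn for weak categories
with term/cost labels and Bernoulli realization; and four production cycles
per farm with seasonal footpad scores, phase-dependent antimicrobial use
and overdispersed treatment-day counts.

Defaults mirror the pilot cohort the instrument was developed on: 13 + 7 +
15 farms in three countries, Beta compliance means per zone matching the
observed zone score levels, a realization gradient that falls with cost
and term, winter-peaking footpad seasonality, and antimicrobial treatment
in roughly three quarters (pre) / two thirds (post) of flock-cycles with
1-11 treatment days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date as Date
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .assessment import Answer, Assessment, FarmProfile
from .health_plan import COSTS, TERMS, HealthPlan, Intervention
from .monitoring import FootpadRecord, ProductionCycle
from .questionnaire import Questionnaire, Zone, load_questionnaire, \
    packaged_questionnaire_path

__all__ = ["CohortConfig", "Cohort", "generate_cohort"]


def _default_countries() -> tuple[tuple[str, int], ...]:
    return (("NL", 13), ("CY", 7), ("GR", 15))


def _default_beta() -> dict[Zone, tuple[float, float]]:
    # Beta(mean*c, (1-mean)*c) with concentration c = 5; means follow the
    # observed per-zone score levels (green/orange ~0.64, transition zones
    # ~0.53-0.59, red ~0.50)
    means = {
        Zone.GREEN: 0.64,
        Zone.ORANGE_GREEN: 0.53,
        Zone.ORANGE: 0.64,
        Zone.RED_ORANGE: 0.59,
        Zone.RED: 0.50,
    }
    return {z: (m * 5.0, (1.0 - m) * 5.0) for z, m in means.items()}


def _default_realization() -> dict[tuple[str, str], float]:
    # decreasing along both the term and the cost axis
    return {
        ("short", "low"): 0.55, ("short", "medium"): 0.40,
        ("short", "high"): 0.25,
        ("medium", "low"): 0.50, ("medium", "medium"): 0.20,
        ("medium", "high"): 0.10,
        ("long", "low"): 0.30, ("long", "medium"): 0.15,
        ("long", "high"): 0.01,
    }


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults emulate the pilot cohort."""

    seed: int = 0
    countries: tuple[tuple[str, int], ...] = field(
        default_factory=_default_countries
    )
    n_cycles: int = 4
    beta_params_per_zone: dict[Zone, tuple[float, float]] = field(
        default_factory=_default_beta
    )
    #: expected interventions per weak (score < weak_threshold) category
    intervention_rate: float = 0.8
    weak_threshold: float = 0.7
    term_probs: tuple[float, float, float] = (0.42, 0.34, 0.24)
    cost_probs: tuple[float, float, float] = (0.49, 0.29, 0.22)
    realization_probs: dict[tuple[str, str], float] = field(
        default_factory=_default_realization
    )
    #: flock footpad score model: baseline + amplitude*cos(winter phase)
    #: + country offset + N(0, noise_sd)
    footpad_baseline: float = 80.0
    footpad_month_amplitude: float = 30.0
    footpad_noise_sd: float = 25.0
    footpad_country_sd: float = 15.0
    #: probability a flock-cycle is treated with antimicrobials, (pre, post)
    amu_prob_by_phase: tuple[float, float] = (0.74, 0.67)
    #: negative binomial (mean, dispersion) for treatment days, truncated >= 1
    amu_days_distribution: tuple[float, float] = (6.0, 4.0)
    na_prob: float = 0.05
    construction_year_range: tuple[int, int] = (1975, 2018)

    def validate(self) -> None:
        if self.n_cycles < 1 or self.n_cycles % 2:
            raise ValueError("n_cycles must be a positive even number")
        if not self.countries or any(n < 1 for _, n in self.countries):
            raise ValueError("each country needs n_farms >= 1")
        for zone, (a, b) in self.beta_params_per_zone.items():
            if a <= 0 or b <= 0:
                raise ValueError(
                    f"Beta parameters for {zone.value} must be positive"
                )
        probs = (
            list(self.realization_probs.values())
            + list(self.term_probs) + list(self.cost_probs)
            + list(self.amu_prob_by_phase) + [self.na_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.intervention_rate < 0:
            raise ValueError("intervention_rate must be >= 0")
        mean, disp = self.amu_days_distribution
        if mean <= 0 or disp <= 0:
            raise ValueError("amu_days_distribution parameters must be > 0")
        if self.footpad_noise_sd < 0 or self.footpad_country_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class Cohort:
    questionnaire: Questionnaire
    farms: list[FarmProfile]
    assessments: list[Assessment]
    plans: list[HealthPlan]
    cycles: list[ProductionCycle]

    @property
    def country_map(self) -> dict[str, str]:
        return {f.farm_id: f.country for f in self.farms}

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Emit the four standard delimited files into ``out_dir``."""
        from .assessment import write_assessments
        from .health_plan import write_plans
        from .monitoring import write_cycles
        from .questionnaire import write_questionnaire

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "questionnaire": out_dir / "questionnaire.csv",
            "answers": out_dir / "answers.csv",
            "plans": out_dir / "plans.csv",
            "cycles": out_dir / "cycles.csv",
            "farms": out_dir / "farms.csv",
        }
        write_questionnaire(self.questionnaire, paths["questionnaire"])
        write_assessments(self.assessments, paths["answers"])
        write_plans(self.plans, paths["plans"])
        write_cycles(self.cycles, paths["cycles"])
        with open(paths["farms"], "w", encoding="utf-8") as fh:
            fh.write("farm_id,country,n_houses,construction_year\n")
            for f in self.farms:
                fh.write(
                    f"{f.farm_id},{f.country},{f.n_houses},"
                    f"{f.construction_year}\n"
                )
        return paths


def _seasonal_term(month: int) -> float:
    """Cosine peaking in mid-winter (January), trough in July."""
    return math.cos(2.0 * math.pi * (month - 1) / 12.0)


def _truncated_negbin(
    rng: np.random.Generator, mean: float, dispersion: float
) -> int:
    """Negative binomial draw (mean/dispersion parametrization), >= 1."""
    n = dispersion
    p = n / (n + mean)
    for _ in range(1000):
        draw = int(rng.negative_binomial(n, p))
        if draw >= 1:
            return draw
    return 1


def generate_cohort(
    cfg: Optional[CohortConfig] = None,
    questionnaire: Optional[Questionnaire] = None,
) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``cfg.seed``.

    Farm compliance: for each farm and zone a compliance level ``p`` is
    drawn from the zone's Beta distribution; every question in the zone is
    then answered with the best option with probability ``p`` and the worst
    option otherwise, so the expected relative zone score equals ``p``.
    Questions that allow it are independently marked not-applicable with a
    small probability.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    q = questionnaire or load_questionnaire(packaged_questionnaire_path())

    farms: list[FarmProfile] = []
    assessments: list[Assessment] = []
    plans: list[HealthPlan] = []
    cycles: list[ProductionCycle] = []

    country_offset = {
        name: rng.normal(0.0, cfg.footpad_country_sd)
        for name, _ in cfg.countries
    }
    lo_year, hi_year = cfg.construction_year_range

    for country, n_farms in cfg.countries:
        for i in range(n_farms):
            farm_id = f"{country}-{i+1:03d}"
            farms.append(
                FarmProfile(
                    farm_id=farm_id,
                    country=country,
                    n_houses=1,
                    construction_year=int(rng.integers(lo_year, hi_year + 1)),
                )
            )
            # --- assessment ------------------------------------------------
            compliance = {
                zone: float(rng.beta(*cfg.beta_params_per_zone[zone]))
                for zone in Zone
            }
            answers = []
            for question in q.questions:
                zone = q.category(question.category_id).zone
                if question.allow_na and rng.random() < cfg.na_prob:
                    answers.append(Answer(question.question_id, None))
                    continue
                ranked = sorted(question.options, key=lambda o: o.points)
                chosen = (
                    ranked[-1] if rng.random() < compliance[zone]
                    else ranked[0]
                )
                answers.append(
                    Answer(question.question_id, chosen.option_id)
                )
            asmt = Assessment(farm_id, Date(2020, 1, 1), answers)
            assessments.append(asmt)

            # --- health plan ----------------------------------------------
            from .assessment import score_all

            _, cat_scores = score_all(q, asmt)
            ivs = []
            for cs in sorted(cat_scores, key=lambda c: c.category_id):
                if cs.relative >= cfg.weak_threshold:
                    continue
                for j in range(int(rng.poisson(cfg.intervention_rate))):
                    term = TERMS[
                        int(rng.choice(3, p=_norm(cfg.term_probs)))
                    ]
                    cost = COSTS[
                        int(rng.choice(3, p=_norm(cfg.cost_probs)))
                    ]
                    ivs.append(
                        Intervention(
                            intervention_id=f"{farm_id}-{cs.category_id}-{j+1}",
                            farm_id=farm_id,
                            zone=cs.zone,
                            category_id=cs.category_id,
                            description=f"improve {cs.category_id}",
                            term=term,
                            cost=cost,
                            realized=bool(
                                rng.random()
                                < cfg.realization_probs[(term, cost)]
                            ),
                            date_planned=Date(2020, 2, 1),
                        )
                    )
            plans.append(HealthPlan(farm_id, ivs, created_from=farm_id))

            # --- production cycles ----------------------------------------
            first_month = int(rng.integers(1, 13))
            year = farms[-1].construction_year
            for cycle in range(1, cfg.n_cycles + 1):
                # consecutive grow-outs start roughly 2 months apart
                month = (first_month - 1 + 2 * (cycle - 1)) % 12 + 1
                mu = (
                    cfg.footpad_baseline
                    + cfg.footpad_month_amplitude * _seasonal_term(month)
                    + country_offset[country]
                    + rng.normal(0.0, cfg.footpad_noise_sd)
                )
                footpad = _score_to_counts(mu)
                phase_idx = 0 if cycle <= cfg.n_cycles // 2 else 1
                treated = rng.random() < cfg.amu_prob_by_phase[phase_idx]
                days = (
                    _truncated_negbin(rng, *cfg.amu_days_distribution)
                    if treated else 0
                )
                cycles.append(
                    ProductionCycle(
                        farm_id=farm_id,
                        cycle_index=cycle,
                        start_month=month,
                        amu_used=treated,
                        amu_days=days,
                        footpad=footpad,
                        mortality_pct=float(
                            max(0.0, rng.normal(3.5, 1.0))
                        ),
                        slaughter_age_days=int(rng.integers(38, 45)),
                        slaughter_weight_g=float(rng.normal(2600.0, 150.0)),
                    )
                )

    return Cohort(q, farms, assessments, plans, cycles)


def _norm(p: Sequence[float]) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    return arr / arr.sum()


def _score_to_counts(target: float, n_birds: int = 100) -> FootpadRecord:
    """Class counts over ``n_birds`` whose flock score is closest to
    ``target`` on the default 0-200 scale (class-2 birds first, then a
    class-1 remainder)."""
    target = float(np.clip(target, 0.0, 200.0))
    # with default weights: score = (0.5*n1 + 2*n2) * 100 / n_birds
    units = target * n_birds / 100.0  # = 0.5*n1 + 2*n2
    n2 = min(n_birds, int(units // 2.0))
    n1 = min(n_birds - n2, int(round((units - 2.0 * n2) / 0.5)))
    n0 = n_birds - n1 - n2
    return FootpadRecord(n0, n1, n2)
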