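"""Statistical evaluation of the cohort.

Three analysis families:

* between-country comparisons of relative zone scores with two-sample
  Wilcoxon rank-sum tests (exact null distribution on small tie-free
  samples, normal approximation with tie correction otherwise);
* pre/post-intervention comparisons of footpad and mortality outcomes with
  Kruskal-Wallis tests (either the two phases or the four cycles as
  groups);
* a linear mixed-effects model for the flock footpad score with a random
  intercept per country and candidate fixed effects cycle number, start
  month (seasonality) and house construction year, selected by greedy
  forward search on AIC.

Mixed models are fitted by maximum likelihood (not REML) so that AIC is
comparable across different fixed-effect sets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TestResult",
    "ModelFit",
    "CANDIDATE_TERMS",
    "rank_sum_test",
    "kruskal_wallis",
    "pairwise_zone_tests",
    "prepost_tests",
    "fit_footpad_model",
    "forward_select_aic",
]

#: candidate fixed effects for the footpad model, in tie-break order
CANDIDATE_TERMS = ("construction_year", "cycle_index", "start_month")

#: significance threshold used in reports
ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ModelFit:
    fixed_terms: tuple[str, ...]
    random_terms: tuple[str, ...]
    aic: float
    coefficients: dict[str, float]
    n_obs: int
    log_likelihood: float = field(default=float("nan"), compare=False)
    p_values: dict[str, float] = field(default_factory=dict, compare=False)
    std_errors: dict[str, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.aic):
            raise ValueError("non-finite AIC")


# ---------------------------------------------------------------------------
# rank tests

def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    groups: tuple[str, str] = ("x", "y"),
) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Uses the exact null distribution when both samples have at most 10
    observations and the pooled data are tie-free; otherwise the normal
    approximation with mid-rank tie correction and continuity correction.
    Degenerate input (every pooled value identical) returns p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1",
                      stacklevel=2)
        return TestResult("wilcoxon_rank_sum", len(x) * len(y) / 2.0, 1.0,
                          groups, (len(x), len(y)))
    exact = len(x) <= 10 and len(y) <= 10 and not _has_ties(pooled)
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return TestResult(
        "wilcoxon_rank_sum", float(res.statistic), float(res.pvalue),
        groups, (len(x), len(y)),
    )


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    groups: Optional[tuple[str, ...]] = None,
) -> TestResult:
    """Kruskal-Wallis H test with tie correction, chi-square reference."""
    samples = [np.asarray(s, dtype=float) for s in samples if len(s) > 0]
    if len(samples) < 2:
        raise ValueError("need at least two nonempty groups")
    if sum(len(s) for s in samples) < 3:
        raise ValueError("need at least three observations in total")
    if groups is None:
        groups = tuple(f"g{i+1}" for i in range(len(samples)))
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; H = 0, p = 1",
                      stacklevel=2)
        return TestResult("kruskal_wallis", 0.0, 1.0, groups,
                          tuple(len(s) for s in samples))
    res = scipy.stats.kruskal(*samples)
    return TestResult(
        "kruskal_wallis", float(res.statistic), float(res.pvalue),
        groups, tuple(len(s) for s in samples),
    )


def pairwise_zone_tests(zone_scores: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum tests for every country pair within every zone.

    ``zone_scores`` needs columns ``country``, ``zone``, ``relative`` (one
    row per farm per zone).  No multiplicity correction is applied across
    the country pairs; each p-value stands on its own.
    """
    rows = []
    for zone, zgrp in zone_scores.groupby("zone", sort=False):
        countries = sorted(zgrp["country"].unique())
        for a, b in itertools.combinations(countries, 2):
            res = rank_sum_test(
                zgrp.loc[zgrp["country"] == a, "relative"],
                zgrp.loc[zgrp["country"] == b, "relative"],
                groups=(a, b),
            )
            rows.append(
                {
                    "zone": zone, "group_a": a, "group_b": b,
                    "n_a": res.n_per_group[0], "n_b": res.n_per_group[1],
                    "statistic": res.statistic, "p_value": res.p_value,
                    "significant": res.p_value < ALPHA,
                }
            )
    return pd.DataFrame(rows)


def prepost_tests(
    cycles: pd.DataFrame,
    outcomes: Sequence[str] = ("footpad_score", "mortality_pct"),
    n_phases: int = 2,
) -> pd.DataFrame:
    """Kruskal-Wallis pre/post comparison per country for each outcome.

    ``n_phases=2`` pools cycles into pre (1-2) vs post (3-4); ``n_phases=4``
    keeps the four cycles as separate groups.
    """
    if n_phases not in (2, 4):
        raise ValueError("n_phases must be 2 or 4")
    key = "phase" if n_phases == 2 else "cycle_index"
    rows = []
    for country, cgrp in cycles.groupby("country", sort=True):
        for outcome in outcomes:
            samples, labels = [], []
            for level, lgrp in cgrp.groupby(key, sort=True):
                samples.append(lgrp[outcome].to_numpy())
                labels.append(str(level))
            res = kruskal_wallis(samples, tuple(labels))
            rows.append(
                {
                    "country": country, "outcome": outcome,
                    "grouping": key, "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.p_value < ALPHA,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# footpad mixed model

def _term_formula(term: str, month_encoding: str) -> str:
    if term == "start_month":
        if month_encoding == "categorical":
            return "C(start_month)"
        if month_encoding == "harmonic":
            return (
                "np.sin(2 * np.pi * start_month / 12) + "
                "np.cos(2 * np.pi * start_month / 12)"
            )
        raise ValueError(f"unknown month encoding {month_encoding!r}")
    if term in ("cycle_index", "construction_year"):
        return term
    raise ValueError(f"unknown candidate term {term!r}")


_MODEL_COLUMNS = ("footpad_score", "country", "cycle_index", "start_month",
                  "construction_year")


def fit_footpad_model(
    cycles: pd.DataFrame,
    fixed_terms: Sequence[str] = (),
    month_encoding: str = "categorical",
) -> ModelFit:
    """Fit the footpad mixed model with the given fixed-effect terms.

    ``cycles`` is a farm-cycle table with columns ``footpad_score``,
    ``country``, ``cycle_index``, ``start_month``, ``construction_year``.
    The model always carries a random intercept per country and is fitted
    by ML.  A fit with (numerically) zero country variance is kept, with a
    warning, rather than refitted.

    AIC is computed as -2*logL + 2*k with k counting the fixed effects, the
    random-intercept variance and the residual variance, so models with
    different fixed-effect sets are directly comparable.
    """
    missing = [c for c in _MODEL_COLUMNS if c not in cycles.columns]
    if missing:
        raise ValueError(f"cycle table missing columns {missing}")
    data = cycles[list(_MODEL_COLUMNS)].dropna().copy()
    if data["country"].nunique() < 2:
        raise ValueError("need at least two countries for the random effect")
    rhs = " + ".join(
        [_term_formula(t, month_encoding) for t in fixed_terms]
    ) or "1"
    model = smf.mixedlm(
        f"footpad_score ~ {rhs}", data=data, groups=data["country"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*[Ss]ingular.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        result = model.fit(reml=False)
        if not np.isfinite(result.llf):
            # near-singular random-effects variance can defeat the default
            # optimizer; retry with more robust methods
            for method in ("lbfgs", "cg", "powell"):
                result = model.fit(reml=False, method=method)
                if np.isfinite(result.llf):
                    break
    if float(result.cov_re.iloc[0, 0]) < 1e-8:
        warnings.warn(
            "singular fit: estimated country variance is zero; "
            "model retained", stacklevel=2,
        )
    k = len(result.fe_params) + model.k_re * (model.k_re + 1) // 2 + 1
    llf = float(result.llf)
    return ModelFit(
        fixed_terms=tuple(fixed_terms),
        random_terms=("country",),
        aic=-2.0 * llf + 2.0 * k,
        coefficients={name: float(v)
                      for name, v in result.fe_params.items()},
        n_obs=int(result.nobs),
        log_likelihood=llf,
        p_values={name: float(result.pvalues[name])
                  for name in result.fe_params.index},
        std_errors={name: float(result.bse[name])
                    for name in result.fe_params.index},
    )


def forward_select_aic(
    cycles: pd.DataFrame,
    candidates: Sequence[str] = CANDIDATE_TERMS,
    month_encoding: str = "categorical",
    verbose: bool = False,
) -> ModelFit:
    """Greedy forward selection of fixed effects by AIC.

    Starts from the random-intercept-only model; at each step the candidate
    whose addition lowers AIC the most is entered; selection stops when no
    remaining candidate lowers AIC.  Deterministic given the data: exact
    AIC ties are broken by candidate name order.
    """
    unknown = set(candidates) - set(CANDIDATE_TERMS)
    if unknown:
        raise ValueError(f"unknown candidates {sorted(unknown)}")
    selected: list[str] = []
    remaining = sorted(candidates)  # name order = tie-break order
    best = fit_footpad_model(cycles, selected, month_encoding)
    while remaining:
        trials = [
            (fit_footpad_model(cycles, selected + [term], month_encoding),
             term)
            for term in remaining
        ]
        fit, term = min(trials, key=lambda t: (t[0].aic, t[1]))
        if fit.aic >= best.aic:
            break
        if verbose:
            print(f"  + {term}: AIC {best.aic:.2f} -> {fit.aic:.2f}")
        selected.append(term)
        remaining.remove(term)
        best = fit
    return best
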