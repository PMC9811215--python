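# beat

Zone-based biosecurity assessment, health-plan tracking and
pre/post-intervention evaluation for broiler farms.

## What this is for

Preventing pathogens from entering and spreading on a broiler farm is the
first line of defence for flock health, and better biosecurity is one of
the few levers that demonstrably reduces antimicrobial use.  `beat`
implements a **B**ios**E**curity **A**ssessment **T**ool built on the FAO
3-zone farm model: every farm is divided into a high-risk external **red**
zone, a medium-risk **orange** service yard, and the access-restricted
**green** zone containing the broiler house, plus the two transition zones
(**red–orange**, **orange–green**) covering the crossings.  Each zone
groups thematic *risk categories* (thinning, access of transport vehicles,
feed storage, …), each category groups questions, and every question
offers predefined answers scored on a 0–1 compliance scale (1 = fully
compliant, 0 = no compliance).

The relative score of a zone (or category) is

```
relative = Σ points attained / Σ points attainable
```

summed over the answered questions (not-applicable questions are excluded
from both sums), so 1 means full compliance and 0 none; traffic-light
classification (red < 0.4 ≤ amber < 0.7 ≤ green by default) makes the weak
spots visible at a glance.  From the weakest categories, farmer and
veterinarian draft a *health plan* of SMART interventions, each labelled
with its zone, category, cost class (low/medium/high), implementation
horizon (short/medium/long term) and — after follow-up — whether it was
realized.  Per-cycle flock monitoring records antimicrobial treatment
days, footpad-lesion class counts (flock score on the conventional 0–200
weighted-prevalence scale), and mortality for two pre- and two
post-intervention production cycles.

The statistical layer provides the standard evaluation for such a cohort:
Wilcoxon rank-sum tests between countries per zone (exact null on small
tie-free samples), Kruskal–Wallis pre/post comparisons, and a linear
mixed-effects model for the flock footpad score — random intercept per
country; candidate fixed effects cycle number, start month (seasonality)
and house construction year — fitted by ML and selected by greedy forward
search on AIC.

The package also ships (a) a questionnaire instrument covering all 46 risk
categories of the five zones, (b) the published summary tables of the
three-country pilot cohort (13 NL / 7 CY / 15 GR farms, 4 cycles) it was
developed on, and (c) a synthetic cohort generator so every analysis is
testable without any real farm data.

## Worked example

Generate a synthetic 35-farm cohort, score it, and report one farm:

```bash
$ beat synth --out demo --seed 42
cohort with 35 farms, 717 interventions, 140 cycles -> demo

$ beat score --answers demo/answers.csv --farms demo/farms.csv \
             --out demo/report.csv --aggregate
scored 35 assessments -> demo/report.csv

$ beat report farm NL-001 --answers demo/answers.csv \
              --plans demo/plans.csv --cycles demo/cycles.csv
farm NL-001

zone scores:
  green            0.71  [green]
  orange_green     0.83  [green]
  orange           0.73  [green]
  red_orange       0.67  [amber]
  red              0.88  [green]

weakest categories (top 5):
  consecutive_flocks            0.00
  bedding_storage               0.00
  bedding_materials             0.50
  ...

health plan: 15 interventions, 4 realized
cycles:
  cycle 1 (pre): footpad   61.0, AMU 2 d, mortality 3.2%
  ...
```

The zone scores are the attained/attainable ratios for this farm's
answers; `red_orange` at 0.67 falls in the amber band, so the transition
between yard and external area is where this farm should act first.  The
weakest-category list ranks draft intervention targets (ties broken
green-zone-first).  The cycle lines show the flock footpad score (0–200),
antimicrobial treatment days and mortality per production cycle.

Other entry points: `beat plan suggest|summarize`, `beat monitor
summarize`, `beat analyze countries|prepost|footpad`, `beat report
cohort`.  Everything is also available as a library:

```python
from beat import load_questionnaire, packaged_questionnaire_path, score_zone
```

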