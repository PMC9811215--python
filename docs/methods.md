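# Methods

This note documents the models, conventions and design choices behind the
package, in the order data flows through it.

## The instrument and its scoring

The questionnaire follows the FAO 3-zone layout of a broiler farm — red
(external), orange (service yard), green (broiler house) — with the two
transition zones modelled as first-class zones, because the crossings
(gates, hygiene locks, vehicle entry points) carry their own risks.  The
instrument shipped in `beat/data/questionnaire.csv` covers 46 risk
categories (14 green, 3 orange–green, 11 orange, 6 red–orange, 12 red)
with two questions each.  The category structure mirrors the published
pilot-cohort tables; the question texts themselves were authored for this
package from the standard broiler biosecurity literature (thinning
hygiene, bedding protection, visitor access, wild-bird proofing, …), since
the original item list was never published.  Options score 0, 0.5 or 1
(some questions are binary 0/1); any value in [0, 1] is accepted by the
model, and every question must contain a full-compliance (1.0) option and
at least one strictly worse one, otherwise it cannot discriminate.

Relative scores are ratios of attained to attainable points.  Three
conventions matter:

* **Not-applicable answers** are excluded from numerator *and*
  denominator.  This avoids penalizing structurally inapplicable items
  (outdoor runs on an indoor-only farm); the number of NA answers is
  carried in every score object so coverage stays visible.
* **Cross-farm aggregation** uses the unweighted mean over farms within a
  group, and the pooled "overall" mean weights every farm equally rather
  than averaging country means.  With unbalanced groups (13/7/15 farms)
  the two differ; farm-pooling is the statistically standard choice and is
  applied consistently.
* **Rounding** happens only at the reporting edge (half-to-even, two
  decimals for scores, whole numbers for cross-tab percentages);
  computation is full precision throughout.

Traffic-light thresholds default to red < 0.4 ≤ amber < 0.7 ≤ green.  The
0–1 scale itself carries the instrument's colour semantics (1 = green,
0 = red); the two numeric cut points are package defaults, configurable
per call and via the CLI.

A cross-zone per-farm total is never emitted as a headline number: the
zones have different numbers of questions and different attainable
maxima, so only within-zone ratios are comparable across farms.

## Health plans

`suggest_targets` is deliberately only a ranking aid — the k
lowest-scoring categories, ties broken by zone inside-out and then
lexicographically, with fully compliant categories filtered out.  Drafting
the actual SMART intervention text is the farmer's and veterinarian's job;
no recommendation engine is pretended.  Realization is binary; partial
completion is not modelled.  The accounting functions (`zone_totals`,
`crosstab_term_cost`, `realization_rate`) are exact tallies and satisfy a
conservation invariant: zone totals, term×cost cell counts and the
realization denominators all sum to the same intervention count.

## Pilot-cohort summary tables

`beat.reference_cohort` ships the published summary margins of the
three-country pilot cohort (35 broiler houses: 13 NL, 7 CY, 15 GR; four
cycles): per-category intervention counts and mean scores per country, the
term×cost cross-tabulation, and per-cycle antimicrobial-use counts.  The
raw farm-level data were never released, so these margins cannot be joined
into one record list — they are even mutually inconsistent by three
interventions in their grand totals — and the expansion helpers therefore
fill the fields the other margin would provide with labelled placeholders.
Expanded records are only meaningful for the margin they came from; the
realized counts of the term×cost table are recovered from the printed
percentages as `round(n · pct/100)`, which round-trips every cell exactly.

## Flock monitoring

Footpad lesions are scored per bird in classes 0/1/2 at slaughter; the
flock score is the weighted prevalence `100·(w0·n0 + w1·n1 + w2·n2)/n`
with default weights (0, 0.5, 2), i.e. the conventional 0–200
surveillance scale.  The weights are parameters because class weightings
differ slightly between national schemes.

Antimicrobial use is recorded as a per-cycle treated/untreated flag plus
total treatment days (no dose-based metrics such as DDDvet — only days
are recorded at farm level).  Treatment-day summaries (median, mean to one
decimal) are computed over treating farms only, so non-users can never
dilute them.  Flock-cycle treatment prevalence divides treated farm-cycles
by all observed farm-cycles of a country and **truncates** to a whole
percent — the convention used in cohort reports of this kind (17/28 →
60%, 22/52 → 42%); missing cycles drop out of numerator and denominator
with a warning.

Mortality and slaughter parameters are carried and summarized
descriptively only; no model is fitted to them.

## Statistics

*Rank tests.*  The two-sample comparison uses the Wilcoxon rank-sum /
Mann–Whitney test: exact null distribution when both samples have ≤ 10
observations and the pooled data are tie-free, otherwise the normal
approximation with mid-rank tie correction and continuity correction.
Kruskal–Wallis uses the tie-corrected H with a χ²(k−1) reference.  On very
small samples the χ² reference is approximate — the exact permutation
distribution of H is discrete and can differ substantially (singleton
groups are the worst case) — which is inherent to the reference
distribution, not to the H computation; the test suite checks H exactly
against a brute-force formula and checks the rank-sum p-values exactly
against full enumeration.  Degenerate input (all values identical) returns
p = 1 with a warning instead of failing.  No multiplicity correction is
applied across the three pairwise country comparisons; each p-value stands
alone.  α = 0.05 is used for the convenience `significant` flags.

*Footpad mixed model.*  `footpad_score ~ fixed effects, random intercept
per country`, fitted by **maximum likelihood** — not REML — because AIC is
only comparable across different fixed-effect sets under ML.  AIC is
computed as −2·logL + 2k with k counting fixed effects, the
random-intercept variance and the residual variance, so the penalty is
consistent across every candidate model.  Start month enters as a
categorical factor by default (a month term, not a trend); a harmonic
encoding (sin/cos of 2π·month/12) is available where a smooth seasonal
curve is preferred.  Cycle number and construction year enter as numeric.
Singular fits (zero estimated country variance) are kept with a warning;
non-finite likelihoods from near-singular fits trigger an optimizer retry
chain (default → lbfgs → cg → powell).

*Forward selection.*  Starts from the random-intercept-only model, adds
the candidate lowering AIC the most, stops when none lowers it; exact AIC
ties break by candidate name order, making the procedure deterministic
given the data.  Two behavioural facts are worth knowing.  First, AIC
admits a pure-noise 1-df term whenever its LR statistic exceeds 2, which
happens for about a fifth of null datasets at this design size — so on
data with a true seasonal effect the selected set reliably *contains* the
month term (and month always enters first), but is the month-only model
in only ~60 % of replicates.  Second, greedy forward search need not find
the AIC-optimal subset; the suite compares it against exhaustive search
over all 8 subsets and only requires that greedy never beats the optimum.

*Pre/post comparisons* can pool cycles into two phases (pre = cycles 1–2,
post = 3–4) or keep the four cycles as groups; both modes are exposed
because either is a defensible reading of a pre/post design.

## Synthetic cohorts

The generator emulates the pilot-cohort design: 13/7/15 farms in three
countries, four cycles (two pre-, two post-intervention).  Per farm and
zone a compliance level p is drawn from a zone-specific Beta distribution
(means 0.64/0.53/0.64/0.59/0.50 inside-out, concentration 5 — matching
the observed zone score levels); each question is then answered with its
best option with probability p, else its worst, so the expected relative
zone score equals p.  Interventions are drawn Poisson(0.8) per weak
(score < 0.7) category with term/cost sampled from the observed margins
and Bernoulli realization from a (term, cost) probability grid that
decreases along both axes.  Footpad flock scores follow `baseline (80) +
amplitude (30) · cos(2π(month−1)/12) + country offset (SD 15) + noise
(SD 25)` — a cosine peaking in January, since flock footpad scores peak in
winter — quantized to 100-bird class counts.  Antimicrobial treatment is
Bernoulli per cycle (0.74 pre, 0.67 post — the pooled observed
prevalences), with treatment days from a negative binomial (mean 6,
dispersion 4) truncated at ≥ 1, giving overdispersed small counts with
medians in the observed 3–11 range.  Consecutive cycles start two months
apart from a uniformly drawn first month.

What the generator does *not* emulate: correlation of compliance across
zones within a farm, assessor effects, within-country farm clustering
beyond the country offset, real seasonality of placement dates, or any
intervention → outcome causal effect (antimicrobial-use phase
probabilities are set exogenously).  Passing tests therefore demonstrate
correctness of the machinery under the design's statistical structure,
not epidemiological conclusions about real farms.

## Problem sizes in the test and acceptance runs

Scoring invariants run on 1,000 randomized assessments of the full
92-question instrument; rank tests are enumerated exhaustively for all
two-group splits up to n = 6; model-selection behaviour is measured over
50 simulated cohorts of 35 farms × 4 cycles (the pilot design) with a
seasonal amplitude of two residual SDs; null-selection behaviour over 20
such cohorts.  These sizes give stable pass/fail behaviour for the
properties asserted while keeping a full run in the minutes range.

## Known limitations

* The packaged questionnaire preserves the zone/category structure and
  scoring semantics of the pilot instrument but not its literal item
  wording; absolute scores from it are not comparable to the pilot's.
* Between-country and pre/post p-values of the pilot cohort cannot be
  recomputed (farm-level raw data unpublished); the statistical layer is
  validated against enumeration oracles and simulations instead.
* One assessment per farm and date; multi-assessor reconciliation is out
  of scope.
* The zone map drawing step of the field protocol is represented only as
  the zone labels embedded in the instrument; no geometry is modelled.
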