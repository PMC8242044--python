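# Methods

## The estimation problem

Pastoralist small-ruminant flocks in arid and semi-arid rangelands are
rarely monitored: longitudinal animal-level follow-up is too expensive
for routine use. A single cross-sectional interview per flock can
nevertheless support a useful set of demographic indicators if the
respondent recalls, for the previous 12 months and separately for
sheep and goats, (i) the current flock structure in four age-sex
categories, (ii) reproduction tallies (parturitions by litter size,
offspring born alive/stillborn, abortions, dystocias) and (iii) flock
flows by cause (natural deaths; offtakes — sale, slaughter for own
consumption, gift/dowry/inheritance, loss, other; intakes — purchase,
gift/dowry/inheritance, other). `flockrate` implements the estimators
over that record shape and validates them against an individual-based
simulator with known hazards.

Females older than 2 years are counted as reproductive females; the
2-year cut-off matches the age at which management of the animals
changes in these systems and is the only age information the record
carries.

## Denominators

Reproduction rates divide by the number of reproductive females
present on the survey date (no averaging over the window; this is a
deliberate simplification of the classical age-structured herd models
and a known source of upward bias when females were lost during the
year — the estimator recovery study quantifies it).

Dynamics rates divide by an animal-years-at-risk proxy:

```
n_start = n_end − (births_alive + intakes) + (deaths + offtakes)
n_mean  = (n_start + n_end) / 2
```

The start size is reconstructed from the recall tallies themselves.
Entries comprise live births and intakes; exits comprise natural
deaths and all offtakes (including slaughter and losses). Only this
reading makes the production identity exact:

```
production_rate · n_mean = (n_end − n_start) + (offtakes − intakes)
                         = births_alive − deaths
```

i.e. production is the balance between births and deaths. The test
suite asserts this identity to 1e-12 on randomly generated records.

## Indicators

Per flock and species (18 for sheep, 19 for goats — sheep carry no
triplet rate):

| indicator | numerator / denominator |
|---|---|
| parturition rate | parturitions / reproductive females |
| prolificacy | offspring (alive + stillborn) / parturitions |
| twinning, triplet rate | twin (triplet) parturitions / parturitions |
| fecundity rate | offspring / reproductive females |
| net prolificacy, net fecundity | live-born variants of the above |
| abortion rate | abortions / reproductive females |
| stillbirth rate | stillborn / offspring born |
| dystocia rate | dystocias / parturitions |
| multiplication rate | n_end / n_start |
| growth rate (%) | 100 · (multiplication − 1) |
| production rate | (Δsize + offtakes − intakes) / n_mean |
| net production rate | (offtakes − intakes) / n_mean |
| mortality, offtake, intake rate | cause totals / n_mean, plus per-cause sub-rates |

Conventions: an indicator with a zero denominator is *undefined* and
encoded as a missing value (`None`/NaN), never 0; a zero numerator
over a positive denominator is exactly 0. Abortions are not
parturitions and aborted foetuses are not offspring. Dystocias are
validated to not exceed parturitions. Internal computation keeps full
precision; report tables round to 2 decimals.

## Flock Efficiency Indicator

For flocks keeping both species (≥ 10 animals of each, ≥ 30 combined,
no deliberate goat removal), four components — sheep and goat net
fecundity, sheep and goat production rate — are each scored 1/2/3
against the component's tertiles estimated over the eligible cohort,
and summed:

```
FEI = SheepNetFecundity_cat + GoatNetFecundity_cat
    + SheepProduction_cat  + GoatProduction_cat        ∈ [4, 12]
```

Multiplication rate is excluded by design: it is driven by intakes
and offtakes, which can be consequences of performance (poor
performers buy animals) rather than performance.

Two details are genuinely open in a tertile construction and were
fixed once, documented, and made configurable:

* **Quantile estimator** — linear interpolation between order
  statistics (the common default of mainstream numerical
  environments). The same convention is shared with the Tukey fences
  so scores and outlier bounds cannot disagree near boundaries.
* **Tie rule** — right-closed intervals `(−∞, q_low]`, `(q_low,
  q_high]`, `(q_high, ∞)`: a value exactly at a cut-off takes the
  lower score. Deterministic, and consistent with "1 = low
  efficiency".

Flocks with any undefined component are excluded from both cut-off
estimation and scoring. Cut-offs are cohort-relative and stored next
to the scores so a re-run reproduces them.

## Cohort statistics

Summaries report median and range first (recall-survey indicators are
right-skewed), with mean and standard error alongside for
comparability. Outliers are flagged with Tukey fences (Q1 − 1.5·IQR,
Q3 + 1.5·IQR) but always retained: every respondent's recall is
treated as equally trustworthy and the median is robust. Associations
use pairwise-complete Spearman correlation and the tie-corrected
Kruskal–Wallis test; p-values are raw, with no multiple-testing
correction, and should be read accordingly.

## The synthetic-flock simulator

No public dataset exists for this record shape, so the package ships
an individual-based simulator that *defines* the study conditions and
provides ground truth. It is the package's own construction, not a
re-implementation of a published generative model (the methodology it
validates is a field survey).

Daily discrete time over 365 days, competing risks per animal:

1. death check per cause, then offtake check per cause, each with
   per-day probability `1 − exp(−h/365)` for annual hazard `h`; first
   success wins, so per-day survival is exactly `exp(−Σh/365)`;
2. surviving reproductive females draw an abortion check, then a
   parturition check; litters are single/twin/triplet; each offspring
   is independently stillborn with fixed probability; each parturition
   is flagged dystocia with fixed probability;
3. live newborns join the young category of their sex (p = 1/2 each)
   and are at risk from the day after birth; they do not reproduce
   within the window;
4. intakes arrive as a flock-level Poisson count per cause spread
   uniformly over days, enter as young females (purchased and gifted
   animals in these systems are predominantly young females), and are
   at risk from the day after arrival.

Daily discretization was chosen over a continuous-time event queue:
for annual hazards up to ~3/yr the discretization error is small,
fully characterized by the expectation recursion below, and the
bookkeeping is easy to verify exactly (day-0 population + births +
intakes − deaths − offtakes = final population, asserted for every
replicate). The process is byte-for-byte deterministic for a fixed
seed. Optional variants: a minimum inter-parturition interval
(default 0: pure hazard model) and within-window aging across the
2-year threshold (default off for a 12-month window).

### The expectation oracle

`flockrate.expectation.expected_outcomes` computes exact expectations
of the daily process by a deterministic recursion (expected at-risk
animals and reproductive females propagated day by day with the same
event probabilities). It shares no code with the simulator and is the
independent reference for the recovery tests: with only a mortality
hazard `m` it reduces to the closed form
`E[mortality estimate] ≈ 2(1 − e^(−m)) / (1 + e^(−m))`, and with a
parturition hazard `p` and nothing else the expected parturitions per
female are `365·(1 − exp(−p/365))` (the expected *count* of the daily
process, not the probability `1 − e^(−p)` of at least one event).
For estimators the oracle reports the ratio of expectations; the
Jensen gap for 50-animal flocks is second-order and far below the
3-Monte-Carlo-SE resolution used by the tests.

### Cohort generator defaults

The default cohort sampler emulates the surveyed population: 130
flocks, both species per flock, flock sizes lognormal around medians
55 (sheep) and 35 (goats) with the observed age-sex composition
(~21% young females, ~17% young males, ~50% reproductive females,
~11% older males), and per-species hazards set to the field cohort's
median indicator levels (sheep: parturition 0.55/yr, mortality
0.10/yr dominated by disease, offtake 0.19/yr dominated by sale,
per-animal intake 0.01/yr; goats: parturition 0.52/yr, mortality
0.07/yr, offtake 0.23/yr, intake 0.03/yr; litter-size, abortion,
stillbirth and dystocia parameters likewise at field-cohort levels).
Inter-flock heterogeneity is lognormal frailty (sd 0.30 on the log
scale) applied to the reproduction and the removal hazards.

47.7% of respondents are "pastoralists and traders" (the share who
reported usually buying animals). In the stratified sampler the
trader stratum gets a 0.6× parturition hazard and a 0.10/yr per-animal
purchase-intake rate — the contrast magnitude is informed by the
field study's low- vs high-score groups, and the direction (traders
score lower) is what the stratified-cohort test asserts; the
magnitude itself is not a validation target.

### What the simulator does and does not emulate

It emulates the *process* the survey measures: competing-risk exits,
hazard-driven reproduction, cause-tagged flows, survey-date category
counts. It does **not** emulate recall error — simulated tallies are
exact aggregates of the event log. Passing recovery tests therefore
show that the estimators are consistent with the demographic process
under perfect recall; they say nothing about robustness to recall
bias, seasonality (hazards are constant within the window), breed
effects, or dependence between neighbouring flocks.

## Problem sizes and numerical choices

Validation runs use 130-flock cohorts, 200-replicate recovery
experiments on 50-animal flocks, and 500-replicate checks for the
parturition closed form; these sizes put Monte-Carlo standard errors
well below the effect sizes of interest while keeping the full suite
fast. Exact identities (production, fecundity decomposition,
cause-sums) are asserted to 1e-12. Degenerate inputs are handled
explicitly: empty flocks yield undefined rates, constant samples
yield coincident tertiles/fences (everything scores 1 under the
right-closed rule; zero outliers), and all-identical pooled samples
short-circuit the Kruskal–Wallis statistic to H = 0, p = 1.

## Known limitations

* Reproductive-female denominators use the survey-date count only;
  flocks with heavy adult-female turnover get biased reproduction
  rates (visible in the recovery study as a parturition-rate estimate
  above the per-initial-female expectation).
* The FEI is cohort-relative: scores are comparable within an
  analysis cohort, not across cohorts with different tertiles.
* Multi-flock respondents are pooled by summing tallies; per-flock
  heterogeneity within a respondent is not recoverable from the
  pooled record.
* "Lost" animals (including theft) are a single offtake cause; the
  record cannot distinguish strayed from stolen.
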