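# flockrate

Rapid-assessment production and reproduction indicators for
pastoralist small-ruminant flocks.

Pastoralist sheep and goat flocks in arid and semi-arid rangelands are
almost never covered by routine performance recording, yet their
productivity is exactly what extension officers and policy makers need
to monitor. `flockrate` implements a survey-first alternative to
longitudinal herd monitoring: from a **single cross-sectional recall
interview** per flock (current flock structure in four age-sex
categories plus 12-month tallies of reproduction events and
cause-tagged deaths, offtakes and intakes, recorded separately for
sheep and goats) it computes a full set of flock demographic
indicators, scores flocks with a composite efficiency indicator, and
— because such estimators are easy to get subtly wrong — validates
every one of them against an individual-based flock simulator with
known hazards.

It is aimed at veterinary epidemiologists and livestock economists
running flock benchmarking or surveillance programmes, and at anyone
who needs a tested reference implementation of recall-survey herd
indicators.

## The estimators

Reproduction rates use the number of reproductive females (females
older than 2 years) present on the survey date as denominator;
dynamics rates use an animal-years proxy `N = (n_start + n_end)/2`,
where the start-of-window flock size is back-calculated from the
recall itself (`n_start = n_end − births − intakes + deaths +
offtakes`). Key quantities, per flock and species:

- parturition rate `= parturitions / repro females`, prolificacy
  `= offspring / parturitions`, fecundity `= offspring / repro
  females`, with live-born ("net") variants, twinning/triplet,
  abortion, stillbirth and dystocia rates;
- multiplication rate `n_end / n_start`, growth `100·(mult − 1)`;
- production rate `P/N` with `P = Δsize + offtakes − intakes`
  (identically the balance between births and deaths), net production
  `(offtakes − intakes)/N`;
- annual mortality, offtake and intake rates (`events/N`) with
  per-cause sub-rates.

The **Flock Efficiency Indicator (FEI)** summarizes two-species flocks
on a 4–12 scale: sheep and goat net fecundity and production rate are
each scored 1–3 against the cohort's tertiles and summed. See
`docs/methods.md` for every convention (quantile estimator, tie
rules, undefined-value handling) and for the simulator's process
model.

## Worked example

```python
import flockrate as fr
from flockrate.records import (SpeciesRecord, SpeciesStructure,
                               ReproductionTallies, FlowTallies)

flock = SpeciesRecord(
    species="sheep",
    structure=SpeciesStructure(young_females=20, young_males=15,
                               repro_females=50, older_males=15),
    reproduction=ReproductionTallies(parturitions_single=26, parturitions_twin=4,
                                     offspring_alive=32, offspring_stillborn=2,
                                     abortions=1, dystocias=3),
    flows=FlowTallies(births_alive=30,
                      deaths_by_cause={"disease": 7, "predation": 2, "drought": 1},
                      offtakes_by_cause={"sale": 20},
                      intakes_by_cause={"purchase": 5}),
)
den = fr.compute_denominators(flock)
ind = fr.compute_indicator_set(flock)
print(den.n_start, den.n_mean)
print(round(ind.parturition_rate, 2), round(ind.prolificacy, 2),
      round(ind.fecundity_rate, 2))
print(round(ind.multiplication_rate, 3), round(ind.production_rate, 3),
      round(ind.mortality_rate, 3))
```

prints

```
95 97.5
0.6 1.13 0.68
1.053 0.205 0.103
```

The flock held 100 animals at interview and 95 a year before (30
births and 5 purchases in, 10 deaths and 20 sales out). Its 50 ewes
produced 0.60 parturitions each at 1.13 lambs per parturition (0.68
lambs per ewe-year); the flock grew 5.3%, produced 0.205 animals per
animal-year (births minus deaths over mean size), and lost 0.103 per
animal-year to natural death.

## Analysis pipeline

The `analysis/` scripts run the whole study flow on a synthetic
cohort and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py      # 130 two-stratum flocks + ground truth
python analysis/02_compute_indicators.py   # validation, indicators, summary tables
python analysis/03_score_efficiency.py     # FEI scores, cut-offs, stratum contrast
python analysis/04_correlations.py         # Spearman matrices per species
python analysis/05_estimator_recovery.py   # estimates vs analytic expectations
```

The same operations are available as a CLI (`flockrate validate /
compute / score / summarize / simulate`) for use on real survey CSVs;
the column dictionary is documented in `flockrate/records.py`.

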