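#!/usr/bin/env python
"""Score flocks with the Flock Efficiency Indicator and compare strata.

Reads results/synthetic_survey.csv and results/synthetic_truth.csv,
scores every eligible two-species flock (tertile scores of sheep/goat
net fecundity and production rate, summed to 4–12), and compares the
score between "pastoralist only" and "pastoralist and trader" flocks
with a Kruskal–Wallis rank sum test.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

import flockrate as fr

ROOT = Path(__file__).resolve().parents[1]


def main():
    results = ROOT / "results"
    survey = fr.read_survey_csv(results / "synthetic_survey.csv")
    truth = pd.read_csv(results / "synthetic_truth.csv")
    stratum = truth.drop_duplicates("flock_id").set_index("flock_id")["stratum"]

    cohort = []
    for record in survey.records:
        indicators = {
            sp: fr.compute_indicator_set(rec)
            for sp, rec in record.species_records().items()
        }
        cohort.append((record, indicators))
    computation = fr.compute_fei(cohort)

    pd.DataFrame([dataclasses.asdict(r) for r in computation.results]).to_csv(
        results / "fei_scores.csv", index=False
    )
    with open(results / "fei_cutoffs.json", "w") as handle:
        json.dump(
            {k: dataclasses.asdict(v) for k, v in computation.cutoffs.items()},
            handle,
            indent=2,
        )

    scored = [r for r in computation.results if r.eligible]
    feis = sorted(r.fei for r in scored)
    median = feis[len(feis) // 2]
    print(f"scored {len(scored)} eligible flocks; FEI median {median}, "
          f"range {feis[0]}-{feis[-1]}")
    at_min = sum(f == 4 for f in feis)
    at_max = sum(f == 12 for f in feis)
    print(f"  {at_min} flock(s) ({fr.percentage(at_min, len(feis))}%) at the minimum, "
          f"{at_max} ({fr.percentage(at_max, len(feis))}%) at the maximum")

    comparison = fr.compare_fei_by_type(computation.results, stratum.to_dict())
    for group in comparison.groups:
        print(f"  {group.label}: n={group.n}, median FEI {group.median:.1f} "
              f"(IQR {group.q1:.0f}-{group.q3:.0f})")
    print(f"  Kruskal-Wallis H={comparison.statistic:.2f}, p={comparison.p_value:.2g}")
    print("wrote results/fei_scores.csv and results/fei_cutoffs.json")


if __name__ == "__main__":
    main()
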