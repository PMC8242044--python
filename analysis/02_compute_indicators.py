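#!/usr/bin/env python
"""Validate the survey and compute per-flock indicators.

Reads results/synthetic_survey.csv (run 01_simulate_cohort.py first),
applies the eligibility filters (≥ 10 animals of the species, no
deliberate goat removal), computes the full indicator set per
flock-species, and writes the indicator table and the median/range/
mean(se) summary with Tukey outlier counts.
"""

from pathlib import Path

import pandas as pd

import flockrate as fr

ROOT = Path(__file__).resolve().parents[1]


def main():
    results = ROOT / "results"
    survey = fr.read_survey_csv(results / "synthetic_survey.csv")
    print(f"validated survey: {len(survey.records)} flocks, {len(survey.rejects)} rejects")

    frames = []
    for species in ("sheep", "goat"):
        pairs = []
        for record in survey.records:
            rec = record.species_records().get(species)
            if rec is None or not fr.species_eligible(rec, record.removing_goats):
                continue
            pairs.append((record.flock_id, fr.compute_indicator_set(rec)))
        frame = fr.indicator_frame(pairs)
        frame.insert(1, "species", species)
        frames.append(frame)
        print(f"  {species}: {len(frame)} eligible flocks")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(results / "indicators.csv", index=False)

    summaries = []
    for species, frame in zip(("sheep", "goat"), frames):
        summary = fr.summary_table(frame.drop(columns=["flock_id", "species"]))
        summary.insert(0, "species", species)
        summaries.append(summary)
        for name in ("parturition_rate", "net_fecundity", "mortality_rate", "production_rate"):
            row = summary.loc[name]
            print(
                f"  {species} {name}: median {row['median']:.2f} "
                f"({row['min']:.2f}-{row['max']:.2f}), mean {row['mean']:.2f} "
                f"(se {row['se']:.2f}), outliers {int(row['n_outliers'])}"
            )
    pd.concat(summaries).to_csv(results / "summary_by_species.csv")
    print("wrote results/indicators.csv and results/summary_by_species.csv")


if __name__ == "__main__":
    main()
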