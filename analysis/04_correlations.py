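#!/usr/bin/env python
"""Spearman rank-correlation structure of the indicators.

Reads results/indicators.csv and writes one pairwise-complete Spearman
rho matrix per species, highlighting the strongest dependencies among
the flock-level indicators (raw p-values, no multiplicity correction).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import flockrate as fr

ROOT = Path(__file__).resolve().parents[1]

KEY_VARS = [
    "parturition_rate",
    "fecundity_rate",
    "net_fecundity",
    "multiplication_rate",
    "production_rate",
    "net_production_rate",
    "mortality_rate",
    "offtake_rate",
    "intake_rate",
]


def main():
    results = ROOT / "results"
    table = pd.read_csv(results / "indicators.csv")
    for species in ("sheep", "goat"):
        sub = table[table["species"] == species].drop(columns=["flock_id", "species"])
        rho, pval = fr.rank_correlation_matrix(sub)
        rho.to_csv(results / f"corr_{species}.csv")
        print(f"{species}: wrote results/corr_{species}.csv "
              f"({rho.shape[0]}x{rho.shape[1]} indicators)")
        strongest = []
        for i, a in enumerate(KEY_VARS):
            for b in KEY_VARS[i + 1:]:
                r = rho.loc[a, b]
                if np.isfinite(r):
                    strongest.append((abs(r), a, b, r, pval.loc[a, b]))
        for _, a, b, r, p in sorted(strongest, reverse=True)[:5]:
            print(f"  {a} ~ {b}: rho={r:+.2f} (p={p:.2g})")


if __name__ == "__main__":
    main()
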