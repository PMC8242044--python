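"""Shared fixtures: worked-example records and synthetic cohort builders."""

from __future__ import annotations

import numpy as np
import pytest

from flockrate.indicators import IndicatorSet
from flockrate.records import (
    DEATH_CAUSES,
    INTAKE_CAUSES,
    OFFTAKE_CAUSES,
    FlockSurveyRecord,
    FlowTallies,
    ReproductionTallies,
    SpeciesRecord,
    SpeciesStructure,
)


@pytest.fixture
def toy_species_record() -> SpeciesRecord:
    """A worked-example flock: 100 animals now, 95 a year ago.

    50 reproductive females; 30 parturitions (26 single + 4 twin),
    32 live and 2 stillborn offspring, 1 abortion, 3 dystocias;
    10 natural deaths (7 disease, 2 predation, 1 drought), 20 offtakes,
    5 intakes, 30 live births recorded in the flow tallies.
    """
    return SpeciesRecord(
        species="sheep",
        structure=SpeciesStructure(
            young_females=20, young_males=15, repro_females=50, older_males=15
        ),
        reproduction=ReproductionTallies(
            parturitions_single=26,
            parturitions_twin=4,
            offspring_alive=32,
            offspring_stillborn=2,
            abortions=1,
            dystocias=3,
        ),
        flows=FlowTallies(
            births_alive=30,
            deaths_by_cause={"disease": 7, "predation": 2, "drought": 1},
            offtakes_by_cause={"sale": 20},
            intakes_by_cause={"purchase": 5},
        ),
    )


def make_species_record(species: str = "sheep", total: int = 20) -> SpeciesRecord:
    """A quiet, valid species record of the requested size."""
    quarter = total // 4
    return SpeciesRecord(
        species=species,
        structure=SpeciesStructure(
            young_females=quarter,
            young_males=quarter,
            repro_females=total - 3 * quarter,
            older_males=quarter,
        ),
    )


def make_eligible_flock(flock_id: str, n_sheep: int = 20, n_goats: int = 20, **meta):
    """A flock passing the two-species efficiency-score eligibility rules."""
    return FlockSurveyRecord(
        flock_id=flock_id,
        sheep=make_species_record("sheep", n_sheep),
        goats=make_species_record("goat", n_goats),
        **meta,
    )


def fei_cohort(component_values, **meta):
    """Build a scoring cohort from explicit component quadruples.

    ``component_values`` is a sequence of (sheep net fecundity,
    goat net fecundity, sheep production, goat production) tuples.
    """
    cohort = []
    for i, (snf, gnf, sp, gp) in enumerate(component_values):
        record = make_eligible_flock(f"f{i + 1:03d}", **meta)
        indicators = {
            "sheep": IndicatorSet(net_fecundity=snf, production_rate=sp),
            "goat": IndicatorSet(net_fecundity=gnf, production_rate=gp),
        }
        cohort.append((record, indicators))
    return cohort


def random_species_record(rng: np.random.Generator, species: str = "sheep") -> SpeciesRecord:
    """A random valid species record (non-negative back-calculated start).

    Exits are drawn freely (they only raise the start size); entries are
    then drawn within the ``n_end + exits`` budget so the record always
    satisfies the start-size invariant.
    """
    structure = SpeciesStructure(
        young_females=int(rng.integers(0, 40)),
        young_males=int(rng.integers(0, 30)),
        repro_females=int(rng.integers(0, 60)),
        older_males=int(rng.integers(0, 20)),
    )
    n_end = structure.total()
    deaths = {c: int(rng.integers(0, 8)) for c in DEATH_CAUSES}
    offtakes = {c: int(rng.integers(0, 8)) for c in OFFTAKE_CAUSES}
    exits = sum(deaths.values()) + sum(offtakes.values())
    budget = n_end + exits
    births = int(rng.integers(0, budget + 1))
    budget -= births
    intakes = {}
    for c in INTAKE_CAUSES:
        intakes[c] = int(rng.integers(0, budget + 1))
        budget -= intakes[c]
    singles = int(rng.integers(0, 30))
    twins = int(rng.integers(0, 10))
    triplets = int(rng.integers(0, 3))
    parturitions = singles + twins + triplets
    return SpeciesRecord(
        species=species,
        structure=structure,
        reproduction=ReproductionTallies(
            parturitions_single=singles,
            parturitions_twin=twins,
            parturitions_triplet=triplets,
            offspring_alive=int(rng.integers(0, 50)),
            offspring_stillborn=int(rng.integers(0, 5)),
            abortions=int(rng.integers(0, 5)),
            dystocias=int(rng.integers(0, parturitions + 1)) if parturitions else 0,
        ),
        flows=FlowTallies(
            births_alive=births,
            deaths_by_cause=deaths,
            offtakes_by_cause=offtakes,
            intakes_by_cause=intakes,
        ),
    )
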