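"""Individual-based stochastic flock simulator.

Simulates one species' flock day by day over a 12-month window and
emits a survey-shaped record together with the generating hazards and
the full event log, providing known ground truth against which the
recall-survey estimators can be validated.

Process model (daily discrete-time competing risks):

* Each animal at risk on a given day faces, in documented order, a
  death check per cause then an offtake check per cause, each with
  per-day probability ``1 − exp(−h/365)`` for annual hazard ``h``; the
  first success wins, so at most one event per animal per day and the
  per-day survival probability is exactly ``exp(−Σh/365)``.
* Reproductive females that survive the day additionally draw an
  abortion check then a parturition check (same per-day probability
  transform).  Litters are sized single/twin/triplet by
  ``litter_probs``; each offspring is independently stillborn with
  ``stillbirth_prob``; each parturition is flagged dystocia with
  ``dystocia_prob``.  Live newborns join the young category of their
  sex (probability 1/2 each) and are at risk from the day after birth.
* Intakes arrive as a flock-level Poisson count per cause (expected
  entries/year), spread uniformly over days; they enter as young
  females and are at risk from the day after arrival.

The process is deterministic for a fixed seed, and bookkeeping is
conserved exactly: day-0 population + births + intakes − deaths −
offtakes = final population for every replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Optional

import numpy as np

from .records import (
    DEATH_CAUSES,
    INTAKE_CAUSES,
    OFFTAKE_CAUSES,
    FlockSurveyRecord,
    FlowTallies,
    ReproductionTallies,
    SpeciesRecord,
    SpeciesStructure,
)

__all__ = [
    "DAYS",
    "SimulationConfig",
    "SimulatedFlock",
    "Event",
    "simulate_flock",
    "simulate_cohort",
    "species_defaults",
    "study_cohort_sampler",
]

DAYS = 365

# age-sex category codes
_YF, _YM, _RF, _OM = 0, 1, 2, 3
_TWO_YEARS_DAYS = 730

_LITTER_SIZES = {"single": 1, "twin": 2, "triplet": 3}


class Event(NamedTuple):
    day: int
    subject: int  # animal id; intakes get fresh ids on arrival
    kind: str  # death | offtake | intake | abortion | parturition | dystocia | birth
    cause: Optional[str]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth hazards and structure for one simulated flock.

    Hazards are annual rates per animal (per reproductive female for
    parturition and abortion); ``intake_rate_by_cause`` is the
    flock-level expected number of entries per year per cause.
    ``aging`` promotes young animals to the adult categories when they
    cross the 2-year threshold; it is off by default for a 12-month
    window.  ``min_interparturition_days`` > 0 imposes a refractory
    period after each parturition (off by default: pure hazard model).
    """

    species: str
    initial_structure: SpeciesStructure
    parturition_hazard: float = 0.0
    litter_probs: Mapping[str, float] = field(
        default_factory=lambda: {"single": 1.0}
    )
    abortion_hazard: float = 0.0
    stillbirth_prob: float = 0.0
    dystocia_prob: float = 0.0
    mortality_hazard_by_cause: Mapping[str, float] = field(default_factory=dict)
    offtake_hazard_by_cause: Mapping[str, float] = field(default_factory=dict)
    intake_rate_by_cause: Mapping[str, float] = field(default_factory=dict)
    aging: bool = False
    min_interparturition_days: int = 0
    seed: int = 0

    def validation_errors(self) -> list[str]:
        errors = []
        for name in ("parturition_hazard", "abortion_hazard"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be ≥ 0")
        for name in ("stillbirth_prob", "dystocia_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                errors.append(f"{name} must be in [0, 1]")
        for label, mapping, causes in (
            ("mortality_hazard_by_cause", self.mortality_hazard_by_cause, DEATH_CAUSES),
            ("offtake_hazard_by_cause", self.offtake_hazard_by_cause, OFFTAKE_CAUSES),
            ("intake_rate_by_cause", self.intake_rate_by_cause, INTAKE_CAUSES),
        ):
            for cause, h in mapping.items():
                if cause not in causes:
                    errors.append(f"{label} has unknown cause {cause!r}")
                if h < 0:
                    errors.append(f"{label}[{cause!r}] must be ≥ 0")
        bad_litter = set(self.litter_probs) - set(_LITTER_SIZES)
        if bad_litter:
            errors.append(f"unknown litter size(s): {sorted(bad_litter)}")
        total = sum(self.litter_probs.values())
        if abs(total - 1.0) > 1e-9:
            errors.append(f"litter_probs must sum to 1, got {total}")
        errors += self.initial_structure.validation_errors()
        return errors


@dataclass
class SimulatedFlock:
    """A survey-shaped record paired with its generating truth."""

    record: SpeciesRecord
    truth: SimulationConfig
    event_log: list[Event]
    n_start: int  # realized day-0 population (== initial structure total)


def _day_prob(hazard: float) -> float:
    return 1.0 - math.exp(-hazard / DAYS)


def simulate_flock(cfg: SimulationConfig) -> SimulatedFlock:
    """Run the daily competing-risk process for one flock."""
    errors = cfg.validation_errors()
    if errors:
        raise ValueError("invalid simulation config: " + "; ".join(errors))

    rng = np.random.default_rng(cfg.seed)
    st = cfg.initial_structure
    cat = np.repeat(
        np.array([_YF, _YM, _RF, _OM], dtype=np.int64),
        [st.young_females, st.young_males, st.repro_females, st.older_males],
    )
    n0 = int(cat.size)
    present = np.ones(n0, dtype=bool)
    active_from = np.zeros(n0, dtype=np.int64)
    last_part = np.full(n0, -(10**9), dtype=np.int64)
    if cfg.aging:
        age = np.where(
            (cat == _YF) | (cat == _YM),
            rng.integers(0, _TWO_YEARS_DAYS, n0),
            _TWO_YEARS_DAYS + rng.integers(0, 6 * 365, n0),
        ).astype(np.int64)
    else:
        age = None

    death_probs = [
        (c, _day_prob(h))
        for c, h in ((c, cfg.mortality_hazard_by_cause.get(c, 0.0)) for c in DEATH_CAUSES)
        if h > 0
    ]
    offtake_probs = [
        (c, _day_prob(h))
        for c, h in ((c, cfg.offtake_hazard_by_cause.get(c, 0.0)) for c in OFFTAKE_CAUSES)
        if h > 0
    ]
    p_abort = _day_prob(cfg.abortion_hazard)
    p_part = _day_prob(cfg.parturition_hazard)
    litter_names = [n for n in ("single", "twin", "triplet") if cfg.litter_probs.get(n, 0) > 0]
    litter_p = np.array([cfg.litter_probs[n] for n in litter_names], dtype=float)
    litter_p = litter_p / litter_p.sum()
    litter_sizes = np.array([_LITTER_SIZES[n] for n in litter_names], dtype=np.int64)

    # schedule intakes: flock-level Poisson per cause, uniform over days
    intake_schedule: dict[int, list[str]] = {}
    for cause in INTAKE_CAUSES:
        rate = cfg.intake_rate_by_cause.get(cause, 0.0)
        if rate <= 0:
            continue
        k = int(rng.poisson(rate))
        for day in rng.integers(0, DAYS, k):
            intake_schedule.setdefault(int(day), []).append(cause)

    log: list[Event] = []
    deaths = {c: 0 for c in DEATH_CAUSES}
    offtakes = {c: 0 for c in OFFTAKE_CAUSES}
    intakes = {c: 0 for c in INTAKE_CAUSES}
    parts = {"single": 0, "twin": 0, "triplet": 0}
    offspring_alive = offspring_stillborn = abortions = dystocias = 0

    def _grow(n_new: int, new_cat: np.ndarray, day: int):
        nonlocal cat, present, active_from, last_part, age
        cat = np.concatenate([cat, new_cat])
        present = np.concatenate([present, np.ones(n_new, dtype=bool)])
        active_from = np.concatenate(
            [active_from, np.full(n_new, day + 1, dtype=np.int64)]
        )
        last_part = np.concatenate([last_part, np.full(n_new, -(10**9), dtype=np.int64)])
        return np.arange(cat.size - n_new, cat.size)

    for day in range(DAYS):
        remaining = np.flatnonzero(present & (active_from <= day))
        for cause, p in death_probs:
            if remaining.size == 0:
                break
            u = rng.random(remaining.size)
            hits = remaining[u < p]
            if hits.size:
                present[hits] = False
                deaths[cause] += int(hits.size)
                log.extend(Event(day, int(a), "death", cause) for a in hits)
            remaining = remaining[u >= p]
        for cause, p in offtake_probs:
            if remaining.size == 0:
                break
            u = rng.random(remaining.size)
            hits = remaining[u < p]
            if hits.size:
                present[hits] = False
                offtakes[cause] += int(hits.size)
                log.extend(Event(day, int(a), "offtake", cause) for a in hits)
            remaining = remaining[u >= p]

        females = remaining[cat[remaining] == _RF]
        if females.size and (p_abort > 0 or p_part > 0):
            if p_abort > 0:
                u = rng.random(females.size)
                aborted = females[u < p_abort]
                if aborted.size:
                    abortions += int(aborted.size)
                    log.extend(Event(day, int(a), "abortion", None) for a in aborted)
                females = females[u >= p_abort]
            if p_part > 0 and females.size:
                if cfg.min_interparturition_days > 0:
                    females = females[
                        day - last_part[females] >= cfg.min_interparturition_days
                    ]
                if females.size:
                    u = rng.random(females.size)
                    dams = females[u < p_part]
                    if dams.size:
                        last_part[dams] = day
                        litter_idx = rng.choice(len(litter_names), size=dams.size, p=litter_p)
                        litters = litter_sizes[litter_idx]
                        dyst = rng.random(dams.size) < cfg.dystocia_prob
                        new_cats = []
                        for dam, li, flagged in zip(dams, litter_idx, dyst):
                            name = litter_names[li]
                            parts[name] += 1
                            log.append(Event(day, int(dam), "parturition", name))
                            if flagged:
                                dystocias += 1
                                log.append(Event(day, int(dam), "dystocia", None))
                            for _ in range(int(litter_sizes[li])):
                                if rng.random() < cfg.stillbirth_prob:
                                    offspring_stillborn += 1
                                    log.append(Event(day, int(dam), "birth", "stillborn"))
                                else:
                                    offspring_alive += 1
                                    new_cats.append(
                                        _YF if rng.random() < 0.5 else _YM
                                    )
                        if new_cats:
                            ids = _grow(
                                len(new_cats),
                                np.array(new_cats, dtype=np.int64),
                                day,
                            )
                            log.extend(
                                Event(day, int(a), "birth", "alive") for a in ids
                            )

        for cause in intake_schedule.get(day, ()):  # arrivals enter as young females
            ids = _grow(1, np.array([_YF], dtype=np.int64), day)
            intakes[cause] += 1
            log.append(Event(day, int(ids[0]), "intake", cause))

        if cfg.aging and age is not None:
            if age.size < cat.size:
                pad = np.zeros(cat.size - age.size, dtype=np.int64)
                age = np.concatenate([age, pad])
            crossing = present & (age + 1 >= _TWO_YEARS_DAYS) & (age < _TWO_YEARS_DAYS)
            cat = np.where(crossing & (cat == _YF), _RF, cat)
            cat = np.where(crossing & (cat == _YM), _OM, cat)
            age = age + 1

    alive_cat = cat[present]
    structure = SpeciesStructure(
        young_females=int(np.sum(alive_cat == _YF)),
        young_males=int(np.sum(alive_cat == _YM)),
        repro_females=int(np.sum(alive_cat == _RF)),
        older_males=int(np.sum(alive_cat == _OM)),
    )
    record = SpeciesRecord(
        species=cfg.species,
        structure=structure,
        reproduction=ReproductionTallies(
            parturitions_single=parts["single"],
            parturitions_twin=parts["twin"],
            parturitions_triplet=parts["triplet"],
            offspring_alive=offspring_alive,
            offspring_stillborn=offspring_stillborn,
            abortions=abortions,
            dystocias=dystocias,
        ),
        flows=FlowTallies(
            births_alive=offspring_alive,
            deaths_by_cause=dict(deaths),
            offtakes_by_cause=dict(offtakes),
            intakes_by_cause=dict(intakes),
        ),
    )
    return SimulatedFlock(record=record, truth=cfg, event_log=log, n_start=n0)


# ---------------------------------------------------------------------------
# cohort generation

#: study-condition default hazards per species: per-animal annual rates
#: matching the survey cohort's median indicator levels; intakes are
#: expressed per animal and scaled to the flock size by the sampler.
_SPECIES_DEFAULTS = {
    "sheep": dict(
        parturition_hazard=0.55,
        litter_probs={"single": 0.96, "twin": 0.04},
        abortion_hazard=0.03,
        stillbirth_prob=0.02,
        dystocia_prob=0.05,
        mortality_hazard_by_cause={"disease": 0.07, "predation": 0.02, "drought": 0.01},
        offtake_hazard_by_cause={
            "sale": 0.14,
            "slaughter_own_consumption": 0.02,
            "gift_dowry_inheritance": 0.01,
            "lost": 0.02,
        },
        intake_per_animal_by_cause={"purchase": 0.008, "gift_dowry_inheritance": 0.002},
        size_median=55,
        size_range=(10, 300),
        structure_props=(0.22, 0.17, 0.50, 0.11),
    ),
    "goat": dict(
        parturition_hazard=0.52,
        litter_probs={"single": 0.885, "twin": 0.11, "triplet": 0.005},
        abortion_hazard=0.04,
        stillbirth_prob=0.02,
        dystocia_prob=0.08,
        mortality_hazard_by_cause={"disease": 0.055, "predation": 0.01, "drought": 0.005},
        offtake_hazard_by_cause={
            "sale": 0.16,
            "slaughter_own_consumption": 0.03,
            "gift_dowry_inheritance": 0.03,
            "lost": 0.01,
        },
        intake_per_animal_by_cause={"purchase": 0.025, "gift_dowry_inheritance": 0.005},
        size_median=35,
        size_range=(10, 241),
        structure_props=(0.21, 0.17, 0.51, 0.11),
    ),
}

#: trader-stratum contrast: reproduction scaled down, purchases scaled up
_TRADER_PARTURITION_FACTOR = 0.6
_TRADER_PURCHASE_PER_ANIMAL = 0.10
#: share of respondents who usually buy animals
_TRADER_FRACTION = 0.477
#: inter-flock lognormal frailty (sd on the log scale) on hazards
_FRAILTY_SIGMA = 0.30


def species_defaults(species: str) -> dict:
    """The study-condition default parameters for one species."""
    return {k: (dict(v) if isinstance(v, dict) else v) for k, v in _SPECIES_DEFAULTS[species].items()}


def _sample_structure(rng: np.random.Generator, defaults: dict) -> SpeciesStructure:
    lo, hi = defaults["size_range"]
    total = int(np.clip(round(rng.lognormal(math.log(defaults["size_median"]), 0.5)), lo, hi))
    counts = rng.multinomial(total, np.asarray(defaults["structure_props"]))
    return SpeciesStructure(
        young_females=int(counts[0]),
        young_males=int(counts[1]),
        repro_females=int(counts[2]),
        older_males=int(counts[3]),
    )


def _sample_species_config(
    rng: np.random.Generator, species: str, trader: bool, seed: int
) -> SimulationConfig:
    d = species_defaults(species)
    frailty = float(rng.lognormal(0.0, _FRAILTY_SIGMA))
    repro_frailty = float(rng.lognormal(0.0, _FRAILTY_SIGMA))
    structure = _sample_structure(rng, d)
    n = structure.total()
    part = d["parturition_hazard"] * repro_frailty
    per_animal_intake = dict(d["intake_per_animal_by_cause"])
    if trader:
        part *= _TRADER_PARTURITION_FACTOR
        per_animal_intake["purchase"] = _TRADER_PURCHASE_PER_ANIMAL
    return SimulationConfig(
        species=species,
        initial_structure=structure,
        parturition_hazard=part,
        litter_probs=d["litter_probs"],
        abortion_hazard=d["abortion_hazard"] * repro_frailty,
        stillbirth_prob=d["stillbirth_prob"],
        dystocia_prob=d["dystocia_prob"],
        mortality_hazard_by_cause={
            c: h * frailty for c, h in d["mortality_hazard_by_cause"].items()
        },
        offtake_hazard_by_cause={
            c: h * frailty for c, h in d["offtake_hazard_by_cause"].items()
        },
        intake_rate_by_cause={c: r * n for c, r in per_animal_intake.items()},
        seed=seed,
    )


def study_cohort_sampler(
    trader_fraction: float = _TRADER_FRACTION,
    stratified: bool = True,
) -> Callable[[np.random.Generator, int], dict]:
    """Sampler emulating the surveyed cohort's conditions.

    Each flock keeps both species; with probability ``trader_fraction``
    the respondent is a "pastoralist and trader", simulated (when
    ``stratified``) with a lower parturition hazard and a higher
    purchase-intake rate than "pastoralist only" flocks.
    """

    def sample(rng: np.random.Generator, index: int) -> dict:
        trader = bool(rng.random() < trader_fraction)
        effect = trader and stratified
        return {
            "usually_buys_animals": trader,
            "removing_goats": False,
            "ward": f"ward_{index % 5 + 1}",
            "sheep": _sample_species_config(
                rng, "sheep", effect, int(rng.integers(2**31))
            ),
            "goat": _sample_species_config(
                rng, "goat", effect, int(rng.integers(2**31))
            ),
        }

    return sample


def simulate_cohort(
    n_flocks: int,
    cfg_sampler: Optional[Callable[[np.random.Generator, int], dict]] = None,
    seed: int = 0,
) -> list[tuple[FlockSurveyRecord, dict]]:
    """Simulate a cohort of independent flocks.

    ``cfg_sampler(rng, index)`` returns per-flock metadata and one
    :class:`SimulationConfig` per species (``None`` to omit a species);
    the default sampler reproduces the two-stratum study conditions.
    Returns one ``(FlockSurveyRecord, truth)`` pair per flock, where
    truth maps species to the generating config plus the stratum label.
    """
    if n_flocks < 1:
        raise ValueError("n_flocks must be ≥ 1")
    sampler = cfg_sampler if cfg_sampler is not None else study_cohort_sampler()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_flocks):
        spec = sampler(rng, i)
        sims = {}
        for species in ("sheep", "goat"):
            cfg = spec.get(species)
            if cfg is not None:
                sims[species] = simulate_flock(cfg)
        record = FlockSurveyRecord(
            flock_id=f"flock_{i + 1:04d}",
            ward=spec.get("ward", ""),
            usually_buys_animals=spec.get("usually_buys_animals"),
            removing_goats=bool(spec.get("removing_goats", False)),
            sheep=sims["sheep"].record if "sheep" in sims else None,
            goats=sims["goat"].record if "goat" in sims else None,
        )
        truth = {
            "stratum": (
                "pastoralist_and_trader"
                if spec.get("usually_buys_animals")
                else "pastoralist_only"
            ),
            **{sp: sim.truth for sp, sim in sims.items()},
        }
        out.append((record, truth))
    return out
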