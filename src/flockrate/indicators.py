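"""Per-flock production and reproduction indicators.

All indicators are computed from a single recall interview covering a
12-month window.  Two denominators are used:

* reproduction rates divide by the number of reproductive females
  (females older than 2 years) present on the survey date;
* flock-dynamics rates (mortality, offtake, intake, production) divide
  by an animal-years-at-risk proxy ``n_mean``, the arithmetic mean of
  the flock size at the survey date and the back-calculated size 12
  months earlier.

The start size is reconstructed from the recall tallies themselves:
subtract the window's entries (live births and intakes) from, and add
its exits (natural deaths and offtakes) to, the animals counted on the
survey date.  With this reconstruction the production rate identity
``production_rate · n_mean = births_alive − deaths`` holds exactly —
production is the balance between births and deaths.

An indicator whose denominator is zero is *undefined* and encoded as
``None`` (never 0 or a sentinel); a zero-event numerator over a
positive denominator is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import (
    DEATH_CAUSES,
    INTAKE_CAUSES,
    OFFTAKE_CAUSES,
    FlowTallies,
    ReproductionTallies,
    SpeciesRecord,
)

__all__ = [
    "Denominators",
    "IndicatorSet",
    "InconsistentRecallError",
    "back_calculate_start",
    "compute_denominators",
    "reproduction_indicators",
    "dynamics_indicators",
    "compute_indicator_set",
    "indicator_frame",
]


class InconsistentRecallError(ValueError):
    """Recalled flows imply a negative flock size 12 months ago."""

    def __init__(self, n_end: int, entries: int, exits: int):
        self.n_end, self.entries, self.exits = n_end, entries, exits
        super().__init__(
            f"back-calculated start size {n_end - entries + exits} < 0 "
            f"(n_end={n_end}, entries={entries}, exits={exits})"
        )


@dataclass(frozen=True)
class Denominators:
    """Flock-size denominators for one species record.

    ``n_mean`` approximates animal-years at risk over the window;
    ``repro_females`` is the survey-date count of females > 2 years.
    """

    n_end: int
    n_start: int
    n_mean: float
    repro_females: int


@dataclass
class IndicatorSet:
    """The per-flock, per-species indicator values.

    ``None`` marks an indicator that is undefined for this flock
    (zero denominator).  Sheep records carry no triplet rate.
    """

    parturition_rate: Optional[float] = None
    prolificacy: Optional[float] = None
    twinning_rate: Optional[float] = None
    triplet_rate: Optional[float] = None
    fecundity_rate: Optional[float] = None
    abortion_rate: Optional[float] = None
    stillbirth_rate: Optional[float] = None
    dystocia_rate: Optional[float] = None
    net_prolificacy: Optional[float] = None
    net_fecundity: Optional[float] = None
    multiplication_rate: Optional[float] = None
    growth_rate_pct: Optional[float] = None
    production_rate: Optional[float] = None
    net_production_rate: Optional[float] = None
    mortality_rate: Optional[float] = None
    intake_rate: Optional[float] = None
    offtake_rate: Optional[float] = None
    mortality_by_cause: Optional[dict[str, float]] = None
    offtake_by_cause: Optional[dict[str, float]] = None
    intake_by_cause: Optional[dict[str, float]] = None
    reported_age_first_parturition: Optional[float] = None
    reported_age_at_replacement: Optional[float] = None


_REPRO_FIELDS = (
    "parturition_rate",
    "prolificacy",
    "twinning_rate",
    "triplet_rate",
    "fecundity_rate",
    "abortion_rate",
    "stillbirth_rate",
    "dystocia_rate",
    "net_prolificacy",
    "net_fecundity",
)
_DYNAMICS_FIELDS = (
    "multiplication_rate",
    "growth_rate_pct",
    "production_rate",
    "net_production_rate",
    "mortality_rate",
    "intake_rate",
    "offtake_rate",
    "mortality_by_cause",
    "offtake_by_cause",
    "intake_by_cause",
)


def back_calculate_start(n_end: int, entries: int, exits: int) -> int:
    """Flock size 12 months before the survey.

    entries = live births + intakes over the window;
    exits = natural deaths + offtakes (including slaughter and losses).
    """
    start = n_end - entries + exits
    if start < 0:
        raise InconsistentRecallError(n_end, entries, exits)
    return start


def compute_denominators(rec: SpeciesRecord) -> Denominators:
    """Back-calculate the start size and form both denominators."""
    n_end = rec.structure.total()
    entries = rec.flows.births_alive + rec.flows.intakes()
    exits = rec.flows.deaths() + rec.flows.offtakes()
    n_start = back_calculate_start(n_end, entries, exits)
    return Denominators(
        n_end=n_end,
        n_start=n_start,
        n_mean=(n_start + n_end) / 2.0,
        repro_females=rec.structure.repro_females,
    )


def _ratio(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def reproduction_indicators(
    rep: ReproductionTallies, den: Denominators
) -> IndicatorSet:
    """Reproduction rates over the survey-date reproductive females.

    Parturition, fecundity (offspring per reproductive female, alive or
    stillborn), their live-born "net" variants, and the annual abortion
    hazard divide by the reproductive-female count; litter-composition
    rates (prolificacy, twinning, triplet, dystocia) divide by
    parturitions; stillbirth divides by total offspring born.
    """
    rf = den.repro_females
    parts = rep.parturitions()
    offspring = rep.offspring_total()
    out = IndicatorSet(
        parturition_rate=_ratio(parts, rf),
        prolificacy=_ratio(offspring, parts),
        twinning_rate=_ratio(rep.parturitions_twin, parts),
        triplet_rate=_ratio(rep.parturitions_triplet, parts),
        fecundity_rate=_ratio(offspring, rf),
        abortion_rate=_ratio(rep.abortions, rf),
        stillbirth_rate=_ratio(rep.offspring_stillborn, offspring),
        dystocia_rate=_ratio(rep.dystocias, parts),
        net_prolificacy=_ratio(rep.offspring_alive, parts),
        net_fecundity=_ratio(rep.offspring_alive, rf),
    )
    out.reported_age_first_parturition = rep.reported_age_first_parturition
    out.reported_age_at_replacement = rep.reported_age_at_replacement
    return out


def dynamics_indicators(flows: FlowTallies, den: Denominators) -> IndicatorSet:
    """Flock-dynamics rates over animal-years at risk.

    Mortality counts natural deaths only (disease, predation, drought,
    other); slaughter for own consumption is an offtake cause.
    """
    deaths = flows.deaths()
    offtakes = flows.offtakes()
    intakes = flows.intakes()
    n_mean = den.n_mean
    multiplication = _ratio(den.n_end, den.n_start)
    out = IndicatorSet(
        multiplication_rate=multiplication,
        growth_rate_pct=None if multiplication is None else 100.0 * (multiplication - 1.0),
        production_rate=_ratio((den.n_end - den.n_start) + (offtakes - intakes), n_mean),
        net_production_rate=_ratio(offtakes - intakes, n_mean),
        mortality_rate=_ratio(deaths, n_mean),
        intake_rate=_ratio(intakes, n_mean),
        offtake_rate=_ratio(offtakes, n_mean),
    )
    if n_mean > 0:
        out.mortality_by_cause = {
            c: flows.deaths_by_cause.get(c, 0) / n_mean for c in DEATH_CAUSES
        }
        out.offtake_by_cause = {
            c: flows.offtakes_by_cause.get(c, 0) / n_mean for c in OFFTAKE_CAUSES
        }
        out.intake_by_cause = {
            c: flows.intakes_by_cause.get(c, 0) / n_mean for c in INTAKE_CAUSES
        }
    return out


def compute_indicator_set(rec: SpeciesRecord) -> IndicatorSet:
    """All indicators for one species record (19 for goats, 18 for sheep)."""
    den = compute_denominators(rec)
    repro = reproduction_indicators(rec.reproduction, den)
    dyn = dynamics_indicators(rec.flows, den)
    out = IndicatorSet()
    for name in _REPRO_FIELDS:
        setattr(out, name, getattr(repro, name))
    for name in _DYNAMICS_FIELDS:
        setattr(out, name, getattr(dyn, name))
    if rec.species == "sheep":
        out.triplet_rate = None
    out.reported_age_first_parturition = rec.reproduction.reported_age_first_parturition
    out.reported_age_at_replacement = rec.reproduction.reported_age_at_replacement
    return out


def indicator_frame(pairs):
    """Tabulate (flock_id, IndicatorSet) pairs as a pandas DataFrame.

    Scalar indicators become columns; per-cause maps expand to
    ``mortality_<cause>``, ``offtake_<cause>`` and ``intake_<cause>``
    columns.  Undefined values become NaN.
    """
    import numpy as np
    import pandas as pd

    rows = []
    for flock_id, ind in pairs:
        row: dict = {"flock_id": flock_id}
        for name in (*_REPRO_FIELDS, *_DYNAMICS_FIELDS[:7]):
            value = getattr(ind, name)
            row[name] = np.nan if value is None else value
        for prefix, causes, mapping in (
            ("mortality", DEATH_CAUSES, ind.mortality_by_cause),
            ("offtake", OFFTAKE_CAUSES, ind.offtake_by_cause),
            ("intake", INTAKE_CAUSES, ind.intake_by_cause),
        ):
            for c in causes:
                row[f"{prefix}_{c}"] = (
                    np.nan if mapping is None else mapping.get(c, np.nan)
                )
        row["reported_age_first_parturition"] = (
            np.nan
            if ind.reported_age_first_parturition is None
            else ind.reported_age_first_parturition
        )
        row["reported_age_at_replacement"] = (
            np.nan
            if ind.reported_age_at_replacement is None
            else ind.reported_age_at_replacement
        )
        rows.append(row)
    return pd.DataFrame(rows)
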