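"""Actuarial expectations of the daily competing-risk flock process.

Deterministic day-by-day recursion over expected counts, derived
directly from the process definition (per-day event probabilities
``1 − exp(−h/365)`` resolved death → offtake, survivors drawing
abortion then parturition, newborns and intakes at risk from the next
day).  It shares no code path with the stochastic simulator and serves
as its independent oracle: replicate means of both the raw event
counts and the survey estimators must match these expectations up to
Monte-Carlo error.

For the estimators (event count over a random denominator) the
expectation reported is the ratio of expectations; for flocks of the
sizes used here the Jensen gap is second-order and far below
Monte-Carlo resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .simulate import DAYS, SimulationConfig, _LITTER_SIZES

__all__ = ["ExpectedOutcomes", "expected_outcomes"]


@dataclass(frozen=True)
class ExpectedOutcomes:
    """Expected event counts and estimator values for one config."""

    n_start: float
    n_end: float
    n_mean: float
    repro_females_end: float
    deaths: float
    offtakes: float
    intakes: float
    parturitions: float
    abortions: float
    births_alive: float
    # expected survey estimators (ratio of expectations)
    mortality_rate: float
    offtake_rate: float
    intake_rate: float
    parturition_rate: float


def expected_outcomes(cfg: SimulationConfig) -> ExpectedOutcomes:
    """Exact expectations of the daily process for ``cfg``.

    Assumes the default process variants: no refractory period and no
    within-window aging (the recursion does not model either).
    """
    if cfg.min_interparturition_days:
        raise ValueError("expectation recursion assumes no refractory period")
    if cfg.aging:
        raise ValueError("expectation recursion assumes aging is off")

    m_total = sum(cfg.mortality_hazard_by_cause.values())
    o_total = sum(cfg.offtake_hazard_by_cause.values())
    p_death = 1.0 - math.exp(-m_total / DAYS)
    # offtake happens only if the death check was survived
    p_offtake = math.exp(-m_total / DAYS) * (1.0 - math.exp(-o_total / DAYS))
    survive = math.exp(-(m_total + o_total) / DAYS)
    p_abort = 1.0 - math.exp(-cfg.abortion_hazard / DAYS)
    p_part = 1.0 - math.exp(-cfg.parturition_hazard / DAYS)
    mean_litter = sum(
        _LITTER_SIZES[name] * p for name, p in cfg.litter_probs.items()
    )
    intake_total = sum(cfg.intake_rate_by_cause.values())
    intake_per_day = intake_total / DAYS

    n0 = float(cfg.initial_structure.total())
    active = n0  # expected animals at risk at the start of the day
    females = float(cfg.initial_structure.repro_females)
    deaths = offtakes = parturitions = abortions = births = 0.0
    for _ in range(DAYS):
        deaths += active * p_death
        offtakes += active * p_offtake
        f_surviving = females * survive
        abortions += f_surviving * p_abort
        part_today = f_surviving * (1.0 - p_abort) * p_part
        parturitions += part_today
        live = part_today * mean_litter * (1.0 - cfg.stillbirth_prob)
        births += live
        active = active * survive + live + intake_per_day
        females = f_surviving

    n_end = active
    n_mean = (n0 + n_end) / 2.0
    return ExpectedOutcomes(
        n_start=n0,
        n_end=n_end,
        n_mean=n_mean,
        repro_females_end=females,
        deaths=deaths,
        offtakes=offtakes,
        intakes=intake_total,
        parturitions=parturitions,
        abortions=abortions,
        births_alive=births,
        mortality_rate=deaths / n_mean if n_mean else float("nan"),
        offtake_rate=offtakes / n_mean if n_mean else float("nan"),
        intake_rate=intake_total / n_mean if n_mean else float("nan"),
        parturition_rate=parturitions / females if females else float("nan"),
    )
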