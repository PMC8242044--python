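"""Indicator arithmetic: denominators, rates, exact identities."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flockrate.indicators import (
    InconsistentRecallError,
    back_calculate_start,
    compute_denominators,
    compute_indicator_set,
    dynamics_indicators,
    reproduction_indicators,
)
from flockrate.records import (
    FlowTallies,
    ReproductionTallies,
    SpeciesRecord,
    SpeciesStructure,
)

from conftest import random_species_record


class TestBackCalculation:
    def test_worked_example(self):
        # 100 now; entries 35 (30 births + 5 intakes); exits 30 (10 deaths + 20 offtakes)
        assert back_calculate_start(100, 35, 30) == 95

    def test_static_flock(self):
        assert back_calculate_start(50, 0, 0) == 50

    def test_negative_start_raises_with_tallies(self):
        with pytest.raises(InconsistentRecallError) as info:
            back_calculate_start(10, 20, 0)
        assert info.value.entries == 20 and info.value.n_end == 10

    def test_denominators(self, toy_species_record):
        den = compute_denominators(toy_species_record)
        assert (den.n_end, den.n_start) == (100, 95)
        assert den.n_mean == 97.5
        assert den.repro_females == 50


class TestReproductionIndicators:
    def test_worked_example_values(self, toy_species_record):
        den = compute_denominators(toy_species_record)
        ind = reproduction_indicators(toy_species_record.reproduction, den)
        expected = {
            "parturition_rate": 0.60,
            "prolificacy": 34 / 30,
            "twinning_rate": 4 / 30,
            "fecundity_rate": 0.68,
            "net_prolificacy": 32 / 30,
            "net_fecundity": 0.64,
            "abortion_rate": 0.02,
            "stillbirth_rate": 2 / 34,
            "dystocia_rate": 0.10,
        }
        for name, value in expected.items():
            assert getattr(ind, name) == pytest.approx(value, abs=1e-12), name

    def test_zero_parturitions_defined_vs_undefined(self):
        den = dataclasses.replace(
            compute_denominators(
                SpeciesRecord("goat", SpeciesStructure(repro_females=20))
            )
        )
        ind = reproduction_indicators(ReproductionTallies(), den)
        assert ind.parturition_rate == 0.0  # zero events over positive denominator
        assert ind.fecundity_rate == 0.0
        assert ind.prolificacy is None  # per-parturition rates undefined
        assert ind.dystocia_rate is None
        assert ind.stillbirth_rate is None

    def test_all_singleton_no_loss_prolificacy_is_one(self):
        rec = SpeciesRecord(
            "goat",
            SpeciesStructure(repro_females=15),
            ReproductionTallies(parturitions_single=10, offspring_alive=10),
        )
        ind = reproduction_indicators(rec.reproduction, compute_denominators(rec))
        assert ind.prolificacy == 1.0 == ind.net_prolificacy

    def test_no_reproductive_females_rates_undefined(self):
        rec = SpeciesRecord("sheep", SpeciesStructure(young_females=12))
        ind = reproduction_indicators(rec.reproduction, compute_denominators(rec))
        assert ind.parturition_rate is None
        assert ind.fecundity_rate is None


class TestDynamicsIndicators:
    def test_worked_example_values(self, toy_species_record):
        den = compute_denominators(toy_species_record)
        ind = dynamics_indicators(toy_species_record.flows, den)
        assert ind.multiplication_rate == pytest.approx(100 / 95, abs=1e-12)
        assert ind.growth_rate_pct == pytest.approx(100 * (100 / 95 - 1), abs=1e-10)
        assert ind.production_rate == pytest.approx(20 / 97.5, abs=1e-12)
        assert ind.net_production_rate == pytest.approx(15 / 97.5, abs=1e-12)
        assert ind.mortality_rate == pytest.approx(10 / 97.5, abs=1e-12)
        assert ind.mortality_by_cause["disease"] == pytest.approx(7 / 97.5, abs=1e-12)
        assert ind.mortality_by_cause["predation"] == pytest.approx(2 / 97.5, abs=1e-12)
        assert ind.mortality_by_cause["drought"] == pytest.approx(1 / 97.5, abs=1e-12)
        assert ind.intake_rate == pytest.approx(5 / 97.5, abs=1e-12)
        assert ind.offtake_rate == pytest.approx(20 / 97.5, abs=1e-12)

    def test_static_flock_all_zero_rates(self):
        rec = SpeciesRecord("sheep", SpeciesStructure(10, 10, 20, 10))
        ind = dynamics_indicators(rec.flows, compute_denominators(rec))
        assert ind.multiplication_rate == 1.0
        assert ind.growth_rate_pct == 0.0
        assert ind.production_rate == 0.0
        assert ind.mortality_rate == 0.0
        assert sum(ind.offtake_by_cause.values()) == 0.0

    def test_empty_flock_rates_undefined(self):
        rec = SpeciesRecord("sheep", SpeciesStructure())
        ind = dynamics_indicators(rec.flows, compute_denominators(rec))
        assert ind.mortality_rate is None
        assert ind.multiplication_rate is None
        assert ind.mortality_by_cause is None


class TestFullIndicatorSet:
    def test_toy_flock_combines_both_parts(self, toy_species_record):
        ind = compute_indicator_set(toy_species_record)
        assert ind.parturition_rate == pytest.approx(0.60)
        assert ind.production_rate == pytest.approx(20 / 97.5)
        assert ind.triplet_rate is None  # sheep carry no triplet rate

    def test_goat_triplet_rate_present(self):
        rec = SpeciesRecord(
            "goat",
            SpeciesStructure(repro_females=10),
            ReproductionTallies(
                parturitions_single=4, parturitions_triplet=1, offspring_alive=7
            ),
        )
        assert compute_indicator_set(rec).triplet_rate == pytest.approx(0.2)

    def test_zero_event_flock(self):
        rec = SpeciesRecord("goat", SpeciesStructure(5, 5, 10, 5))
        ind = compute_indicator_set(rec)
        assert ind.mortality_rate == 0.0
        assert ind.parturition_rate == 0.0
        assert ind.prolificacy is None


@st.composite
def _random_records(draw):
    seed = draw(st.integers(0, 2**31 - 1))
    return random_species_record(np.random.default_rng(seed))


class TestExactIdentities:
    """Algebraic identities that must hold for every valid record."""

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(rec=_random_records())
    def test_production_is_birth_death_balance(self, rec):
        den = compute_denominators(rec)
        ind = compute_indicator_set(rec)
        if den.n_mean == 0:
            assert ind.production_rate is None
            return
        balance = rec.flows.births_alive - rec.flows.deaths()
        assert ind.production_rate * den.n_mean == pytest.approx(balance, abs=1e-12)
        # and production - net_production == relative size change
        assert ind.production_rate - ind.net_production_rate == pytest.approx(
            (den.n_end - den.n_start) / den.n_mean, abs=1e-12
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(rec=_random_records())
    def test_fecundity_decomposition_and_cause_sums(self, rec):
        ind = compute_indicator_set(rec)
        if ind.parturition_rate is not None and ind.prolificacy is not None:
            assert ind.fecundity_rate == pytest.approx(
                ind.parturition_rate * ind.prolificacy, abs=1e-12
            )
            assert ind.net_fecundity == pytest.approx(
                ind.parturition_rate * ind.net_prolificacy, abs=1e-12
            )
            assert ind.net_fecundity <= ind.fecundity_rate + 1e-12
            assert ind.net_prolificacy <= ind.prolificacy + 1e-12
        if ind.mortality_rate is not None:
            assert sum(ind.mortality_by_cause.values()) == pytest.approx(
                ind.mortality_rate, abs=1e-12
            )
            assert sum(ind.offtake_by_cause.values()) == pytest.approx(
                ind.offtake_rate, abs=1e-12
            )
            assert sum(ind.intake_by_cause.values()) == pytest.approx(
                ind.intake_rate, abs=1e-12
            )

    def test_one_extra_death_moves_rates_monotonically(self, toy_species_record):
        before = compute_indicator_set(toy_species_record)
        deaths = dict(toy_species_record.flows.deaths_by_cause)
        deaths["disease"] += 1
        worse = dataclasses.replace(
            toy_species_record,
            flows=dataclasses.replace(toy_species_record.flows, deaths_by_cause=deaths),
        )
        after = compute_indicator_set(worse)
        assert after.mortality_rate > before.mortality_rate
        assert after.production_rate < before.production_rate
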