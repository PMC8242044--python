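"""Survey data model for pastoralist small-ruminant flocks.

A single cross-sectional interview yields, per flock and per species
(sheep and goats separately), the current flock structure in four
age-sex categories, twelve months of recalled reproduction tallies, and
twelve months of recalled flock flows (deaths, offtakes and intakes,
each broken down by cause).  One CSV row encodes one flock-species
pair; flock-level metadata is repeated on both rows of a flock.

Column dictionary (snake_case, UTF-8)
-------------------------------------
Metadata: ``flock_id``, ``ward``, ``species`` ("sheep"/"goat"),
``usually_buys_animals`` (true/false, blank = unknown),
``removing_goats`` (true/false, blank = false), ``adverse_events``
(semicolon-separated tags, optional column).

Structure counts (animals present on the survey date):
``young_females``, ``young_males`` (≤ 2 years), ``repro_females``,
``older_males`` (> 2 years).

Reproduction tallies (previous 12 months): ``parturitions_single``,
``parturitions_twin``, ``parturitions_triplet``, ``offspring_alive``,
``offspring_stillborn``, ``abortions``, ``dystocias``, and the reported
ages ``age_first_parturition``, ``age_at_replacement`` (optional
columns, blank = not reported).

Flows (previous 12 months): ``births_alive``; deaths by cause
``deaths_disease``, ``deaths_predation``, ``deaths_drought``,
``deaths_other``; offtakes by cause ``offtakes_sale``,
``offtakes_slaughter_own_consumption``,
``offtakes_gift_dowry_inheritance``, ``offtakes_lost``,
``offtakes_other``; intakes by cause ``intakes_purchase``,
``intakes_gift_dowry_inheritance``, ``intakes_other``.

When a respondent owns several flocks the interview covers all of
them; the loader therefore pools rows sharing the same
(flock_id, species) by summing their tallies, so every record is one
respondent's flock of that species.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "DEATH_CAUSES",
    "OFFTAKE_CAUSES",
    "INTAKE_CAUSES",
    "SPECIES",
    "SpeciesStructure",
    "ReproductionTallies",
    "FlowTallies",
    "SpeciesRecord",
    "FlockSurveyRecord",
    "RowIssue",
    "ReadResult",
    "SchemaError",
    "read_survey_csv",
    "write_survey_csv",
    "classify_pastoralist",
    "species_eligible",
    "fei_eligible",
]

DEATH_CAUSES = ("disease", "predation", "drought", "other")
OFFTAKE_CAUSES = (
    "sale",
    "slaughter_own_consumption",
    "gift_dowry_inheritance",
    "lost",
    "other",
)
INTAKE_CAUSES = ("purchase", "gift_dowry_inheritance", "other")
SPECIES = ("sheep", "goat")

#: minimum per-species flock size for the species to enter the analysis
MIN_SPECIES_SIZE = 10
#: minimum combined flock size for the two-species efficiency score
MIN_COMBINED_SIZE = 30


class SchemaError(ValueError):
    """The CSV header does not match the documented column dictionary."""


@dataclass(frozen=True)
class SpeciesStructure:
    """Animals present on the survey date, in the four age-sex categories.

    Young animals are 2 years old or less; females older than 2 years
    are counted as reproductive females (the field cut-off for
    reproductive maturity).
    """

    young_females: int = 0
    young_males: int = 0
    repro_females: int = 0
    older_males: int = 0

    def total(self) -> int:
        return (
            self.young_females + self.young_males + self.repro_females + self.older_males
        )

    def validation_errors(self) -> list[str]:
        errors = []
        for name in ("young_females", "young_males", "repro_females", "older_males"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                errors.append(f"{name} must be a non-negative integer, got {value!r}")
        return errors


@dataclass(frozen=True)
class ReproductionTallies:
    """Recalled reproduction events over the 12-month window.

    Tallies are reported independently by recall, so offspring counts
    are not forced to match the litter-size bookkeeping; abortions are
    not parturitions and aborted foetuses are not offspring.
    """

    parturitions_single: int = 0
    parturitions_twin: int = 0
    parturitions_triplet: int = 0
    offspring_alive: int = 0
    offspring_stillborn: int = 0
    abortions: int = 0
    dystocias: int = 0
    reported_age_first_parturition: Optional[float] = None
    reported_age_at_replacement: Optional[float] = None

    def parturitions(self) -> int:
        return self.parturitions_single + self.parturitions_twin + self.parturitions_triplet

    def offspring_total(self) -> int:
        return self.offspring_alive + self.offspring_stillborn

    def validation_errors(self) -> list[str]:
        errors = []
        for name in (
            "parturitions_single",
            "parturitions_twin",
            "parturitions_triplet",
            "offspring_alive",
            "offspring_stillborn",
            "abortions",
            "dystocias",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                errors.append(f"{name} must be a non-negative integer, got {value!r}")
        if not errors and self.parturitions() > 0 and self.dystocias > self.parturitions():
            errors.append(
                f"dystocias ({self.dystocias}) exceed parturitions ({self.parturitions()})"
            )
        return errors


def _check_cause_map(
    mapping: Mapping[str, int], causes: Sequence[str], label: str
) -> list[str]:
    errors = []
    for cause in mapping:
        if cause not in causes:
            errors.append(f"{label} has unknown cause {cause!r}")
    for cause in causes:
        value = mapping.get(cause, 0)
        if not isinstance(value, int) or value < 0:
            errors.append(
                f"{label}_{cause} must be a non-negative integer, got {value!r}"
            )
    return errors


@dataclass(frozen=True)
class FlowTallies:
    """Recalled flock entries and exits over the 12-month window, by cause."""

    births_alive: int = 0
    deaths_by_cause: Mapping[str, int] = field(default_factory=dict)
    offtakes_by_cause: Mapping[str, int] = field(default_factory=dict)
    intakes_by_cause: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        # canonicalize: every known cause present, so equality is by value
        for name, causes in (
            ("deaths_by_cause", DEATH_CAUSES),
            ("offtakes_by_cause", OFFTAKE_CAUSES),
            ("intakes_by_cause", INTAKE_CAUSES),
        ):
            mapping = getattr(self, name)
            full = {c: mapping.get(c, 0) for c in causes}
            full.update({c: v for c, v in mapping.items() if c not in causes})
            object.__setattr__(self, name, full)

    def deaths(self) -> int:
        return sum(self.deaths_by_cause.get(c, 0) for c in DEATH_CAUSES)

    def offtakes(self) -> int:
        return sum(self.offtakes_by_cause.get(c, 0) for c in OFFTAKE_CAUSES)

    def intakes(self) -> int:
        return sum(self.intakes_by_cause.get(c, 0) for c in INTAKE_CAUSES)

    def validation_errors(self) -> list[str]:
        errors = []
        if not isinstance(self.births_alive, int) or self.births_alive < 0:
            errors.append(
                f"births_alive must be a non-negative integer, got {self.births_alive!r}"
            )
        errors += _check_cause_map(self.deaths_by_cause, DEATH_CAUSES, "deaths")
        errors += _check_cause_map(self.offtakes_by_cause, OFFTAKE_CAUSES, "offtakes")
        errors += _check_cause_map(self.intakes_by_cause, INTAKE_CAUSES, "intakes")
        return errors


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' full survey response for one flock."""

    species: str
    structure: SpeciesStructure
    reproduction: ReproductionTallies = field(default_factory=ReproductionTallies)
    flows: FlowTallies = field(default_factory=FlowTallies)

    def validation_errors(self) -> list[str]:
        errors = []
        if self.species not in SPECIES:
            errors.append(f"species must be one of {SPECIES}, got {self.species!r}")
        errors += self.structure.validation_errors()
        errors += self.reproduction.validation_errors()
        errors += self.flows.validation_errors()
        if not errors:
            start = (
                self.structure.total()
                - (self.flows.births_alive + self.flows.intakes())
                + (self.flows.deaths() + self.flows.offtakes())
            )
            if start < 0:
                errors.append(
                    "back-calculated start size is negative "
                    f"({start}): recalled entries exceed current size plus exits"
                )
        return errors

    def validation_warnings(self) -> list[str]:
        warnings = []
        if self.flows.births_alive != self.reproduction.offspring_alive:
            warnings.append(
                f"births_alive ({self.flows.births_alive}) disagrees with "
                f"offspring_alive ({self.reproduction.offspring_alive}); "
                "recall tallies kept as reported"
            )
        return warnings


@dataclass(frozen=True)
class FlockSurveyRecord:
    """One respondent's flock: metadata plus per-species records."""

    flock_id: str
    ward: str = ""
    usually_buys_animals: Optional[bool] = None
    removing_goats: bool = False
    sheep: Optional[SpeciesRecord] = None
    goats: Optional[SpeciesRecord] = None
    adverse_events: frozenset[str] = frozenset()

    def species_records(self) -> dict[str, SpeciesRecord]:
        out = {}
        if self.sheep is not None:
            out["sheep"] = self.sheep
        if self.goats is not None:
            out["goat"] = self.goats
        return out

    def validation_errors(self) -> list[str]:
        errors = []
        if self.sheep is None and self.goats is None:
            errors.append("at least one species record must be present")
        for rec in (self.sheep, self.goats):
            if rec is not None:
                errors += rec.validation_errors()
        return errors


@dataclass(frozen=True)
class RowIssue:
    """A rejected row (or pooled flock-species aggregate) with its reason."""

    row: Optional[int]  # 1-based data row in the CSV, None for aggregates
    flock_id: str
    species: str
    field: str
    reason: str


@dataclass
class ReadResult:
    """Outcome of reading a survey CSV: accepted records, rejects, warnings."""

    records: list[FlockSurveyRecord]
    rejects: list[RowIssue]
    warnings: list[str]


_COUNT_COLUMNS = (
    "young_females",
    "young_males",
    "repro_females",
    "older_males",
    "parturitions_single",
    "parturitions_twin",
    "parturitions_triplet",
    "offspring_alive",
    "offspring_stillborn",
    "abortions",
    "dystocias",
    "births_alive",
    *(f"deaths_{c}" for c in DEATH_CAUSES),
    *(f"offtakes_{c}" for c in OFFTAKE_CAUSES),
    *(f"intakes_{c}" for c in INTAKE_CAUSES),
)
_OPTIONAL_COLUMNS = ("ward", "adverse_events", "age_first_parturition", "age_at_replacement")
_MANDATORY_COLUMNS = (
    "flock_id",
    "species",
    "usually_buys_animals",
    "removing_goats",
    *_COUNT_COLUMNS,
)
COLUMNS = (
    "flock_id",
    "ward",
    "species",
    "usually_buys_animals",
    "removing_goats",
    "adverse_events",
    *_COUNT_COLUMNS[:4],
    *_COUNT_COLUMNS[4:11],
    "age_first_parturition",
    "age_at_replacement",
    *_COUNT_COLUMNS[11:],
)


def _parse_bool(text: str) -> Optional[bool]:
    text = text.strip().lower()
    if text in ("", "na", "nan"):
        return None
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _format_bool(value: Optional[bool]) -> str:
    return "" if value is None else ("true" if value else "false")


def _parse_count(text: str) -> int:
    value = int(text.strip())
    return value


def read_survey_csv(path) -> ReadResult:
    """Read and validate a survey CSV.

    Every data row is classified as exactly one of accepted or
    rejected-with-reason; nothing is silently dropped.  Rows sharing a
    (flock_id, species) pair are pooled by summing their tallies
    (multi-flock respondents).  Pooled aggregates failing a record
    invariant (e.g. a negative back-calculated start size) are rejected
    at the aggregate level.
    """
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        raw_rows = list(reader)

    rejects: list[RowIssue] = []
    warnings: list[str] = []
    parsed: list[tuple[int, dict]] = []  # (row number, parsed fields)

    for i, row in enumerate(raw_rows, start=1):
        flock_id = (row.get("flock_id") or "").strip()
        species = (row.get("species") or "").strip().lower()
        if not flock_id:
            rejects.append(RowIssue(i, flock_id, species, "flock_id", "empty flock_id"))
            continue
        if species not in SPECIES:
            rejects.append(
                RowIssue(i, flock_id, species, "species", f"unknown species {species!r}")
            )
            continue
        fields: dict = {"flock_id": flock_id, "species": species}
        bad = None
        for col in _COUNT_COLUMNS:
            text = (row.get(col) or "").strip()
            if not text:
                bad = RowIssue(i, flock_id, species, col, "missing count")
                break
            try:
                value = _parse_count(text)
            except (TypeError, ValueError):
                bad = RowIssue(i, flock_id, species, col, f"not an integer: {text!r}")
                break
            if value < 0:
                bad = RowIssue(i, flock_id, species, col, f"negative count {value}")
                break
            fields[col] = value
        if bad is not None:
            rejects.append(bad)
            continue
        try:
            fields["usually_buys_animals"] = _parse_bool(row.get("usually_buys_animals", ""))
            removing = _parse_bool(row.get("removing_goats", ""))
        except ValueError as exc:
            rejects.append(RowIssue(i, flock_id, species, "boolean", str(exc)))
            continue
        fields["removing_goats"] = bool(removing)
        fields["ward"] = (row.get("ward") or "").strip()
        tags = (row.get("adverse_events") or "").strip()
        fields["adverse_events"] = frozenset(t for t in tags.split(";") if t)
        for col in ("age_first_parturition", "age_at_replacement"):
            text = (row.get(col) or "").strip()
            if text:
                try:
                    fields[col] = float(text)
                except ValueError:
                    bad = RowIssue(i, flock_id, species, col, f"not a number: {text!r}")
                    break
            else:
                fields[col] = None
        if bad is not None:
            rejects.append(bad)
            continue
        parsed.append((i, fields))

    # pool rows by (flock_id, species), preserving first-seen flock order
    by_flock: dict[str, dict[str, dict]] = {}
    flock_order: list[str] = []
    for _, fields in parsed:
        fid = fields["flock_id"]
        if fid not in by_flock:
            by_flock[fid] = {}
            flock_order.append(fid)
        bucket = by_flock[fid]
        sp = fields["species"]
        if sp in bucket:
            agg = bucket[sp]
            for col in _COUNT_COLUMNS:
                agg[col] += fields[col]
            for col in ("age_first_parturition", "age_at_replacement"):
                if agg[col] is None:
                    agg[col] = fields[col]
            agg["adverse_events"] = agg["adverse_events"] | fields["adverse_events"]
            for meta in ("ward", "usually_buys_animals", "removing_goats"):
                if agg[meta] != fields[meta]:
                    warnings.append(
                        f"flock {fid}: conflicting {meta} across pooled rows; "
                        "keeping first value"
                    )
        else:
            bucket[sp] = dict(fields)

    records: list[FlockSurveyRecord] = []
    for fid in flock_order:
        bucket = by_flock[fid]
        species_recs: dict[str, SpeciesRecord] = {}
        meta = next(iter(bucket.values()))
        for sp, fields in bucket.items():
            rec = SpeciesRecord(
                species=sp,
                structure=SpeciesStructure(
                    young_females=fields["young_females"],
                    young_males=fields["young_males"],
                    repro_females=fields["repro_females"],
                    older_males=fields["older_males"],
                ),
                reproduction=ReproductionTallies(
                    parturitions_single=fields["parturitions_single"],
                    parturitions_twin=fields["parturitions_twin"],
                    parturitions_triplet=fields["parturitions_triplet"],
                    offspring_alive=fields["offspring_alive"],
                    offspring_stillborn=fields["offspring_stillborn"],
                    abortions=fields["abortions"],
                    dystocias=fields["dystocias"],
                    reported_age_first_parturition=fields["age_first_parturition"],
                    reported_age_at_replacement=fields["age_at_replacement"],
                ),
                flows=FlowTallies(
                    births_alive=fields["births_alive"],
                    deaths_by_cause={c: fields[f"deaths_{c}"] for c in DEATH_CAUSES},
                    offtakes_by_cause={c: fields[f"offtakes_{c}"] for c in OFFTAKE_CAUSES},
                    intakes_by_cause={c: fields[f"intakes_{c}"] for c in INTAKE_CAUSES},
                ),
            )
            errors = rec.validation_errors()
            if errors:
                rejects.append(RowIssue(None, fid, sp, "record", "; ".join(errors)))
                continue
            for w in rec.validation_warnings():
                warnings.append(f"flock {fid} ({sp}): {w}")
            species_recs[sp] = rec
        if not species_recs:
            continue
        records.append(
            FlockSurveyRecord(
                flock_id=fid,
                ward=meta["ward"],
                usually_buys_animals=meta["usually_buys_animals"],
                removing_goats=meta["removing_goats"],
                sheep=species_recs.get("sheep"),
                goats=species_recs.get("goat"),
                adverse_events=meta["adverse_events"],
            )
        )
    return ReadResult(records=records, rejects=rejects, warnings=warnings)


def write_survey_csv(records: Iterable[FlockSurveyRecord], path) -> None:
    """Write records as one CSV row per flock-species pair.

    Reading the file back reproduces the records field for field.
    """
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COLUMNS)
        for record in records:
            for sp, rec in record.species_records().items():
                st, rep, fl = rec.structure, rec.reproduction, rec.flows
                row = {
                    "flock_id": record.flock_id,
                    "ward": record.ward,
                    "species": sp,
                    "usually_buys_animals": _format_bool(record.usually_buys_animals),
                    "removing_goats": _format_bool(record.removing_goats),
                    "adverse_events": ";".join(sorted(record.adverse_events)),
                    "young_females": st.young_females,
                    "young_males": st.young_males,
                    "repro_females": st.repro_females,
                    "older_males": st.older_males,
                    "parturitions_single": rep.parturitions_single,
                    "parturitions_twin": rep.parturitions_twin,
                    "parturitions_triplet": rep.parturitions_triplet,
                    "offspring_alive": rep.offspring_alive,
                    "offspring_stillborn": rep.offspring_stillborn,
                    "abortions": rep.abortions,
                    "dystocias": rep.dystocias,
                    "age_first_parturition": (
                        "" if rep.reported_age_first_parturition is None
                        else rep.reported_age_first_parturition
                    ),
                    "age_at_replacement": (
                        "" if rep.reported_age_at_replacement is None
                        else rep.reported_age_at_replacement
                    ),
                    "births_alive": fl.births_alive,
                }
                for c in DEATH_CAUSES:
                    row[f"deaths_{c}"] = fl.deaths_by_cause.get(c, 0)
                for c in OFFTAKE_CAUSES:
                    row[f"offtakes_{c}"] = fl.offtakes_by_cause.get(c, 0)
                for c in INTAKE_CAUSES:
                    row[f"intakes_{c}"] = fl.intakes_by_cause.get(c, 0)
                writer.writerow([row[col] for col in COLUMNS])


def classify_pastoralist(record: FlockSurveyRecord) -> str:
    """Classify a respondent by reported trading habit.

    Respondents who usually buy animals to bring into the flock are
    "pastoralist_and_trader"; those who do not are "pastoralist_only";
    a missing answer yields "unknown".
    """
    if record.usually_buys_animals is None:
        return "unknown"
    return "pastoralist_and_trader" if record.usually_buys_animals else "pastoralist_only"


def species_eligible(record: SpeciesRecord, removing_goats: bool = False) -> bool:
    """Whether a species record enters the per-species indicator analysis.

    Flocks with fewer than 10 animals of the species, and goat flocks
    being deliberately run down, are excluded.
    """
    if record.structure.total() < MIN_SPECIES_SIZE:
        return False
    if record.species == "goat" and removing_goats:
        return False
    return True


def fei_eligible(record: FlockSurveyRecord) -> bool:
    """Whether a flock is eligible for the two-species efficiency score.

    Requires both species present, at least 10 animals of each, at
    least 30 small ruminants combined, and no deliberate goat removal.
    """
    if record.sheep is None or record.goats is None:
        return False
    if record.removing_goats:
        return False
    n_sheep = record.sheep.structure.total()
    n_goats = record.goats.structure.total()
    if n_sheep < MIN_SPECIES_SIZE or n_goats < MIN_SPECIES_SIZE:
        return False
    return n_sheep + n_goats >= MIN_COMBINED_SIZE
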