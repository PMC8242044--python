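"""Flock Efficiency Indicator (FEI).

A composite three-point-per-component score for flocks keeping both
sheep and goats.  Four components are used: sheep and goat net
fecundity rate (reproduction performance) and sheep and goat production
rate (post-birth flock performance).  Each component is scored 1 (low
efficiency) to 3 (high) against the component's tertiles estimated
over the eligible cohort itself, and the FEI is the sum of the four
scores, ranging 4–12.  Multiplication rate is deliberately excluded:
it is driven by intakes and offtakes, which may reflect consequences
of performance rather than performance itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .quantiles import DEFAULT_METHOD, quantile
from .records import FlockSurveyRecord, fei_eligible
from .indicators import IndicatorSet

__all__ = [
    "TertileCutoffs",
    "FEIResult",
    "FEIComputation",
    "GroupSummary",
    "FEIComparison",
    "InsufficientCohortError",
    "FEI_COMPONENTS",
    "tertile_cutoffs",
    "score_component",
    "compute_fei",
    "compare_fei_by_type",
]

#: (result attribute, species key, indicator field) for the four components
FEI_COMPONENTS = (
    ("score_sheep_net_fecundity", "sheep", "net_fecundity"),
    ("score_goat_net_fecundity", "goat", "net_fecundity"),
    ("score_sheep_production", "sheep", "production_rate"),
    ("score_goat_production", "goat", "production_rate"),
)


class InsufficientCohortError(ValueError):
    """Fewer defined values than tertile estimation requires."""


@dataclass(frozen=True)
class TertileCutoffs:
    """Tertile boundaries of one component over the eligible cohort."""

    variable: str
    q_low: float
    q_high: float


@dataclass
class FEIResult:
    flock_id: str
    score_sheep_net_fecundity: Optional[int] = None
    score_goat_net_fecundity: Optional[int] = None
    score_sheep_production: Optional[int] = None
    score_goat_production: Optional[int] = None
    fei: Optional[int] = None
    eligible: bool = False
    reason: Optional[str] = None


@dataclass
class FEIComputation:
    """Scored cohort plus the cut-offs used (stored for reproducibility)."""

    results: list[FEIResult]
    cutoffs: dict[str, TertileCutoffs]


def tertile_cutoffs(
    values: Sequence[float], variable: str = "", method: str = DEFAULT_METHOD
) -> TertileCutoffs:
    """1/3 and 2/3 empirical quantiles of the defined values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise InsufficientCohortError(
            f"tertiles need at least 3 defined values, got {arr.size}"
        )
    return TertileCutoffs(
        variable=variable,
        q_low=quantile(arr, 1.0 / 3.0, method=method),
        q_high=quantile(arr, 2.0 / 3.0, method=method),
    )


def score_component(value: float, cut: TertileCutoffs) -> int:
    """Three-point efficiency score with right-closed tertile intervals.

    1 for value ≤ q_low, 2 for q_low < value ≤ q_high, 3 above q_high.
    """
    if value is None or np.isnan(value):
        raise ValueError("cannot score an undefined value")
    if value <= cut.q_low:
        return 1
    if value <= cut.q_high:
        return 2
    return 3


def _component_value(
    indicators: Mapping[str, IndicatorSet], species: str, fld: str
) -> Optional[float]:
    ind = indicators.get(species)
    if ind is None:
        return None
    return getattr(ind, fld)


def compute_fei(
    cohort: Sequence[tuple[FlockSurveyRecord, Mapping[str, IndicatorSet]]],
    method: str = DEFAULT_METHOD,
) -> FEIComputation:
    """Score a cohort of flocks.

    Cut-offs are estimated from eligible flocks only (both species
    present and above size thresholds, all four components defined);
    ineligible flocks are returned unscored with a reason.
    """
    eligible_idx: list[int] = []
    values: dict[str, list[float]] = {name: [] for name, _, _ in FEI_COMPONENTS}
    reasons: dict[int, str] = {}

    for i, (record, indicators) in enumerate(cohort):
        if not fei_eligible(record):
            reasons[i] = "fails flock eligibility (species presence/size/removal)"
            continue
        comps = {
            name: _component_value(indicators, sp, fld)
            for name, sp, fld in FEI_COMPONENTS
        }
        undefined = [name for name, v in comps.items() if v is None]
        if undefined:
            reasons[i] = f"undefined component(s): {', '.join(undefined)}"
            continue
        eligible_idx.append(i)
        for name, _, _ in FEI_COMPONENTS:
            values[name].append(comps[name])

    if len(eligible_idx) < 3:
        raise InsufficientCohortError(
            f"FEI needs at least 3 eligible flocks, got {len(eligible_idx)}"
        )

    cutoffs = {
        name: tertile_cutoffs(values[name], variable=name, method=method)
        for name, _, _ in FEI_COMPONENTS
    }

    results: list[FEIResult] = []
    for i, (record, indicators) in enumerate(cohort):
        result = FEIResult(flock_id=record.flock_id)
        if i in reasons:
            result.reason = reasons[i]
        else:
            result.eligible = True
            total = 0
            for name, sp, fld in FEI_COMPONENTS:
                score = score_component(
                    _component_value(indicators, sp, fld), cutoffs[name]
                )
                setattr(result, name, score)
                total += score
            result.fei = total
        results.append(result)
    return FEIComputation(results=results, cutoffs=cutoffs)


@dataclass
class GroupSummary:
    label: str
    n: int
    median: float
    q1: float
    q3: float


@dataclass
class FEIComparison:
    groups: list[GroupSummary]
    statistic: Optional[float]
    p_value: Optional[float]
    warnings: list[str]


def compare_fei_by_type(
    results: Sequence[FEIResult], types: Mapping[str, str]
) -> FEIComparison:
    """Compare FEI between pastoralist types with a rank-sum test.

    Uses the Kruskal–Wallis rank sum test (two groups or more) on the
    scores of eligible flocks; reports each group's median and
    quartiles.  Groups with fewer than 2 scored flocks are dropped
    with a warning.
    """
    by_group: dict[str, list[int]] = {}
    warnings: list[str] = []
    for result in results:
        if not result.eligible or result.fei is None:
            continue
        label = types.get(result.flock_id, "unknown")
        by_group.setdefault(label, []).append(result.fei)

    groups = []
    samples = []
    for label in sorted(by_group):
        scores = by_group[label]
        if len(scores) < 2:
            warnings.append(f"group {label!r} has {len(scores)} flock(s); skipped")
            continue
        arr = np.asarray(scores, dtype=float)
        groups.append(
            GroupSummary(
                label=label,
                n=arr.size,
                median=float(np.median(arr)),
                q1=quantile(arr, 0.25),
                q3=quantile(arr, 0.75),
            )
        )
        samples.append(arr)

    if len(samples) < 2:
        warnings.append("fewer than 2 usable groups; test skipped")
        return FEIComparison(groups=groups, statistic=None, p_value=None, warnings=warnings)

    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        # no rank variation at all: no evidence of any difference
        return FEIComparison(groups=groups, statistic=0.0, p_value=1.0, warnings=warnings)
    stat, p = sps.kruskal(*samples)
    return FEIComparison(
        groups=groups, statistic=float(stat), p_value=float(p), warnings=warnings
    )
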