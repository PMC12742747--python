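"""Cost and QALY accrual on life histories, discounting, ICER / net monetary
benefit decision rules, overdiagnosis estimation and budget impact.

The analysis takes a health-system (payer) perspective over a lifetime
horizon.  Because the engine is continuous-time, discounting is applied
continuously at event times on an annual base: a cost ``c`` incurred ``t``
years after the reference time contributes ``c / (1 + r)**t``.  Quality-of-
life weights multiply state occupancy: well until the first diagnosis,
thereafter the weight of the worst stage diagnosed so far, with a terminal
weight in the final window before a melanoma death.

The per-year program fixed cost in the tariff is deliberately excluded from
per-capita accrual and from the budget-impact rows, which scale linearly
with the modelled population; it is reported separately by the CLI decision
summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .engine import CohortResult, EventType, LifeHistory
from .mortality import STAGES
from .params import Tariff, UtilityWeights

__all__ = [
    "CEAResult",
    "discount",
    "accrue",
    "compare",
    "overdiagnosis_estimate",
    "budget_impact",
    "Tariff",
    "UtilityWeights",
]

_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


def discount(amount: float, time: float, rate: float) -> float:
    """Present value of ``amount`` incurred ``time`` years after the
    reference point: ``amount / (1 + rate)**time``."""
    if time < 0:
        raise ValueError("time must be >= 0")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return amount / (1.0 + rate) ** time


def _discounted_integral(a: float, b: float, rate: float) -> float:
    """Integral of the discount factor over ``[a, b]`` (years from the
    reference time)."""
    if b <= a:
        return 0.0
    if rate == 0.0:
        return b - a
    log_x = math.log1p(rate)
    return (math.exp(-log_x * a) - math.exp(-log_x * b)) / log_x


def event_costs(history: LifeHistory, tariff: Tariff):
    """Yield ``(age, cost)`` pairs for every cost-bearing event, plus
    ``(start_age, end_age, annual_rate)`` streams for continuing treatment."""
    point, streams = [], []
    check_cost = tariff.skin_check
    adjunct = tariff.keratinocyte_adjunct_cost
    channel_of = {
        EventType.CLINICIAN_VISIT: "opportunistic_visit",
        EventType.ROUTINE_CHECK: "routine_check",
        EventType.SURVEILLANCE_VISIT: "surveillance",
    }
    for e in history.events:
        if e.type in channel_of:
            point.append((e.age, check_cost[channel_of[e.type]] + adjunct))
        elif e.type is EventType.SCREENING_ROUND:
            cost = tariff.program_cost_per_invitee
            if e.payload.get("attended"):
                cost += check_cost["organised_screen"] + adjunct
            point.append((e.age, cost))
        elif e.type is EventType.FALSE_POSITIVE:
            point.append((e.age, tariff.false_positive_workup))
        elif e.type is EventType.DIAGNOSIS:
            stage = e.payload["stage"]
            point.append((e.age, tariff.diagnostic_excision
                          + tariff.treatment_initial[stage]))
            rate = tariff.treatment_continuing.get(stage, 0.0)
            if rate > 0:
                end = min(e.age + tariff.continuing_years, history.exit_age)
                streams.append((e.age, end, rate))
    return point, streams


def _utility_segments(history: LifeHistory, utilities: UtilityWeights):
    """Piecewise-constant utility over the lifetime as (start, end, weight)."""
    dx = sorted((t.diagnosis_age, t.stage_at_diagnosis)
                for t in history.tumours if t.diagnosed)
    entry = history.entry_age
    exit_age = history.exit_age
    breaks = [entry]
    weights = [utilities.well]
    worst = None
    for age, stage in dx:
        if age >= exit_age:
            continue
        if worst is None or _STAGE_ORDER[stage] > _STAGE_ORDER[worst]:
            worst = stage
        breaks.append(age)
        weights.append(utilities.by_stage.get(worst, utilities.well))
    if history.exit_cause == EventType.MELANOMA_DEATH.value and utilities.terminal_window > 0:
        t0 = max(exit_age - utilities.terminal_window, breaks[-1])
        if t0 < exit_age:
            breaks.append(t0)
            weights.append(utilities.terminal)
    segments = []
    for i, (start, w) in enumerate(zip(breaks, weights)):
        end = breaks[i + 1] if i + 1 < len(breaks) else exit_age
        if end > start:
            segments.append((start, end, w))
    return segments


def accrue(history: LifeHistory, tariff: Tariff, utilities: UtilityWeights,
           rate: float, reference_age: float | None = None):
    """(discounted cost, discounted life years, discounted QALYs) for one
    history.  Times are measured from ``reference_age`` (the individual's
    entry age by default)."""
    ref = reference_age
    if ref is None:
        ref = history.entry_age
    cost = 0.0
    point, streams = event_costs(history, tariff)
    for age, c in point:
        cost += discount(c, max(age - ref, 0.0), rate)
    for start, end, annual in streams:
        cost += annual * _discounted_integral(max(start - ref, 0.0),
                                              max(end - ref, 0.0), rate)
    ly = 0.0
    qaly = 0.0
    for start, end, w in _utility_segments(history, utilities):
        seg = _discounted_integral(max(start - ref, 0.0), max(end - ref, 0.0), rate)
        ly += seg
        qaly += w * seg
    return cost, ly, qaly


@dataclass
class CEAResult:
    """Cost-effectiveness comparison of a strategy against a comparator
    (per-capita discounted means)."""
    cost_strategy: float
    cost_comparator: float
    ly_strategy: float
    ly_comparator: float
    qaly_strategy: float
    qaly_comparator: float
    incremental_cost: float
    incremental_ly: float
    incremental_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    net_monetary_benefit: float
    wtp_threshold: float
    dominant: bool          # strategy cheaper and more effective
    dominated: bool         # strategy dearer and less effective
    icer_defined: bool

    @property
    def cost_effective(self) -> bool:
        return self.net_monetary_benefit > 0


def _cohort_means(result: CohortResult, tariff, utilities, rate):
    total_c = total_l = total_q = 0.0
    for h in result.histories:
        c, l, q = accrue(h, tariff, utilities, rate)
        total_c += c
        total_l += l
        total_q += q
    n = len(result.histories)
    return total_c / n, total_l / n, total_q / n


def compare(strategy: CohortResult, comparator: CohortResult, tariff: Tariff,
            utilities: UtilityWeights, rate: float, wtp: float) -> CEAResult:
    """Per-capita incremental cost-effectiveness of ``strategy`` versus
    ``comparator``, which should be simulated under common random numbers
    (same seed) so the increments are policy effects, not sampling noise."""
    cs, ls, qs = _cohort_means(strategy, tariff, utilities, rate)
    cc, lc, qc = _cohort_means(comparator, tariff, utilities, rate)
    d_cost, d_ly, d_qaly = cs - cc, ls - lc, qs - qc
    icer_ly = d_cost / d_ly if d_ly != 0 else None
    icer_qaly = d_cost / d_qaly if d_qaly != 0 else None
    nmb = wtp * d_qaly - d_cost
    return CEAResult(
        cost_strategy=cs, cost_comparator=cc,
        ly_strategy=ls, ly_comparator=lc,
        qaly_strategy=qs, qaly_comparator=qc,
        incremental_cost=d_cost, incremental_ly=d_ly, incremental_qaly=d_qaly,
        icer_per_ly=icer_ly, icer_per_qaly=icer_qaly,
        net_monetary_benefit=nmb, wtp_threshold=wtp,
        dominant=(d_cost < 0 and d_qaly > 0),
        dominated=(d_cost > 0 and d_qaly < 0),
        icer_defined=(d_qaly != 0),
    )


def overdiagnosis_estimate(screened: CohortResult, unscreened: CohortResult) -> float:
    """Proportion of screen-detected melanomas that are overdiagnosed.

    The two cohorts must be paired by seed and size (common random numbers on
    the natural-history channels, so the same tumours emerge).  A
    screen-detected tumour is overdiagnosed when the paired unscreened
    history exits - by other-cause death, melanoma death from another
    tumour, or the age cap - without that tumour (matched by index) ever
    being clinically diagnosed.  NaN if nothing was screen-detected.
    """
    if screened.seed != unscreened.seed or screened.n != unscreened.n:
        raise ValueError("cohorts are not paired: seeds and sizes must match")
    unscreened_by_id = {h.individual_id: h for h in unscreened.histories}
    n_screen = 0
    n_over = 0
    for h in screened.histories:
        twin = unscreened_by_id[h.individual_id]
        counterfactual_dx = {t.tumour_index for t in twin.tumours if t.diagnosed}
        for t in h.tumours:
            if t.diagnosed and t.detection_channel == "organised_screen":
                n_screen += 1
                if t.tumour_index not in counterfactual_dx:
                    n_over += 1
    return n_over / n_screen if n_screen else math.nan


def _yearly_costs(result: CohortResult, tariff: Tariff) -> dict:
    """Total undiscounted cost per calendar year, summed over the cohort."""
    out: dict = {}
    for h in result.histories:
        point, streams = event_costs(h, tariff)
        for age, c in point:
            year = math.floor(h.birth_year + age)
            out[year] = out.get(year, 0.0) + c
        for start, end, annual in streams:
            a = start
            while a < end:
                nxt = min(math.floor(h.birth_year + a) + 1 - h.birth_year, end)
                year = math.floor(h.birth_year + a)
                out[year] = out.get(year, 0.0) + annual * (nxt - a)
                a = nxt
    return out


def budget_impact(strategy: CohortResult, comparator: CohortResult,
                  population_size: float, start_year: int, horizon: int,
                  tariff: Tariff) -> pd.DataFrame:
    """Undiscounted incremental health-system cost per calendar year over a
    short horizon (default use: five years), scaled from per-capita cohort
    costs to ``population_size``.  Program fixed costs are excluded (they do
    not scale with population) and reported separately elsewhere."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ys = _yearly_costs(strategy, tariff)
    yc = _yearly_costs(comparator, tariff)
    n_s, n_c = len(strategy.histories), len(comparator.histories)
    rows = []
    for k in range(horizon):
        year = start_year + k
        inc = ys.get(year, 0.0) / n_s - yc.get(year, 0.0) / n_c
        rows.append({"year": year, "incremental_cost": inc * population_size})
    return pd.DataFrame(rows)
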