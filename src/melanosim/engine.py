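"""Continuous-time competing-risks discrete-event core.

One individual's lifetime is advanced event by event: candidate times for
every active process (tumour emergence, deaths, skin checks of each channel)
are drawn from piecewise-constant hazards by exact inversion, the earliest
candidate is selected, its state change is applied, and any hazards the
change invalidated are re-drawn from their own random channels.  The
memoryless structure of piecewise-exponential competing risks makes this
re-draw-after-stopping scheme exact.

Draw discipline: channels listed in :data:`~melanosim.rng.NATURAL_HISTORY_CHANNELS`
consume their deviates in a fixed order that cannot be perturbed by the
screening policy (one exponential per tumour index, one uniform per
histology/body-site assignment, one exponential for other-cause death), so
two runs of the same individual under different policies share their
other-cause death age and the emergence age and histology of the first
primary exactly - the common-random-numbers pairing that policy comparison
and the overdiagnosis estimator rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import detection as det
from . import natural_history as nh
from .hazards import NEVER, PiecewiseHazard
from .mortality import total_death_hazard_profile
from .rng import Channel, RandomStream

__all__ = [
    "EventType",
    "Event",
    "LifeHistory",
    "CohortResult",
    "sample_event_time",
    "resolve_competing",
    "simulate_individual",
    "simulate_cohort",
]


class EventType(str, Enum):
    SKIN_CHECK_UPTAKE = "skin_check_uptake"
    CLINICIAN_VISIT = "clinician_visit"
    ROUTINE_CHECK = "routine_check"
    SCREENING_ROUND = "screening_round"
    SURVEILLANCE_VISIT = "surveillance_visit"
    MELANOMA_EMERGENCE = "melanoma_emergence"
    DIAGNOSIS = "diagnosis"
    FALSE_POSITIVE = "false_positive"
    MELANOMA_DEATH = "melanoma_death"
    OTHER_DEATH = "other_death"
    AGE_CAP_EXIT = "age_cap_exit"


ABSORBING = frozenset({EventType.MELANOMA_DEATH, EventType.OTHER_DEATH,
                       EventType.AGE_CAP_EXIT})

#: Exact-tie priority, highest first.  Death outranks everything so a
#: same-instant diagnosis never post-dates death; the age cap sits just
#: below the deaths.  Routine checks, unlisted in the core ordering, rank
#: last.
TIE_PRIORITY = {
    EventType.OTHER_DEATH: 0,
    EventType.MELANOMA_DEATH: 1,
    EventType.AGE_CAP_EXIT: 2,
    EventType.DIAGNOSIS: 3,
    EventType.MELANOMA_EMERGENCE: 4,
    EventType.SURVEILLANCE_VISIT: 5,
    EventType.SCREENING_ROUND: 6,
    EventType.CLINICIAN_VISIT: 7,
    EventType.SKIN_CHECK_UPTAKE: 8,
    EventType.ROUTINE_CHECK: 9,
    EventType.FALSE_POSITIVE: 10,
}


@dataclass
class Event:
    type: EventType
    age: float
    payload: dict = field(default_factory=dict)


@dataclass
class LifeHistory:
    """The complete, ordered event record of one simulated individual."""
    individual_id: int
    sex: str
    birth_year: float
    risk_group: str
    entry_age: float = 15.0
    events: list = field(default_factory=list)
    tumours: list = field(default_factory=list)
    exit_age: float = math.nan
    exit_cause: str = ""

    @property
    def first_diagnosis_age(self):
        for t in self.tumours:
            if t.tumour_index == 1 and t.diagnosed:
                return t.diagnosis_age
        return None

    def diagnosed_tumours(self) -> list:
        return [t for t in self.tumours if t.diagnosed]

    def check(self, params) -> None:
        """Assert the structural invariants of a finished history."""
        ages = [e.age for e in self.events]
        assert all(b >= a - 1e-12 for a, b in zip(ages, ages[1:])), "events out of order"
        assert self.exit_age <= params.simulation.max_age + 1e-12
        absorbing = [e for e in self.events if e.type in ABSORBING]
        assert len(absorbing) == 1, "exactly one absorbing exit required"
        emerged = set()
        for e in self.events:
            if e.type is EventType.MELANOMA_EMERGENCE:
                emerged.add(e.payload["tumour_index"])
            if e.type is EventType.DIAGNOSIS:
                assert e.payload["tumour_index"] in emerged, \
                    "diagnosis without prior emergence"


def sample_event_time(hazard: PiecewiseHazard, start_age: float,
                      rng: np.random.Generator) -> float:
    """Event age sampled by exact inversion of the cumulative hazard from
    ``start_age``; :data:`~melanosim.hazards.NEVER` if the total remaining
    hazard is exhausted first."""
    return hazard.sample(start_age, rng)


def resolve_competing(candidates: list) -> Event:
    """The earliest event; exact ties broken by the documented priority."""
    if not candidates:
        raise ValueError("resolve_competing requires a non-empty candidate list")
    return min(candidates, key=lambda e: (e.age, TIE_PRIORITY[e.type]))


# ---------------------------------------------------------------------------
# per-individual simulation
# ---------------------------------------------------------------------------

class _State:
    """Mutable view of one individual during simulation (duck-typed for
    :func:`melanosim.detection.run_check_event`)."""

    def __init__(self):
        self.tumours: list = []
        self.undiagnosed_tumour = None

    @property
    def n_diagnosed(self) -> int:
        return sum(1 for t in self.tumours if t.diagnosed)


def _uptake_profile(sex, risk_group, birth_year, params) -> PiecewiseHazard:
    """Uptake hazard over age in 1-year calendar bands for one individual."""
    entry, cap = params.simulation.entry_age, params.simulation.max_age
    edges, rates = [], []
    age = entry
    while age < cap:
        edges.append(age)
        rates.append(det.uptake_hazard(age, sex, risk_group, birth_year + age, params))
        age += 1.0
    return PiecewiseHazard(tuple(edges), tuple(rates))


def _visit_profile(age, sex, risk_group, tumour, params) -> PiecewiseHazard:
    """Clinician-visit hazard from ``age`` on; symptom steps at the
    undiagnosed ``tumour``'s implicit stage transitions (None when well)."""
    base = det.visit_hazard(age, sex, risk_group, None, params)
    if tumour is None:
        return PiecewiseHazard((age,), (base,))
    emergence = tumour.emergence_age
    dwell_now = max(age - emergence, 0.0)
    edges = [age]
    rates = [det.visit_hazard(age, sex, risk_group, dwell_now, params,
                              histology=tumour.histology)]
    thresholds = params.histologies[tumour.histology].stage_schedule.thresholds
    for th in thresholds:
        breakpoint_age = emergence + th
        if breakpoint_age > age:
            edges.append(breakpoint_age)
            rates.append(det.visit_hazard(age, sex, risk_group, th, params,
                                          histology=tumour.histology))
    return PiecewiseHazard(tuple(edges), tuple(rates))


def simulate_individual(params, sex: str, birth_year: float, risk_label: str,
                        policy: det.ScreeningPolicy | None,
                        stream: RandomStream, individual_id: int = 0) -> LifeHistory:
    """Simulate one complete life history from entry (age 15) to the
    absorbing exit (death or the age cap at 85)."""
    sim = params.simulation
    entry, cap = sim.entry_age, sim.max_age
    rg = params.risk_group(risk_label)
    history = LifeHistory(individual_id=individual_id, sex=sex,
                          birth_year=birth_year, risk_group=risk_label,
                          entry_age=entry)
    state = _State()
    history.tumours = state.tumours

    # --- natural-history draws (policy-invariant order) -------------------
    g_death = stream.channel(Channel.OTHER_DEATH)
    other_death_age = params.life_table.hazard(sex).sample(entry, g_death)

    g_emerge = stream.channel(Channel.EMERGENCE)
    g_hist = stream.channel(Channel.HISTOLOGY)
    g_site = stream.channel(Channel.BODY_SITE)

    def draw_emergence(from_age: float, n_previous: int, first_histology) -> float:
        e = g_emerge.standard_exponential()
        if n_previous == 0:
            profile = nh.first_primary_hazard_profile(sex, birth_year, rg, params)
        else:
            profile = nh.subsequent_primary_hazard_profile(
                sex, birth_year, rg, first_histology, n_previous, params)
        return profile.invert(from_age, e)

    emergence_age = draw_emergence(entry, 0, None)
    emergence_pending = True

    # --- policy-side draws -------------------------------------------------
    g_uptake = stream.channel(Channel.UPTAKE)
    g_visit = stream.channel(Channel.VISIT)
    g_routine = stream.channel(Channel.ROUTINE_CHECK)
    g_screen = stream.channel(Channel.SCREEN)
    g_surv = stream.channel(Channel.SURVEILLANCE)

    uptake_age = _uptake_profile(sex, rg, birth_year, params).sample(entry, g_uptake)
    uptaken = False
    routine_idx = 0

    next_visit = _visit_profile(entry, sex, rg, None, params).sample(entry, g_visit)

    if policy is not None:
        k0 = math.ceil(max(0.0, (birth_year + entry) - policy.start_year) / policy.interval)
        round_ages = []
        k = k0
        while True:
            age_k = policy.start_year + k * policy.interval - birth_year
            if age_k > cap:
                break
            if age_k >= entry:
                round_ages.append(age_k)
            k += 1
    else:
        round_ages = []
    round_idx = 0

    surveillance_ages: list = []
    surv_idx = 0
    first_dx_stage = None
    first_dx_age = None
    first_histology = None

    melanoma_death_age = NEVER

    # ----------------------------------------------------------------------
    age = entry

    def record(etype: EventType, at: float, **payload) -> None:
        history.events.append(Event(etype, at, payload))

    def handle_diagnosis(outcome, at: float, channel: str) -> None:
        nonlocal emergence_age, emergence_pending, melanoma_death_age
        nonlocal surveillance_ages, first_dx_stage, first_dx_age, first_histology
        tumour = state.undiagnosed_tumour
        state.undiagnosed_tumour = None
        record(EventType.DIAGNOSIS, at, tumour_index=tumour.tumour_index,
               channel=channel, stage=tumour.stage_at_diagnosis,
               breslow=tumour.breslow_category, behaviour=tumour.behaviour_code,
               dwell=tumour.dwell_at_diagnosis)
        n_prev = state.n_diagnosed
        if n_prev == 1:
            first_dx_stage = tumour.stage_at_diagnosis
            first_dx_age = at
            first_histology = tumour.histology
            offsets = det.surveillance_schedule(first_dx_stage, rg, params,
                                                diagnosis_age=at)
            surveillance_ages = [at + o for o in offsets]
        emergence_age = draw_emergence(at, n_prev, first_histology)
        emergence_pending = True
        if tumour.behaviour_code == 3:
            profile = total_death_hazard_profile(state.tumours, params)
            melanoma_death_age = profile.sample(at, stream.channel(Channel.MELANOMA_DEATH))

    while True:
        candidates = [Event(EventType.AGE_CAP_EXIT, cap),
                      Event(EventType.OTHER_DEATH, other_death_age)]
        if melanoma_death_age < NEVER:
            candidates.append(Event(EventType.MELANOMA_DEATH, melanoma_death_age))
        if emergence_pending and emergence_age < NEVER:
            candidates.append(Event(EventType.MELANOMA_EMERGENCE, emergence_age))
        if next_visit < NEVER:
            candidates.append(Event(EventType.CLINICIAN_VISIT, next_visit))
        if state.n_diagnosed == 0:
            if not uptaken and uptake_age < NEVER:
                candidates.append(Event(EventType.SKIN_CHECK_UPTAKE, uptake_age))
            if uptaken:
                candidates.append(Event(EventType.ROUTINE_CHECK,
                                        uptake_age + routine_idx * 1.0))
            if round_idx < len(round_ages):
                candidates.append(Event(EventType.SCREENING_ROUND, round_ages[round_idx]))
        elif surv_idx < len(surveillance_ages):
            candidates.append(Event(EventType.SURVEILLANCE_VISIT,
                                    surveillance_ages[surv_idx]))

        ev = resolve_competing(candidates)
        age = ev.age
        year = birth_year + age

        if ev.type in ABSORBING:
            history.exit_age = min(age, cap)
            history.exit_cause = ev.type.value
            record(ev.type, history.exit_age)
            break

        if ev.type is EventType.MELANOMA_EMERGENCE:
            idx = len(state.tumours) + 1
            if idx == 1:
                histology = nh.assign_histology(age, g_hist, params)
            else:
                histology = nh.assign_subsequent_histology(first_histology, g_hist, params)
            site = nh.assign_body_site(g_site, params)
            tumour = nh.Tumour(tumour_index=idx, histology=histology,
                               emergence_age=age, body_site=site)
            state.tumours.append(tumour)
            state.undiagnosed_tumour = tumour
            emergence_pending = False
            record(EventType.MELANOMA_EMERGENCE, age, tumour_index=idx,
                   histology=histology, body_site=site)
            # symptom-prompted presentation alters the visit hazard
            next_visit = _visit_profile(age, sex, rg, tumour, params).sample(age, g_visit)
            continue

        if ev.type is EventType.CLINICIAN_VISIT:
            record(EventType.CLINICIAN_VISIT, age)
            ctx = det.DetectionContext("opportunistic_visit", year, age, sex,
                                       risk_label,
                                       after_first_diagnosis=state.n_diagnosed > 0)
            outcome = det.run_check_event(state, ctx, g_visit, params)
            if outcome.kind == "diagnosis":
                handle_diagnosis(outcome, age, "opportunistic_visit")
            elif outcome.kind == "false_positive":
                record(EventType.FALSE_POSITIVE, age, channel="opportunistic_visit")
            next_visit = _visit_profile(age, sex, rg, state.undiagnosed_tumour,
                                        params).sample(age, g_visit)
            continue

        if ev.type is EventType.SKIN_CHECK_UPTAKE:
            uptaken = True
            routine_idx = 0
            record(EventType.SKIN_CHECK_UPTAKE, age)
            continue

        if ev.type is EventType.ROUTINE_CHECK:
            t_since = age - uptake_age
            routine_idx += 1
            if g_routine.random() < det.attendance_probability(t_since, params):
                record(EventType.ROUTINE_CHECK, age)
                ctx = det.DetectionContext("routine_check", year, age, sex, risk_label)
                outcome = det.run_check_event(state, ctx, g_routine, params)
                if outcome.kind == "diagnosis":
                    handle_diagnosis(outcome, age, "routine_check")
                elif outcome.kind == "false_positive":
                    record(EventType.FALSE_POSITIVE, age, channel="routine_check")
            continue

        if ev.type is EventType.SCREENING_ROUND:
            round_idx += 1
            if not policy.eligible(age, risk_label):
                continue
            attended = g_screen.random() < policy.participation
            record(EventType.SCREENING_ROUND, age, attended=attended)
            if attended:
                ctx = det.DetectionContext("organised_screen", year, age, sex,
                                           risk_label, policy=policy)
                outcome = det.run_check_event(state, ctx, g_screen, params)
                if outcome.kind == "diagnosis":
                    handle_diagnosis(outcome, age, "organised_screen")
                elif outcome.kind == "false_positive":
                    record(EventType.FALSE_POSITIVE, age, channel="organised_screen")
            continue

        if ev.type is EventType.SURVEILLANCE_VISIT:
            surv_idx += 1
            t_since_dx = age - first_dx_age
            p_attend = det.surveillance_attendance(t_since_dx, first_histology,
                                                   first_dx_stage, params)
            if g_surv.random() < p_attend:
                record(EventType.SURVEILLANCE_VISIT, age)
                ctx = det.DetectionContext("surveillance", year, age, sex, risk_label,
                                           after_first_diagnosis=True)
                outcome = det.run_check_event(state, ctx, g_surv, params)
                if outcome.kind == "diagnosis":
                    handle_diagnosis(outcome, age, "surveillance")
                elif outcome.kind == "false_positive":
                    record(EventType.FALSE_POSITIVE, age, channel="surveillance")
            continue

        raise AssertionError(f"unhandled event type {ev.type}")  # pragma: no cover

    return history


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """A simulated cohort plus the inputs needed to reproduce it."""
    histories: list
    seed: int
    n: int
    policy: det.ScreeningPolicy | None = None

    def events_frame(self):
        import pandas as pd
        rows = []
        for h in self.histories:
            for e in h.events:
                row = {"individual_id": h.individual_id, "event": e.type.value,
                       "age": e.age, "calendar_year": math.floor(h.birth_year + e.age)}
                row.update(e.payload)
                rows.append(row)
        return pd.DataFrame(rows)

    def tumours_frame(self):
        import pandas as pd
        rows = []
        for h in self.histories:
            for t in h.tumours:
                rows.append({
                    "individual_id": h.individual_id,
                    "tumour_index": t.tumour_index,
                    "histology": t.histology,
                    "morphology": nh.MORPHOLOGY_BANDS[t.histology],
                    "topography": t.body_site,
                    "emergence_age": t.emergence_age,
                    "diagnosed": t.diagnosed,
                    "diagnosis_age": t.diagnosis_age,
                    "dwell_at_diagnosis": t.dwell_at_diagnosis,
                    "stage_at_diagnosis": t.stage_at_diagnosis,
                    "breslow_category": t.breslow_category,
                    "behaviour_code": t.behaviour_code,
                    "detection_channel": t.detection_channel,
                })
        return pd.DataFrame(rows)


def draw_attributes(params, stream: RandomStream):
    """Sex, birth year and risk group for one individual (natural-history
    channel, so attribute draws are policy-invariant)."""
    g = stream.channel(Channel.ATTRIBUTES)
    pop = params.population
    sex = "female" if g.random() < pop.female_fraction else "male"
    birth_year = pop.birth_year_min + g.random() * (pop.birth_year_max - pop.birth_year_min)
    u = g.random()
    cum = 0.0
    label = params.risk_groups[-1].label
    for grp in params.risk_groups:
        cum += grp.fraction
        if u < cum:
            label = grp.label
            break
    return sex, birth_year, label


def simulate_cohort(params, n: int, seed: int,
                    policy: det.ScreeningPolicy | None = None) -> CohortResult:
    """Simulate ``n`` independent individuals under per-individual
    substreams, so the result is invariant to execution order and
    reproducible from ``seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    root = RandomStream(seed)
    histories = []
    for i in range(n):
        stream = root.for_individual(i)
        sex, birth_year, label = draw_attributes(params, stream)
        histories.append(simulate_individual(params, sex, birth_year, label,
                                             policy, stream, individual_id=i))
    return CohortResult(histories=histories, seed=seed, n=n, policy=policy)
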