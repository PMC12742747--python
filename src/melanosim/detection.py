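"""Routes from undiagnosed tumour to diagnosis.

Four detection channels exist.  Before the first diagnosis: opportunistic
clinician visits, routine skin checks (after an uptake event), and organised
screening rounds.  After the first diagnosis: surveillance visits only -
screening, in the population sense, refers to detection of a *first* cancer,
so routine checks and organised rounds are gated off once a melanoma has
been diagnosed.

Diagnosis factorises into attendance (getting in front of a clinician) and
detection (the clinician finding the tumour).  The per-check detection
probability is the product of a histology-specific dwell curve, a body-site
visibility factor, a diagnostic-technology period factor, and - for
organised rounds - the programme's test sensitivity; the product is capped
at 1.  A check on a melanoma-free attendee yields a false positive with
probability one minus the applicable specificity: cost-bearing, but with no
change to the individual's state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import natural_history as nh

__all__ = [
    "ScreeningPolicy",
    "DetectionContext",
    "CheckOutcome",
    "uptake_hazard",
    "attendance_probability",
    "visit_hazard",
    "detection_probability",
    "run_check_event",
    "surveillance_schedule",
    "surveillance_attendance",
]

CHANNELS = ("opportunistic_visit", "routine_check", "organised_screen", "surveillance")
PRE_DIAGNOSIS_CHANNELS = ("opportunistic_visit", "routine_check", "organised_screen")


@dataclass
class ScreeningPolicy:
    """An organised screening programme."""
    name: str = "organised"
    age_start: float = 50.0
    age_end: float = 69.0
    risk_groups: list | None = None     # None = all groups eligible
    start_year: float = 2025.0
    interval: float = 2.0
    test_sensitivity: float = 0.9
    test_specificity: float = 0.9
    participation: float = 0.6

    def __post_init__(self):
        for name in ("test_sensitivity", "test_specificity", "participation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.age_start >= self.age_end:
            raise ValueError("age_start must be < age_end")

    def eligible(self, age: float, risk_label: str) -> bool:
        if not self.age_start <= age <= self.age_end:
            return False
        return self.risk_groups is None or risk_label in self.risk_groups

    def to_dict(self) -> dict:
        return {
            "name": self.name, "age_start": self.age_start, "age_end": self.age_end,
            "risk_groups": self.risk_groups, "start_year": self.start_year,
            "interval": self.interval, "test_sensitivity": self.test_sensitivity,
            "test_specificity": self.test_specificity, "participation": self.participation,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScreeningPolicy":
        return cls(**data)


@dataclass
class DetectionContext:
    """Where and when a check happens."""
    channel: str
    calendar_year: float
    age: float
    sex: str
    risk_label: str
    after_first_diagnosis: bool = False
    policy: ScreeningPolicy | None = None

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.channel == "surveillance" and not self.after_first_diagnosis:
            raise ValueError("surveillance checks require a prior first diagnosis")
        if self.channel in ("organised_screen", "routine_check") and self.after_first_diagnosis:
            raise ValueError(f"{self.channel} checks cannot occur after the first diagnosis")


@dataclass
class CheckOutcome:
    """Result of one attended check: a diagnosis, a false positive, or nothing."""
    kind: str                       # "diagnosis" | "false_positive" | "none"
    tumour_index: int | None = None


def uptake_hazard(age: float, sex: str, risk_group, calendar_year: float,
                  params, *, diagnosed: bool = False) -> float:
    """Rate of starting routine skin checks; only defined before the first
    melanoma diagnosis."""
    if diagnosed:
        raise ValueError("skin-check uptake is only modelled before the first diagnosis")
    up = params.uptake
    if calendar_year <= up.year_start:
        year_factor = up.factor_start
    elif calendar_year >= up.year_end:
        year_factor = up.factor_end
    else:
        frac = (calendar_year - up.year_start) / (up.year_end - up.year_start)
        year_factor = up.factor_start + frac * (up.factor_end - up.factor_start)
    sex_factor = up.male_factor if sex == "male" else up.female_factor
    return up.base_rate * year_factor * sex_factor * risk_group.uptake_multiplier


def attendance_probability(time_since_uptake: float, params) -> float:
    """Probability of attending a scheduled routine check, declining with
    time since uptake when no melanoma has been diagnosed."""
    if time_since_uptake < 0:
        raise ValueError("time_since_uptake must be >= 0")
    att = params.attendance_decay
    return att.initial * math.exp(-att.rate * time_since_uptake)


def visit_hazard(age: float, sex: str, risk_group, time_since_emergence,
                 params, histology: str | None = None) -> float:
    """Opportunistic clinician-visit rate: a sex-specific background rate
    plus a symptom-prompted component while an undiagnosed tumour is present
    (``time_since_emergence`` is None for a well individual).

    With ``histology`` given, the symptom component follows the tumour's
    current implicit stage, so fast-progressing histologies present early in
    their dwell and slow ones late; otherwise a histology-agnostic dwell
    ramp applies.  Either way the rate is non-decreasing in dwell.
    """
    base = params.visit_rates.male if sex == "male" else params.visit_rates.female
    if time_since_emergence is None:
        return base
    if histology is not None:
        stage, _, _ = nh.stage_at_diagnosis(histology, time_since_emergence, params)
        return base + params.visit_rates.stage_symptom_rates.get(stage, 0.0)
    extra = 0.0
    for edge, rate in zip(params.visit_rates.symptom_edges, params.visit_rates.symptom_rates):
        if time_since_emergence >= edge:
            extra = rate
    return base + extra


def detection_probability(histology: str, dwell: float, calendar_year: float,
                          body_site: str, context: DetectionContext, params) -> float:
    """Per-check probability that an attending clinician diagnoses the
    tumour, capped at 1."""
    if dwell < 0:
        raise ValueError("dwell must be >= 0")
    curve = params.histologies[histology].detection
    p = min(curve.base + curve.per_year * dwell, curve.max_prob)
    bs = params.body_sites
    try:
        visible = bs.visible[bs.codes.index(body_site)]
    except ValueError:
        visible = False
    if not visible:
        p *= bs.less_visible_factor
    p *= params.period_scaling.at_year(calendar_year)
    if context.channel == "organised_screen":
        if context.policy is None:
            raise ValueError("organised_screen context requires a policy")
        p *= context.policy.test_sensitivity
    return min(max(p, 0.0), 1.0)


def run_check_event(state, context: DetectionContext,
                    rng: np.random.Generator, params) -> CheckOutcome:
    """Resolve one attended check.

    ``state`` is any object exposing ``undiagnosed_tumour`` (a Tumour or
    None) and ``n_diagnosed``.  If an undiagnosed tumour is present it is
    diagnosed with the context's detection probability (fixing its dwell,
    stage, Breslow category and behaviour code); otherwise a false positive
    occurs with probability 1 - specificity.
    """
    if context.channel == "surveillance" and state.n_diagnosed == 0:
        raise ValueError("surveillance check before any diagnosis")
    tumour = state.undiagnosed_tumour
    if tumour is not None:
        dwell = context.age - tumour.emergence_age
        p = detection_probability(tumour.histology, dwell, context.calendar_year,
                                  tumour.body_site, context, params)
        if rng.random() < p:
            tumour.diagnose(context.age, params, context.channel)
            return CheckOutcome("diagnosis", tumour_index=tumour.tumour_index)
        return CheckOutcome("none")
    if context.channel == "organised_screen":
        specificity = context.policy.test_specificity
    else:
        specificity = params.clinical_specificity
    if rng.random() < 1.0 - specificity:
        return CheckOutcome("false_positive")
    return CheckOutcome("none")


def surveillance_schedule(stage_at_first_diagnosis: str, risk_group, params,
                          *, diagnosis_age: float | None = None) -> list:
    """Visit offsets (years) from the first diagnosis: 6-monthly for higher
    stage or high-risk individuals, annual otherwise, continuing to the age
    cap (or indefinitely if ``diagnosis_age`` is not given, in which case a
    lifetime-maximum number of offsets is returned)."""
    sv = params.surveillance
    intense = (stage_at_first_diagnosis in sv.intense_stages
               or (sv.intense_for_high_risk and risk_group.relative_risk > 1.0))
    interval = sv.intense_interval if intense else sv.routine_interval
    if diagnosis_age is None:
        horizon = params.simulation.max_age - params.simulation.entry_age
    else:
        horizon = params.simulation.max_age - diagnosis_age
    n = int(math.floor(horizon / interval + 1e-9))
    return [interval * (k + 1) for k in range(n)]


def surveillance_attendance(time_since_diagnosis: float, histology: str,
                            stage_at_first_diagnosis: str, params) -> float:
    """Per-visit surveillance attendance probability, decaying with time
    since diagnosis and modified by histology and stage factors."""
    if time_since_diagnosis < 0:
        raise ValueError("time_since_diagnosis must be >= 0")
    sv = params.surveillance
    p = sv.attendance_initial * math.exp(-sv.attendance_decay_rate * time_since_diagnosis)
    p *= sv.histology_attendance_factors.get(histology, 1.0)
    p *= sv.stage_attendance_factors.get(stage_at_first_diagnosis, 1.0)
    return min(max(p, 0.0), 1.0)
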