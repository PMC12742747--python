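"""Natural history: emergence hazards for first and subsequent primary
melanomas, histology and body-site assignment, and implicit progression to
stage and Breslow thickness at diagnosis.

Progression is *implicit*: an undiagnosed tumour has no per-stage states.
The stage recorded at diagnosis is a pure function of the tumour's histology
and its dwell time (years spent detectable but undiagnosed), via the
histology's stage schedule.  A nodular melanoma reaches stage IV within six
months of dwell under the default fixture, a lentigo maligna only after 20
years; screening consequently over-samples the slow histologies
(length-time bias), which the detection module makes observable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hazards import PiecewiseHazard
from .mortality import STAGES, BRESLOW_CATEGORIES

__all__ = [
    "Tumour",
    "first_primary_hazard",
    "first_primary_hazard_profile",
    "cohort_effect",
    "assign_histology",
    "assign_body_site",
    "stage_at_diagnosis",
    "post_diagnosis_risk_multiplier",
    "subsequent_primary_hazard",
    "subsequent_primary_hazard_profile",
    "assign_subsequent_histology",
]

#: ICD-O-3 morphology band labels by histology code (M872-M879 range).
MORPHOLOGY_BANDS = {
    "superficial_spreading": "M8743",
    "lentigo_maligna": "M8742",
    "nodular": "M8721",
    "other": "M872-M879",
}


@dataclass
class Tumour:
    """One primary melanoma, from emergence (the instant it becomes
    detectable) to diagnosis."""

    tumour_index: int              # 1 = first primary
    histology: str
    emergence_age: float
    body_site: str                 # ICD-O-3 topography C44.0-C44.9
    diagnosed: bool = False
    diagnosis_age: float | None = None
    dwell_at_diagnosis: float | None = None
    stage_at_diagnosis: str | None = None
    breslow_category: str | None = None
    behaviour_code: int | None = None  # 2 in situ, 3 invasive
    detection_channel: str | None = None

    def diagnose(self, age: float, params, channel: str) -> None:
        if age < self.emergence_age:
            raise ValueError("diagnosis before emergence")
        dwell = age - self.emergence_age
        stage, breslow, behaviour = stage_at_diagnosis(self.histology, dwell, params)
        self.diagnosed = True
        self.diagnosis_age = age
        self.dwell_at_diagnosis = dwell
        self.stage_at_diagnosis = stage
        self.breslow_category = breslow
        self.behaviour_code = behaviour
        self.detection_channel = channel


def cohort_effect(birth_year: float, params) -> float:
    """Birth-cohort multiplier on melanoma emergence: 1 (the reference
    plateau) for cohorts born up to the configured plateau end, declining
    linearly until the sun-protection-campaign level is reached, constant
    thereafter."""
    ce = params.cohort_effect
    if birth_year <= ce.plateau_end:
        return 1.0
    if birth_year >= ce.decline_end:
        return ce.final_level
    frac = (birth_year - ce.plateau_end) / (ce.decline_end - ce.plateau_end)
    return 1.0 + frac * (ce.final_level - 1.0)


def first_primary_hazard(age: float, sex: str, birth_year: float, risk_group,
                         params) -> float:
    """First-primary emergence rate: baseline(age, sex) x cohort multiplier
    x the risk group's relative risk."""
    if age < params.simulation.entry_age:
        raise ValueError(f"age {age} below entry age {params.simulation.entry_age}")
    bi = params.baseline_incidence
    idx = int(np.searchsorted(bi.age_edges, age, side="right")) - 1
    idx = min(max(idx, 0), len(bi.age_edges) - 1)
    base = bi.rates_for(sex)[idx] * bi.scale
    return base * cohort_effect(birth_year, params) * risk_group.relative_risk


def first_primary_hazard_profile(sex: str, birth_year: float, risk_group,
                                 params) -> PiecewiseHazard:
    """The same hazard as a piecewise-constant function of age."""
    bi = params.baseline_incidence
    factor = bi.scale * cohort_effect(birth_year, params) * risk_group.relative_risk
    return PiecewiseHazard(tuple(bi.age_edges),
                           tuple(r * factor for r in bi.rates_for(sex)))


def assign_histology(age: float, rng: np.random.Generator, params) -> str:
    """Draw a histology code from the age-indexed mix.  The mix is shared by
    both sexes and has no calendar-time dependence, so the operation takes
    neither a sex nor a year argument."""
    mix = params.histology_mix.at_age(age)
    codes = list(mix)
    probs = np.array([mix[c] for c in codes])
    return codes[int(rng.choice(len(codes), p=probs / probs.sum()))]


def assign_body_site(rng: np.random.Generator, params) -> str:
    """Draw an ICD-O-3 topography code (C44.0-C44.9) once, at emergence."""
    bs = params.body_sites
    probs = np.array(bs.probabilities)
    return bs.codes[int(rng.choice(len(bs.codes), p=probs / probs.sum()))]


def stage_at_diagnosis(histology: str, dwell: float, params):
    """(stage, breslow_category, behaviour_code) for a tumour of the given
    histology diagnosed after ``dwell`` years undetected.

    Stage advances through the histology's dwell thresholds; dwell 0 is in
    situ (behaviour code 2).  The Breslow category is assigned from the
    within-stage cutpoints for stages I-II and is None otherwise.
    """
    if dwell < 0:
        raise ValueError("dwell must be >= 0")
    schedule = params.histologies[histology].stage_schedule
    stage_idx = 0
    for th in schedule.thresholds:
        if dwell >= th:
            stage_idx += 1
    stage = STAGES[stage_idx]
    behaviour = 2 if stage == "in_situ" else 3
    breslow = None
    if stage in ("I", "II"):
        c1, c2 = schedule.breslow_cutpoints
        if dwell < c1:
            breslow = BRESLOW_CATEGORIES[0]
        elif dwell < c2:
            breslow = BRESLOW_CATEGORIES[1]
        else:
            breslow = BRESLOW_CATEGORIES[2]
    return stage, breslow, behaviour


def post_diagnosis_risk_multiplier(n_previous: int, params) -> float:
    """Hazard multiplier after ``n_previous`` diagnosed primaries;
    non-decreasing and > 1 for every count >= 1."""
    if n_previous < 1:
        raise ValueError("n_previous must be >= 1 (use the baseline hazard otherwise)")
    mults = params.subsequent_primaries.risk_multipliers
    return mults[min(n_previous - 1, len(mults) - 1)]


def subsequent_primary_hazard(age: float, sex: str, birth_year: float, risk_group,
                              first_histology: str, n_previous: int, params) -> float:
    """Emergence rate of the next primary for an individual with
    ``n_previous`` diagnosed primaries whose first primary had
    ``first_histology``.  Progression of the new tumour uses the same stage
    schedules as a first tumour of its histology."""
    sp = params.subsequent_primaries
    factor = sp.histology_factors.get(first_histology, 1.0)
    return (first_primary_hazard(age, sex, birth_year, risk_group, params)
            * post_diagnosis_risk_multiplier(n_previous, params)
            * factor * sp.scale)


def subsequent_primary_hazard_profile(sex: str, birth_year: float, risk_group,
                                      first_histology: str, n_previous: int,
                                      params) -> PiecewiseHazard:
    sp = params.subsequent_primaries
    factor = (post_diagnosis_risk_multiplier(n_previous, params)
              * sp.histology_factors.get(first_histology, 1.0) * sp.scale)
    return first_primary_hazard_profile(sex, birth_year, risk_group, params).scaled(factor)


def assign_subsequent_histology(first_histology: str, rng: np.random.Generator,
                                params) -> str:
    """The next primary keeps the first primary's histology with probability
    equal to the configured concordance (> 0.5); otherwise a code is drawn
    from the marginal mix restricted to the other histologies."""
    sp = params.subsequent_primaries
    if rng.random() < sp.concordance:
        return first_histology
    # split the remaining mass proportional to the marginal mix at age 60
    mix = params.histology_mix.at_age(60.0)
    others = [c for c in mix if c != first_histology]
    probs = np.array([mix[c] for c in others], dtype=float)
    if probs.sum() <= 0:
        return first_histology
    return others[int(rng.choice(len(others), p=probs / probs.sum()))]
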