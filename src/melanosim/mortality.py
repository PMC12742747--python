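"""Other-cause mortality from life tables and melanoma-specific death hazards.

Melanoma-specific death requires a prior diagnosis: an undiagnosed tumour
keeps progressing, so a late diagnosis lands in a high stage with a high
death hazard, which is how mortality from long-undiagnosed disease enters the
model.  Post-diagnosis hazards are piecewise constant in time since diagnosis
(bands 0-1, 1-5, 5+ years by default), mimicking the shape of relative
survival curves without a parametric commitment.  In situ tumours (behaviour
code 2) carry no melanoma-specific death hazard.

The death hazard of an individual with several diagnosed invasive primaries
is the *sum* of the per-tumour hazards: each tumour contributes according to
its own stage and thickness, and there is no extra term in the number of
tumours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .hazards import PiecewiseHazard

__all__ = [
    "LifeTable",
    "other_cause_hazard",
    "melanoma_death_hazard",
    "total_melanoma_death_hazard",
]

STAGES = ("in_situ", "I", "II", "III", "IV")
BRESLOW_CATEGORIES = ("le_1mm", "1_4mm", "gt_4mm")


@dataclass
class LifeTable:
    """Annual other-cause mortality rates by age band and sex.

    ``age_edges`` has one more entry than each rate list; band ``i`` covers
    ``[age_edges[i], age_edges[i+1])`` and the bands are contiguous from the
    simulation entry age to the age cap.
    """

    age_edges: list = field(default_factory=list)
    male: list = field(default_factory=list)
    female: list = field(default_factory=list)

    def rates_for(self, sex: str) -> Sequence[float]:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"unknown sex {sex!r}")

    def hazard(self, sex: str) -> PiecewiseHazard:
        """Piecewise-constant hazard over age for one sex (extends the last
        band's rate beyond the final edge so the age cap can be reached)."""
        return PiecewiseHazard(tuple(self.age_edges[:-1]), tuple(self.rates_for(sex)))

    def validate(self) -> list:
        issues = []
        n = len(self.age_edges)
        if n < 2:
            issues.append("life_table.age_edges: need at least one band")
            return issues
        if any(b <= a for a, b in zip(self.age_edges, self.age_edges[1:])):
            issues.append("life_table.age_edges: not strictly increasing")
        for sex in ("male", "female"):
            rates = self.rates_for(sex)
            if len(rates) != n - 1:
                issues.append(f"life_table.{sex}: expected {n - 1} rates, got {len(rates)}")
            elif any(r < 0 for r in rates):
                issues.append(f"life_table.{sex}: negative rate")
        return issues

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in ("female", "male"):
            for lo, hi, rate in zip(self.age_edges, self.age_edges[1:], self.rates_for(sex)):
                rows.append({"age_low": lo, "age_high": hi, "sex": sex, "rate": rate})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        table = cls()
        female = df[df.sex == "female"].sort_values("age_low")
        male = df[df.sex == "male"].sort_values("age_low")
        table.age_edges = list(female.age_low) + [float(female.age_high.iloc[-1])]
        table.female = list(female.rate)
        table.male = list(male.rate)
        return table


def other_cause_hazard(age: float, sex: str, life_table: LifeTable) -> float:
    """Annual other-cause mortality rate for the (age band, sex) cell."""
    if age < life_table.age_edges[0] or age > life_table.age_edges[-1]:
        raise ValueError(f"age {age} outside life table range "
                         f"[{life_table.age_edges[0]}, {life_table.age_edges[-1]}]")
    if age == life_table.age_edges[-1]:
        return life_table.rates_for(sex)[-1]
    return life_table.hazard(sex).rate_at(age)


def melanoma_death_hazard(tumour, time_since_diagnosis: float, age: float, params) -> float:
    """Melanoma-specific death hazard (per person-year) of one diagnosed tumour.

    Zero for in situ tumours.  For invasive tumours the hazard is the
    stage-specific rate for the time-since-diagnosis band, multiplied within
    stages I-II by the Breslow-category factor.
    """
    if not tumour.diagnosed:
        raise ValueError("melanoma_death_hazard requires a diagnosed tumour")
    if tumour.behaviour_code == 2:
        return 0.0
    if time_since_diagnosis < 0:
        raise ValueError("time_since_diagnosis must be >= 0")
    surv = params.survival
    band = _band_index(surv.time_band_edges, time_since_diagnosis)
    rate = surv.stage_hazards[tumour.stage_at_diagnosis][band]
    if tumour.stage_at_diagnosis in ("I", "II") and tumour.breslow_category is not None:
        rate *= surv.breslow_multipliers[BRESLOW_CATEGORIES.index(tumour.breslow_category)]
    return rate


def tumour_death_hazard_profile(tumour, params) -> PiecewiseHazard:
    """The hazard of `melanoma_death_hazard` as a piecewise function of age."""
    surv = params.survival
    dx = tumour.diagnosis_age
    edges = [dx] + [dx + e for e in surv.time_band_edges]
    rates = []
    for band in range(len(edges)):
        t = 0.0 if band == 0 else surv.time_band_edges[band - 1]
        rates.append(melanoma_death_hazard(tumour, t, dx + t, params))
    return PiecewiseHazard(tuple(edges), tuple(rates))


def total_melanoma_death_hazard(tumours, age: float, params) -> float:
    """Sum of per-tumour death hazards over all diagnosed invasive tumours."""
    total = 0.0
    for t in tumours:
        if t.diagnosed and t.behaviour_code == 3:
            total += melanoma_death_hazard(t, age - t.diagnosis_age, age, params)
    return total


def total_death_hazard_profile(tumours, params) -> PiecewiseHazard | None:
    """Combined piecewise age-profile of melanoma death hazard; None if no
    diagnosed invasive tumour exists."""
    profile = None
    for t in tumours:
        if t.diagnosed and t.behaviour_code == 3:
            h = tumour_death_hazard_profile(t, params)
            profile = h if profile is None else profile.plus(h)
    return profile


def _band_index(edges: Sequence[float], t: float) -> int:
    for i, e in enumerate(edges):
        if t < e:
            return i
    return len(edges)
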