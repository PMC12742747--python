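"""Synthetic fixture bundles that make the whole platform testable without
any restricted registry, insurance-claims or survey data.

Each scenario yields a self-consistent bundle: its calibration targets are
*computed by simulating the bundled parameter set*, so calibration exercises
have a known generating truth, and recomputing the targets from a fresh
simulation at the same seed reproduces them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import params as P
from .calibration import (CalibrationTarget, StrataDefinition, compute_summaries)
from .detection import ScreeningPolicy
from .engine import simulate_cohort
from .mortality import LifeTable

__all__ = ["FixtureBundle", "generate_fixture_bundle", "SCENARIOS",
           "default_policy", "RegistryRateTable"]

SCENARIOS = ("australia_like", "calibration_demo", "stress_multiprimary")


@dataclass
class RegistryRateTable:
    """Registry-style rate table: one row per (statistic, stratum) with the
    rate (per 100,000 person-years for incidence/mortality; a proportion for
    the rest) and an ABC weight."""
    frame: pd.DataFrame

    def __post_init__(self):
        key = ["statistic", "age_low", "age_high", "sex", "stage"]
        if self.frame.duplicated(subset=key).any():
            raise ValueError("duplicate stratum keys in rate table")
        rates = self.frame.loc[self.frame.statistic.isin(["incidence", "mortality"]),
                               "value"]
        if (rates < 0).any():
            raise ValueError("negative rate in rate table")

    def to_targets(self) -> list:
        targets = []
        for _, row in self.frame.iterrows():
            stratum = {k: row[k] for k in ("age_low", "age_high", "sex", "stage")
                       if pd.notna(row[k])}
            targets.append(CalibrationTarget(statistic=row["statistic"],
                                             stratum=stratum,
                                             value=float(row["value"]),
                                             weight=float(row.get("weight", 1.0))))
        return targets

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegistryRateTable":
        return cls(pd.read_csv(path))


@dataclass
class FixtureBundle:
    scenario: str
    seed: int
    params: P.ParameterSet
    life_table: LifeTable
    rate_table: RegistryRateTable
    targets: list
    tariff: P.Tariff
    utilities: P.UtilityWeights
    strata: StrataDefinition
    target_seed: int = 0
    target_n: int = 0


def default_policy(name: str = "organised_biennial") -> ScreeningPolicy:
    """Built-in screening programmes used by the CLI and the examples."""
    if name == "organised_biennial":
        return ScreeningPolicy(name=name, age_start=50.0, age_end=69.0,
                               risk_groups=None, start_year=2005.0, interval=2.0,
                               test_sensitivity=0.9, test_specificity=0.9,
                               participation=0.6)
    if name == "risk_tailored":
        return ScreeningPolicy(name=name, age_start=40.0, age_end=69.0,
                               risk_groups=["high"], start_year=2005.0, interval=1.0,
                               test_sensitivity=0.9, test_specificity=0.9,
                               participation=0.7)
    raise KeyError(f"unknown policy {name!r}; available: "
                   "organised_biennial, risk_tailored")


def _calibration_demo_params() -> P.ParameterSet:
    """A deliberately small, fast parameterisation for calibration tests:
    one risk group, flat incidence, near-certain detection at clinician
    visits, a 40-year horizon."""
    params = P.default_parameters()
    params.simulation.max_age = 55.0
    params.population.birth_year_min = 1960.0
    params.population.birth_year_max = 1960.0
    params.baseline_incidence.age_edges = [15.0]
    params.baseline_incidence.male = [0.002]
    params.baseline_incidence.female = [0.002]
    params.risk_groups = [P.RiskGroup("average", 1.0, 1.0, 1.0)]
    params.cohort_effect = P.CohortEffect(1972.0, 1992.0, 1.0)
    params.uptake.base_rate = 0.0
    params.visit_rates.male = 0.3
    params.visit_rates.female = 0.3
    params.visit_rates.symptom_edges = [0.0]
    params.visit_rates.symptom_rates = [0.5]
    params.visit_rates.stage_symptom_rates = {s: 0.5 for s in
                                              ("in_situ", "I", "II", "III", "IV")}
    for h in params.histologies.values():
        h.detection = P.DetectionCurve(base=1.0, per_year=0.0, max_prob=1.0)
    params.period_scaling = P.PeriodScaling(1980.0, 2010.0, 1.0, 1.0)
    params.clinical_specificity = 1.0
    params.life_table = LifeTable(age_edges=[15.0, 90.0], male=[0.005], female=[0.005])
    return params


def _stress_multiprimary_params() -> P.ParameterSet:
    """Extreme hazards so individuals accumulate three or more primaries."""
    params = P.default_parameters()
    params.baseline_incidence.scale = 150.0
    params.visit_rates.male = 1.0
    params.visit_rates.female = 1.0
    for h in params.histologies.values():
        h.detection = P.DetectionCurve(base=1.0, per_year=0.0, max_prob=1.0)
    params.period_scaling = P.PeriodScaling(1980.0, 2010.0, 1.0, 1.0)
    params.life_table = LifeTable(age_edges=[15.0, 90.0], male=[0.001], female=[0.001])
    return params


def generate_fixture_bundle(scenario: str, seed: int, *,
                            target_n: int | None = None) -> FixtureBundle:
    """Build the named scenario's self-consistent bundle.

    Targets are the summaries of a cohort simulated at the bundled
    parameters with ``target_seed = seed`` (noise in the targets therefore
    varies with the seed while the generating parameters do not).
    """
    if scenario == "australia_like":
        params = P.default_parameters()
        n = target_n or 4000
    elif scenario == "calibration_demo":
        params = _calibration_demo_params()
        n = target_n or 800
    elif scenario == "stress_multiprimary":
        params = _stress_multiprimary_params()
        n = target_n or 500
    else:
        raise KeyError(f"unknown scenario {scenario!r}; available: "
                       + ", ".join(SCENARIOS))

    strata = StrataDefinition(age_edges=[15.0, 45.0, 65.0, 85.0]
                              if params.simulation.max_age >= 85.0
                              else [15.0, 35.0, params.simulation.max_age],
                              by_sex=True)
    cohort = simulate_cohort(params, n, seed)
    summaries = compute_summaries(cohort, strata)
    frame = summaries.dropna(subset=["value"]).copy()
    if scenario == "calibration_demo":
        # the demo exists to exercise 1-D recovery of the hazard scale;
        # incidence rates carry that signal, while the near-zero mortality
        # and rare-stage statistics only add heavy-tailed relative noise
        frame = frame[frame.statistic == "incidence"]
    frame["weight"] = 1.0
    rate_table = RegistryRateTable(frame.reset_index(drop=True))
    return FixtureBundle(
        scenario=scenario, seed=seed, params=params,
        life_table=params.life_table, rate_table=rate_table,
        targets=rate_table.to_targets(),
        tariff=params.economics.tariff, utilities=params.economics.utilities,
        strata=strata, target_seed=seed, target_n=n,
    )
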