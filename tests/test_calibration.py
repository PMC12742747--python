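"""Summary statistics, the ABC distance, ABC-SMC recovery and PSA."""

import math

import numpy as np
import pytest

from melanosim import simulate_cohort
from melanosim.calibration import (CalibrationError, CalibrationTarget,
                                   StrataDefinition, calibrate,
                                   compute_summaries, distance,
                                   probabilistic_sensitivity_analysis,
                                   second_primary_proportion)
from melanosim.engine import CohortResult, Event, EventType, LifeHistory
from melanosim.fixtures import generate_fixture_bundle
from melanosim.natural_history import Tumour
from melanosim.params import Prior


def _history(iid, sex, exit_age, dx=(), exit_cause="age_cap_exit",
             birth_year=1950.0):
    h = LifeHistory(individual_id=iid, sex=sex, birth_year=birth_year,
                    risk_group="average", entry_age=15.0)
    for k, (dx_age, stage) in enumerate(dx, start=1):
        t = Tumour(k, "superficial_spreading", emergence_age=dx_age - 1.0,
                   body_site="C44.5")
        t.diagnosed = True
        t.diagnosis_age = dx_age
        t.dwell_at_diagnosis = 1.0
        t.stage_at_diagnosis = stage
        t.breslow_category = "le_1mm" if stage in ("I", "II") else None
        t.behaviour_code = 2 if stage == "in_situ" else 3
        h.tumours.append(t)
        h.events.append(Event(EventType.DIAGNOSIS, dx_age,
                              {"tumour_index": k, "stage": stage}))
    h.exit_age = exit_age
    h.exit_cause = exit_cause
    h.events.append(Event(EventType[exit_cause.upper()], exit_age))
    h.events.sort(key=lambda e: e.age)
    return h


STRATA = StrataDefinition(age_edges=[15.0, 50.0, 85.0], by_sex=True)


def _value(summaries, statistic, **stratum):
    t = CalibrationTarget(statistic, stratum, value=0.0, weight=1.0)
    from melanosim.calibration import _lookup
    return _lookup(summaries, t)


def test_hand_enumerated_incidence_rate():
    """Three individuals, one diagnosis at age 40 (female, band 15-50):
    rate = 1 / person-years in that stratum x 1e5."""
    cohort = CohortResult([
        _history(0, "female", 85.0, dx=[(40.0, "I")]),
        _history(1, "female", 30.0, exit_cause="other_death"),
        _history(2, "male", 85.0),
    ], seed=0, n=3)
    s = compute_summaries(cohort, STRATA)
    py_female_young = (50.0 - 15.0) + (30.0 - 15.0)  # ids 0 and 1
    expected = 1 / py_female_young * 1e5
    assert _value(s, "incidence", age_low=15.0, age_high=50.0, sex="female") \
        == pytest.approx(expected)
    assert _value(s, "incidence", age_low=15.0, age_high=50.0, sex="male") == 0.0


def test_zero_melanoma_cohort_rates_and_missing_proportion():
    cohort = CohortResult([_history(0, "male", 85.0)], seed=0, n=1)
    s = compute_summaries(cohort, STRATA)
    assert _value(s, "incidence", age_low=15.0, age_high=50.0, sex="male") == 0.0
    assert math.isnan(_value(s, "second_primary_10y"))
    # empty stratum (no female person-time) is missing, not zero
    assert math.isnan(_value(s, "incidence", age_low=15.0, age_high=50.0,
                             sex="female"))


def test_rates_pool_additively_across_split_halves():
    a = [_history(0, "male", 85.0, dx=[(60.0, "I")]),
         _history(1, "male", 45.0, exit_cause="other_death")]
    b = [_history(2, "male", 85.0, dx=[(70.0, "II")]),
         _history(3, "male", 85.0)]
    pooled = compute_summaries(CohortResult(a + b, seed=0, n=4), STRATA)
    # hand enumeration: male 50-85 stratum has 3 x 35 person-years, 2 events
    assert _value(pooled, "incidence", age_low=50.0, age_high=85.0, sex="male") \
        == pytest.approx(2 / (3 * 35.0) * 1e5)


def test_second_primary_window_and_follow_up_rules():
    cohort = CohortResult([
        _history(0, "male", 85.0, dx=[(50.0, "I"), (55.0, "I")]),   # hit
        _history(1, "male", 85.0, dx=[(50.0, "I"), (75.0, "I")]),   # miss (>10y)
        _history(2, "male", 85.0, dx=[(50.0, "I")]),                # at risk
        _history(3, "male", 55.0, dx=[(50.0, "I")],
                 exit_cause="other_death"),                          # <10y follow-up
    ], seed=0, n=4)
    assert second_primary_proportion(cohort) == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------

def test_distance_identity_positivity_and_weighting():
    cohort = CohortResult([_history(0, "male", 85.0, dx=[(60.0, "I")])],
                          seed=0, n=1)
    s = compute_summaries(cohort, STRATA)
    targets = [CalibrationTarget("incidence",
                                 {"age_low": 50.0, "age_high": 85.0, "sex": "male"},
                                 value=_value(s, "incidence", age_low=50.0,
                                              age_high=85.0, sex="male"),
                                 weight=1.0)]
    assert distance(s, targets) == 0.0

    perturbed = s.copy()
    mask = perturbed.statistic == "incidence"
    perturbed.loc[mask, "value"] = perturbed.loc[mask, "value"] + 10.0
    d1 = distance(perturbed, targets)
    assert d1 > 0.0
    heavier = [CalibrationTarget(t.statistic, t.stratum, t.value, weight=2.0)
               for t in targets]
    assert distance(perturbed, heavier) == pytest.approx(2 * d1)


def test_distance_missing_stratum_names_target():
    cohort = CohortResult([_history(0, "male", 85.0)], seed=0, n=1)
    s = compute_summaries(cohort, STRATA)
    bad = [CalibrationTarget("incidence",
                             {"age_low": 90.0, "age_high": 95.0, "sex": "male"},
                             value=5.0)]
    with pytest.raises(KeyError, match="incidence"):
        distance(s, bad)


def test_target_invariants():
    with pytest.raises(ValueError):
        CalibrationTarget("incidence", {}, value=math.inf)
    with pytest.raises(ValueError):
        CalibrationTarget("incidence", {}, value=1.0, weight=0.0)


# ---------------------------------------------------------------------------
# ABC-SMC
# ---------------------------------------------------------------------------

def test_distance_grid_minimised_at_generating_scale():
    """Brute-force oracle: on a coarse grid of the baseline hazard scale the
    ABC distance is smallest at the value that generated the targets."""
    bundle = generate_fixture_bundle("calibration_demo", 21, target_n=1200)
    dists = {}
    for scale in (0.3, 1.0, 3.0):
        candidate = bundle.params.with_value("baseline_incidence.scale", scale)
        cohort = simulate_cohort(candidate, 1200, 99)
        dists[scale] = distance(compute_summaries(cohort, bundle.strata),
                                bundle.targets)
    assert min(dists, key=dists.get) == 1.0


def test_calibrate_recovers_scale_and_concentrates():
    bundle = generate_fixture_bundle("calibration_demo", 31, target_n=800)
    prior = Prior("baseline_incidence.scale", "uniform",
                  {"low": 0.3, "high": 3.0})
    history = []
    samples = calibrate(bundle.params, [prior], bundle.targets,
                        n_per_draw=400, population_size=16, n_generations=2,
                        budget=400, seed=31, strata=bundle.strata,
                        history_out=history)
    from melanosim.calibration import posterior_interval
    lo, hi = posterior_interval(samples, "baseline_incidence.scale")
    assert lo <= 1.0 <= hi
    medians = [float(np.median([s.distance for s in pop])) for pop in history]
    assert all(b <= a + 1e-12 for a, b in zip(medians, medians[1:]))
    # reproducibility from the seed
    again = calibrate(bundle.params, [prior], bundle.targets,
                      n_per_draw=400, population_size=16, n_generations=2,
                      budget=400, seed=31, strata=bundle.strata)
    assert [s.values for s in again] == [s.values for s in samples]


def test_degenerate_prior_returns_prior(default_params):
    bundle = generate_fixture_bundle("calibration_demo", 41, target_n=300)
    prior = Prior("baseline_incidence.scale", "normal",
                  {"mean": 1.0, "sd": 1e-9})
    samples = calibrate(bundle.params, [prior], bundle.targets,
                        n_per_draw=100, population_size=6, n_generations=1,
                        budget=100, seed=41, strata=bundle.strata)
    assert all(abs(s.values["baseline_incidence.scale"] - 1.0) < 1e-6
               for s in samples)


def test_budget_exhaustion_raises_with_diagnostics():
    bundle = generate_fixture_bundle("calibration_demo", 51, target_n=200)
    prior = Prior("baseline_incidence.scale", "uniform",
                  {"low": 0.5, "high": 2.0})
    with pytest.raises(CalibrationError, match="budget"):
        calibrate(bundle.params, [prior], bundle.targets,
                  n_per_draw=50, population_size=8, n_generations=3,
                  budget=10, seed=51, strata=bundle.strata)


def test_calibrate_requires_priors_and_targets(default_params):
    with pytest.raises(ValueError):
        calibrate(default_params, [], [], seed=0)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def test_psa_identical_policies_yield_zero_increments():
    from melanosim import default_policy
    from melanosim.calibration import PosteriorSample
    bundle = generate_fixture_bundle("calibration_demo", 61, target_n=100)
    pol = default_policy("organised_biennial")
    samples = [PosteriorSample({"baseline_incidence.scale": 1.0}, 0.0, 0)]
    frame = probabilistic_sensitivity_analysis(samples, bundle.params, pol,
                                               comparator_policy=pol,
                                               n_per_draw=150, seed=61)
    assert len(frame) == 1
    assert frame.incremental_cost.iloc[0] == 0.0
    assert frame.incremental_qaly.iloc[0] == 0.0


def test_psa_acceptability_is_mean_of_indicators():
    from melanosim import default_policy
    from melanosim.calibration import PosteriorSample
    bundle = generate_fixture_bundle("calibration_demo", 71, target_n=100)
    samples = [PosteriorSample({"baseline_incidence.scale": v}, 0.0, 0)
               for v in (0.6, 0.8, 1.0, 1.2, 1.4)]
    frame = probabilistic_sensitivity_analysis(
        samples, bundle.params, default_policy("organised_biennial"),
        n_per_draw=120, seed=71)
    assert len(frame) == 5
    by_hand = sum(frame.nmb > 0) / 5
    assert frame.cost_effective.mean() == pytest.approx(by_hand)
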