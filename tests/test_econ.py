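"""Discounting closed forms, hand-enumerated accrual, CEA decision rules,
overdiagnosis pairing and budget impact."""

import math

import pytest

from melanosim import default_parameters, default_policy, simulate_cohort
from melanosim.econ import (accrue, budget_impact, compare, discount,
                            overdiagnosis_estimate)
from melanosim.engine import CohortResult, Event, EventType, LifeHistory
from melanosim.natural_history import Tumour


@pytest.fixture(scope="module")
def econ_blocks(default_params):
    ec = default_params.economics
    return ec.tariff, ec.utilities


def _history(iid=0, exit_age=85.0, exit_cause="age_cap_exit", events=(),
             tumours=(), birth_year=1950.0):
    h = LifeHistory(individual_id=iid, sex="female", birth_year=birth_year,
                    risk_group="average", entry_age=15.0)
    h.events = sorted(list(events), key=lambda e: e.age)
    h.tumours = list(tumours)
    h.exit_age = exit_age
    h.exit_cause = exit_cause
    h.events.append(Event(EventType[exit_cause.upper()], exit_age))
    return h


def _dx_tumour(dx_age, stage, index=1):
    t = Tumour(index, "superficial_spreading", emergence_age=dx_age - 1.0,
               body_site="C44.5")
    t.diagnosed = True
    t.diagnosis_age = dx_age
    t.dwell_at_diagnosis = 1.0
    t.stage_at_diagnosis = stage
    t.breslow_category = "le_1mm" if stage in ("I", "II") else None
    t.behaviour_code = 2 if stage == "in_situ" else 3
    return t


# ---------------------------------------------------------------------------
# discounting
# ---------------------------------------------------------------------------

def test_discount_closed_forms():
    assert discount(100.0, 5.0, 0.0) == 100.0
    assert discount(100.0, 0.0, 0.05) == 100.0
    assert discount(100.0, 1.0, 0.05) == pytest.approx(100.0 / 1.05)
    assert discount(100.0, 10.0, 0.05) == pytest.approx(100.0 / 1.05 ** 10)
    with pytest.raises(ValueError):
        discount(100.0, -1.0, 0.05)


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

def test_event_free_lifetime_gives_seventy_undiscounted_life_years(econ_blocks):
    tariff, utilities = econ_blocks
    h = _history()
    cost, ly, qaly = accrue(h, tariff, utilities, rate=0.0)
    assert cost == 0.0
    assert ly == pytest.approx(70.0)
    assert qaly == pytest.approx(70.0 * utilities.well)


def test_every_skin_check_bears_the_keratinocyte_adjunct_once(econ_blocks):
    tariff, utilities = econ_blocks
    h = _history(events=[Event(EventType.CLINICIAN_VISIT, 40.0),
                         Event(EventType.ROUTINE_CHECK, 50.0)])
    cost, _, _ = accrue(h, tariff, utilities, rate=0.0)
    expected = (tariff.skin_check["opportunistic_visit"]
                + tariff.skin_check["routine_check"]
                + 2 * tariff.keratinocyte_adjunct_cost)
    assert cost == pytest.approx(expected)


def test_three_event_toy_history_matches_hand_total():
    """One visit at 40, a false positive at 40, a stage I diagnosis at 45,
    exit at 50, discounted at 5% from entry (age 15)."""
    p = default_parameters()
    tariff, utilities = p.economics.tariff, p.economics.utilities
    t = _dx_tumour(45.0, "I")
    h = _history(exit_age=50.0, exit_cause="other_death",
                 events=[Event(EventType.CLINICIAN_VISIT, 40.0),
                         Event(EventType.FALSE_POSITIVE, 40.0),
                         Event(EventType.DIAGNOSIS, 45.0,
                               {"tumour_index": 1, "stage": "I"})],
                 tumours=[t])
    r = 0.05
    cost, ly, qaly = accrue(h, tariff, utilities, rate=r)

    x = 1 + r
    hand_cost = ((tariff.skin_check["opportunistic_visit"]
                  + tariff.keratinocyte_adjunct_cost
                  + tariff.false_positive_workup) / x ** 25
                 + (tariff.diagnostic_excision
                    + tariff.treatment_initial["I"]) / x ** 30)
    annual = tariff.treatment_continuing["I"]
    hand_cost += annual * (x ** -30 - x ** -35) / math.log(x)
    assert cost == pytest.approx(hand_cost, abs=1e-9)

    w = utilities.by_stage["I"]
    seg = lambda a, b: (x ** -a - x ** -b) / math.log(x)
    assert ly == pytest.approx(seg(0, 35), abs=1e-9)
    assert qaly == pytest.approx(utilities.well * seg(0, 30) + w * seg(30, 35),
                                 abs=1e-9)


def test_discounting_and_utility_bounds_on_simulated_histories(default_params):
    tariff = default_params.economics.tariff
    utilities = default_params.economics.utilities
    cohort = simulate_cohort(default_params, 300, 19)
    for h in cohort.histories[:100]:
        c0, l0, q0 = accrue(h, tariff, utilities, rate=0.0)
        c5, l5, q5 = accrue(h, tariff, utilities, rate=0.05)
        assert c5 <= c0 + 1e-9
        assert l5 <= l0 + 1e-9
        assert q5 <= l5 + 1e-9  # weights <= 1 force QALY <= LY
        assert q0 <= l0 + 1e-9


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def test_identical_cohorts_compare_to_zero(econ_blocks, default_params):
    tariff, utilities = econ_blocks
    cohort = simulate_cohort(default_params, 200, 3)
    res = compare(cohort, cohort, tariff, utilities, 0.05, 50_000.0)
    assert res.incremental_cost == 0.0
    assert res.incremental_qaly == 0.0
    assert res.net_monetary_benefit == 0.0
    assert not res.icer_defined


def test_nmb_decision_boundary_and_icer_definition(econ_blocks):
    tariff, utilities = econ_blocks
    # craft per-capita differences by hand: strategy costs 50,000 more and
    # yields exactly one extra (undiscounted) QALY per person
    base = _history(exit_age=84.0, exit_cause="other_death")
    better = _history(exit_age=85.0,
                      events=[Event(EventType.FALSE_POSITIVE, 20.0)])
    a = CohortResult([better], seed=1, n=1)
    b = CohortResult([base], seed=1, n=1)
    res = compare(a, b, tariff, utilities, rate=0.0,
                  wtp=50_000.0)
    assert res.incremental_ly == pytest.approx(1.0)
    assert res.icer_per_qaly == pytest.approx(
        res.incremental_cost / res.incremental_qaly)
    assert res.net_monetary_benefit == pytest.approx(
        50_000.0 * res.incremental_qaly - res.incremental_cost)
    # NMB and ICER-vs-WTP agree for positive increments
    if res.incremental_cost > 0 and res.incremental_qaly > 0:
        assert (res.net_monetary_benefit > 0) == \
            (res.icer_per_qaly < 50_000.0)


def test_dominance_flags(econ_blocks):
    tariff, utilities = econ_blocks
    cheap_long = CohortResult([_history(exit_age=85.0)], seed=1, n=1)
    dear_short = CohortResult(
        [_history(exit_age=80.0, exit_cause="other_death",
                  events=[Event(EventType.FALSE_POSITIVE, 20.0)])],
        seed=1, n=1)
    res = compare(cheap_long, dear_short, tariff, utilities, 0.0, 50_000.0)
    assert res.dominant and not res.dominated
    res = compare(dear_short, cheap_long, tariff, utilities, 0.0, 50_000.0)
    assert res.dominated and not res.dominant


# ---------------------------------------------------------------------------
# overdiagnosis
# ---------------------------------------------------------------------------

def _paired(screen_dx, counter_dx):
    """Build paired 1-individual cohorts; screen_dx/counter_dx flag whether
    the single tumour is (screen-)diagnosed in each arm."""
    t1 = _dx_tumour(60.0, "I")
    t1.detection_channel = "organised_screen" if screen_dx else None
    t1.diagnosed = screen_dx
    h1 = _history(tumours=[t1] if screen_dx else [])
    t2 = _dx_tumour(70.0, "I")
    t2.diagnosed = counter_dx
    h2 = _history(tumours=[t2] if counter_dx else [])
    return (CohortResult([h1], seed=9, n=1), CohortResult([h2], seed=9, n=1))


def test_overdiagnosis_hand_paired_toy_counts():
    histories_s, histories_u = [], []
    # 10 individuals: 6 screen-detected, of which 2 lack a counterfactual
    # clinical diagnosis -> proportion 2/6
    for i in range(10):
        screen = i < 6
        counter = i not in (0, 1)
        t = _dx_tumour(60.0, "I")
        t.detection_channel = "organised_screen" if screen else "opportunistic_visit"
        hs = _history(iid=i, tumours=[t] if screen else [])
        tc = _dx_tumour(70.0, "I")
        tc.detection_channel = "opportunistic_visit"
        hu = _history(iid=i, tumours=[tc] if counter else [])
        histories_s.append(hs)
        histories_u.append(hu)
    screened = CohortResult(histories_s, seed=4, n=10)
    unscreened = CohortResult(histories_u, seed=4, n=10)
    assert overdiagnosis_estimate(screened, unscreened) == pytest.approx(2 / 6)


def test_overdiagnosis_pairing_contract():
    a, b = _paired(True, True)
    b.seed = 99
    with pytest.raises(ValueError):
        overdiagnosis_estimate(a, b)


def test_overdiagnosis_degenerate_extremes():
    """Guaranteed counterfactual diagnosis -> 0; impossible counterfactual
    diagnosis with certain early death -> 1 (simulated end to end)."""
    p = default_parameters()
    from melanosim.mortality import LifeTable
    for h in p.histologies.values():
        h.detection.base = 1.0
        h.detection.max_prob = 1.0
    p.body_sites.less_visible_factor = 1.0
    p.period_scaling.factor_start = 1.0
    p.baseline_incidence.scale = 30.0
    pol = default_policy("organised_biennial")

    # no other-cause death, visits certain to find tumours quickly
    p0 = p.copy()
    p0.visit_rates.male = 1.0
    p0.visit_rates.female = 1.0
    p0.life_table = LifeTable(age_edges=[15.0, 90.0], male=[0.0], female=[0.0])
    screened = simulate_cohort(p0, 400, 6, policy=pol)
    unscreened = simulate_cohort(p0, 400, 6)
    value = overdiagnosis_estimate(screened, unscreened)
    assert value == 0.0

    # clinical detection impossible, death very likely soon after screening
    p1 = p.copy()
    p1.visit_rates.male = 0.0
    p1.visit_rates.female = 0.0
    p1.visit_rates.stage_symptom_rates = {s: 0.0 for s in
                                          ("in_situ", "I", "II", "III", "IV")}
    p1.uptake.base_rate = 0.0
    p1.survival.stage_hazards = {s: [0.0, 0.0, 0.0]
                                 for s in ("in_situ", "I", "II", "III", "IV")}
    p1.life_table = LifeTable(age_edges=[15.0, 90.0], male=[0.01], female=[0.01])
    screened = simulate_cohort(p1, 1500, 8, policy=pol)
    unscreened = simulate_cohort(p1, 1500, 8)
    value = overdiagnosis_estimate(screened, unscreened)
    assert value == 1.0


# ---------------------------------------------------------------------------
# budget impact
# ---------------------------------------------------------------------------

def test_budget_impact_rows_identity_and_linearity(econ_blocks, default_params):
    tariff, _ = econ_blocks
    pol = default_policy("organised_biennial")
    strategy = simulate_cohort(default_params, 400, 12, policy=pol)
    comparator = simulate_cohort(default_params, 400, 12)

    table = budget_impact(strategy, comparator, 1_000_000, 2005, 5, tariff)
    assert len(table) == 5
    assert list(table.year) == [2005, 2006, 2007, 2008, 2009]

    same = budget_impact(strategy, strategy, 1_000_000, 2005, 5, tariff)
    assert (same.incremental_cost == 0.0).all()

    double = budget_impact(strategy, comparator, 2_000_000, 2005, 5, tariff)
    assert double.incremental_cost.values == pytest.approx(
        2 * table.incremental_cost.values)

    with pytest.raises(ValueError):
        budget_impact(strategy, comparator, 1e6, 2005, 0, tariff)
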